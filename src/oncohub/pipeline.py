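"""End-to-end orchestration: simulate -> preprocess -> network -> perturb ->
sga -> integrate -> survival -> synergy.

``run_all`` executes every stage in order on a synthetic study (or on
ingested files), collects the stage outputs in a ``PipelineResult``, and
optionally writes every table plus a run manifest (parameter snapshot,
output files, SHA-256 hashes, timestamps) to an output directory.  Any
stage failure raises with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Set

import pandas as pd

from . import io as ohio
from .config import PipelineConfig
from .containers import ExpressionCompendium, make_trait_table
from .integrate import (HubGeneSet, intersect_hub, km_estimate, logrank_test,
                        zscore_alteration)
from .network import (ModulePartition, adjacency, cluster_modules,
                      merge_modules, module_eigengenes,
                      module_trait_correlation, pick_soft_threshold,
                      tom_dissimilarity, AdjacencyParams)
from .perturb import control_filter, differential_expression, module_overlap
from .preprocess import preprocess_compendium
from .sga import augment_essential, call_hits, map_orthologs
from .simulate import SyntheticStudy, simulate_all
from .synergy import analyze_dose_response

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    config: PipelineConfig
    study: SyntheticStudy
    compendium: ExpressionCompendium = None
    excluded_samples: list = field(default_factory=list)
    adjacency_params: AdjacencyParams = None
    partition: ModulePartition = None
    eigengenes: pd.DataFrame = None
    module_trait: pd.DataFrame = None
    disease_module_labels: list = field(default_factory=list)
    target_result: object = None
    control_result: object = None
    filtered_regulated: Set[str] = field(default_factory=set)
    overlap_table: pd.DataFrame = None
    sga_hits: pd.DataFrame = None
    human_interactome: pd.DataFrame = None
    hub: HubGeneSet = None
    alteration: pd.DataFrame = None
    km_curves: dict = field(default_factory=dict)
    logrank: tuple = None
    synergy_fits: tuple = None
    synergy_report: pd.DataFrame = None
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


@_stage("network")
def _network_stage(cfg: PipelineConfig, comp: ExpressionCompendium):
    if cfg.beta == "auto":
        params = pick_soft_threshold(comp, grid=cfg.beta_grid,
                                     r2_target=cfg.r2_target,
                                     mode=cfg.network_mode)
    else:
        params = AdjacencyParams(beta=float(cfg.beta), mode=cfg.network_mode)
    adj = adjacency(comp, params)
    dissim = tom_dissimilarity(adj)
    partition = cluster_modules(dissim, min_size=cfg.min_module_size, cut=cfg.cut)
    partition = merge_modules(comp, partition, threshold=cfg.merge_threshold)
    eigen = module_eigengenes(comp, partition)
    traits = make_trait_table(comp.sample_meta, cfg.sim.phenotypes)
    mt = module_trait_correlation(eigen, traits)
    return params, partition, eigen, mt


def _disease_modules(cfg: PipelineConfig, partition: ModulePartition,
                     mt: pd.DataFrame) -> list[int]:
    """Module labels whose eigengene correlates positively with disease rank."""
    sel = mt[(mt["trait"] == cfg.trait_for_disease)
             & (mt["r"] > 0) & (mt["p"] < cfg.disease_p_threshold)]
    return sorted(int(m[2:]) for m in sel["module"])


def run_all(config: PipelineConfig | None = None,
            outdir=None,
            seed: int | None = None,
            study: SyntheticStudy | None = None) -> PipelineResult:
    """Run the full pipeline and return every stage output.

    A synthetic study is generated from ``config.sim`` (with ``seed``
    overriding its seed) unless a pre-built ``study`` is supplied.  When
    ``outdir`` is given, all inputs and outputs are written there together
    with a run manifest.
    """
    config = config or PipelineConfig()
    config.validate()
    if seed is not None:
        config = dataclasses.replace(
            config, sim=dataclasses.replace(config.sim, seed=int(seed)))

    t0 = time.time()
    stages: list[str] = []

    # --- simulate ----------------------------------------------------------
    if study is None:
        try:
            study = simulate_all(config.sim)
        except Exception as exc:
            raise StageError(f"stage 'simulate' failed: {exc}") from exc
    stages.append("simulate")
    res = PipelineResult(config=config, study=study)

    # --- preprocess --------------------------------------------------------
    try:
        comp, excluded = preprocess_compendium(
            study.compendium, sd_threshold=config.sd_threshold,
            scope=config.outlier_scope,
            skip_outlier_filter=config.skip_outlier_filter)
    except Exception as exc:
        raise StageError(f"stage 'preprocess' failed: {exc}") from exc
    res.compendium, res.excluded_samples = comp, excluded
    stages.append("preprocess")

    # --- network -----------------------------------------------------------
    params, partition, eigen, mt = _network_stage(config, comp)
    res.adjacency_params, res.partition = params, partition
    res.eigengenes, res.module_trait = eigen, mt
    res.disease_module_labels = _disease_modules(config, partition, mt)
    stages.append("network")

    # --- perturbation ------------------------------------------------------
    try:
        pert = study.perturbation
        target = differential_expression(pert.target_induced,
                                         pert.target_noninduced,
                                         alpha=config.perturb_alpha,
                                         adjust=config.perturb_adjust)
        control = differential_expression(pert.control_induced,
                                          pert.control_noninduced,
                                          alpha=config.perturb_alpha,
                                          adjust=config.perturb_adjust)
        filtered = control_filter(target, control)
        directions = target.table.loc[sorted(filtered), "direction"].to_dict()
        overlap = module_overlap(directions, partition)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'perturb' failed: {exc}") from exc
    res.target_result, res.control_result = target, control
    res.filtered_regulated, res.overlap_table = filtered, overlap
    stages.append("perturb")

    # --- SGA / interactome -------------------------------------------------
    try:
        hits = call_hits(study.sga, alpha=config.sga_alpha,
                         metric=config.fitness_metric)
        library = set(study.sga["strain"].unique())
        hits = augment_essential(hits, study.network, library,
                                 min_conf=config.min_conf,
                                 min_neighbors=config.min_neighbors)
        humans = map_orthologs(hits, study.orthologs)
    except Exception as exc:
        raise StageError(f"stage 'sga' failed: {exc}") from exc
    res.sga_hits, res.human_interactome = hits, humans
    stages.append("sga")

    # --- integrate ---------------------------------------------------------
    try:
        disease_genes: Set[str] = set()
        for lab in res.disease_module_labels:
            disease_genes |= set(partition.module_genes(lab))
        upregulated = {g for g in res.filtered_regulated
                       if target.table.loc[g, "direction"] == "down"}
        interactome_set = set(humans["human_gene"])
        hub = intersect_hub(
            disease_genes, upregulated, interactome_set,
            module_of_gene=partition.labels.to_dict(),
            perturb_direction=target.table["direction"].to_dict(),
            interactome_category=dict(zip(humans["human_gene"],
                                          humans["category"])),
        )
    except Exception as exc:
        raise StageError(f"stage 'integrate' failed: {exc}") from exc
    res.hub = hub
    stages.append("integrate")

    # --- survival ----------------------------------------------------------
    try:
        cohort = study.survival.set_index("patient")
        genes = [g for g in hub.genes if g in cohort.columns]
        if not genes:
            # fall back to the planted hub columns so the stage still runs
            genes = [c for c in cohort.columns
                     if c not in ("time", "event", "true_altered")]
        calls = zscore_alteration(cohort, genes,
                                  threshold=config.z_threshold,
                                  k=config.k_of_m, method=config.z_method)
        groups = calls["altered"].map({True: "altered", False: "normal"})
        if groups.nunique() == 2 and cohort["event"].sum() > 0:
            km = km_estimate(cohort["time"], cohort["event"], groups)
            lr = logrank_test(cohort["time"], cohort["event"], groups)
        else:
            km, lr = {}, None
            log.warning("survival stratification degenerate; log-rank skipped")
    except Exception as exc:
        raise StageError(f"stage 'survival' failed: {exc}") from exc
    res.alteration, res.km_curves, res.logrank = calls, km, lr
    stages.append("survival")

    # --- synergy -----------------------------------------------------------
    try:
        fit1, fit2, report = analyze_dose_response(
            study.dose_response, form=config.ci_form,
            additive_tol=config.additive_tol)
    except Exception as exc:
        raise StageError(f"stage 'synergy' failed: {exc}") from exc
    res.synergy_fits, res.synergy_report = (fit1, fit2), report
    stages.append("synergy")

    res.manifest = {
        "stages": stages,
        "seed": config.sim.seed,
        "parameters": config.to_dict(),
        "hub_genes": hub.genes,
        "n_modules": partition.n_modules,
        "elapsed_s": round(time.time() - t0, 3),
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if outdir is not None:
        _write_outputs(res, Path(outdir))
    return res


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_outputs(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    study = res.study
    files: dict[str, Path] = {}

    def save(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        files[name] = path

    save("expression.tsv", ohio.write_expression_tsv, study.compendium)
    save("sample_meta.tsv", ohio.write_sample_meta_tsv, study.compendium.sample_meta)
    save("traits.tsv", ohio.write_sample_meta_tsv, study.traits)
    save("growth.csv", ohio.write_growth_csv, study.sga)
    save("edges.tsv", ohio.write_edges_tsv, study.network)
    save("orthologs.tsv", ohio.write_orthologs_tsv, study.orthologs)
    save("survival.csv", ohio.write_survival_csv, study.survival)
    save("dose_response.csv", ohio.write_dose_response_csv, study.dose_response)
    save("truth.json", ohio.write_truth_json, study.truth)

    assign = pd.DataFrame({
        "module": res.partition.labels,
        "color": res.partition.labels.map(res.partition.module_colors),
    })
    save("module_assignment.tsv", ohio.write_matrix_tsv, assign)
    save("eigengenes.tsv",
         lambda df, p: df.to_csv(p, sep="\t", index_label="sample"),
         res.eigengenes)
    save("module_trait.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False),
         res.module_trait)
    save("perturbation_target.tsv", ohio.write_matrix_tsv, res.target_result.table)
    save("module_overlap.tsv",
         lambda df, p: df.to_csv(p, sep="\t", index_label="module"),
         res.overlap_table)
    save("sga_hits.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False),
         res.sga_hits)
    save("human_interactome.tsv",
         lambda df, p: df.to_csv(p, sep="\t", index=False), res.human_interactome)
    save("hub_evidence.tsv",
         lambda df, p: df.to_csv(p, sep="\t", index_label="gene"),
         res.hub.evidence)
    save("synergy_report.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False),
         res.synergy_report)
    if res.logrank is not None:
        stat, p = res.logrank
        ohio.atomic_write_json({"statistic": stat, "p": p},
                               outdir / "logrank.json")
        files["logrank.json"] = outdir / "logrank.json"
    for name, curve in res.km_curves.items():
        path = outdir / f"km_{name}.tsv"
        curve.to_csv(path, sep="\t", index=False)
        files[f"km_{name}.tsv"] = path

    res.manifest["files"] = {name: _sha256(p) for name, p in sorted(files.items())}
    ohio.atomic_write_json(res.manifest, outdir / "manifest.json")
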