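"""Synthetic study generator with machine-readable planted ground truth.

Every input the pipeline consumes is generated here under one seed:

* a multi-dataset expression compendium from a planted factor model whose
  disease-module activity rises linearly with phenotype rank;
* a two-construct knockdown experiment (target + control) whose regulated
  genes concentrate in one disease module, with control-condition artifacts
  to exercise the subtraction filter;
* a yeast deletion-screen growth dataset with planted suppressor/enhancer
  interactions under induced vs non-induced conditions;
* a scored protein-interaction network and an ortholog map that wire
  library-absent essential genes and project yeast hits onto human symbols;
* a survival cohort with an elevated hazard in patients whose hub-gene
  expression is altered;
* single-agent and combination dose-response tables from median-effect
  models under Loewe additivity or a planted interaction.

``PlantedTruth`` records what was planted; the generators assert the
three-way hub-gene set identity at build time so parameter-recovery tests
compare against a self-consistent truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Set

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import SimConfig
from .containers import ExpressionCompendium, make_trait_table


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    Module labels are 1..n_modules with 0 reserved for background genes.
    ``hub_genes`` is recomputable as
    regulated(down) & genes(disease modules) & human-orthologs(interactors | essentials)
    and the generator asserts that identity when the network layer is built.
    """

    module_of_gene: Dict[str, int] = field(default_factory=dict)
    disease_modules: FrozenSet[int] = frozenset()
    regulated_genes: Dict[str, str] = field(default_factory=dict)  # gene -> "up"/"down"
    control_artifact_genes: Set[str] = field(default_factory=set)
    interaction_genes: Dict[str, str] = field(default_factory=dict)  # yeast -> suppressor/enhancer
    essential_interactors: Set[str] = field(default_factory=set)
    interactome_human_genes: Set[str] = field(default_factory=set)
    hub_genes: Set[str] = field(default_factory=set)
    survival_altered_patients: Set[str] = field(default_factory=set)

    def disease_module_genes(self) -> Set[str]:
        return {g for g, m in self.module_of_gene.items() if m in self.disease_modules}

    def recompute_hub(self) -> Set[str]:
        down = {g for g, d in self.regulated_genes.items() if d == "down"}
        return down & self.disease_module_genes() & self.interactome_human_genes

    def assert_hub_identity(self) -> None:
        recomputed = self.recompute_hub()
        if recomputed != self.hub_genes:
            raise AssertionError(
                f"hub-gene identity violated: planted {sorted(self.hub_genes)} "
                f"vs recomputed {sorted(recomputed)}"
            )


@dataclass
class PerturbationExperiment:
    """Replicated induced/non-induced matrices for target and control constructs."""

    target_induced: pd.DataFrame
    target_noninduced: pd.DataFrame
    control_induced: pd.DataFrame
    control_noninduced: pd.DataFrame


# ---------------------------------------------------------------------------
# expression compendium
# ---------------------------------------------------------------------------

def generate_compendium(config: SimConfig):
    """Generate the multi-dataset expression compendium.

    Module-gene expression follows ``x = baseline + loading * score + batch + noise``
    where the latent module score of a disease module increases linearly
    with phenotype rank (slope ``trait_effect``); background genes carry
    only baseline, batch, and noise.

    Returns ``(compendium, trait_table, truth)``.
    """
    config.validate()
    rng = config.rng("compendium")

    phenos: List[str] = []
    for p in config.phenotypes:
        phenos.extend([p] * config.samples_per_phenotype[p])
    n_samples = len(phenos)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    datasets = [f"D{(i % config.n_datasets) + 1}" for i in range(n_samples)]
    meta = pd.DataFrame({"dataset": datasets, "phenotype": phenos}, index=sample_ids)
    ranks = np.array([list(config.phenotypes).index(p) for p in phenos], float)

    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    perm = rng.permutation(config.n_genes)
    labels = np.zeros(config.n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[perm[pos:pos + size]] = m
        pos += size

    # latent module scores over samples
    scores = rng.normal(size=(config.n_modules, n_samples))
    scores += np.asarray(config.trait_effect, float)[:, None] * ranks[None, :]

    lo, hi = config.loading_range
    loadings = rng.uniform(lo, hi, size=config.n_genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    batch = rng.normal(0.0, config.batch_sd, size=config.n_datasets)
    ds_idx = np.array([int(d[1:]) - 1 for d in datasets])

    x = baseline[:, None] + batch[ds_idx][None, :]
    x = x + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    module_rows = labels > 0
    x[module_rows] += loadings[module_rows, None] * scores[labels[module_rows] - 1]

    values = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    compendium = ExpressionCompendium(values, meta)
    traits = make_trait_table(meta, config.phenotypes)

    truth = PlantedTruth(
        module_of_gene={g: int(m) for g, m in zip(gene_ids, labels)},
        disease_modules=config.disease_modules,
    )
    return compendium, traits, truth


# ---------------------------------------------------------------------------
# knockdown perturbation experiment
# ---------------------------------------------------------------------------

def generate_perturbation(truth: PlantedTruth, config: SimConfig) -> PerturbationExperiment:
    """Generate target and control knockdown matrices (induced vs non-induced).

    Regulated genes in the targeted disease module shift DOWN upon induction
    of the target construct (they are upregulated by the factor being
    depleted); extra background genes shift in random directions; control
    artifact genes shift in BOTH constructs so the control filter has work
    to do.  ``truth.regulated_genes`` and ``truth.control_artifact_genes``
    are filled in.
    """
    config.validate()
    if config.perturb_replicates < 2:
        raise ValueError("at least 2 replicates per condition are required")
    target_label = config.perturb_module + 1
    if target_label not in truth.disease_modules:
        raise ValueError("perturb_module must index a disease module")
    rng = config.rng("perturbation")

    genes = sorted(truth.module_of_gene)
    module_genes = [g for g in genes if truth.module_of_gene[g] == target_label]
    background = [g for g in genes if truth.module_of_gene[g] == 0]

    n_reg = int(round(config.perturb_fraction * len(module_genes)))
    regulated = list(rng.choice(module_genes, size=n_reg, replace=False))
    truth.regulated_genes = {g: "down" for g in regulated}

    n_extra = min(config.extra_regulated_count, len(background))
    extras = list(rng.choice(background, size=n_extra, replace=False))
    for g in extras:
        truth.regulated_genes[g] = "down" if rng.random() < 0.5 else "up"

    candidates = [g for g in genes if g not in truth.regulated_genes]
    n_art = min(config.control_artifact_count, len(candidates))
    artifacts = list(rng.choice(candidates, size=n_art, replace=False))
    art_sign = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in artifacts}
    truth.control_artifact_genes = set(artifacts)

    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes)), index=genes
    )
    delta_target = pd.Series(0.0, index=genes)
    for g, d in truth.regulated_genes.items():
        delta_target[g] = -config.perturb_effect if d == "down" else config.perturb_effect
    delta_artifact = pd.Series(0.0, index=genes)
    for g, s in art_sign.items():
        delta_artifact[g] = s * config.perturb_effect
    # dox-driven artifacts appear in the induced state of BOTH constructs
    delta_target = delta_target + delta_artifact

    R = config.perturb_replicates
    cols = [f"rep{i + 1}" for i in range(R)]

    def matrix(shift: pd.Series) -> pd.DataFrame:
        noise = rng.normal(0.0, config.perturb_noise_sd, size=(len(genes), R))
        return pd.DataFrame(
            baseline.values[:, None] + shift.values[:, None] + noise,
            index=genes, columns=cols,
        )

    zero = pd.Series(0.0, index=genes)
    return PerturbationExperiment(
        target_induced=matrix(delta_target),
        target_noninduced=matrix(zero),
        control_induced=matrix(delta_artifact),
        control_noninduced=matrix(zero),
    )


# ---------------------------------------------------------------------------
# yeast deletion screen
# ---------------------------------------------------------------------------

def logistic_curve(t: np.ndarray, rate: float, carrying: float = 1.0, s0: float = 0.01) -> np.ndarray:
    """Three-parameter logistic colony size over time (hours)."""
    a = (carrying - s0) / s0
    return carrying / (1.0 + a * np.exp(-rate * t))


def generate_sga(truth: PlantedTruth, config: SimConfig) -> pd.DataFrame:
    """Generate replicated growth curves for every deletion strain.

    Each strain is grown under induced and non-induced conditions in
    ``sga_replicates`` replicates, sampled every ``sga_interval`` hours over
    ``sga_hours``.  Planted interactors have their growth rate multiplied by
    ``interaction_effect`` (suppressors, < 1) or its reciprocal (enhancers)
    only when induced; replicate noise is multiplicative lognormal.  Essential
    interactors are absent from the strain list (they enter through the
    interaction network only).  Returns a long-format DataFrame with columns
    strain, condition, replicate, time_h, size.
    """
    config.validate()
    if config.interaction_effect <= 0:
        raise ValueError("growth-rate multiplier must be positive")
    rng = config.rng("sga")

    strains = [f"Y{i + 1:04d}" for i in range(config.n_strains)]
    chosen = list(rng.choice(strains, size=config.n_interactors, replace=False))
    half = config.n_interactors // 2
    truth.interaction_genes = {}
    for i, g in enumerate(chosen):
        truth.interaction_genes[g] = "suppressor" if i < half else "enhancer"
    truth.essential_interactors = {f"E{i + 1:02d}" for i in range(config.n_essential)}

    times = np.arange(0.0, config.sga_hours + 1e-9, config.sga_interval)
    base_rate = rng.uniform(0.10, 0.14, size=config.n_strains)

    records = []
    for s_idx, strain in enumerate(strains):
        kind = truth.interaction_genes.get(strain)
        if kind == "suppressor":
            mult = config.interaction_effect
        elif kind == "enhancer":
            mult = 1.0 / config.interaction_effect
        else:
            mult = 1.0
        for condition, rate in (("non_induced", base_rate[s_idx]),
                                ("induced", base_rate[s_idx] * mult)):
            curve = logistic_curve(times, rate)
            for rep in range(1, config.sga_replicates + 1):
                factor = float(np.exp(rng.normal(0.0, config.sga_noise_sd)))
                records.append(pd.DataFrame({
                    "strain": strain,
                    "condition": condition,
                    "replicate": rep,
                    "time_h": times,
                    "size": curve * factor,
                }))
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# interaction network and ortholog map
# ---------------------------------------------------------------------------

def generate_ppi_and_orthologs(truth: PlantedTruth, config: SimConfig):
    """Generate the scored edge list and the yeast->human ortholog map.

    Each planted essential interactor connects to >= 2 planted primary hits
    at confidence >= 0.7; decoy edges (between library strains, and from
    decoy library-absent genes wired below the augmentation rule) are added
    so that exhaustive neighbour counting is exercised.  The ortholog map
    contains one-to-one, many-to-one (to produce the mixed category), and
    unmapped yeast genes.  Picks ``truth.hub_genes`` and asserts the
    three-way set-algebra identity.
    """
    config.validate()
    if not truth.interaction_genes:
        raise ValueError("generate_sga must run first (no planted interactors)")
    if not truth.regulated_genes:
        raise ValueError("generate_perturbation must run first (no regulated genes)")
    rng = config.rng("ppi")

    strains = [f"Y{i + 1:04d}" for i in range(config.n_strains)]
    interactors = sorted(truth.interaction_genes)
    essentials = sorted(truth.essential_interactors)

    edges: list[tuple[str, str, float]] = []
    # essential genes: >= 2 primary-hit neighbours at high confidence
    for e in essentials:
        n_nb = int(rng.integers(2, 5))
        for hit in rng.choice(interactors, size=n_nb, replace=False):
            edges.append((e, str(hit), float(rng.uniform(0.70, 1.0))))
        # plus a low-confidence distractor edge to a non-hit strain
        non_hit = [s for s in strains if s not in truth.interaction_genes]
        edges.append((e, str(rng.choice(non_hit)), float(rng.uniform(0.1, 0.69))))

    # decoy library-absent genes that must NOT be augmentable:
    # X..a: one primary hit at high confidence; X..b: two hits below threshold
    decoy_absent = []
    for i in range(2):
        ga = f"X{2 * i + 1:02d}"
        gb = f"X{2 * i + 2:02d}"
        decoy_absent += [ga, gb]
        edges.append((ga, str(rng.choice(interactors)), float(rng.uniform(0.70, 1.0))))
        for hit in rng.choice(interactors, size=2, replace=False):
            edges.append((gb, str(hit), float(rng.uniform(0.1, 0.699))))

    # random decoy edges among library strains (never augmentable: in library)
    seen = {(a, b) for a, b, _ in edges} | {(b, a) for a, b, _ in edges}
    n_added = 0
    while n_added < config.n_decoy_edges:
        a, b = rng.choice(strains, size=2, replace=False)
        a, b = str(a), str(b)
        if (a, b) in seen:
            continue
        seen.add((a, b))
        seen.add((b, a))
        edges.append((a, b, float(rng.uniform(0.1, 1.0))))
        n_added += 1

    network = pd.DataFrame(edges, columns=["geneA", "geneB", "confidence"])

    # --- hub-gene selection and ortholog map -------------------------------
    target_label = config.perturb_module + 1
    down_module = sorted(
        g for g, d in truth.regulated_genes.items()
        if d == "down" and truth.module_of_gene.get(g) == target_label
    )
    if len(down_module) < config.n_hub_genes:
        raise ValueError("not enough down-regulated module genes to pick hub genes")
    hubs = [str(g) for g in rng.choice(down_module, size=config.n_hub_genes, replace=False)]

    ortho: Dict[str, Set[str]] = {}

    def add(yeast: str, human: str) -> None:
        ortho.setdefault(yeast, set()).add(human)

    # hub 0: identified by both an essential and a non-essential hit (mixed/pink)
    add(essentials[0], hubs[0])
    add(interactors[0], hubs[0])
    # hub 1: essential-only evidence, if a second essential exists
    next_hub = 1
    if len(essentials) > 1 and config.n_hub_genes > 1:
        add(essentials[1], hubs[1])
        next_hub = 2
    # hub next: many-to-one from two non-essential hits
    i_ptr = 1
    if config.n_hub_genes > next_hub:
        add(interactors[i_ptr], hubs[next_hub])
        add(interactors[i_ptr + 1], hubs[next_hub])
        i_ptr += 2
        next_hub += 1
    # remaining hubs: one-to-one from non-essential hits
    for h in hubs[next_hub:]:
        add(interactors[i_ptr], h)
        i_ptr += 1

    # remaining interactors: decoy humans, many-to-one pairs, or unmapped
    decoy_idx = 1
    rest = interactors[i_ptr:]
    for j, y in enumerate(rest):
        if j % 4 == 3:
            continue  # unmapped yeast hit
        add(y, f"DEC_H{decoy_idx:02d}")
        if j % 4 == 1:
            decoy_idx += 1  # consecutive pairs share a decoy -> many-to-one
        else:
            decoy_idx += 1
    # remaining essentials map to decoy humans
    for e in essentials[2:]:
        add(e, f"DEC_H{decoy_idx:02d}")
        decoy_idx += 1
    # a few non-hit strains carry orthologs too (never enter the interactome)
    non_hits = [s for s in strains if s not in truth.interaction_genes]
    for y in non_hits[:10]:
        add(y, f"DEC_H{decoy_idx:02d}")
        decoy_idx += 1

    truth.hub_genes = set(hubs)
    truth.interactome_human_genes = set()
    for y in list(interactors) + list(essentials):
        truth.interactome_human_genes |= ortho.get(y, set())
    truth.assert_hub_identity()
    return network, ortho


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def _uniform_censor_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound b of U(0, b) censoring giving the target censored fraction.

    For T ~ Exp(rate) and C ~ U(0, b), P(censored) = P(C < T)
    = (1 - exp(-rate*b)) / (rate*b); the cohort-level fraction is the mean
    over patients' rates, decreasing in b, solved by bisection.
    """
    def frac(b: float) -> float:
        x = rates * b
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e6
    return brentq(lambda b: frac(b) - target, lo, hi)


def generate_survival(truth: PlantedTruth, config: SimConfig) -> pd.DataFrame:
    """Generate the per-patient survival cohort.

    Altered patients (fraction ``altered_fraction``) have hub-gene expression
    shifted by ``alteration_shift`` SDs and exponential event times with the
    hazard multiplied by ``hazard_ratio``; censoring times are independent
    uniform, scaled so the expected censored fraction matches
    ``censoring_rate``.  Columns: patient, time, event, one column per hub
    gene, plus a ``true_altered`` convenience flag.
    """
    config.validate()
    if not truth.hub_genes:
        raise ValueError("hub_genes is empty; run the upstream generators first")
    if config.hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    rng = config.rng("survival")

    patients = [f"P{i + 1:04d}" for i in range(config.n_patients)]
    n_alt = int(round(config.altered_fraction * config.n_patients))
    altered = set(rng.choice(patients, size=n_alt, replace=False))
    truth.survival_altered_patients = {str(p) for p in altered}

    hubs = sorted(truth.hub_genes)
    is_alt = np.array([p in altered for p in patients])
    expr = rng.normal(0.0, 1.0, size=(config.n_patients, len(hubs)))
    expr[is_alt] += config.alteration_shift

    rates = np.where(is_alt, config.baseline_hazard * config.hazard_ratio,
                     config.baseline_hazard)
    event_t = rng.exponential(1.0 / rates)
    if config.censoring_rate > 0:
        bound = _uniform_censor_bound(rates, config.censoring_rate)
        censor_t = rng.uniform(0.0, bound, size=config.n_patients)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
    else:
        time = event_t
        event = np.ones(config.n_patients, dtype=int)

    out = pd.DataFrame({"patient": patients, "time": time, "event": event})
    for j, g in enumerate(hubs):
        out[g] = expr[:, j]
    out["true_altered"] = is_alt.astype(int)
    return out


# ---------------------------------------------------------------------------
# dose-response surfaces
# ---------------------------------------------------------------------------

def median_effect_fa(dose: np.ndarray | float, m: float, dm: float) -> np.ndarray | float:
    """Affected fraction of the median-effect equation fa/(1-fa) = (D/Dm)^m."""
    r = (np.asarray(dose, float) / dm) ** m
    return r / (1.0 + r)


def loewe_combo_fa(d1: float, d2: float, m1: float, dm1: float,
                   m2: float, dm2: float, alpha: float = 1.0) -> float:
    """Solve the combined affected fraction under (generalized) Loewe additivity.

    Finds fa with d1/Dx1(fa) + d2/Dx2(fa) = alpha, where Dx is the
    median-effect effective dose.  alpha = 1 is exact Loewe additivity;
    alpha < 1 plants synergy, alpha > 1 antagonism.
    """
    if alpha <= 0:
        raise ValueError("interaction parameter must be > 0")

    def g(fa: float) -> float:
        ratio = fa / (1.0 - fa)
        dx1 = dm1 * ratio ** (1.0 / m1)
        dx2 = dm2 * ratio ** (1.0 / m2)
        return d1 / dx1 + d2 / dx2 - alpha

    return brentq(g, 1e-12, 1.0 - 1e-12)


def generate_dose_response(config: SimConfig) -> pd.DataFrame:
    """Generate single-agent and combination dose-response rows.

    Single-agent affected fractions follow the median-effect equation
    exactly (plus optional logit-scale noise); combination rows carry the fa
    solving the generalized Loewe equation with interaction parameter
    ``combo_alpha``.  Columns: drug1_dose, drug2_dose, fraction_affected.
    """
    config.validate()
    rng = config.rng("dose_response")
    (m1, dm1), (m2, dm2) = (config.drug_params[k] for k in sorted(config.drug_params))

    rows = []
    fold = 2.0 ** np.arange(-3, 4)
    for d in dm1 * fold:
        rows.append((d, 0.0, float(median_effect_fa(d, m1, dm1))))
    for d in dm2 * fold:
        rows.append((0.0, d, float(median_effect_fa(d, m2, dm2))))
    for a in (0.25, 0.5, 1.0, 2.0):
        for b in (0.25, 0.5, 1.0, 2.0):
            d1, d2 = a * dm1, b * dm2
            rows.append((d1, d2, loewe_combo_fa(d1, d2, m1, dm1, m2, dm2,
                                                config.combo_alpha)))
    table = pd.DataFrame(rows, columns=["drug1_dose", "drug2_dose", "fraction_affected"])

    if config.dose_noise_sd > 0:
        fa = table["fraction_affected"].to_numpy()
        logit = np.log10(fa / (1.0 - fa))
        logit += rng.normal(0.0, config.dose_noise_sd, size=len(fa))
        table["fraction_affected"] = 10.0 ** logit / (1.0 + 10.0 ** logit)
    return table


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """All generated inputs of one synthetic study plus the planted truth."""

    config: SimConfig
    compendium: ExpressionCompendium
    traits: pd.DataFrame
    perturbation: PerturbationExperiment
    sga: pd.DataFrame
    network: pd.DataFrame
    orthologs: Mapping[str, Set[str]]
    survival: pd.DataFrame
    dose_response: pd.DataFrame
    truth: PlantedTruth


def simulate_all(config: SimConfig) -> SyntheticStudy:
    """Run every generator in order under one seed and return the bundle."""
    compendium, traits, truth = generate_compendium(config)
    perturbation = generate_perturbation(truth, config)
    sga = generate_sga(truth, config)
    network, orthologs = generate_ppi_and_orthologs(truth, config)
    survival = generate_survival(truth, config)
    dose_response = generate_dose_response(config)
    return SyntheticStudy(config, compendium, traits, perturbation, sga,
                          network, orthologs, survival, dose_response, truth)
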