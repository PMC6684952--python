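"""File-format adapters shared by all pipeline stages.

All formats are plain text: TSV for matrices/tables with a header row,
long-format CSV for growth curves and cohorts, JSON for the planted truth
and run manifests, GMT for gene signatures.  Readers and writers round-trip
(read(write(x)) == x) for every type.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Mapping, Set

import pandas as pd

from .containers import ExpressionCompendium
from .simulate import PlantedTruth


class ParseError(ValueError):
    """Malformed input file."""


# --- expression matrices ---------------------------------------------------

def write_expression_tsv(expr: ExpressionCompendium, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path, sample_meta: pd.DataFrame | None = None) -> ExpressionCompendium:
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.name != "gene":
        raise ParseError(f"{path}: expected a 'gene' index column header")
    return ExpressionCompendium(values, sample_meta)


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# --- sample metadata / traits ----------------------------------------------

def write_sample_meta_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_sample_meta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# --- long-format growth curves ---------------------------------------------

GROWTH_COLUMNS = ["strain", "condition", "replicate", "time_h", "size"]


def write_growth_csv(curves: pd.DataFrame, path) -> None:
    curves[GROWTH_COLUMNS].to_csv(path, index=False)


def read_growth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: growth CSV missing columns {sorted(missing)}")
    return df


# --- edge lists and ortholog maps ------------------------------------------

def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges[["geneA", "geneB", "confidence"]].to_csv(path, sep="\t", index=False)


def read_edges_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"geneA", "geneB", "confidence"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: edge list missing columns {sorted(missing)}")
    return df


def write_orthologs_tsv(ortho: Mapping[str, Set[str]], path) -> None:
    rows = [(y, h) for y in sorted(ortho) for h in sorted(ortho[y])]
    pd.DataFrame(rows, columns=["yeast_gene", "human_gene"]).to_csv(
        path, sep="\t", index=False)


def read_orthologs_tsv(path) -> dict[str, Set[str]]:
    df = pd.read_csv(path, sep="\t")
    missing = {"yeast_gene", "human_gene"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: ortholog map missing columns {sorted(missing)}")
    out: dict[str, Set[str]] = {}
    for y, h in zip(df["yeast_gene"], df["human_gene"]):
        out.setdefault(str(y), set()).add(str(h))
    return out


# --- survival and dose-response --------------------------------------------

def write_survival_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_survival_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"patient", "time", "event"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: survival CSV missing columns {sorted(missing)}")
    return df


def write_dose_response_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_dose_response_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"drug1_dose", "drug2_dose", "fraction_affected"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: dose-response CSV missing columns {sorted(missing)}")
    return df


# --- GMT signatures ---------------------------------------------------------

def read_gmt(path) -> dict[str, Set[str]]:
    """GMT: one gene set per line as name <TAB> description <TAB> genes..."""
    sets: dict[str, Set[str]] = {}
    with open(path, encoding="utf8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, "
                                 "description and at least one gene")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Set[str]], path, description: str = "") -> None:
    with open(path, "w", encoding="utf8") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# --- planted truth ----------------------------------------------------------

def write_truth_json(truth: PlantedTruth, path) -> None:
    payload = {
        "module_of_gene": truth.module_of_gene,
        "disease_modules": sorted(truth.disease_modules),
        "regulated_genes": truth.regulated_genes,
        "control_artifact_genes": sorted(truth.control_artifact_genes),
        "interaction_genes": truth.interaction_genes,
        "essential_interactors": sorted(truth.essential_interactors),
        "interactome_human_genes": sorted(truth.interactome_human_genes),
        "hub_genes": sorted(truth.hub_genes),
        "survival_altered_patients": sorted(truth.survival_altered_patients),
    }
    atomic_write_json(payload, path)


def read_truth_json(path) -> PlantedTruth:
    with open(path, encoding="utf8") as fh:
        d = json.load(fh)
    return PlantedTruth(
        module_of_gene={g: int(m) for g, m in d["module_of_gene"].items()},
        disease_modules=frozenset(d["disease_modules"]),
        regulated_genes=dict(d["regulated_genes"]),
        control_artifact_genes=set(d["control_artifact_genes"]),
        interaction_genes=dict(d["interaction_genes"]),
        essential_interactors=set(d["essential_interactors"]),
        interactome_human_genes=set(d["interactome_human_genes"]),
        hub_genes=set(d["hub_genes"]),
        survival_altered_patients=set(d["survival_altered_patients"]),
    )


# --- JSON helpers -----------------------------------------------------------

def atomic_write_json(payload, path) -> None:
    """Write JSON atomically (tmp file + rename) so manifests are never partial."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_json(path):
    with open(path, encoding="utf8") as fh:
        return json.load(fh)
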