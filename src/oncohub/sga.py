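"""Deletion-screen analysis: growth fitness, hit calling, network augmentation.

A deletion strain is a genetic-interaction hit when expressing the query
factor changes its growth relative to its own non-induced behaviour.
Fitness is the trapezoidal area under the colony-size curve per replicate;
induced vs non-induced fitness is compared with a Welch test.  Significant
strains are labelled suppressor (growth reduced when induced) or enhancer
(growth increased).  Essential genes, absent from the deletion library,
join the hit list when they connect to at least ``min_neighbors`` primary
hits in a scored protein-interaction network at confidence >= ``min_conf``,
and all hits are finally projected onto human gene symbols through an
ortholog map.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CATEGORY_COLORS = {
    "suppressor": "red",
    "enhancer": "green",
    "essential": "white",
    "mixed": "pink",
}

_REQUIRED_COLUMNS = {"strain", "condition", "replicate", "time_h", "size"}


def _check_growth_frame(curves: pd.DataFrame) -> None:
    missing = _REQUIRED_COLUMNS - set(curves.columns)
    if missing:
        raise ValueError(f"growth dataset missing columns: {sorted(missing)}")


def growth_fitness(curves: pd.DataFrame, strain: str | None = None,
                   metric: str = "auc") -> pd.DataFrame:
    """Per-replicate, per-condition fitness of deletion strains.

    ``metric='auc'`` integrates colony size over time with the trapezoid
    rule; ``metric='endpoint'`` uses the final colony size.  Returns a tidy
    frame with columns strain, condition, replicate, fitness.
    """
    _check_growth_frame(curves)
    if strain is not None:
        curves = curves[curves["strain"] == strain]
        if curves.empty:
            raise ValueError(f"strain {strain!r} not present")
    if metric not in ("auc", "endpoint"):
        raise ValueError("metric must be 'auc' or 'endpoint'")

    rows = []
    for (st, cond, rep), grp in curves.groupby(
            ["strain", "condition", "replicate"], sort=True):
        t = grp["time_h"].to_numpy(float)
        y = grp["size"].to_numpy(float)
        order_idx = np.argsort(t, kind="mergesort")
        t, y = t[order_idx], y[order_idx]
        if len(t) < 2:
            raise ValueError(f"strain {st!r}: need at least 2 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"strain {st!r}: non-monotone time grid")
        fit = float(np.trapezoid(y, t)) if metric == "auc" else float(y[-1])
        rows.append({"strain": st, "condition": cond, "replicate": rep,
                     "fitness": fit})
    return pd.DataFrame(rows)


def call_hits(dataset: pd.DataFrame, alpha: float = 0.05,
              metric: str = "auc", adjust: str | None = None) -> pd.DataFrame:
    """Call suppressor/enhancer interaction hits from replicate growth curves.

    Per strain, replicate fitness under induced vs non-induced conditions is
    compared with a Welch test; significant strains are labelled by the
    fitness ratio (induced/non-induced): suppressor < 1, enhancer > 1.
    p-values are unadjusted by default ('bh' optional).  Returns all strains
    with columns gene, ratio, p, category (category is empty for
    non-significant strains); strains missing a condition are skipped with a
    warning.
    """
    fitness = growth_fitness(dataset, metric=metric)
    rows = []
    for strain, grp in fitness.groupby("strain", sort=True):
        ind = grp.loc[grp["condition"] == "induced", "fitness"].to_numpy()
        non = grp.loc[grp["condition"] == "non_induced", "fitness"].to_numpy()
        if len(ind) == 0 or len(non) == 0:
            log.warning("strain %s missing a condition; skipped", strain)
            continue
        ratio = float(ind.mean() / non.mean())
        if len(ind) < 2 or len(non) < 2:
            log.warning("strain %s has <2 replicates in a condition; skipped", strain)
            continue
        if np.var(ind) == 0 and np.var(non) == 0:
            p = 1.0 if ind.mean() == non.mean() else 0.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.ttest_ind(ind, non, equal_var=False)
            p = float(p)
        rows.append({"gene": strain, "ratio": ratio, "p": p})
    table = pd.DataFrame(rows, columns=["gene", "ratio", "p"])

    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        table["p"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError("adjust must be None or 'bh'")

    sig = table["p"] < alpha
    table["category"] = ""
    table.loc[sig & (table["ratio"] < 1), "category"] = "suppressor"
    table.loc[sig & (table["ratio"] > 1), "category"] = "enhancer"
    return table


def augment_essential(hits: pd.DataFrame, network: pd.DataFrame,
                      library: Set[str] | Sequence[str],
                      min_conf: float = 0.7,
                      min_neighbors: int = 2) -> pd.DataFrame:
    """Add library-absent genes wired to >= min_neighbors primary hits.

    Primary hits are the significant non-essential calls (suppressors and
    enhancers).  A gene absent from the deletion library is added with
    category 'essential' when it has at least ``min_neighbors`` distinct
    primary-hit neighbours through edges of confidence >= ``min_conf``
    (inclusive threshold).  Genes already in the library are never added.
    """
    if not (0.0 <= min_conf <= 1.0):
        raise ValueError("min_conf must be in [0, 1]")
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    library = set(library)
    primary = set(hits.loc[hits["category"].isin(["suppressor", "enhancer"]), "gene"])

    strong = network[network["confidence"] >= min_conf]
    neighbours: dict[str, set[str]] = {}
    for a, b in zip(strong["geneA"], strong["geneB"]):
        if a == b:
            continue
        if b in primary:
            neighbours.setdefault(a, set()).add(b)
        if a in primary:
            neighbours.setdefault(b, set()).add(a)

    added = sorted(
        g for g, nb in neighbours.items()
        if g not in library and len(nb) >= min_neighbors
    )
    extra = pd.DataFrame({
        "gene": added,
        "ratio": np.nan,
        "p": np.nan,
        "category": "essential",
    })
    return pd.concat([hits, extra], ignore_index=True)


def map_orthologs(hits: pd.DataFrame,
                  ortholog_map: Mapping[str, Set[str]]) -> pd.DataFrame:
    """Project yeast hits onto human gene symbols with merged categories.

    The union of human symbols over all categorized hits is returned; a
    human gene supported by both an essential and a non-essential yeast hit
    gets category 'mixed'.  Unmapped yeast genes are dropped (count logged).
    Returns a frame with columns human_gene, category, yeast_genes.
    """
    categorized = hits[hits["category"] != ""]
    human: dict[str, dict] = {}
    unmapped = 0
    for _, row in categorized.iterrows():
        targets = ortholog_map.get(row["gene"], set())
        if not targets:
            unmapped += 1
            continue
        for h in targets:
            rec = human.setdefault(h, {"categories": set(), "yeast": set()})
            rec["categories"].add(row["category"])
            rec["yeast"].add(row["gene"])
    if unmapped:
        log.info("%d hit yeast gene(s) had no human ortholog", unmapped)

    rows = []
    for h in sorted(human):
        cats = human[h]["categories"]
        essential = "essential" in cats
        non_essential = bool(cats & {"suppressor", "enhancer"})
        if essential and non_essential:
            category = "mixed"
        elif essential:
            category = "essential"
        elif cats == {"suppressor", "enhancer"}:
            category = "mixed"
        else:
            category = next(iter(cats))
        rows.append({
            "human_gene": h,
            "category": category,
            "yeast_genes": ",".join(sorted(human[h]["yeast"])),
        })
    out = pd.DataFrame(rows, columns=["human_gene", "category", "yeast_genes"])
    out.attrs["n_unmapped"] = unmapped
    return out
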