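"""Evidence integration and clinical validation.

Intersects the three evidence layers (disease-module membership, regulation
by the perturbed factor, membership in the functional interactome) into a
hub gene set, then validates it: z-score alteration calls per patient,
Kaplan-Meier survival stratification with a log-rank test, marker-quartile
expression comparison (Mann-Whitney), and pairwise co-expression (Spearman
plus Fisher's exact test on dichotomized alteration status).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class HubGeneSet:
    """Genes supported by all three evidence layers, with provenance."""

    genes: list[str]
    evidence: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes)
        if self.evidence is None:
            self.evidence = pd.DataFrame(index=self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def as_set(self) -> Set[str]:
        return set(self.genes)


def intersect_hub(
    disease_module_genes: Set[str],
    upregulated_by_factor: Set[str],
    interactome_humans: Set[str],
    module_of_gene: Mapping[str, int] | None = None,
    perturb_direction: Mapping[str, str] | None = None,
    interactome_category: Mapping[str, str] | None = None,
) -> HubGeneSet:
    """Three-way intersection of the evidence layers with provenance attached.

    An empty intersection is a valid outcome (returned empty, logged).
    """
    disease_module_genes = set(disease_module_genes)
    upregulated_by_factor = set(upregulated_by_factor)
    interactome_humans = set(interactome_humans)
    genes = sorted(disease_module_genes & upregulated_by_factor & interactome_humans)
    if not genes:
        log.info("hub intersection is empty")
    evidence = pd.DataFrame(index=genes)
    evidence["module"] = [
        (module_of_gene or {}).get(g, np.nan) for g in genes]
    evidence["perturbation"] = [
        (perturb_direction or {}).get(g, "down-upon-knockdown") for g in genes]
    evidence["interactome"] = [
        (interactome_category or {}).get(g, "hit") for g in genes]
    return HubGeneSet(genes=genes, evidence=evidence)


def _zscores(expr: pd.DataFrame, method: str) -> pd.DataFrame:
    """Per-gene standardization across patients.

    ``method='robust'`` (default) centers on the median and scales by
    1.4826*MAD, which stays calibrated when an altered subpopulation shifts
    the cohort mean and inflates its SD; ``method='mean'`` uses cohort
    mean/SD.
    """
    if method == "mean":
        center = expr.mean(axis=0)
        scale = expr.std(axis=0, ddof=1)
    elif method == "robust":
        center = expr.median(axis=0)
        scale = 1.4826 * (expr - expr.median(axis=0)).abs().median(axis=0)
    else:
        raise ValueError("method must be 'robust' or 'mean'")
    return (expr - center) / scale


def zscore_alteration(
    cohort: pd.DataFrame,
    geneset: HubGeneSet | Sequence[str],
    threshold: float = 1.96,
    k: int | None = None,
    method: str = "robust",
) -> pd.DataFrame:
    """Per-patient alteration calls from gene-level expression z-scores.

    A gene counts as upregulated in a patient when its z-score >= threshold;
    a patient is 'altered' when at least ``k`` genes are upregulated
    (default: all genes of the set).  Zero-scale genes are excluded from the
    rule with a warning (an explicit ``k`` is capped at the usable gene
    count).  Returns a frame indexed by patient with per-gene z columns,
    ``n_up``, and the boolean ``altered``.
    """
    genes = list(geneset.genes if isinstance(geneset, HubGeneSet) else geneset)
    missing = [g for g in genes if g not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing hub gene columns: {missing}")
    expr = cohort[genes].astype(float)
    z = _zscores(expr, method)
    usable = [g for g in genes if np.isfinite(z[g]).all() and expr[g].nunique() > 1]
    dropped = sorted(set(genes) - set(usable))
    if dropped:
        log.warning("genes excluded from alteration rule (degenerate scale): %s",
                    dropped)
    if not usable:
        raise ValueError("no usable genes for the alteration rule")
    m = len(usable)
    k_eff = m if k is None else min(int(k), m)
    if k is not None and int(k) <= 0:
        k_eff = 0

    out = z.copy()
    out["n_up"] = (z[usable] >= threshold).sum(axis=1)
    out["altered"] = out["n_up"] >= k_eff
    out.attrs["threshold"] = threshold
    out.attrs["k"] = k_eff
    out.attrs["m"] = m
    return out


def km_estimate(times, events, groups) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group (right-censoring honoured).

    Returns, per group, a frame with columns time, survival, at_risk; each
    curve starts at S(0) = 1.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    if np.any(times < 0):
        raise ValueError("negative survival times")
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        table = pd.DataFrame({
            "time": sf.index.to_numpy(float),
            "survival": sf.iloc[:, 0].to_numpy(float),
            "at_risk": kmf.event_table["at_risk"].reindex(sf.index).to_numpy(float),
        })
        out[str(g)] = table.reset_index(drop=True)
    return out


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Uses the observed-minus-expected statistic with hypergeometric variance
    at each distinct event time (1 degree of freedom).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValueError("exactly 2 groups are required")
    for g in uniq:
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")
    if events.sum() == 0:
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def group_compare_expression(
    expr: pd.DataFrame,
    marker: str | pd.Series,
    geneset: HubGeneSet | Sequence[str],
    method: str = "auto",
) -> pd.DataFrame:
    """Marker-top-quartile vs rest comparison per gene (two-sided Mann-Whitney).

    Samples are split at the marker's 75th percentile; the high group is
    strictly above it (deterministic tie policy).  ``expr`` is samples x
    genes.  Returns per-gene U statistic, p-value, and group means.
    """
    if expr.shape[0] < 8:
        raise ValueError("need at least 8 samples")
    marker_values = expr[marker] if isinstance(marker, str) else marker.loc[expr.index]
    q75 = float(np.quantile(marker_values.to_numpy(float), 0.75))
    high = marker_values > q75
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("degenerate marker split (all samples on one side)")

    genes = list(geneset.genes if isinstance(geneset, HubGeneSet) else geneset)
    rows = []
    for g in genes:
        x = expr.loc[high, g].to_numpy(float)
        y = expr.loc[~high, g].to_numpy(float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            u, p = len(x) * len(y) / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append({"gene": g, "U": float(u), "p": float(p),
                     "mean_high": float(x.mean()), "mean_rest": float(y.mean())})
    return pd.DataFrame(rows).set_index("gene")


def pairwise_coexpression(
    expr: pd.DataFrame,
    geneset: HubGeneSet | Sequence[str],
    z_threshold: float = 1.96,
    method: str = "robust",
) -> pd.DataFrame:
    """Pairwise Spearman correlation plus Fisher's exact test on alteration calls.

    For each gene pair the Spearman rho/p over samples is reported together
    with a two-sided Fisher's exact test on the 2x2 table of dichotomized
    (z >= threshold) upregulation status.  Constant genes yield missing
    rows.  ``expr`` is samples x genes.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    genes = list(geneset.genes if isinstance(geneset, HubGeneSet) else geneset)
    z = _zscores(expr[genes].astype(float), method)
    up = z >= z_threshold

    rows = []
    for i, gi in enumerate(genes):
        for gj in genes[i + 1:]:
            xi = expr[gi].to_numpy(float)
            xj = expr[gj].to_numpy(float)
            if np.all(xi == xi[0]) or np.all(xj == xj[0]):
                log.warning("constant gene in pair (%s, %s); reported missing", gi, gj)
                rows.append({"gene_a": gi, "gene_b": gj, "rho": np.nan,
                             "rho_p": np.nan, "fisher_p": np.nan})
                continue
            rho, rho_p = stats.spearmanr(xi, xj)
            a = int((up[gi] & up[gj]).sum())
            b = int((up[gi] & ~up[gj]).sum())
            c = int((~up[gi] & up[gj]).sum())
            d = int((~up[gi] & ~up[gj]).sum())
            _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({"gene_a": gi, "gene_b": gj, "rho": float(rho),
                         "rho_p": float(rho_p), "fisher_p": float(fisher_p)})
    return pd.DataFrame(rows)
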