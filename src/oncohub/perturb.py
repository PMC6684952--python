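"""Knockdown transcriptome analysis and module mapping.

Identifies genes regulated by a transcription-factor perturbation (Welch
test per gene, induced vs non-induced), removes genes that also respond in
the control construct (vehicle/induction artifacts), and maps the remaining
regulated genes onto co-expression modules with hypergeometric enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import ModulePartition


@dataclass
class PerturbationResult:
    """Per-gene differential statistics for one construct.

    ``table`` has one row per gene with columns delta (induced minus
    non-induced mean), stat, p, direction ('down' = expression decreased
    upon induction of the knockdown, i.e. the gene is upregulated by the
    depleted factor).
    """

    table: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant_set(self) -> Set[str]:
        return set(self.table.index[self.table["p"] < self.alpha])

    def regulated(self, direction: str | None = None) -> Set[str]:
        mask = self.table["p"] < self.alpha
        if direction is not None:
            mask &= self.table["direction"] == direction
        return set(self.table.index[mask])


def differential_expression(
    induced: pd.DataFrame,
    noninduced: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> PerturbationResult:
    """Per-gene Welch two-sample test, induced vs non-induced replicates.

    p-values are unadjusted by default (mirroring the p < 0.05 convention of
    the emulated study); ``adjust='bh'`` applies Benjamini-Hochberg before
    thresholding.  Genes with zero variance in both groups and equal means
    get p = 1.
    """
    if not induced.index.equals(noninduced.index):
        raise ValueError("gene sets of the two conditions differ")
    if induced.shape[1] < 2 or noninduced.shape[1] < 2:
        raise ValueError("need at least 2 replicates per condition")

    a = induced.to_numpy(float)
    b = noninduced.to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    delta = a.mean(axis=1) - b.mean(axis=1)
    # degenerate rows: zero variance in both groups
    degenerate = np.isnan(p)
    p = np.where(degenerate & (delta == 0), 1.0, p)
    p = np.where(degenerate & (delta != 0), 0.0, p)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)

    if adjust == "bh":
        p = multipletests(p, method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError("adjust must be None or 'bh'")

    table = pd.DataFrame({
        "delta": delta,
        "stat": t,
        "p": p,
        "direction": np.where(delta < 0, "down", "up"),
    }, index=induced.index)
    return PerturbationResult(table=table, alpha=alpha)


def control_filter(target: PerturbationResult,
                   control_result: PerturbationResult) -> Set[str]:
    """Remove control-construct-regulated genes from the target hit list.

    Returns target.significant_set minus control.significant_set; both
    results must cover the same gene universe.
    """
    if set(target.table.index) != set(control_result.table.index):
        raise ValueError("target and control results cover different gene universes")
    return target.significant_set - control_result.significant_set


def module_overlap(regulated: Mapping[str, str],
                   partition: ModulePartition) -> pd.DataFrame:
    """Distribute regulated genes over modules with enrichment statistics.

    ``regulated`` maps gene -> direction ('up'/'down').  For each module the
    up/down counts, the regulated fraction, and a one-sided hypergeometric
    over-representation p-value are reported; the universe is every gene
    carried by the partition (including unassigned genes).
    """
    universe = set(partition.labels.index)
    reg = {g: d for g, d in regulated.items() if g in universe}
    n_universe = len(universe)
    n_reg = len(reg)
    rows = []
    for lab in partition.module_labels():
        genes = set(partition.module_genes(lab))
        hits = {g: reg[g] for g in genes & set(reg)}
        k = len(hits)
        n_down = sum(1 for d in hits.values() if d == "down")
        p = float(stats.hypergeom.sf(k - 1, n_universe, n_reg, len(genes)))
        rows.append({
            "module": lab,
            "color": partition.module_colors[lab],
            "size": len(genes),
            "n_regulated": k,
            "n_up": k - n_down,
            "n_down": n_down,
            "fraction": k / len(genes),
            "fraction_down": n_down / len(genes),
            "p_enrichment": p,
        })
    return pd.DataFrame(rows).set_index("module")


def signature_cross_tabulation(signature: Set[str],
                               partition: ModulePartition) -> pd.Series:
    """Fraction of each module covered by an external gene signature."""
    sig = set(signature)
    out = {}
    for lab in partition.module_labels():
        genes = set(partition.module_genes(lab))
        out[lab] = len(genes & sig) / len(genes)
    return pd.Series(out, name="fraction")
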