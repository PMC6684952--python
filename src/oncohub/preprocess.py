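"""Compendium assembly: outlier exclusion, quantile normalization, combination."""

from __future__ import annotations

import logging
from typing import List, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionCompendium

log = logging.getLogger(__name__)


def sample_outlier_filter(
    expr: ExpressionCompendium, sd_threshold: float = 2.5
) -> tuple[ExpressionCompendium, List[str]]:
    """Exclude samples whose mean inter-sample correlation is anomalously low.

    For each sample the mean Pearson correlation to all other samples is
    computed; samples falling below (grand mean - sd_threshold * SD) are
    excluded in a single pass.  When the SD of mean correlations is zero
    (e.g. identical samples) nothing is excluded.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be > 0")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for outlier filtering")
    if not np.isfinite(sd_threshold):
        return expr.copy(), []

    corr = np.corrcoef(expr.values.to_numpy().T)
    n = corr.shape[0]
    mean_corr = (corr.sum(axis=1) - 1.0) / (n - 1)
    sd = float(np.std(mean_corr, ddof=1))
    if sd == 0.0:
        return expr.copy(), []
    cutoff = float(np.mean(mean_corr)) - sd_threshold * sd
    keep = mean_corr >= cutoff
    if not keep.any():
        raise ValueError("outlier filter would exclude every sample")
    excluded = [s for s, k in zip(expr.sample_ids, keep) if not k]
    if excluded:
        log.info("outlier filter excluded %d sample(s): %s", len(excluded), excluded)
    kept_ids = [s for s, k in zip(expr.sample_ids, keep) if k]
    return expr.subset_samples(kept_ids), excluded


def quantile_normalize(expr: ExpressionCompendium) -> ExpressionCompendium:
    """Force every sample onto the mean empirical distribution.

    After normalization each sample's sorted value vector equals the
    across-sample mean of sorted vectors; tied values within a sample
    receive the mean of the reference values their ranks span, and the
    gene-wise rank order within each sample is preserved.
    """
    x = expr.values.to_numpy(float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # ties: average the reference values spanned by each tied group
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        groups = np.split(order, boundaries)
        for grp in groups:
            if len(grp) > 1:
                assigned[grp] = assigned[grp].mean()
        out[:, j] = assigned
    values = pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids)
    return ExpressionCompendium(values, expr.sample_meta.copy())


def combine_datasets(datasets: Sequence[ExpressionCompendium],
                     labels: Sequence[str] | None = None) -> ExpressionCompendium:
    """Column-concatenate datasets restricted to their shared gene set.

    Gene order follows the first dataset; sample order is stable across
    inputs.  ``sample_meta`` records the source dataset (existing
    ``dataset`` columns are preserved, otherwise ``labels`` or positional
    names are used).
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    shared = datasets[0].gene_ids
    for d in datasets[1:]:
        shared = shared.intersection(d.gene_ids)
    if len(shared) == 0:
        raise ValueError("empty gene-identifier intersection across datasets")
    shared = [g for g in datasets[0].gene_ids if g in set(shared)]

    if labels is None:
        labels = [f"dataset{i + 1}" for i in range(len(datasets))]
    blocks, metas = [], []
    for d, lab in zip(datasets, labels):
        blocks.append(d.values.loc[shared])
        meta = d.sample_meta.copy()
        if "dataset" not in meta.columns:
            meta["dataset"] = lab
        metas.append(meta)
    values = pd.concat(blocks, axis=1)
    meta = pd.concat(metas, axis=0)
    if values.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers across datasets")
    return ExpressionCompendium(values, meta)


def preprocess_compendium(
    expr: ExpressionCompendium,
    sd_threshold: float = 2.5,
    scope: str = "per_dataset",
    skip_outlier_filter: bool = False,
) -> tuple[ExpressionCompendium, List[str]]:
    """Outlier-filter (per source dataset by default), combine, quantile normalize."""
    excluded: List[str] = []
    if skip_outlier_filter:
        combined = expr.copy()
    elif scope == "per_dataset" and "dataset" in expr.sample_meta.columns:
        parts = []
        for _, meta in expr.sample_meta.groupby("dataset", sort=False):
            sub = expr.subset_samples(list(meta.index))
            filt, exc = sample_outlier_filter(sub, sd_threshold)
            parts.append(filt)
            excluded.extend(exc)
        combined = combine_datasets(parts)
        # restore original stable sample order
        order = [s for s in expr.sample_ids if s in set(combined.sample_ids)]
        combined = combined.subset_samples(order)
    else:
        combined, excluded = sample_outlier_filter(expr, sd_threshold)
    return quantile_normalize(combined), excluded
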