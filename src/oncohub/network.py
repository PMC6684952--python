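"""Weighted co-expression network: soft threshold, TOM, modules, eigengenes.

The construction follows the classic weighted-network recipe: a Pearson
correlation matrix is raised elementwise to a soft-threshold power beta
chosen by the scale-free topology criterion, converted to a topological
overlap matrix (TOM), and 1 - TOM is clustered with average linkage.
Branches of at least ``min_size`` genes become modules; each module is
summarized by its eigengene (first principal component of the standardized
module submatrix) and highly similar modules are merged by eigengene
dissimilarity.  Module eigengenes are then correlated with sample traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionCompendium

log = logging.getLogger(__name__)

# stable arbitrary module colour names, assigned by decreasing module size;
# label 0 ("grey") is reserved for unassigned genes
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)

DEFAULT_BETA_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


@dataclass
class AdjacencyParams:
    """Soft-threshold exponent and network sign mode."""

    beta: float
    mode: str = "unsigned"
    fit_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.mode not in ("unsigned", "signed"):
            raise ValueError("mode must be 'unsigned' or 'signed'")


@dataclass
class ModulePartition:
    """Per-gene module labels; 0 is reserved for unassigned ('grey') genes."""

    labels: pd.Series  # gene -> int label
    min_size: int = 30
    module_colors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        if not self.module_colors:
            self.module_colors = {0: "grey"}
            for lab in self.module_labels():
                self.module_colors[lab] = MODULE_COLORS[(lab - 1) % len(MODULE_COLORS)]

    def module_labels(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def module_genes(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()

    @property
    def n_modules(self) -> int:
        return len(self.module_labels())


def _correlation(values: np.ndarray) -> np.ndarray:
    """Gene x gene Pearson correlation; zero-variance genes get 0 correlations."""
    sd = values.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    if degenerate.any():
        log.warning("%d zero-variance gene(s): correlations set to 0", degenerate.sum())
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.nan_to_num(corr, nan=0.0)
    return corr


def _as_matrix(expr) -> tuple[np.ndarray, pd.Index]:
    if isinstance(expr, ExpressionCompendium):
        return expr.values.to_numpy(float), expr.gene_ids
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(float), expr.index
    arr = np.asarray(expr, float)
    return arr, pd.RangeIndex(arr.shape[0])


def adjacency(expr, params: AdjacencyParams) -> pd.DataFrame:
    """Soft-thresholded adjacency: |r|^beta (unsigned) or ((1+r)/2)^beta (signed)."""
    values, genes = _as_matrix(expr)
    corr = _correlation(values)
    if params.mode == "unsigned":
        adj = np.abs(corr) ** params.beta
    else:
        adj = ((1.0 + corr) / 2.0) ** params.beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=genes, columns=genes)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index: R^2 of log-log degree fit, signed by slope.

    Connectivities are split into equal-width bins; log10(frequency) is
    regressed on log10(mean connectivity per bin) and the R^2 is multiplied
    by the sign of the negative slope (a positive index requires the
    decreasing degree distribution of scale-free graphs).
    """
    k = np.asarray(k, float)
    k = k[k > 0]
    if k.size < n_bins or np.allclose(k, k[0]):
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3 or np.allclose(ys, ys[0]):
        return float("nan")
    res = stats.linregress(xs, ys)
    return float(res.rvalue ** 2 * (1.0 if res.slope < 0 else -1.0))


def pick_soft_threshold(
    expr,
    grid: Sequence[float] = DEFAULT_BETA_GRID,
    r2_target: float = 0.8,
    mode: str = "unsigned",
) -> AdjacencyParams:
    """Choose the soft-threshold exponent by the scale-free topology criterion.

    Returns the smallest beta in the grid whose fit index reaches
    ``r2_target``; if none does (or the fit is degenerate), the beta
    maximizing the fit is returned with a warning (falling back to the
    largest beta when every fit is undefined).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("beta grid must be nonempty")
    values, _ = _as_matrix(expr)
    if values.shape[0] < 20:
        raise ValueError("need at least 20 genes to assess scale-free topology")
    corr = _correlation(values)
    base = np.abs(corr) if mode == "unsigned" else (1.0 + corr) / 2.0

    rows = []
    for beta in grid:
        adj = base ** float(beta)
        k = adj.sum(axis=0) - 1.0  # exclude the diagonal contribution
        fit = scale_free_fit(k)
        rows.append({"beta": float(beta), "fit": fit, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)

    valid = table.dropna(subset=["fit"])
    if valid.empty:
        log.warning("scale-free fit undefined for every beta; using max beta")
        chosen = max(grid)
    else:
        passing = valid[valid["fit"] >= r2_target]
        if not passing.empty:
            chosen = float(passing["beta"].iloc[0])
        else:
            chosen = float(valid.loc[valid["fit"].idxmax(), "beta"])
            log.warning("no beta reached fit %.2f; using beta=%g (max fit %.3f)",
                        r2_target, chosen, valid["fit"].max())
    return AdjacencyParams(beta=float(chosen), mode=mode, fit_table=table)


def topological_overlap(adj) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric adjacency with entries in [0,1].

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i, j and k_i the connectivity of i
    excluding itself; the diagonal is 1.
    """
    if isinstance(adj, pd.DataFrame):
        genes = adj.index
        a = adj.to_numpy(float)
    else:
        a = np.asarray(adj, float)
        genes = pd.RangeIndex(a.shape[0])
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be a symmetric square matrix")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")

    d = np.diag(a).copy()
    shared = a @ a
    # remove the u = i and u = j terms from the shared-neighbour sum
    shared -= d[:, None] * a
    shared -= a * d[None, :]
    k = a.sum(axis=0) - d
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=genes, columns=genes)


def tom_dissimilarity(adj) -> pd.DataFrame:
    return 1.0 - topological_overlap(adj)


def _cut_height(heights: np.ndarray, cut) -> float:
    if isinstance(cut, str):
        if cut != "gap":
            raise ValueError("cut must be 'gap' or a quantile in (0, 1)")
        hs = np.sort(heights)
        gaps = np.diff(hs)
        if len(gaps) == 0 or gaps.max() == 0:
            return float(hs[-1])
        i = int(np.argmax(gaps))
        return float((hs[i] + hs[i + 1]) / 2.0)
    return float(np.quantile(heights, float(cut)))


def cluster_modules(dissim, min_size: int = 30, cut="gap") -> ModulePartition:
    """Average-linkage clustering of the TOM dissimilarity into modules.

    The tree is cut at a single static height -- by default the midpoint of
    the largest gap in the sorted merge heights, which separates tight
    planted branches from the diffuse background; a float ``cut`` instead
    uses that quantile of merge heights.  Branches with at least
    ``min_size`` genes become modules (labelled by decreasing size);
    everything else gets label 0.
    """
    if isinstance(dissim, pd.DataFrame):
        genes = dissim.index
        d = dissim.to_numpy(float)
    else:
        d = np.asarray(dissim, float)
        genes = pd.RangeIndex(d.shape[0])
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be a symmetric square matrix")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity must have a zero diagonal")

    n = d.shape[0]
    if min_size > n:
        log.warning("min_size %d exceeds gene count %d: all genes unassigned",
                    min_size, n)
        return ModulePartition(pd.Series(0, index=genes), min_size=min_size)

    z = linkage(squareform(d, checks=False), method="average")
    height = _cut_height(z[:, 2], cut)
    raw = fcluster(z, t=height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_size].sort_values(ascending=False)
    relabel = {old: new for new, old in enumerate(big.index, start=1)}
    labels = pd.Series([relabel.get(r, 0) for r in raw], index=genes)
    return ModulePartition(labels, min_size=min_size)


def module_eigengenes(expr, partition: ModulePartition) -> pd.DataFrame:
    """First principal component of each module's standardized submatrix.

    Genes are standardized across samples; each module's eigengene is the
    leading right singular vector, scaled to unit variance and oriented so
    that its correlation with the module's mean expression profile is
    non-negative.  Returns samples x modules (columns ``ME1``, ``ME2``, ...).
    """
    values, genes = _as_matrix(expr)
    samples = (expr.sample_ids if isinstance(expr, ExpressionCompendium)
               else expr.columns if isinstance(expr, pd.DataFrame)
               else pd.RangeIndex(values.shape[1]))
    labels = partition.labels.reindex(genes).fillna(0).astype(int).to_numpy()

    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant gene(s) dropped from eigengene computation",
                    constant.sum())
    std = np.zeros_like(values)
    ok = ~constant
    std[ok] = (values[ok] - values[ok].mean(axis=1, keepdims=True)) / sd[ok, None]

    out = {}
    for lab in partition.module_labels():
        rows = (labels == lab) & ok
        if rows.sum() < 2:
            raise ValueError(f"module {lab} has fewer than 2 usable genes")
        sub = std[rows]
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        eig = vt[0]
        eig = eig / eig.std(ddof=1)
        mean_profile = sub.mean(axis=0)
        if np.corrcoef(eig, mean_profile)[0, 1] < 0:
            eig = -eig
        out[f"ME{lab}"] = eig
    return pd.DataFrame(out, index=samples)


def eigengene_variance_explained(expr, partition: ModulePartition) -> pd.Series:
    """Fraction of module variance captured by the first principal component."""
    values, genes = _as_matrix(expr)
    labels = partition.labels.reindex(genes).fillna(0).astype(int).to_numpy()
    sd = values.std(axis=1, ddof=1)
    out = {}
    for lab in partition.module_labels():
        rows = (labels == lab) & (sd > 0)
        sub = (values[rows] - values[rows].mean(axis=1, keepdims=True)) / sd[rows, None]
        s = np.linalg.svd(sub, compute_uv=False)
        out[f"ME{lab}"] = float(s[0] ** 2 / (s ** 2).sum())
    return pd.Series(out)


def merge_modules(expr, partition: ModulePartition,
                  threshold: float = 0.25) -> ModulePartition:
    """Iteratively merge the closest eigengene pair while its dissimilarity < threshold.

    Dissimilarity between modules is 1 - cor(ME_i, ME_j); after each merge
    the eigengenes are recomputed.  Labels are renumbered by decreasing
    module size at the end.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    labels = partition.labels.copy()
    while True:
        current = ModulePartition(labels, min_size=partition.min_size)
        mods = current.module_labels()
        if len(mods) < 2:
            break
        me = module_eigengenes(expr, current)
        corr = np.corrcoef(me.to_numpy().T)
        diss = 1.0 - corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= threshold:
            break
        a, b = mods[i], mods[j]
        labels[labels == b] = a

    # renumber by decreasing size
    final = ModulePartition(labels, min_size=partition.min_size)
    sizes = final.sizes().sort_values(ascending=False)
    relabel = {old: new for new, old in enumerate(sizes.index, start=1)}
    labels = labels.map(lambda v: relabel.get(v, 0))
    return ModulePartition(labels, min_size=partition.min_size)


def module_trait_correlation(eigengenes: pd.DataFrame,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation and two-sided p-value per (module, trait) pair.

    p-values come from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of
    freedom; zero-variance traits yield missing entries.  Returns a tidy
    frame with columns module, trait, r, p, n.
    """
    common = eigengenes.index.intersection(traits.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    me = eigengenes.loc[common]
    tr = traits.loc[common]
    n = len(common)
    rows = []
    for mod in me.columns:
        x = me[mod].to_numpy(float)
        for trait in tr.columns:
            y = tr[trait].to_numpy(float)
            if np.std(y) == 0 or np.std(x) == 0:
                log.warning("zero-variance trait or eigengene: %s vs %s", mod, trait)
                rows.append({"module": mod, "trait": trait,
                             "r": np.nan, "p": np.nan, "n": n})
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
                p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            rows.append({"module": mod, "trait": trait, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)
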