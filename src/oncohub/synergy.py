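"""Median-effect dose-response modeling and combination-index analysis.

The median-effect equation fa/(1-fa) = (D/Dm)^m linearizes to
log10(fa/(1-fa)) = m*log10(D) - m*log10(Dm), so the potency Dm and
sigmoidicity m of each single agent come from a least-squares fit on the
logit-log scale.  The combination index at a dose pair (d1, d2) producing a
combined affected fraction fa is CI = d1/Dx1(fa) + d2/Dx2(fa) with
Dx = Dm*(fa/(1-fa))^(1/m): CI < 1 indicates synergy, CI = 1 additivity,
CI > 1 antagonism.  The normalized isobologram plots (d1/Dx1, d2/Dx2);
points below the unit line are synergistic combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MedianEffectFit:
    """Median-effect parameters of one drug: slope m, median-effect dose Dm,
    and the correlation coefficient of the linearized fit."""

    m: float
    dm: float
    r: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.dm <= 0:
            raise ValueError("Dm must be > 0")


@dataclass
class CombinationIndexResult:
    """Combination index at one dose pair with isobologram coordinates."""

    d1: float
    d2: float
    fa: float
    dx1: float
    dx2: float
    ci: float
    classification: str


def fit_median_effect(doses, fa) -> MedianEffectFit:
    """Least-squares median-effect fit on the logit-log scale.

    Only rows with dose > 0 and fa strictly inside (0, 1) are used; at least
    two such rows are required.
    """
    doses = np.asarray(doses, float)
    fa = np.asarray(fa, float)
    mask = (doses > 0) & (fa > 0) & (fa < 1)
    if mask.sum() < 2:
        raise ValueError("need >= 2 usable points with dose > 0 and 0 < fa < 1")
    x = np.log10(doses[mask])
    y = np.log10(fa[mask] / (1.0 - fa[mask]))
    if np.allclose(x, x[0]):
        raise ValueError("need >= 2 distinct positive doses")
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ValueError("non-positive median-effect slope; dose-response not increasing")
    dm = float(10.0 ** (-res.intercept / m))
    r = float(res.rvalue) if len(x) > 2 else 1.0
    return MedianEffectFit(m=m, dm=dm, r=r, n_points=int(mask.sum()))


def effective_dose(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing affected fraction fa: Dx = Dm*(fa/(1-fa))^(1/m)."""
    if not (0.0 < fa < 1.0):
        raise ValueError("fa must lie strictly inside (0, 1)")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def classify_ci(ci: float, additive_tol: float = 0.05) -> str:
    if ci < 1.0 - additive_tol:
        return "synergistic"
    if ci > 1.0 + additive_tol:
        return "antagonistic"
    return "additive"


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    d1: float,
    d2: float,
    fa_combo: float,
    form: str = "exclusive",
    additive_tol: float = 0.05,
) -> CombinationIndexResult:
    """Combination index of a dose pair at the combined effect level fa_combo.

    The mutually-exclusive form (default) is the sum of the two normalized
    dose ratios; the mutually-nonexclusive form adds their product as a
    cross-term.
    """
    if d1 < 0 or d2 < 0 or (d1 == 0 and d2 == 0):
        raise ValueError("doses must be non-negative and not both zero")
    if not (0.0 < fa_combo < 1.0):
        raise ValueError("fa_combo must lie strictly inside (0, 1)")
    if form not in ("exclusive", "nonexclusive"):
        raise ValueError("form must be 'exclusive' or 'nonexclusive'")
    dx1 = effective_dose(fit1, fa_combo)
    dx2 = effective_dose(fit2, fa_combo)
    ci = d1 / dx1 + d2 / dx2
    if form == "nonexclusive":
        ci += (d1 / dx1) * (d2 / dx2)
    return CombinationIndexResult(
        d1=float(d1), d2=float(d2), fa=float(fa_combo),
        dx1=dx1, dx2=dx2, ci=float(ci),
        classification=classify_ci(float(ci), additive_tol),
    )


def normalized_isobologram(results) -> pd.DataFrame:
    """Normalized-isobologram coordinates (d1/Dx1, d2/Dx2) per combination.

    x + y equals the (exclusive-form) combination index, so points lie
    below the x + y = 1 line exactly when CI < 1.
    """
    rows = [{
        "d1": r.d1, "d2": r.d2, "fa": r.fa,
        "x": r.d1 / r.dx1, "y": r.d2 / r.dx2,
        "ci": r.ci, "classification": r.classification,
    } for r in results]
    return pd.DataFrame(rows)


def analyze_dose_response(
    table: pd.DataFrame,
    form: str = "exclusive",
    additive_tol: float = 0.05,
) -> tuple[MedianEffectFit, MedianEffectFit, pd.DataFrame]:
    """Full synergy analysis of a two-drug dose-response table.

    The table needs columns drug1_dose, drug2_dose, fraction_affected
    (replicate rows at the same dose pair are averaged).  Single-agent rows
    (one dose zero) feed the median-effect fits; each combination row gets
    a combination index.  Returns (fit1, fit2, report) where the report has
    columns d1, d2, fa, dx1, dx2, ci, classification, x, y.
    """
    required = {"drug1_dose", "drug2_dose", "fraction_affected"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"dose-response table missing columns: {sorted(missing)}")
    grouped = (table.groupby(["drug1_dose", "drug2_dose"], as_index=False)
               ["fraction_affected"].mean())

    single1 = grouped[(grouped["drug1_dose"] > 0) & (grouped["drug2_dose"] == 0)]
    single2 = grouped[(grouped["drug2_dose"] > 0) & (grouped["drug1_dose"] == 0)]
    fit1 = fit_median_effect(single1["drug1_dose"], single1["fraction_affected"])
    fit2 = fit_median_effect(single2["drug2_dose"], single2["fraction_affected"])

    combos = grouped[(grouped["drug1_dose"] > 0) & (grouped["drug2_dose"] > 0)]
    results = []
    for _, row in combos.iterrows():
        fa = float(row["fraction_affected"])
        fa = min(max(fa, 1e-6), 1.0 - 1e-6)  # reporting clamp only
        results.append(combination_index(
            fit1, fit2, float(row["drug1_dose"]), float(row["drug2_dose"]),
            fa, form=form, additive_tol=additive_tol))
    report = normalized_isobologram(results)
    return fit1, fit2, report
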