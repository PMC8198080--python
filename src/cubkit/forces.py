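"""Evolutionary-force diagnostics.

The neutrality plot regresses GC12 on GC3 across sequences: a slope near 1
means directional mutation pressure moves all codon positions together, a
slope near 0 means selection holds positions 1–2 still while position 3
drifts. The slope times 100 is reported as the mutational contribution in
percent; its complement as the selection contribution.

PR2 (parity rule 2) plots A3/(A3+T3) against G3/(G3+C3); (0.5, 0.5) is the
no-asymmetry point. ENc–GC3 deviations measure how far observed ENc falls
below the composition-only expectation. Correlation/regression tables use
Pearson r with two-tailed p from the t transform (n−2 df); no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import CompositionProfile
from .cub_indices import enc_expected


class DegenerateXError(ValueError):
    """Regressor is constant; the fit is undefined."""


@dataclass(frozen=True)
class NeutralityResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int

    @property
    def mutation_pct(self) -> float:
        return 100.0 * self.slope

    @property
    def selection_pct(self) -> float:
        return 100.0 * (1.0 - self.slope)


@dataclass(frozen=True)
class PR2Point:
    label: str
    at_bias: float | None  # A3 / (A3 + T3)
    gc_bias: float | None  # G3 / (G3 + C3)


@dataclass(frozen=True)
class EncGc3Point:
    label: str
    gc3: float
    enc_observed: float
    enc_expected: float

    @property
    def deviation(self) -> float:
        return self.enc_observed - self.enc_expected


def neutrality(points: Sequence[tuple[float, float]]) -> NeutralityResult:
    """OLS of GC12 on GC3 over (gc12, gc3) pairs (percent or fraction, as
    long as both axes use the same units)."""
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    gc12 = np.array([p[0] for p in points], dtype=float)
    gc3 = np.array([p[1] for p in points], dtype=float)
    if np.ptp(gc3) == 0:
        raise DegenerateXError("DEGENERATE_X: GC3 is constant")
    fit = stats.linregress(gc3, gc12)
    return NeutralityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(points),
    )


def _pr2_from_pcts(label: str, a3: float, t3: float, g3: float, c3: float) -> PR2Point:
    at = a3 / (a3 + t3) if (a3 + t3) > 0 else None
    gc = g3 / (g3 + c3) if (g3 + c3) > 0 else None
    return PR2Point(label=label, at_bias=at, gc_bias=gc)


def pr2(profiles: Sequence[CompositionProfile]) -> tuple[list[PR2Point], PR2Point]:
    """Per-sequence PR2 points plus the overall point from dataset mean
    third-position percentages. All third positions are used (not only
    four-fold families); a zero denominator flags the affected axis None."""
    if not profiles:
        raise ValueError("no profiles")
    pts = [
        _pr2_from_pcts(p.id, p.pct_A3, p.pct_T3, p.pct_G3, p.pct_C3) for p in profiles
    ]
    overall = _pr2_from_pcts(
        "overall",
        float(np.mean([p.pct_A3 for p in profiles])),
        float(np.mean([p.pct_T3 for p in profiles])),
        float(np.mean([p.pct_G3 for p in profiles])),
        float(np.mean([p.pct_C3 for p in profiles])),
    )
    return pts, overall


def pr2_from_means(a3: float, t3: float, g3: float, c3: float) -> PR2Point:
    """PR2 point straight from third-position mean percentages."""
    return _pr2_from_pcts("overall", a3, t3, g3, c3)


def enc_gc3_points(
    enc_values: Sequence[float],
    gc3_values: Sequence[float],
    labels: Sequence[str] | None = None,
) -> tuple[list[EncGc3Point], float]:
    """Observed-vs-expected ENc per sequence and the fraction of points below
    the expected curve. ``gc3_values`` are fractions in [0, 1]."""
    if len(enc_values) != len(gc3_values):
        raise ValueError("enc and gc3 lists differ in length")
    labels = labels or [str(i) for i in range(len(enc_values))]
    pts = [
        EncGc3Point(label=l, gc3=g, enc_observed=e, enc_expected=enc_expected(g))
        for l, e, g in zip(labels, enc_values, gc3_values)
    ]
    below = sum(1 for p in pts if p.deviation < 0)
    return pts, below / len(pts) if pts else 0.0


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def correlation_table(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations over feature columns.

    Returns (r, p, stars) DataFrames. A constant column yields NaN against
    everything (flagged, not raised); the diagonal is exactly 1 with no stars.
    """
    cols = list(features.columns)
    if len(features) < 3:
        raise ValueError("need at least 3 rows")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    s = pd.DataFrame("", index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x, y = features[a].to_numpy(float), features[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
            s.loc[a, b] = s.loc[b, a] = _stars(res.pvalue)
    return r, p, s


def enc_regressions(features: pd.DataFrame, enc_col: str = "enc") -> pd.DataFrame:
    """OLS of ENc against each other column, one line per feature.

    Returns slope, intercept, r, p and the slope sign per feature; a constant
    feature is flagged NaN.
    """
    if enc_col not in features.columns:
        raise ValueError(f"missing column {enc_col!r}")
    y = features[enc_col].to_numpy(float)
    rows = []
    for col in features.columns:
        if col == enc_col:
            continue
        x = features[col].to_numpy(float)
        if np.ptp(x) == 0:
            rows.append({"feature": col, "slope": np.nan, "intercept": np.nan,
                         "r": np.nan, "p": np.nan, "sign": "undefined"})
            continue
        fit = stats.linregress(x, y)
        rows.append(
            {
                "feature": col,
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r": float(fit.rvalue),
                "p": float(fit.pvalue),
                "sign": "positive" if fit.slope > 0 else "negative" if fit.slope < 0 else "zero",
            }
        )
    return pd.DataFrame(rows).set_index("feature")
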