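"""Validation and convergence statistics.

Agreement between predicted (in silico) and reference (in vitro) values is
measured with Lin's concordance correlation coefficient and per-pair
percentage errors; mesh convergence with Richardson extrapolation; and
model-form sensitivity with the one-at-a-time SD/mean summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairedSample",
    "RichardsonResult",
    "SensitivityResult",
    "lins_ccc",
    "percent_error",
    "richardson",
    "oat_sensitivity",
]


@dataclass(frozen=True)
class PairedSample:
    """Paired reference (in vitro role) and predicted (in silico role)
    values in common units."""

    reference: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.reference, dtype=float)
        y = np.asarray(self.predicted, dtype=float)
        object.__setattr__(self, "reference", x)
        object.__setattr__(self, "predicted", y)
        if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
            raise ValueError("paired sample needs two equal-length 1-d arrays, n >= 2")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("paired sample must be finite")


def lins_ccc(s: PairedSample) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with population
    (1/n) moments.  Measures agreement with the identity line: 1 is perfect
    concordance, -1 perfect reversed concordance.
    """
    x, y = s.reference, s.predicted
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("concordance undefined: zero variance and equal means")
    return float(2.0 * sxy / denom)


def percent_error(reference: float, predicted: float) -> float:
    """Absolute percentage error 100 |predicted - reference| / |reference|."""
    if reference == 0:
        raise ValueError("percent error undefined for zero reference")
    return float(100.0 * abs(predicted - reference) / abs(reference))


@dataclass(frozen=True)
class RichardsonResult:
    """Observed-order Richardson extrapolation from three uniformly refined
    solutions (edge lengths 2h, h, h/2)."""

    refinement_ratio: float
    observed_order: float           # NaN when the sequence is already exact
    extrapolated: float
    relative_error: float           # |u_{h/2} - u*| / |u*| at the finest level
    converged: bool


def richardson(values: tuple[float, float, float],
               refinement_ratio: float = 2.0) -> RichardsonResult:
    """Richardson extrapolation of a scalar solution on meshes with edge
    lengths (2h, h, h/2).

    p = ln((u_2h - u_h) / (u_h - u_h/2)) / ln r;
    u* = u_h/2 + (u_h/2 - u_h) / (r^p - 1).

    A constant sequence reports converged with zero error; a non-monotone
    (oscillatory) sequence raises, directing the user to refine further.
    """
    if refinement_ratio <= 1:
        raise ValueError("refinement ratio must exceed 1")
    u_2h, u_h, u_h2 = (float(v) for v in values)
    d1 = u_2h - u_h
    d2 = u_h - u_h2
    if d1 == 0.0 and d2 == 0.0:
        return RichardsonResult(refinement_ratio, float("nan"), u_h2, 0.0, True)
    if d1 * d2 <= 0.0:
        raise ValueError(
            "non-monotone solution sequence (oscillatory convergence); refine "
            "the mesh further before extrapolating")
    p = float(np.log(d1 / d2) / np.log(refinement_ratio))
    u_star = u_h2 + (u_h2 - u_h) / (refinement_ratio ** p - 1.0)
    rel = abs(u_h2 - u_star) / abs(u_star) if u_star != 0 else float("inf")
    return RichardsonResult(refinement_ratio, p, float(u_star), float(rel),
                            converged=rel < 0.01)


@dataclass
class SensitivityResult:
    """Per-gauge variability across model variants: one sample SD as a
    percentage of the mean strain."""

    table: pd.DataFrame  # columns: gauge, mean, sd, sd_pct_of_mean


def oat_sensitivity(variant_results: pd.DataFrame) -> SensitivityResult:
    """One-at-a-time sensitivity summary.

    ``variant_results``: rows = model variants, columns = gauge labels,
    values = strain at that gauge.  Reports 100 * SD / |mean| per gauge
    (sample SD, n-1).  A zero-mean gauge is flagged as undefined (NaN), not
    fatal.
    """
    df = pd.DataFrame(variant_results)
    if len(df) < 2:
        raise ValueError("need at least two model variants")
    rows = []
    for gauge in df.columns:
        vals = df[gauge].to_numpy(dtype=float)
        mean = vals.mean()
        sd = vals.std(ddof=1)
        pct = float("nan") if mean == 0 else 100.0 * sd / abs(mean)
        rows.append({"gauge": gauge, "mean": mean, "sd": sd, "sd_pct_of_mean": pct})
    return SensitivityResult(table=pd.DataFrame(rows))
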