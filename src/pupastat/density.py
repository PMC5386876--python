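"""Vial-density covariate: slope estimation and the linear length correction.

Crowded vials produce shorter pupae.  The per-stock relationship is an
ordinary least-squares regression of mean vial length on the automated
density proxy; across stocks the slopes concentrate around a modal value
near -0.002 mm per pupa.  The correction moves a measurement to the value
expected at the experiment-wide mean density M:

    corrected = (D - M) * S + Q

with D the vial's density, S the (negative) slope and Q the raw length or
vial mean.  Corrected values are reported alongside raw ones, never in
place of them.

Sign convention: ``correct_length`` evaluates the formula exactly as
written.  Note that with S set to the fitted length-on-density slope
(negative) the formula *shifts dense vials further down*; the value of S
that cancels a fitted trend ``s`` is ``-s``.  The published study quotes
S = -0.002 with this formula but never applied corrections to its
results, so the convention ambiguity was harmless there; here it is kept
as printed and flagged, with trend removal achieved by passing the
negated fitted slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DensityModel", "fit_density_slope", "mode_slope",
           "correct_length", "correction_distribution"]

DEFAULT_M = 65.0  # mean vial density across the experiment
DEFAULT_S = -0.002  # mm per pupa


@dataclass(frozen=True)
class DensityModel:
    M: float
    S: float
    per_stock_slopes: pd.DataFrame | None = None  # stock_id, slope, r2, p, n_vials


@dataclass(frozen=True)
class SlopeFit:
    slope: float  # mm per pupa
    intercept: float
    r2: float
    p: float
    n_vials: int


def fit_density_slope(vials: pd.DataFrame, min_vials: int = 3) -> SlopeFit:
    """OLS of mean vial length on measured density for one stock.

    Uses qc_pass vials only (when the column is present); requires >= 3
    vials and non-degenerate densities.
    """
    if "qc_pass" in vials:
        vials = vials[vials["qc_pass"].astype(bool)]
    if len(vials) < min_vials:
        raise ValueError(f"need >= {min_vials} qc_pass vials, got {len(vials)}")
    x = vials["n_measured"].to_numpy(dtype=float)
    y = vials["mean_length_mm"].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("all vial densities identical: degenerate design")
    fit = stats.linregress(x, y)
    return SlopeFit(slope=float(fit.slope), intercept=float(fit.intercept),
                    r2=float(fit.rvalue**2), p=float(fit.pvalue), n_vials=len(vials))


def mode_slope(slopes, bin_width: float = 0.0005) -> float:
    """Modal slope across stocks: midpoint of the most populated
    fixed-width histogram bin; ties break toward the bin nearer the median.
    """
    s = np.asarray(list(slopes), dtype=float)
    if len(s) == 0:
        raise ValueError("no slopes given")
    if len(s) == 1:
        return float(s[0])
    lo = np.floor(s.min() / bin_width) * bin_width
    hi = np.ceil(s.max() / bin_width) * bin_width
    nbins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(s, bins=nbins, range=(lo, lo + nbins * bin_width))
    mids = (edges[:-1] + edges[1:]) / 2.0
    best = counts.max()
    cand = np.nonzero(counts == best)[0]
    med = np.median(s)
    pick = cand[np.argmin(np.abs(mids[cand] - med))]
    return float(mids[pick])


def correct_length(Q, D, M: float = DEFAULT_M, S: float = DEFAULT_S):
    """Density-corrected length: (D - M) * S + Q, exactly."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 1):
        raise ValueError("densities must be >= 1")
    out = (D - M) * S + np.asarray(Q, dtype=float)
    return float(out) if out.ndim == 0 else out


def correction_distribution(vials: pd.DataFrame, M: float = DEFAULT_M,
                            S: float = DEFAULT_S,
                            percentiles=(50, 95, 99, 100)) -> pd.DataFrame:
    """Empirical percentiles of |(D - M) * S| over qc_pass vials.

    Quantifies how large the density correction would be if applied; vials
    failing QC (density < 15) are excluded first.
    """
    if "qc_pass" in vials:
        vials = vials[vials["qc_pass"].astype(bool)]
    if len(vials) == 0:
        raise ValueError("no qc_pass vials")
    corr = np.abs((vials["n_measured"].to_numpy(dtype=float) - M) * S)
    return pd.DataFrame({
        "percentile": list(percentiles),
        "abs_correction_mm": [float(np.percentile(corr, p)) for p in percentiles],
    })
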