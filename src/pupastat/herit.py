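"""Heritability estimators for pupal length (and any family-trio trait).

Narrow-sense heritability h² is the slope of offspring value on the
midparent value (the parents' average).  Offspring of a cross can enter
either as their vial mean (one point per cross) or individually (the
midparent repeated per offspring); under additivity both give the same
expected slope.  Regressions on a single parent estimate h²/2.

Broad-sense heritability H² comes from a one-way random-effects model on
replicate vial means of inbred lines, y_ij = mu + alpha_j + e_ij, using
the ANOVA (method-of-moments) estimator for unbalanced data:

    n0 = (N - sum n_i² / N) / (k - 1)
    sigma²_between = max(0, (MS_between - MS_within) / n0)
    H² = sigma²_between / (sigma²_between + sigma²_within)

Under pure additivity with inbred lines, H² relates to h² as
2 h² / (1 + h²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth.genetics import TrioTable

__all__ = ["HeritabilityEstimate", "VarianceComponents",
           "midparent_regression", "single_parent_regression",
           "broad_sense_h2", "expected_H2_additive"]


@dataclass(frozen=True)
class HeritabilityEstimate:
    slope: float  # = h-hat² for midparent regressions
    se: float
    r2: float
    intercept: float  # mm
    n: int
    response_mode: str  # vial_mean | individual
    predictor_mode: str  # midparent | mother | father


def _trio_xy(trios: TrioTable, response_mode: str, predictor_mode: str):
    crosses = trios.crosses
    if predictor_mode == "midparent":
        pred = (crosses["mother_len_mm"] + crosses["father_len_mm"]) / 2.0
    elif predictor_mode == "mother":
        pred = crosses["mother_len_mm"]
    elif predictor_mode == "father":
        pred = crosses["father_len_mm"]
    else:
        raise ValueError(f"unknown predictor_mode {predictor_mode!r}")
    pred = pd.Series(pred.to_numpy(), index=crosses["cross_id"].to_numpy())

    if response_mode == "vial_mean":
        resp = trios.offspring_vial_means()
        common = resp.index.intersection(pred.index)
        return pred.loc[common].to_numpy(), resp.loc[common].to_numpy()
    if response_mode == "individual":
        off = trios.offspring
        x = pred.loc[off["cross_id"].to_numpy()].to_numpy()
        return x, off["offspring_len_mm"].to_numpy()
    raise ValueError(f"unknown response_mode {response_mode!r}")


def _regress(x: np.ndarray, y: np.ndarray, response_mode: str,
             predictor_mode: str) -> HeritabilityEstimate:
    n_crosses = len(np.unique(x)) if response_mode == "individual" else len(x)
    if len(x) < 3 or n_crosses < 3:
        raise ValueError(f"need >= 3 trios, got {n_crosses}")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in the parental predictor")
    fit = stats.linregress(x, y)
    return HeritabilityEstimate(
        slope=float(fit.slope), se=float(fit.stderr),
        r2=float(fit.rvalue**2), intercept=float(fit.intercept),
        n=len(x), response_mode=response_mode, predictor_mode=predictor_mode)


def midparent_regression(trios: TrioTable,
                         response_mode: str = "vial_mean") -> HeritabilityEstimate:
    """h² as the slope of offspring on midparent length."""
    x, y = _trio_xy(trios, response_mode, "midparent")
    return _regress(x, y, response_mode, "midparent")


def single_parent_regression(trios: TrioTable, parent: str,
                             response_mode: str = "vial_mean") -> HeritabilityEstimate:
    """Offspring regressed on one parent; expected slope h²/2 under
    additivity, so asymmetry between mother and father slopes flags
    parental effects."""
    if parent not in ("mother", "father"):
        raise ValueError(f"parent must be 'mother' or 'father', got {parent!r}")
    x, y = _trio_xy(trios, response_mode, parent)
    return _regress(x, y, response_mode, parent)


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_between: float  # mm², Var(alpha_j)
    sigma2_within: float  # mm², Var(e_ij)
    H2: float
    F: float
    p_value: float
    df_between: int
    df_within: int
    MS_between: float  # mm²
    SS_between: float  # mm²
    n0: float  # effective replicates per line
    n_lines: int
    n_obs: int
    truncated: bool  # between-variance estimate was negative, set to 0


def broad_sense_h2(ril_vials: pd.DataFrame, min_reps: int = 3,
                   value_col: str = "vial_mean_mm",
                   group_col: str = "ril_id") -> VarianceComponents:
    """One-way random-effects ANOVA estimator of H² from vial means.

    Lines with fewer than ``min_reps`` replicate vials are dropped first.
    """
    counts = ril_vials.groupby(group_col)[value_col].count()
    keep = counts[counts >= min_reps].index
    df = ril_vials[ril_vials[group_col].isin(keep)]
    groups = [g.to_numpy(dtype=float) for _, g in df.groupby(group_col)[value_col]]
    k = len(groups)
    if k < 2:
        raise ValueError(f"need >= 2 lines with >= {min_reps} replicates, got {k}")
    n_i = np.array([len(g) for g in groups])
    N = int(n_i.sum())
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    SS_between = float(np.sum(n_i * (means - grand) ** 2))
    SS_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_between, df_within = k - 1, N - k
    MS_between = SS_between / df_between
    MS_within = SS_within / df_within
    if MS_within == 0 and k >= 2 and np.ptp(means) > 0:
        # perfectly repeatable lines with different means
        return VarianceComponents(
            sigma2_between=float(np.var(means, ddof=1)), sigma2_within=0.0,
            H2=1.0, F=float("inf"), p_value=0.0, df_between=df_between,
            df_within=df_within, MS_between=MS_between, SS_between=SS_between,
            n0=float((N - (n_i**2).sum() / N) / df_between), n_lines=k,
            n_obs=N, truncated=False)
    if MS_within == 0:
        raise ValueError("zero within-line variance and no between-line signal")
    n0 = float((N - (n_i**2).sum() / N) / df_between)
    raw_between = (MS_between - MS_within) / n0
    truncated = raw_between < 0
    sigma2_between = max(0.0, raw_between)
    F = MS_between / MS_within
    p = float(stats.f.sf(F, df_between, df_within))
    H2 = sigma2_between / (sigma2_between + MS_within) if sigma2_between + MS_within > 0 else 0.0
    return VarianceComponents(
        sigma2_between=float(sigma2_between), sigma2_within=float(MS_within),
        H2=float(H2), F=float(F), p_value=p, df_between=df_between,
        df_within=df_within, MS_between=float(MS_between),
        SS_between=float(SS_between), n0=n0, n_lines=k, n_obs=N,
        truncated=truncated)


def expected_H2_additive(h2: float) -> float:
    """Broad-sense heritability expected under a purely additive model,
    2 h² / (1 + h²); rounding is left to presentation."""
    if not 0 <= h2 <= 1:
        raise ValueError(f"h2 must lie in [0, 1], got {h2}")
    return 2.0 * h2 / (1.0 + h2)
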