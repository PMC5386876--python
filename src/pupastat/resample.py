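"""Subsampling variance of vial means and RIL means.

How many pupae must a vial contain, and how many replicate vials must an
inbred line have, for their means to be trustworthy?  Both questions are
answered the same way: repeatedly draw random subsamples (without
replacement) of a given size, recompute the mean, and record its deviation
from the mean over everything.  The deviation at full size is exactly
zero, deviations are unbiased, and their spread shrinks with the
finite-population factor sqrt(1/n_s - 1/N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SubsampleReport", "vial_subsample_deviation",
           "ril_subsample_deviation"]


@dataclass
class SubsampleReport:
    unit: str  # "vial" | "ril"
    n_reps: int
    summary: pd.DataFrame  # per size: mean deviation + central 95% band
    deviations: pd.DataFrame  # long: unit_id, subsample_size, rep, deviation_mm
    n_skipped: dict  # size -> units skipped (too few members)


def _subsample_deviation(values_by_unit: dict, unit: str, sizes, reps: int,
                         seed: int | None) -> SubsampleReport:
    rng = np.random.default_rng(seed)
    sizes = [int(s) for s in sizes]
    rows = []
    n_skipped: dict[int, int] = {s: 0 for s in sizes}
    for unit_id, values in values_by_unit.items():
        values = np.asarray(values, dtype=float)
        full_mean = values.mean()
        n = len(values)
        for size in sizes:
            if size > n:
                n_skipped[size] += 1
                continue
            if size == n:
                # the subsample IS the full set: exactly zero by definition,
                # not up to floating-point summation order
                rows.extend((unit_id, size, rep, 0.0) for rep in range(reps))
                continue
            for rep in range(reps):
                sub = rng.choice(values, size=size, replace=False)
                rows.append((unit_id, size, rep, sub.mean() - full_mean))
    deviations = pd.DataFrame(
        rows, columns=["unit_id", "subsample_size", "rep", "deviation_mm"])
    summ = []
    for size in sizes:
        d = deviations.loc[deviations["subsample_size"] == size, "deviation_mm"]
        if len(d) == 0:
            continue
        summ.append({
            "subsample_size": size,
            "n_units": deviations.loc[deviations["subsample_size"] == size,
                                      "unit_id"].nunique(),
            "mean_deviation_mm": float(d.mean()),
            "central95_low_mm": float(np.percentile(d, 2.5)),
            "central95_high_mm": float(np.percentile(d, 97.5)),
            "sd_deviation_mm": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        })
    return SubsampleReport(unit=unit, n_reps=reps,
                           summary=pd.DataFrame(summ),
                           deviations=deviations, n_skipped=n_skipped)


def _to_groups(data, group_col, value_col) -> dict:
    if isinstance(data, pd.DataFrame):
        return {k: g.to_numpy(dtype=float)
                for k, g in data.groupby(group_col)[value_col]}
    return {k: np.asarray(v, dtype=float) for k, v in dict(data).items()}


def vial_subsample_deviation(lengths_by_vial, sizes, reps: int = 100,
                             seed: int | None = None,
                             group_col: str = "vial_id",
                             value_col: str = "length_mm") -> SubsampleReport:
    """Deviation of subsampled vial means from the all-pupae vial mean.

    ``lengths_by_vial``: mapping vial -> per-pupa lengths, or a DataFrame
    with vial_id/length_mm columns.  For each subsample size, each vial is
    resampled ``reps`` times without replacement; deviations are pooled
    across (vial, rep) pairs.  Vials smaller than a requested size are
    skipped for that size and counted.
    """
    groups = _to_groups(lengths_by_vial, group_col, value_col)
    return _subsample_deviation(groups, "vial", sizes, reps, seed)


def ril_subsample_deviation(means_by_ril, sizes, reps: int = 100,
                            seed: int | None = None,
                            group_col: str = "ril_id",
                            value_col: str = "vial_mean_mm") -> SubsampleReport:
    """Deviation of RIL means recomputed from subsets of replicate vials.

    The RIL mean is the unweighted mean of its vial means: every pupa in a
    vial still contributes to that vial's mean, only the number of vial
    means entering the RIL mean varies.
    """
    groups = _to_groups(means_by_ril, group_col, value_col)
    return _subsample_deviation(groups, "ril", sizes, reps, seed)
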