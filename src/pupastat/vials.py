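"""Vial-level aggregation, QC, measurement precision, simulated exclusion.

A vial summary averages the lengths of high- and medium-confidence,
non-excluded pupae; the automated count of those pupae doubles as the
density proxy D.  Vials with fewer than 15 measured pupae fail QC and are
dropped from downstream analyses.

Measurement precision is quantified by re-measuring a film after rotating
it 180 degrees and comparing matched pupae (``match_duplicates`` +
``assess_precision``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = ["VialSummary", "PrecisionReport", "summarize_vial",
           "summarize_vials", "match_duplicates", "assess_precision",
           "apply_exclusion"]

USABLE_CLASSES = ("high", "medium")


@dataclass(frozen=True)
class VialSummary:
    vial_id: str
    n_measured: int  # density proxy D
    mean_length: float  # mm, nan when n_measured == 0
    sd_length: float  # mm
    n_excluded: int
    qc_pass: bool


def summarize_vial(records: pd.DataFrame, min_density: int = 15,
                   vial_id: str | None = None) -> VialSummary:
    """Summarize one vial over high/medium-confidence, non-excluded pupae.

    ``qc_pass`` is ``n_measured >= min_density`` (default 15).
    """
    if vial_id is None:
        ids = records["vial_id"].unique() if "vial_id" in records else ["vial"]
        if len(ids) > 1:
            raise ValueError(f"records span multiple vials: {list(ids)[:5]}")
        vial_id = str(ids[0]) if len(ids) else "vial"
    usable = records[records["confidence"].isin(USABLE_CLASSES)
                     & ~records["excluded"].astype(bool)]
    n = len(usable)
    n_excl = int((records["confidence"].isin(USABLE_CLASSES)
                  & records["excluded"].astype(bool)).sum())
    lengths = usable["length_mm"].to_numpy()
    return VialSummary(
        vial_id=vial_id,
        n_measured=n,
        mean_length=float(lengths.mean()) if n else float("nan"),
        sd_length=float(lengths.std(ddof=1)) if n > 1 else (0.0 if n else float("nan")),
        n_excluded=n_excl,
        qc_pass=n >= min_density,
    )


def summarize_vials(records: pd.DataFrame, min_density: int = 15) -> pd.DataFrame:
    """Per-vial summary table (one row per vial_id)."""
    rows = [summarize_vial(grp, min_density, vial_id=str(vid))
            for vid, grp in records.groupby("vial_id")]
    return pd.DataFrame([{
        "vial_id": s.vial_id, "n_measured": s.n_measured,
        "mean_length_mm": s.mean_length, "sd_length_mm": s.sd_length,
        "n_excluded": s.n_excluded, "qc_pass": s.qc_pass,
    } for s in rows])


def match_duplicates(pass1: pd.DataFrame, pass2: pd.DataFrame,
                     image_shape: tuple[int, int],
                     isolation_px: float = 15.0,
                     match_tol_px: float = 10.0) -> pd.DataFrame:
    """Pair pupae measured twice: once normally, once after 180° rotation.

    Pass-2 centroids are mapped through (H-1-row, W-1-col) back into the
    pass-1 frame, then matched to the nearest pass-1 pupa within
    ``match_tol_px``.  Only pupae isolated from all neighbours by more than
    ``isolation_px`` (per the recorded boundary gap) are eligible;
    ambiguous matches are dropped and counted in ``attrs['n_ambiguous']``.
    """
    H, W = image_shape

    def eligible(df):
        keep = df["confidence"].isin(USABLE_CLASSES)
        if "neighbor_gap_px" in df:
            keep &= df["neighbor_gap_px"] > isolation_px
        return df[keep].reset_index(drop=True)

    p1 = eligible(pass1)
    p2 = eligible(pass2).copy()
    p2["centroid_row"] = (H - 1) - p2["centroid_row"]
    p2["centroid_col"] = (W - 1) - p2["centroid_col"]

    pairs, n_ambiguous = [], 0
    if len(p1) and len(p2):
        tree = cKDTree(p1[["centroid_row", "centroid_col"]].to_numpy())
        d, idx = tree.query(p2[["centroid_row", "centroid_col"]].to_numpy(),
                            k=min(2, len(p1)))
        d = np.atleast_2d(d.T).T
        idx = np.atleast_2d(idx.T).T
        claimed: dict[int, int] = {}
        for j in range(len(p2)):
            if d[j, 0] > match_tol_px:
                continue
            if d.shape[1] > 1 and d[j, 1] <= match_tol_px:
                n_ambiguous += 1
                continue
            i = int(idx[j, 0])
            if i in claimed:  # two pass-2 pupae claim the same pass-1 pupa
                n_ambiguous += 1
                claimed[i] = -1
                continue
            claimed[i] = j
        for i, j in claimed.items():
            if j >= 0:
                pairs.append({
                    "pupa_id_1": p1.loc[i, "pupa_id"],
                    "pupa_id_2": p2.loc[j, "pupa_id"],
                    "length_mm_1": p1.loc[i, "length_mm"],
                    "length_mm_2": p2.loc[j, "length_mm"],
                })
    out = pd.DataFrame(pairs, columns=["pupa_id_1", "pupa_id_2",
                                       "length_mm_1", "length_mm_2"])
    out.attrs["n_ambiguous"] = n_ambiguous
    out.attrs["n_eligible"] = min(len(p1), len(p2))
    return out


@dataclass(frozen=True)
class PrecisionReport:
    n_pairs: int
    mean_abs_diff: float  # mm
    sd_abs_diff: float  # mm
    slope: float  # pass-2 on pass-1
    r2: float


def assess_precision(pairs: pd.DataFrame) -> PrecisionReport:
    """Precision from duplicate pairs: mean/SD of |Δ| and the pass-2 on
    pass-1 regression slope and R²."""
    if len(pairs) < 2:
        raise ValueError(f"need >= 2 pairs, got {len(pairs)}")
    x = pairs["length_mm_1"].to_numpy()
    y = pairs["length_mm_2"].to_numpy()
    diff = np.abs(y - x)
    if np.allclose(x, x[0]):
        slope, r2 = float("nan"), float("nan")
    else:
        fit = stats.linregress(x, y)
        slope, r2 = float(fit.slope), float(fit.rvalue**2)
    return PrecisionReport(
        n_pairs=len(pairs),
        mean_abs_diff=float(diff.mean()),
        sd_abs_diff=float(diff.std(ddof=1)),
        slope=slope,
        r2=r2,
    )


def apply_exclusion(records: pd.DataFrame, p_high: float = 0.02,
                    p_medium: float = 0.10,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate manual curation: exclude high-confidence pupae with
    probability 0.02 and medium-confidence with 0.10 (seeded Bernoulli).

    Excluded rows are flagged, never deleted, preserving the audit trail.
    """
    for name, p in (("p_high", p_high), ("p_medium", p_medium)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    out = records.copy()
    u = rng.random(len(out))
    p_vec = np.select(
        [out["confidence"] == "high", out["confidence"] == "medium"],
        [p_high, p_medium], default=0.0)
    out["excluded"] = u < p_vec
    return out
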