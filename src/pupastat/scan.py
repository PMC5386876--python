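"""Haplotype-regression genome scan of RIL means with permutation thresholds.

At every genomic position (abstract 10-kb bins) the RIL mean phenotype is
regressed on founder-indicator dummies (k-1 columns for the k founders
present); the evidence is summarized as

    LOD = (n / 2) * log10(RSS_null / RSS_full).

For a categorical design the full-model residual sum of squares equals the
pooled within-founder-group sum of squares, which lets the scan — and the
genome-wide-maximum null distribution over phenotype permutations — be
computed with group-sum arithmetic instead of per-position least squares.

Genome-wide significance uses the standard permutation scheme: shuffle
phenotypes across RILs, record the maximum LOD anywhere in the genome, and
take the (1 - alpha) quantile over permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScanResult", "scan", "permutation_threshold"]

RSS_FLOOR_FRAC = 1e-12  # RSS_full floored at this fraction of RSS_null


@dataclass
class ScanResult:
    positions: np.ndarray  # position indices (or column names)
    lod: np.ndarray
    n_rils: int
    threshold: float | None = None
    alpha: float | None = None
    n_perms: int | None = None
    flags: dict = field(default_factory=dict)  # position -> reason

    @property
    def max_lod(self) -> float:
        return float(self.lod.max())

    @property
    def argmax_position(self):
        return self.positions[int(np.argmax(self.lod))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "lod": self.lod})


def _as_matrix(ril_means, haplotypes):
    if isinstance(haplotypes, pd.DataFrame):
        hap = haplotypes.to_numpy(dtype=int)
        positions = np.asarray(haplotypes.columns)
        if isinstance(ril_means, pd.Series):
            ril_means = ril_means.reindex(haplotypes.index)
            if ril_means.isna().any():
                missing = haplotypes.index[ril_means.isna()][:5]
                raise ValueError(f"phenotypes missing for RILs {list(missing)}")
    else:
        hap = np.asarray(haplotypes, dtype=int)
        positions = np.arange(hap.shape[1])
    y = np.asarray(ril_means, dtype=float)
    if len(y) != hap.shape[0]:
        raise ValueError(
            f"{len(y)} phenotypes but {hap.shape[0]} haplotype rows")
    return y, hap, positions


def _lod_matrix(y_cols: np.ndarray, hap: np.ndarray) -> tuple[np.ndarray, dict]:
    """LOD for every (position, phenotype column): shape (P, C).

    y_cols: (n, C) phenotype columns (original and/or permuted).
    """
    n, C = y_cols.shape
    P = hap.shape[1]
    total_sq = (y_cols**2).sum(axis=0)
    n_mean = y_cols.mean(axis=0)
    lod = np.zeros((P, C))
    flags: dict = {}
    nf = int(hap.max()) + 1
    for p in range(P):
        labels = hap[:, p]
        counts = np.bincount(labels, minlength=nf).astype(float)
        present = counts > 0
        if present.sum() < 2:
            flags[p] = "single_founder"
            continue
        # group sums for all phenotype columns at once: (nf, C)
        onehot = (labels[:, None] == np.arange(nf)).astype(float)
        sums = onehot.T @ y_cols
        with np.errstate(divide="ignore", invalid="ignore"):
            explained = np.where(present[:, None],
                                 sums**2 / counts[:, None], 0.0).sum(axis=0)
        rss_full = total_sq - explained
        rss_null = total_sq - n * n_mean**2
        floor = RSS_FLOOR_FRAC * rss_null
        capped = rss_full < floor
        if np.any(capped):
            flags[p] = "rss_capped"
        rss_full = np.maximum(rss_full, floor)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(rss_null > 0, rss_null / rss_full, 1.0)
        lod[p] = (n / 2.0) * np.log10(np.maximum(ratio, 1.0))
    return lod, flags


def scan(ril_means, haplotypes) -> ScanResult:
    """Single-position founder-indicator regression scan over all positions.

    ``ril_means``: per-RIL phenotype (unweighted mean of replicate vial
    means), aligned with the rows of ``haplotypes`` (RIL x position integer
    founder labels).  Positions where only one founder is represented get
    LOD 0 and are flagged.
    """
    y, hap, positions = _as_matrix(ril_means, haplotypes)
    nf = int(hap.max()) + 1
    if hap.shape[0] < nf + 2:
        raise ValueError(
            f"need at least n_founders + 2 = {nf + 2} RILs, got {hap.shape[0]}")
    if np.ptp(y) == 0:
        lod = np.zeros(hap.shape[1])
        return ScanResult(positions, lod, len(y),
                          flags={"*": "constant_phenotype"})
    lod, flags = _lod_matrix(y[:, None], hap)
    return ScanResult(positions, lod[:, 0], len(y), flags=flags)


def permutation_threshold(ril_means, haplotypes, n_perms: int = 1000,
                          alpha: float = 0.05,
                          seed: int | None = None,
                          batch: int = 250) -> ScanResult:
    """Scan plus a genome-wide LOD threshold from phenotype permutations.

    Phenotype labels are shuffled across RILs ``n_perms`` times; the
    threshold is the (1 - alpha) quantile (linear interpolation) of the
    per-permutation genome-wide maximum LOD.  A constant phenotype yields
    threshold 0 and is flagged degenerate.
    """
    if n_perms < 20:
        raise ValueError(f"need >= 20 permutations, got {n_perms}")
    result = scan(ril_means, haplotypes)
    y, hap, _ = _as_matrix(ril_means, haplotypes)
    if np.ptp(y) == 0:
        result.threshold = 0.0
        result.alpha = alpha
        result.n_perms = n_perms
        result.flags["*"] = "constant_phenotype"
        return result
    rng = np.random.default_rng(seed)
    max_lods = np.empty(n_perms)
    done = 0
    while done < n_perms:
        b = min(batch, n_perms - done)
        perm_cols = np.column_stack([rng.permutation(y) for _ in range(b)])
        lod, _ = _lod_matrix(perm_cols, hap)
        max_lods[done:done + b] = lod.max(axis=0)
        done += b
    result.threshold = float(np.quantile(max_lods, 1.0 - alpha,
                                         method="linear"))
    result.alpha = alpha
    result.n_perms = n_perms
    result.flags["perm_max_lods"] = max_lods
    return result
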