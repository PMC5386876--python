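"""Synthetic backlit film images of pupae with ground truth.

Pupae are drawn as dark rounded capsules (a rectangle with semicircular
caps) on a bright background, mimicking bottom-illuminated transparency
film.  Every image carries one dark calibration disc emulating a 1-cent
coin of 16.25 mm diameter.  A fraction of pupae is placed in touching
clusters of 2-3 to exercise downstream untangling.

The layout (positions, orientations, true lengths) is planned
deterministically from the seed, so the same film can be rasterized both
in its normal orientation and after a 180-degree rotation of coordinates
with independent pixel noise -- the protocol used to assess measurement
precision with physical films.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["SimImageConfig", "FilmLayout", "PlacementError",
           "plan_film", "rasterize_film", "render_film"]

COIN_DIAMETER_MM = 16.25


class PlacementError(RuntimeError):
    """Raised when pupae cannot be placed without violating overlap rules."""


@dataclass(frozen=True)
class SimImageConfig:
    """Geometry and photometry of a synthetic film image.

    mm_per_px defaults to 0.035 (a typical pupa of 3.5 mm then spans 100
    px and the coin disc ~464 px).  noise_sd is additive Gaussian pixel
    noise on the 0-255 scale; the default was fixed by a pilot run against
    the measurement pipeline as the highest level that leaves detection
    robust.  Smooth ideal capsules re-measure more repeatably than real
    pupae, so end-to-end precision on these films bounds, rather than
    matches, the precision achievable on real films.
    """

    image_size: tuple[int, int] = (1400, 1800)  # (H, W) px
    mm_per_px: float = 0.035
    pupa_length_mm: tuple = ("normal", 3.4, 0.21)
    pupa_aspect: float = 0.29  # width / length
    n_pupae: int = 60
    touch_prob: float = 0.0
    noise_sd: float = 15.0  # additive Gaussian, 0-255 scale; pilot-calibrated
    coin_diameter_mm: float = COIN_DIAMETER_MM
    background: float = 230.0
    pupa_intensity: float = 40.0
    coin_intensity: float = 60.0
    psf_sigma_px: float = 1.0
    psf_sigma_jitter: float = 0.35  # per-exposure focus variation (+/- px)
    max_place_tries: int = 200

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0")
        if not 0 <= self.touch_prob <= 1:
            raise ValueError("touch_prob must lie in [0, 1]")


@dataclass
class FilmLayout:
    """Planned film: capsule segments in pixel coordinates plus the coin."""

    config: SimImageConfig
    # each pupa: (centroid_row, centroid_col, orientation_rad, length_px, width_px, cluster_id)
    pupae: list[tuple] = field(default_factory=list)
    coin_center: tuple[float, float] = (0.0, 0.0)
    coin_radius_px: float = 0.0

    def truth_table(self) -> pd.DataFrame:
        cfg = self.config
        rows = []
        for i, (r, c, theta, length_px, width_px, cluster) in enumerate(self.pupae):
            rows.append({
                "pupa_id": i,
                "centroid_row": r,
                "centroid_col": c,
                "orientation_deg": math.degrees(theta) % 180.0,
                "length_px": length_px,
                "length_mm": length_px * cfg.mm_per_px,
                "width_px": width_px,
                "width_mm": width_px * cfg.mm_per_px,
                "cluster_id": cluster,
            })
        cols = ["pupa_id", "centroid_row", "centroid_col", "orientation_deg",
                "length_px", "length_mm", "width_px", "width_mm", "cluster_id"]
        return pd.DataFrame(rows, columns=cols)

    def rotated180(self) -> "FilmLayout":
        """Coordinates mapped through (H-1-r, W-1-c); true lengths unchanged."""
        H, W = self.config.image_size
        pupae = [(H - 1 - r, W - 1 - c, (theta + math.pi) % (2 * math.pi), L, wd, cl)
                 for (r, c, theta, L, wd, cl) in self.pupae]
        cr, cc = self.coin_center
        return FilmLayout(self.config, pupae, (H - 1 - cr, W - 1 - cc),
                          self.coin_radius_px)


def _draw_length_px(spec, cfg: SimImageConfig, rng: np.random.Generator) -> float:
    if isinstance(spec, (int, float)):
        mm = float(spec)
    else:
        kind = spec[0]
        if kind == "normal":
            mm = float(rng.normal(spec[1], spec[2]))
            mm = float(np.clip(mm, 0.5 * spec[1], 1.5 * spec[1]))
        elif kind == "uniform":
            mm = float(rng.uniform(spec[1], spec[2]))
        elif kind == "fixed":
            mm = float(spec[1])
        else:
            raise ValueError(f"unknown length distribution {spec!r}")
    return mm / cfg.mm_per_px


def _segment_endpoints(r, c, theta, length_px, width_px):
    """Axis segment of the capsule: total length = segment + 2 * radius."""
    half = max(length_px / 2.0 - width_px / 2.0, 0.0)
    dr, dc = math.sin(theta), math.cos(theta)
    return (r - half * dr, c - half * dc), (r + half * dr, c + half * dc)


def _segments_min_dist(p0, p1, q0, q1) -> float:
    """Minimum distance between two 2-D segments."""
    p0, p1, q0, q1 = map(np.asarray, (p0, p1, q0, q1))
    # sample-based lower bound is fine at capsule scales; use fine sampling
    t = np.linspace(0.0, 1.0, 25)
    a = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    b = q0[None, :] + t[:, None] * (q1 - q0)[None, :]
    d = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
    return float(d.min())


def plan_film(config: SimImageConfig, seed: int | None = None) -> FilmLayout:
    """Place the coin and pupae; raises PlacementError if the density
    cannot be achieved under the overlap rules within bounded retries."""
    cfg = config
    rng = np.random.default_rng(seed)
    H, W = cfg.image_size
    coin_r = cfg.coin_diameter_mm / cfg.mm_per_px / 2.0
    if 2 * coin_r + 20 > min(H, W):
        raise PlacementError("image too small for the calibration coin")
    coin_center = (
        float(rng.uniform(coin_r + 10, H - coin_r - 10)),
        float(rng.uniform(coin_r + 10, W - coin_r - 10)),
    )

    layout = FilmLayout(cfg, [], coin_center, coin_r)
    placed = []  # (p0, p1, radius)

    def ok(p0, p1, radius, min_gap) -> bool:
        for (r0, c0) in (p0, p1):
            if not (radius + 2 <= r0 <= H - radius - 2
                    and radius + 2 <= c0 <= W - radius - 2):
                return False
        # keep clear of the coin
        for q in np.linspace(np.asarray(p0), np.asarray(p1), 25):
            if math.hypot(q[0] - coin_center[0], q[1] - coin_center[1]) \
                    < coin_r + radius + 3:
                return False
        for (q0, q1, rad2) in placed:
            if _segments_min_dist(p0, p1, q0, q1) < radius + rad2 + min_gap:
                return False
        return True

    cluster_id = -1
    i = 0
    while i < cfg.n_pupae:
        in_cluster = rng.random() < cfg.touch_prob and i + 1 < cfg.n_pupae
        cluster_size = int(rng.integers(2, 4)) if in_cluster else 1
        cluster_size = min(cluster_size, cfg.n_pupae - i)
        length_px = _draw_length_px(cfg.pupa_length_mm, cfg, rng)
        width_px = length_px * cfg.pupa_aspect
        radius = width_px / 2.0

        for attempt in range(cfg.max_place_tries):
            r = float(rng.uniform(0, H))
            c = float(rng.uniform(0, W))
            theta = float(rng.uniform(0, 2 * math.pi))
            p0, p1 = _segment_endpoints(r, c, theta, length_px, width_px)
            if ok(p0, p1, radius, min_gap=4.0):
                break
        else:
            raise PlacementError(
                f"could not place pupa {i} after {cfg.max_place_tries} tries; "
                f"requested density {cfg.n_pupae} exceeds film capacity")

        if cluster_size > 1:
            cluster_id += 1
        members = [(r, c, theta, length_px, width_px,
                    cluster_id if cluster_size > 1 else -1)]
        # additional cluster members laid side-by-side, just touching; one
        # side per cluster so chains extend outward instead of folding back
        side = 1.0 if rng.random() < 0.5 else -1.0
        for k in range(1, cluster_size):
            placed_member = False
            for attempt in range(cfg.max_place_tries):
                L2 = _draw_length_px(cfg.pupa_length_mm, cfg, rng)
                w2 = L2 * cfg.pupa_aspect
                jitter_theta = theta + float(rng.normal(0, 0.02))
                base_r, base_c, _, _, base_w, _ = members[k - 1]
                # near-parallel with a hair of clearance: the point-spread
                # blur fuses the silhouettes into one thresholded component
                # while a faint gray seam line survives between the bodies
                offset = (base_w + w2) / 2.0 + float(rng.uniform(1.2, 2.8))
                # displace perpendicular to the axis so capsules lie side by side
                r2 = base_r - side * offset * math.cos(jitter_theta)
                c2 = base_c + side * offset * math.sin(jitter_theta)
                shift = float(rng.uniform(-0.25, 0.25)) * L2
                r2 += shift * math.sin(jitter_theta)
                c2 += shift * math.cos(jitter_theta)
                q0, q1 = _segment_endpoints(r2, c2, jitter_theta, L2, w2)
                # `placed` holds earlier pupae only (cluster-mates join later),
                # so a normal clearance check keeps clusters isolated from them
                if ok(q0, q1, w2 / 2.0, min_gap=4.0):
                    members.append((r2, c2, jitter_theta, L2, w2, cluster_id))
                    placed_member = True
                    break
            if not placed_member:
                break  # smaller cluster than drawn; acceptable

        for (mr, mc, mth, mL, mw, mcl) in members:
            e0, e1 = _segment_endpoints(mr, mc, mth, mL, mw)
            placed.append((e0, e1, mw / 2.0))
            layout.pupae.append((mr, mc, mth, mL, mw, mcl))
            i += 1
    return layout


def _paint_capsule(canvas: np.ndarray, p0, p1, radius: float, intensity: float,
                   background: float) -> None:
    """Anti-aliased capsule: coverage from distance to the axis segment."""
    H, W = canvas.shape
    rmin = int(max(0, math.floor(min(p0[0], p1[0]) - radius - 2)))
    rmax = int(min(H, math.ceil(max(p0[0], p1[0]) + radius + 3)))
    cmin = int(max(0, math.floor(min(p0[1], p1[1]) - radius - 2)))
    cmax = int(min(W, math.ceil(max(p0[1], p1[1]) + radius + 3)))
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    a = np.array(p0, dtype=float)
    d = np.array(p1, dtype=float) - a
    denom = float(d @ d)
    pr = rr - a[0]
    pc = cc - a[1]
    if denom == 0:
        dist = np.hypot(pr, pc)
    else:
        t = np.clip((pr * d[0] + pc * d[1]) / denom, 0.0, 1.0)
        dist = np.hypot(pr - t * d[0], pc - t * d[1])
    coverage = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    patch = canvas[rmin:rmax, cmin:cmax]
    np.minimum(patch, background + coverage * (intensity - background),
               out=patch)


def rasterize_film(layout: FilmLayout, rotated: bool = False,
                   noise_seed: int | None = None) -> np.ndarray:
    """Render a planned film to an 8-bit grayscale image."""
    cfg = layout.config
    lay = layout.rotated180() if rotated else layout
    H, W = cfg.image_size
    canvas = np.full((H, W), cfg.background, dtype=float)

    # coin disc
    cr, cc_ = lay.coin_center
    rr, cc = np.mgrid[0:H, 0:W]
    dist = np.hypot(rr - cr, cc - cc_)
    coverage = np.clip(lay.coin_radius_px + 0.5 - dist, 0.0, 1.0)
    canvas = np.minimum(canvas, cfg.background
                        + coverage * (cfg.coin_intensity - cfg.background))

    for (r, c, theta, L, wd, _cl) in lay.pupae:
        p0, p1 = _segment_endpoints(r, c, theta, L, wd)
        _paint_capsule(canvas, p0, p1, wd / 2.0, cfg.pupa_intensity,
                       cfg.background)

    nrng = np.random.default_rng(noise_seed)
    sigma = cfg.psf_sigma_px
    if cfg.psf_sigma_jitter > 0:
        # exposure-to-exposure focus variation: each photograph of the same
        # film is blurred a little differently
        sigma = max(0.0, sigma + float(
            nrng.uniform(-cfg.psf_sigma_jitter, cfg.psf_sigma_jitter)))
    if sigma > 0:
        canvas = ndimage.gaussian_filter(canvas, sigma)
    if cfg.noise_sd > 0:
        canvas = canvas + nrng.normal(0, cfg.noise_sd, canvas.shape)
    return np.clip(canvas, 0, 255).astype(np.uint8)


def render_film(config: SimImageConfig, seed: int | None = None,
                truth_out=None, image_out=None, rotated: bool = False,
                noise_seed: int | None = None):
    """Plan and rasterize a film; returns (image, ground-truth DataFrame).

    The truth table always reports coordinates in the rendered frame: when
    ``rotated`` is set, centroids are mapped through (H-1-r, W-1-c) while
    true lengths are unchanged.
    """
    layout = plan_film(config, seed)
    if noise_seed is None and seed is not None:
        noise_seed = seed * 2 + (1 if rotated else 0)
    image = rasterize_film(layout, rotated=rotated, noise_seed=noise_seed)
    truth = (layout.rotated180() if rotated else layout).truth_table()
    if truth_out is not None:
        truth.to_csv(truth_out, index=False)
    if image_out is not None:
        iio.imwrite(image_out, image)
    return image, truth
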