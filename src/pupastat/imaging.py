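"""Detection, untangling, refinement and measurement of pupae in film images.

The chain mirrors a classical object-based pipeline for backlit films:

1. ``detect_objects`` -- global threshold (Otsu by default, objects dark),
   connected components, no size restriction;
2. ``untangle_clusters`` -- touching pupae separated by a watershed cut
   along the brighter intensity seam between bodies (distance-transform
   watershed as the fallback when no intensity image is available);
3. ``refine_boundaries`` -- each candidate shrunk and re-grown to the
   strongest local intensity-gradient boundary;
4. ``measure_pupa`` -- length along the medial-axis skeleton extended to the
   boundary at both ends (curved pupae are measured along the body), width
   from the distance transform;
5. ``classify_confidence`` -- size/aspect filters plus the 20-px neighbour
   rule that splits valid pupae into high and medium confidence.

Pixel-to-mm conversion comes from a 16.25 mm calibration disc present in
every image (``calibrate``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage import filters, measure, morphology, segmentation, feature

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationRef", "CalibrationError", "SizeFilters", "FilmConfig",
    "detect_objects", "untangle_clusters", "refine_boundaries",
    "measure_pupa", "classify_confidence", "calibrate", "measure_film",
    "make_overlay",
]

COIN_DIAMETER_MM = 16.25


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationRef:
    coin_diameter_mm: float
    coin_diameter_px: float
    mm_per_px: float

    @classmethod
    def from_coin_px(cls, coin_diameter_px: float,
                     coin_diameter_mm: float = COIN_DIAMETER_MM) -> "CalibrationRef":
        return cls(coin_diameter_mm, coin_diameter_px,
                   coin_diameter_mm / coin_diameter_px)


@dataclass(frozen=True)
class SizeFilters:
    """Crude shape filters separating plausible pupae from junk objects.

    Bounds are in mm; aspect is length/width.  Area bounds derive from the
    length/aspect extremes of a capsule (area ~ L*W) with slack.
    """

    length_mm: tuple[float, float] = (1.5, 5.0)
    aspect: tuple[float, float] = (2.0, 5.0)

    @property
    def area_mm2(self) -> tuple[float, float]:
        lo = 0.5 * self.length_mm[0] * (self.length_mm[0] / self.aspect[1])
        hi = 1.5 * self.length_mm[1] * (self.length_mm[1] / self.aspect[0])
        return (lo, hi)

    def passes(self, length_mm: float, aspect: float, area_mm2: float) -> bool:
        return (self.length_mm[0] <= length_mm <= self.length_mm[1]
                and self.aspect[0] <= aspect <= self.aspect[1]
                and self.area_mm2[0] <= area_mm2 <= self.area_mm2[1])


@dataclass(frozen=True)
class FilmConfig:
    """End-to-end configuration for ``measure_film``."""

    mm_per_px: float | str = "auto"  # "auto" = calibrate from the coin
    threshold: float | None = None  # None = Otsu
    size_filters: SizeFilters = SizeFilters()
    neighbor_radius_px: float = 20.0
    expected_length_mm: float = 3.4
    expected_aspect: float = 0.29  # width/length, matches the renderer
    erode_radius_px: int = 3
    min_object_px: int = 30  # specks below this are dropped before measuring
    denoise_sigma_px: float = 1.0  # Gaussian pre-filter before thresholding


def detect_objects(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Label connected components of dark (below-threshold) pixels.

    No size filtering is applied at this stage; the calibration disc and
    any debris are labelled alongside pupae.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got shape {img.shape}")
    img = img.astype(float)
    if threshold is None:
        if img.max() == img.min():
            logger.warning("constant image: no objects detected")
            return np.zeros(img.shape, dtype=np.int32)
        threshold = filters.threshold_otsu(img)
    mask = img < threshold
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return labels.astype(np.int32)


def calibrate(image_or_labels: np.ndarray,
              coin_diameter_mm: float = COIN_DIAMETER_MM,
              min_diameter_px: float = 100.0,
              min_circularity: float = 0.9) -> CalibrationRef:
    """Locate the calibration disc and derive the mm-per-pixel scale.

    Requires exactly one large, highly circular object (4*pi*A/P^2 >= 0.9).
    """
    arr = np.asarray(image_or_labels)
    # label maps from detect_objects are signed ints; images are uint8/float
    if np.issubdtype(arr.dtype, np.signedinteger):
        labels = arr
    else:
        labels = detect_objects(arr)
    candidates = []
    for prop in measure.regionprops(labels):
        if prop.equivalent_diameter_area < min_diameter_px:
            continue
        # clean speckle holes/fringes before judging roundness
        m = ndimage.binary_fill_holes(
            morphology.closing(labels[prop.slice] == prop.label,
                               morphology.disk(3)))
        clean = measure.regionprops(m.astype(np.uint8))[0]
        # Crofton perimeter: unbiased for rasterized discs, unlike the
        # chain-code perimeter which overestimates and sinks circularity
        perim = clean.perimeter_crofton
        if perim == 0:
            continue
        circularity = 4 * math.pi * clean.area / perim**2
        if circularity >= min_circularity:
            candidates.append((prop.label, clean.equivalent_diameter_area))
    if not candidates:
        raise CalibrationError("no circular calibration disc found")
    if len(candidates) > 1:
        raise CalibrationError(
            f"multiple calibration candidates found: {[c[0] for c in candidates]}")
    return CalibrationRef.from_coin_px(candidates[0][1], coin_diameter_mm)


def _clean_markers(markers: np.ndarray, min_px: int) -> tuple[np.ndarray, int]:
    sizes = np.bincount(markers.ravel())
    for lab in np.nonzero(sizes[1:] < min_px)[0] + 1:
        markers[markers == lab] = 0
    return markers, int((np.unique(markers) > 0).sum())


def _split_object(mask: np.ndarray, expected_width_px: float,
                  min_fragment_px: int, patch: np.ndarray | None = None,
                  core_threshold: float | None = None) -> list[np.ndarray]:
    """Watershed split of one merged object; falls back to the input mask.

    Touching pupae fuse below the detection threshold but keep a brighter
    seam line between their dark bodies, so when the image patch is given
    the markers are the connected dark cores under ``core_threshold`` and
    the watershed floods the intensity landscape, cutting along the seam.
    Without intensity information (or when it yields a single core) the
    fallback is a distance-transform watershed seeded at ridge maxima
    spaced at least ~0.8 expected widths apart.
    """
    markers = None
    if patch is not None and core_threshold is not None:
        cores, n = ndimage.label((patch < core_threshold) & mask,
                                 structure=np.ones((3, 3), dtype=int))
        cores, n = _clean_markers(cores, min_px=25)
        if n >= 2:
            markers = cores
            ws = segmentation.watershed(patch, markers, mask=mask)
    if markers is None:
        edt = ndimage.distance_transform_edt(mask)
        coords = feature.peak_local_max(
            edt, min_distance=max(3, int(0.8 * expected_width_px)),
            labels=mask, exclude_border=False)
        if len(coords) < 2:
            return [mask]
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        ws = segmentation.watershed(-edt, markers, mask=mask)
    frags = [ws == lab for lab in np.unique(ws) if lab > 0]
    frags = [f for f in frags if f.sum() >= min_fragment_px]
    if len(frags) < 2:
        return [mask]
    return frags


def untangle_clusters(label_map: np.ndarray,
                      expected_length_px: float = 100.0,
                      expected_width_px: float = 29.0,
                      image: np.ndarray | None = None,
                      threshold: float | None = None) -> np.ndarray:
    """Separate merged objects composed of touching pupae.

    Objects up to ~1.6x a single expected capsule area pass unchanged, as
    do very large objects (the coin; never a 2-3 pupa cluster).  Everything
    in between is watershed-split (see ``_split_object``); passing the
    source ``image`` and detection ``threshold`` enables the more reliable
    intensity-seam split.  Unsplittable blobs pass through for downstream
    low-confidence routing.  Returns a fresh label map.
    """
    single_area = expected_length_px * expected_width_px
    out = np.zeros_like(label_map, dtype=np.int32)
    next_label = 1
    img = None if image is None else np.asarray(image, dtype=float)
    for lab, sl in enumerate(ndimage.find_objects(label_map), start=1):
        if sl is None:
            continue
        submask = label_map[sl] == lab
        area = int(submask.sum())
        if area <= 1.6 * single_area or area > 12 * single_area:
            pieces = [submask]
        else:
            patch = img[sl] if img is not None else None
            core_threshold = None
            if patch is not None:
                interior = float(np.median(patch[submask]))
                outer = threshold if threshold is not None \
                    else float(filters.threshold_otsu(img))
                core_threshold = 0.5 * (interior + outer)
            pieces = _split_object(submask, expected_width_px,
                                   min_fragment_px=int(0.25 * single_area),
                                   patch=patch, core_threshold=core_threshold)
        for piece in pieces:
            out[sl][piece] = next_label
            next_label += 1
    return out


def refine_boundaries(image: np.ndarray, label_map: np.ndarray,
                      erode_radius: int = 3) -> np.ndarray:
    """Shrink each mask and regrow it to the strongest gradient boundary.

    A seed eroded away entirely keeps its original mask (with a warning);
    a refinement drifting past 2x or under 0.5x the original area is
    rejected in favour of the original.
    """
    img = np.asarray(image, dtype=float)
    out = np.zeros_like(label_map, dtype=np.int32)
    selem = morphology.disk(erode_radius)
    margin = erode_radius + 6
    for lab, sl in enumerate(ndimage.find_objects(label_map), start=1):
        if sl is None:
            continue
        rsl = (slice(max(0, sl[0].start - margin), min(label_map.shape[0], sl[0].stop + margin)),
               slice(max(0, sl[1].start - margin), min(label_map.shape[1], sl[1].stop + margin)))
        mask = label_map[rsl] == lab
        seed = morphology.erosion(mask, selem)
        if not seed.any():
            logger.warning("object %d vanished under erosion; keeping original mask", lab)
            out[rsl][mask] = lab
            continue
        patch = img[rsl]
        grad = filters.sobel(patch)
        if grad.max() - grad.min() < 1e-9:
            # featureless surroundings: nothing to repropagate towards
            logger.warning("object %d sits in uniform intensity; mask kept", lab)
            out[rsl][mask] = lab
            continue
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[seed] = 1
        outside = ~morphology.dilation(mask, morphology.disk(3))
        markers[outside] = 2
        ws = segmentation.watershed(grad, markers)
        refined = ws == 1
        # strip any disconnected flood leakage, keep the component on the seed
        lab_ref, _ = ndimage.label(refined)
        seed_labels = np.unique(lab_ref[seed])
        seed_labels = seed_labels[seed_labels > 0]
        if len(seed_labels):
            refined = np.isin(lab_ref, seed_labels)
        area0, area1 = mask.sum(), refined.sum()
        if area1 == 0 or not (0.5 * area0 <= area1 <= 2.0 * area0):
            refined = mask
        out[rsl][refined] = lab
    return out


@dataclass(frozen=True)
class PupaMeasure:
    length_px: float
    width_px: float
    area_px: float
    centroid: tuple[float, float]
    orientation_deg: float
    ellipse_major_px: float
    flags: str = ""


# Kulpa's unbiased chain-length weights: a raw 8-connected pixel path
# overestimates Euclidean length by up to ~8% depending on orientation
_KULPA_STRAIGHT = 0.948
_KULPA_DIAGONAL = 1.340


def _skeleton_geodesic(skel: np.ndarray) -> tuple[float, tuple, tuple]:
    """Longest geodesic path length over a skeleton (px) and its endpoints."""
    pts = np.argwhere(skel)
    n = len(pts)
    if n < 2:
        return 0.0, pts
    index = -np.ones(skel.shape, dtype=int)
    index[tuple(pts.T)] = np.arange(n)
    rows, cols, data = [], [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1)]
    for dr, dc in offsets:
        shifted = pts + (dr, dc)
        valid = ((shifted[:, 0] >= 0) & (shifted[:, 0] < skel.shape[0])
                 & (shifted[:, 1] >= 0) & (shifted[:, 1] < skel.shape[1]))
        j = np.full(n, -1)
        j[valid] = index[tuple(shifted[valid].T)]
        hit = j >= 0
        w = _KULPA_DIAGONAL if dr and dc else _KULPA_STRAIGHT
        rows.extend(np.nonzero(hit)[0])
        cols.extend(j[hit])
        data.extend([w] * int(hit.sum()))
    graph = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    graph = graph + graph.T
    d0 = dijkstra(graph, indices=0, directed=False)
    d0[~np.isfinite(d0)] = -1
    u = int(np.argmax(d0))
    du, pred = dijkstra(graph, indices=u, directed=False,
                        return_predecessors=True)
    du[~np.isfinite(du)] = -1
    v = int(np.argmax(du))
    path = [v]
    while path[-1] != u and pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    path_pts = pts[path]  # ordered v -> u
    return float(du[v]), path_pts


def _extend_to_boundary(mask: np.ndarray, end: np.ndarray,
                        direction: np.ndarray, max_steps: float) -> float:
    """Distance from a path endpoint to the mask boundary along a ray.

    The mask is sampled with bilinear interpolation and the 0.5-crossing
    located by linear interpolation, giving a sub-pixel edge position.
    """
    norm = float(np.hypot(*direction))
    if norm == 0:
        return 0.0
    d = direction / norm
    step = 0.2
    ts = np.arange(step, max_steps + step, step)
    coords = np.stack([end[0] + ts * d[0], end[1] + ts * d[1]])
    vals = ndimage.map_coordinates(mask.astype(float), coords, order=1,
                                   mode="constant", cval=0.0)
    below = np.nonzero(vals < 0.5)[0]
    if len(below) == 0:
        return float(ts[-1])
    i = below[0]
    if i == 0:
        return 0.0
    # linear interpolation of the 0.5 crossing between samples i-1 and i
    v0, v1 = vals[i - 1], vals[i]
    frac = (v0 - 0.5) / (v0 - v1) if v0 != v1 else 0.5
    return float(ts[i - 1] + frac * step)


def measure_pupa(mask: np.ndarray, mm_per_px: float | None = None) -> PupaMeasure:
    """Measure one pupa mask: skeleton length, EDT width, area, orientation.

    Length is the geodesic length of the medial-axis skeleton extended to
    the mask boundary at both ends (using the distance transform at the
    endpoints), so curved pupae are measured along the body.  Masks too thin
    to skeletonize fall back to the ellipse major axis and are flagged.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    orientation_deg = (90.0 - math.degrees(props.orientation)) % 180.0
    edt = ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
    skel = morphology.skeletonize(mask)
    flags = ""
    # masks thinner than ~2 px everywhere cannot anchor a medial axis
    if skel.sum() >= 2 and edt.max() >= 1.5:
        _, path_pts = _skeleton_geodesic(skel)
        # smooth the pixel path to suppress staircase zigzag, then take the
        # polyline arc length of the smoothed curve
        smooth = ndimage.gaussian_filter1d(path_pts.astype(float), sigma=3.0,
                                           axis=0, mode="nearest")
        path_len = float(np.hypot(*np.diff(smooth, axis=0).T).sum())
        # extend each end to the boundary along its terminal direction
        max_reach = 2.0 * edt.max() + 3
        ext = 0.0
        for end_slice in (slice(0, 9), slice(-9, None)):
            seg = smooth[end_slice]
            end = seg[0] if end_slice.start == 0 else seg[-1]
            inner = seg.mean(axis=0)
            ext += _extend_to_boundary(mask, end, end - inner, max_reach)
        length_px = path_len + ext
        if length_px < props.axis_major_length * 0.7:
            # fragmented skeleton; the ellipse axis is more trustworthy
            length_px = float(props.axis_major_length)
            flags = "ellipse_fallback"
        skel_edt = edt[skel]
        width_px = 2.0 * float(skel_edt.mean())
    else:
        length_px = float(props.axis_major_length)
        width_px = float(props.axis_minor_length)
        flags = "ellipse_fallback"
    return PupaMeasure(
        length_px=length_px,
        width_px=width_px,
        area_px=float(props.area),
        centroid=tuple(props.centroid),
        orientation_deg=orientation_deg,
        ellipse_major_px=float(props.axis_major_length),
        flags=flags,
    )


def _neighbor_gaps(label_map: np.ndarray, records: pd.DataFrame,
                   max_relevant: float = 200.0) -> np.ndarray:
    """Minimum boundary-to-boundary gap (px) to any other object, per record.

    Candidate neighbours are pre-filtered by centroid distance; pairs
    farther than ``max_relevant`` px report inf.
    """
    boundaries = {}
    eroded = {}
    for lab, sl in enumerate(ndimage.find_objects(label_map), start=1):
        if sl is None:
            continue
        m = label_map[sl] == lab
        b = m & ~morphology.erosion(m, morphology.disk(1))
        pts = np.argwhere(b) + (sl[0].start, sl[1].start)
        boundaries[lab] = pts
    labs = records["label"].to_numpy()
    cents = records[["centroid_row", "centroid_col"]].to_numpy()
    half_ext = records["length_px"].to_numpy() / 2.0
    gaps = np.full(len(records), np.inf)
    if len(records) < 2:
        return gaps
    tree = cKDTree(cents)
    for i in range(len(records)):
        reach = half_ext[i] + half_ext.max() + max_relevant
        cand = tree.query_ball_point(cents[i], reach)
        pts_i = boundaries.get(labs[i])
        if pts_i is None or not len(pts_i):
            continue
        tree_i = cKDTree(pts_i)
        for j in cand:
            if j == i:
                continue
            pts_j = boundaries.get(labs[j])
            if pts_j is None or not len(pts_j):
                continue
            d, _ = tree_i.query(pts_j, k=1)
            gaps[i] = min(gaps[i], float(d.min()))
    return gaps


def classify_confidence(records: pd.DataFrame,
                        label_map: np.ndarray | None = None,
                        neighbor_radius_px: float = 20.0,
                        size_filters: SizeFilters = SizeFilters()) -> pd.DataFrame:
    """Assign {high, medium, low} confidence to measured objects.

    low: fails the size/aspect filters.  Otherwise high if the nearest
    other object is farther than ``neighbor_radius_px`` (boundary-to-
    boundary gap), else medium.  A lone object on the film is high.
    """
    records = records.copy()
    if "neighbor_gap_px" not in records.columns:
        if label_map is None:
            raise ValueError("need label_map or a neighbor_gap_px column")
        records["neighbor_gap_px"] = _neighbor_gaps(label_map, records)
    shape_ok = records.apply(
        lambda r: size_filters.passes(r["length_mm"], r["aspect"], r["area_mm2"]),
        axis=1) if len(records) else pd.Series(dtype=bool)
    conf = np.where(~shape_ok, "low",
                    np.where(records["neighbor_gap_px"] > neighbor_radius_px,
                             "high", "medium"))
    records["confidence"] = conf
    return records


def measure_film(image, config: FilmConfig = FilmConfig(),
                 film_id: str = "film") -> pd.DataFrame:
    """Run the full chain on one film image (array or path).

    Returns one row per candidate object with pixel and mm measurements,
    confidence class, and an ``excluded`` flag (False here; manual-style
    exclusion is simulated downstream).  Deterministic for a fixed image.
    """
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        try:
            image = iio.imread(image)
        except (OSError, ValueError) as exc:
            raise IOError(f"cannot read image {image!r}: {exc}") from exc
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    img = img.astype(float)
    if config.denoise_sigma_px > 0:
        img = ndimage.gaussian_filter(img, config.denoise_sigma_px)

    threshold = config.threshold
    if threshold is None and img.max() > img.min():
        threshold = float(filters.threshold_otsu(img))
    labels = detect_objects(img, threshold=threshold)
    if config.mm_per_px == "auto":
        cal = calibrate(labels)
        mm_per_px = cal.mm_per_px
    else:
        mm_per_px = float(config.mm_per_px)

    exp_len_px = config.expected_length_mm / mm_per_px
    exp_wid_px = exp_len_px * config.expected_aspect
    labels = untangle_clusters(labels, exp_len_px, exp_wid_px,
                               image=img, threshold=threshold)
    labels = refine_boundaries(img, labels, erode_radius=config.erode_radius_px)

    rows = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        if mask.sum() < config.min_object_px:
            labels[sl][mask] = 0
            continue
        m = measure_pupa(mask)
        rows.append({
            "film_id": film_id,
            "pupa_id": lab,
            "label": lab,
            "centroid_row": m.centroid[0] + sl[0].start,
            "centroid_col": m.centroid[1] + sl[1].start,
            "length_px": m.length_px,
            "length_mm": m.length_px * mm_per_px,
            "width_mm": m.width_px * mm_per_px,
            "area_mm2": m.area_px * mm_per_px**2,
            "orientation_deg": m.orientation_deg,
            "aspect": m.length_px / m.width_px if m.width_px > 0 else np.inf,
            "flags": m.flags,
        })
    cols = ["film_id", "pupa_id", "label", "centroid_row", "centroid_col",
            "length_px", "length_mm", "width_mm", "area_mm2",
            "orientation_deg", "aspect", "flags"]
    records = pd.DataFrame(rows, columns=cols)
    records = classify_confidence(records, labels,
                                  config.neighbor_radius_px,
                                  config.size_filters)
    records["excluded"] = False
    records.attrs["mm_per_px"] = mm_per_px
    records.attrs["label_map"] = labels
    return records


_CLASS_COLORS = {"high": (40, 90, 255), "medium": (255, 60, 60),
                 "low": (250, 220, 40)}


def make_overlay(image: np.ndarray, records: pd.DataFrame,
                 label_map: np.ndarray | None = None) -> np.ndarray:
    """RGB overlay: object outlines coloured by confidence class
    (blue high, red medium, yellow low)."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if label_map is None:
        label_map = records.attrs.get("label_map")
        if label_map is None:
            raise ValueError("need a label map to draw outlines")
    rgb = np.stack([img] * 3, axis=-1).astype(np.uint8)
    conf_by_label = dict(zip(records["label"], records["confidence"]))
    for lab, sl in enumerate(ndimage.find_objects(label_map), start=1):
        if sl is None or lab not in conf_by_label:
            continue
        m = label_map[sl] == lab
        outline = m & ~morphology.erosion(m, morphology.disk(1))
        color = _CLASS_COLORS[conf_by_label[lab]]
        patch = rgb[sl]
        patch[outline] = color
    return rgb
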