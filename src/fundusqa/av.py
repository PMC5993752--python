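"""Artery/vein classification from the optical density ratio (ODR).

Oxygenated arterial blood absorbs the two channels differently from venous
blood, so the per-pixel ratio ODR = (R - G)/G separates the two vessel
classes: arteries show a lower ODR than veins.  The vessel map is
decomposed into centerline segments (skeleton paths between branch
points), each segment gets the mean ODR along its centerline, and a global
brightness threshold on the segment means labels below-threshold segments
artery and above-threshold segments vein.  An optional refinement pass
uses the anatomical rule that an artery is narrower than its accompanying
vein to fix near-threshold pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .channels import _as_2d
from .errors import InvalidInputError
from .segmentation import VesselMask

__all__ = [
    "VesselSegment",
    "odr_map",
    "extract_segments",
    "segment_mean_odr",
    "otsu_split",
    "classify_av",
]


@dataclass
class VesselSegment:
    """One centerline path with its per-segment measurements."""

    segment_id: int
    centerline: np.ndarray  # (N, 2) ordered (row, col) pixel coordinates
    mean_odr: float | None = None
    mean_diameter_um: float | None = None
    tortuosity: float | None = None
    label: str = "unknown"  # "artery" | "vein" | "unknown"

    @property
    def n_points(self) -> int:
        return len(self.centerline)


def odr_map(red, green, mask: VesselMask | np.ndarray, g_floor: float = 1.0) -> np.ndarray:
    """Per-pixel (R - G) / max(G, g_floor) on vessel pixels, NaN elsewhere.

    ``g_floor`` guards against division blow-up where the green intensity
    approaches zero; it must be positive.
    """
    r = _as_2d(red)
    g = _as_2d(green)
    m = mask.pixels if isinstance(mask, VesselMask) else np.asarray(mask, dtype=bool)
    if r.shape != g.shape or r.shape != m.shape:
        raise InvalidInputError(
            f"shape mismatch: red {r.shape}, green {g.shape}, mask {m.shape}"
        )
    if g_floor <= 0:
        raise InvalidInputError("g_floor must be positive")
    out = np.full(r.shape, np.nan)
    denom = np.maximum(g, g_floor)
    out[m] = (r[m] - g[m]) / denom[m]
    return out


_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _trace_path(coords: np.ndarray) -> np.ndarray:
    """Order a set of 8-connected skeleton pixels into a path.

    Starts from an endpoint (pixel with a single neighbour) when one
    exists, otherwise from the first pixel (small residual loops), and
    walks greedily to the nearest unvisited 8-neighbour.
    """
    coord_set = {tuple(c) for c in coords}
    pix = [tuple(c) for c in coords]

    def neighbours(p):
        r, c = p
        return [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr or dc) and (r + dr, c + dc) in coord_set
        ]

    degree = {p: len(neighbours(p)) for p in pix}
    endpoints = [p for p in pix if degree[p] <= 1]
    start = endpoints[0] if endpoints else pix[0]

    path = [start]
    visited = {start}
    current = start
    while True:
        nxt = [p for p in neighbours(current) if p not in visited]
        if not nxt:
            break
        # prefer 4-connected steps to keep the path tight
        nxt.sort(key=lambda p: abs(p[0] - current[0]) + abs(p[1] - current[1]))
        current = nxt[0]
        visited.add(current)
        path.append(current)
    return np.array(path, dtype=np.intp)


def _arc_length(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    return float(np.hypot(*np.diff(path.astype(float), axis=0).T).sum())


def _prune_spurs(skel: np.ndarray, spur_min_px: int) -> np.ndarray:
    """Delete dangling skeleton twigs shorter than ``spur_min_px``.

    Boundary bumps of the mask sprout short side-twigs on the skeleton;
    each twig turns its attachment pixel into a junction and would split
    one vessel into two.  A twig is a branch (junction-free skeleton
    component) that contains a skeleton endpoint; removing short twigs and
    repeating until stable lets the main paths run unbroken through the
    former attachment points.
    """
    skel = skel.copy()
    for _ in range(4):
        n_neigh = ndimage.convolve(skel.astype(np.uint8), _NEIGH, mode="constant")
        junction = skel & (n_neigh >= 3)
        endpoint = skel & (n_neigh == 1)
        lbl, n = ndimage.label(skel & ~junction, structure=np.ones((3, 3)))
        removed = False
        for comp in range(1, n + 1):
            coords = lbl == comp
            if coords.sum() < spur_min_px and endpoint[coords].any():
                skel[coords] = False
                removed = True
        if not removed:
            break
    return skel


def extract_segments(
    mask: VesselMask | np.ndarray,
    min_length_px: int = 30,
    spur_min_px: int = 15,
) -> list[VesselSegment]:
    """Skeletonise the mask and split the skeleton at branch points.

    Dangling skeleton twigs shorter than ``spur_min_px`` are pruned first
    (see :func:`_prune_spurs`); then branch-point pixels (three or more
    skeleton neighbours) are deleted and every remaining connected path
    whose arc length reaches ``min_length_px`` becomes one unlabeled
    segment with an ordered centerline.
    """
    m = mask.pixels if isinstance(mask, VesselMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    skel = skeletonize(m)
    if spur_min_px > 0:
        skel = _prune_spurs(skel, spur_min_px)
    n_neigh = ndimage.convolve(skel.astype(np.uint8), _NEIGH, mode="constant")
    branch = skel & (n_neigh >= 3)
    pruned = skel & ~branch
    labeled, n = ndimage.label(pruned, structure=np.ones((3, 3)))
    segments: list[VesselSegment] = []
    sid = 0
    for comp in range(1, n + 1):
        coords = np.argwhere(labeled == comp)
        path = _trace_path(coords)
        if len(path) < len(coords):  # untraceable residue (loop/junction)
            path = coords
        if _arc_length(path) < min_length_px or len(path) < 2:
            continue
        segments.append(VesselSegment(segment_id=sid, centerline=path))
        sid += 1
    return segments


def segment_mean_odr(segment: VesselSegment, odr: np.ndarray) -> float:
    vals = odr[segment.centerline[:, 0], segment.centerline[:, 1]]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InvalidInputError(
            f"segment {segment.segment_id}: no centerline pixel with defined ODR"
        )
    return float(vals.mean())


def otsu_split(values: np.ndarray) -> float:
    """Exact 2-class Otsu threshold for a small 1-D sample.

    Exhaustively maximises the between-class variance over all splits of
    the sorted values; returns the midpoint between the two boundary
    values.  Suitable for the handful of per-segment means produced by one
    scene (histogram-based Otsu needs many samples).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2 or v[0] == v[-1]:
        raise InvalidInputError("need >= 2 distinct values for an automatic split")
    best, best_t = -np.inf, None
    for k in range(1, v.size):
        lo, hi = v[:k], v[k:]
        between = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if between > best:
            best, best_t = between, 0.5 * (v[k - 1] + v[k])
    return float(best_t)


def _segment_direction(seg: VesselSegment) -> np.ndarray:
    d = seg.centerline[-1].astype(float) - seg.centerline[0].astype(float)
    n = np.hypot(*d)
    return d / n if n > 0 else np.array([1.0, 0.0])


def _min_centerline_distance(a: VesselSegment, b: VesselSegment) -> float:
    # subsample for speed; adequate for an adjacency test
    pa = a.centerline[:: max(1, len(a.centerline) // 50)].astype(float)
    pb = b.centerline[:: max(1, len(b.centerline) // 50)].astype(float)
    d = np.hypot(
        pa[:, None, 0] - pb[None, :, 0], pa[:, None, 1] - pb[None, :, 1]
    )
    return float(d.min())


def classify_av(
    segments: list[VesselSegment],
    odr: np.ndarray,
    threshold: str | float = "otsu",
    refine: bool = True,
    pairing_radius_px: float = 40.0,
    parallel_tol_deg: float = 30.0,
    refine_margin: float = 0.15,
) -> tuple[list[VesselSegment], float | None]:
    """Label every segment artery or vein by its mean centerline ODR.

    The threshold over segment-mean ODRs is found by exact 2-class Otsu
    (or given as a fixed float); segments below it become arteries, the
    rest veins.  With ``refine=True``, spatially adjacent near-parallel
    same-label pairs whose mean ODRs both fall within ``refine_margin`` of
    the threshold are re-labeled by the width rule (narrower -> artery,
    wider -> vein), provided their diameters are known.

    Returns the labeled segments and the threshold used (None when the
    scene was degenerate and labels stay "unknown").
    """
    for seg in segments:
        seg.mean_odr = segment_mean_odr(seg, odr)

    means = np.array([s.mean_odr for s in segments])
    if isinstance(threshold, (int, float)):
        t = float(threshold)
    else:
        if len(segments) < 2 or np.ptp(means) == 0:
            warnings.warn(
                "cannot auto-threshold (<2 segments or identical ODRs); "
                "labels left unknown",
                stacklevel=2,
            )
            for seg in segments:
                seg.label = "unknown"
            return segments, None
        t = otsu_split(means)

    for seg in segments:
        seg.label = "artery" if seg.mean_odr < t else "vein"

    if refine:
        candidates = [
            s
            for s in segments
            if s.mean_diameter_um is not None and abs(s.mean_odr - t) < refine_margin
        ]
        for i, a in enumerate(candidates):
            for b in candidates[i + 1 :]:
                if a.label != b.label:
                    continue
                da, db = _segment_direction(a), _segment_direction(b)
                ang = np.degrees(np.arccos(np.clip(abs(np.dot(da, db)), 0, 1)))
                if ang > parallel_tol_deg:
                    continue
                if _min_centerline_distance(a, b) > pairing_radius_px:
                    continue
                narrow, wide = (
                    (a, b) if a.mean_diameter_um <= b.mean_diameter_um else (b, a)
                )
                narrow.label, wide.label = "artery", "vein"
    return segments, t
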