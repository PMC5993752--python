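"""Synthetic fundus scenes with exactly known vessel ground truth.

Real wide-field fundus photographs come with no pixel-level truth, so every
stage of the analysis pipeline is exercised here on rendered phantoms: a
small tree of primary vessels radiating from a disc-like origin, arteries
narrower and with lower optical density ratio (ODR = (R-G)/G) than veins,
drawn dark-in-green on a red-predominated background whose channel means
keep the red:green:blue ratio near 16:4:1.  Vessel centerlines carry a
sinusoidal lateral perturbation whose arc/chord tortuosity is known
analytically, so diameter, tortuosity and AVR recovery can be scored
against truth.

The generator is deliberately simple where realism does not pay for
itself: no choroidal texture, no optic-disc rendering, no branching beyond
primary vessels by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .channels import FundusImage
from .errors import InvalidSpecificationError

__all__ = [
    "VesselTreeSpec",
    "RenderSpec",
    "TrueSegment",
    "GroundTruth",
    "generate_vessel_tree",
    "render_fundus",
    "simulate_scene",
    "LABEL_BACKGROUND",
    "LABEL_ARTERY",
    "LABEL_VEIN",
]

LABEL_BACKGROUND = 0
LABEL_ARTERY = 1
LABEL_VEIN = 2
_LABEL_NAMES = {LABEL_ARTERY: "artery", LABEL_VEIN: "vein"}


@dataclass
class VesselTreeSpec:
    """Geometry of the synthetic vessel tree.

    Vein diameters sit strictly above artery diameters by default,
    mirroring the anatomical rule (the artery is narrower than its
    accompanying vein) that the classifier's refinement pass relies on.
    ``tortuosity_amplitude`` is the lateral sine amplitude as a fraction of
    the sine wavelength; 0 gives perfectly straight vessels.
    """

    n_primary_vessels: int = 6
    artery_diameter_range_um: tuple[float, float] = (150.0, 180.0)
    vein_diameter_range_um: tuple[float, float] = (200.0, 240.0)
    tortuosity_amplitude: float = 0.07
    image_extent_um: float = 8192.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_primary_vessels < 1:
            raise InvalidSpecificationError("n_primary_vessels must be >= 1")
        for name, rng in (
            ("artery_diameter_range_um", self.artery_diameter_range_um),
            ("vein_diameter_range_um", self.vein_diameter_range_um),
        ):
            lo, hi = rng
            if not (0 < lo <= hi):
                raise InvalidSpecificationError(f"{name} must be positive and ordered")
        if self.tortuosity_amplitude < 0:
            raise InvalidSpecificationError("tortuosity_amplitude must be >= 0")
        if self.image_extent_um <= 0:
            raise InvalidSpecificationError("image_extent_um must be positive")


@dataclass
class RenderSpec:
    """Rasterisation parameters for a synthetic scene.

    Default background RGB means (120, 30, 8) reproduce the red-dominated
    statistics of trans-scleral illumination (red mean ~4x green, ~16x
    blue).  Vessel colours are darker than background in the green channel
    — that is where segmentation contrast lives — and chosen so the artery
    ODR (2.0) lies well below the vein ODR (4.0).
    """

    height_px: int = 512
    width_px: int = 512
    pixel_pitch_um: float = 16.0
    background_rgb_means: tuple[float, float, float] = (120.0, 30.0, 8.0)
    artery_rgb: tuple[float, float, float] = (60.0, 20.0, 6.0)
    vein_rgb: tuple[float, float, float] = (70.0, 14.0, 5.0)
    illumination_field_amplitude: float = 0.2
    noise_sd: float = 2.0
    seed: int = 0
    scale_max: float = 255.0

    def validate(self) -> None:
        if self.height_px < 8 or self.width_px < 8:
            raise InvalidSpecificationError("image must be at least 8x8 pixels")
        if self.pixel_pitch_um <= 0:
            raise InvalidSpecificationError("pixel_pitch_um must be positive")
        if not (0 <= self.illumination_field_amplitude < 1):
            raise InvalidSpecificationError(
                "illumination_field_amplitude must lie in [0, 1)"
            )
        if self.noise_sd < 0:
            raise InvalidSpecificationError("noise_sd must be >= 0")

    def odr(self, rgb: tuple[float, float, float]) -> float:
        r, g, _ = rgb
        return (r - g) / g


@dataclass
class TrueSegment:
    """One generated vessel: analytic centerline plus its true metrics."""

    segment_id: int
    label: str  # "artery" | "vein"
    polyline_um: np.ndarray  # (N, 2) of (x, y) in micrometres
    diameter_um: float
    tortuosity: float


@dataclass
class GroundTruth:
    """Pixel-level truth for a rendered scene.

    ``mask`` is exactly ``label_map != LABEL_BACKGROUND``; ``segments``
    carry centerlines converted to (row, col) pixel coordinates.
    """

    mask: np.ndarray  # bool H x W
    label_map: np.ndarray  # uint8 H x W of LABEL_* codes
    segments: list  # of TrueSegment with polyline in pixel coords

    def class_mean_diameter_um(self, label: str) -> float:
        vals = [s.diameter_um for s in self.segments if s.label == label]
        return float(np.mean(vals))

    def class_mean_tortuosity(self, label: str) -> float:
        vals = [s.tortuosity for s in self.segments if s.label == label]
        return float(np.mean(vals))


def _lateral_offset(s: np.ndarray, amp: float, wavelength: float) -> np.ndarray:
    """Sinusoidal meander with a smooth amplitude ramp over the first
    wavelength, so vessels emerge radially from the disc and meander only
    peripherally."""
    u = np.clip(s / wavelength, 0.0, 1.0)
    ramp = u * u * (3.0 - 2.0 * u)
    return amp * np.sin(2 * np.pi * s / wavelength) * ramp


def _curve_arc_chord(amp: float, wavelength: float, length: float) -> float:
    # dense numeric arc-length of the ramped sinusoid over its chord
    s = np.linspace(0.0, length, 8193)
    y = _lateral_offset(s, amp, wavelength)
    arc = float(np.hypot(np.diff(s), np.diff(y)).sum())
    return arc / length


def generate_vessel_tree(spec: VesselTreeSpec) -> list[TrueSegment]:
    """Generate primary vessels radiating from a disc-like origin.

    Labels alternate artery/vein so both classes are present whenever
    ``n_primary_vessels >= 2``.  Each centerline is a straight ray plus a
    lateral sinusoid completing an integer number of periods, which pins
    the chord to the ray and makes the arc/chord tortuosity analytic; the
    recorded true tortuosity is a dense numeric arc-length evaluation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    extent = spec.image_extent_um
    origin = np.array([0.38 * extent, 0.5 * extent])
    n = spec.n_primary_vessels
    base_angles = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    segments: list[TrueSegment] = []
    for i in range(n):
        label = "artery" if i % 2 == 0 else "vein"
        lo, hi = (
            spec.artery_diameter_range_um
            if label == "artery"
            else spec.vein_diameter_range_um
        )
        diameter = float(rng.uniform(lo, hi))
        angle = base_angles[i] + rng.uniform(-0.25, 0.25)
        direction = np.array([math.cos(angle), math.sin(angle)])
        normal = np.array([-direction[1], direction[0]])

        amp_frac = spec.tortuosity_amplitude * float(rng.uniform(0.7, 1.3))
        margin = 0.5 * diameter + 0.04 * extent
        start = origin + direction * (0.06 * extent)
        # longest t with the unperturbed ray inside the margin box
        t_max = extent
        for k in range(2):
            d = direction[k]
            if d > 1e-12:
                t_max = min(t_max, (extent - margin - start[k]) / d)
            elif d < -1e-12:
                t_max = min(t_max, (margin - start[k]) / d)
        if t_max <= 0.05 * extent:
            t_max = 0.05 * extent
        length = t_max

        n_periods = int(rng.integers(2, 4))
        wavelength = length / n_periods
        # cap the lateral excursion by the non-diameter part of the margin
        amp = min(amp_frac * wavelength, 0.04 * extent)

        n_pts = max(64, int(round(length / 4.0)))  # ~4 um sampling
        s = np.linspace(0.0, length, n_pts)
        offset = _lateral_offset(s, amp, wavelength)
        pts = start[None, :] + s[:, None] * direction[None, :] + offset[:, None] * normal[None, :]
        np.clip(pts, 0.5 * diameter, extent - 0.5 * diameter, out=pts)

        tort = _curve_arc_chord(amp, wavelength, length) if amp > 0 else 1.0
        segments.append(
            TrueSegment(
                segment_id=i,
                label=label,
                polyline_um=pts,
                diameter_um=diameter,
                tortuosity=tort,
            )
        )
    return segments


def _resample_px(polyline_px: np.ndarray, step: float = 0.4) -> np.ndarray:
    """Resample a polyline at roughly uniform sub-pixel spacing."""
    d = np.hypot(*np.diff(polyline_px, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(d)])
    total = arc[-1]
    if total <= 0:
        return polyline_px[:1]
    n = max(2, int(math.ceil(total / step)) + 1)
    t = np.linspace(0.0, total, n)
    return np.column_stack(
        [np.interp(t, arc, polyline_px[:, 0]), np.interp(t, arc, polyline_px[:, 1])]
    )


def render_fundus(
    segments: list[TrueSegment], render: RenderSpec
) -> tuple[FundusImage, GroundTruth]:
    """Rasterise a vessel tree into an RGB fundus phantom plus ground truth.

    Vessels are drawn with anti-aliased edges (linear coverage over one
    pixel) at width ``diameter / pixel_pitch``; a multiplicative cosine
    illumination bump and additive clipped Gaussian noise are applied on
    top.  The ground-truth mask marks pixels with >= 50% vessel coverage,
    so its width matches the true diameter.
    """
    render.validate()
    h, w = render.height_px, render.width_px
    pitch = render.pixel_pitch_um

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(render.background_rgb_means)

    label_map = np.zeros((h, w), dtype=np.uint8)
    best_dist = np.full((h, w), np.inf)
    gt_segments: list[TrueSegment] = []

    for seg in segments:
        radius_px = 0.5 * seg.diameter_um / pitch
        if 2 * radius_px >= min(h, w):
            raise InvalidSpecificationError(
                f"segment {seg.segment_id}: vessel wider than the image"
            )
        # (x, y) um -> (row, col) px; row ~ y, col ~ x
        poly_px = np.column_stack(
            [seg.polyline_um[:, 1] / pitch, seg.polyline_um[:, 0] / pitch]
        )
        if (poly_px < -0.5).any() or (poly_px[:, 0] > h - 0.5).any() or (
            poly_px[:, 1] > w - 0.5
        ).any():
            raise InvalidSpecificationError(
                f"segment {seg.segment_id}: centerline outside the image field"
            )
        dense = _resample_px(poly_px)
        canvas = np.zeros((h, w), dtype=bool)
        rr = np.clip(np.rint(dense[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.rint(dense[:, 1]).astype(int), 0, w - 1)
        canvas[rr, cc] = True
        dist = ndimage.distance_transform_edt(~canvas)

        alpha = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
        color = render.artery_rgb if seg.label == "artery" else render.vein_rgb
        img = img * (1.0 - alpha[..., None]) + np.asarray(color) * alpha[..., None]

        inside = (dist <= radius_px) & (dist < best_dist)
        code = LABEL_ARTERY if seg.label == "artery" else LABEL_VEIN
        label_map[inside] = code
        best_dist[inside] = dist[inside]

        gt_segments.append(
            TrueSegment(
                segment_id=seg.segment_id,
                label=seg.label,
                polyline_um=poly_px,  # (row, col) pixel coords
                diameter_um=seg.diameter_um,
                tortuosity=seg.tortuosity,
            )
        )

    if render.illumination_field_amplitude > 0:
        u = np.linspace(-0.5, 0.5, w)[None, :]
        v = np.linspace(-0.5, 0.5, h)[:, None]
        bump = np.cos(np.pi * u) * np.cos(np.pi * v)
        img = img * (1.0 + render.illumination_field_amplitude * bump)[..., None]

    if render.noise_sd > 0:
        rng = np.random.default_rng(render.seed)
        img = img + rng.normal(0.0, render.noise_sd, size=img.shape)

    np.clip(img, 0.0, render.scale_max, out=img)

    image = FundusImage(
        pixels=img, pixel_pitch_um=pitch, scale_max=render.scale_max
    )
    truth = GroundTruth(
        mask=label_map != LABEL_BACKGROUND, label_map=label_map, segments=gt_segments
    )
    return image, truth


def simulate_scene(
    tree: VesselTreeSpec | None = None, render: RenderSpec | None = None, seed: int = 0
) -> tuple[FundusImage, GroundTruth]:
    """Convenience wrapper: default tree + render, both driven by ``seed``."""
    tree = tree if tree is not None else VesselTreeSpec(seed=seed)
    render = render if render is not None else RenderSpec(seed=seed + 1)
    return render_fundus(generate_vessel_tree(tree), render)
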