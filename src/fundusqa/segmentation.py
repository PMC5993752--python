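"""Matched-filter vessel segmentation of the green channel.

The classic vessel matched filter: a bank of oriented, zero-mean kernels
with a Gaussian cross-profile (constant along the local vessel axis) is
convolved with the green channel, the pixel-wise maximum over all
orientations and scales forms the enhanced vessel image, white top-hat
filtering removes smooth illumination drift, and a global threshold
produces the binary vessel map.

Vessels are darker than background in the green channel, so the channel is
negated before filtering; because every kernel is zero-mean, negation is
exactly equivalent to inverting about any constant level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu
from skimage.morphology import (
    disk,
    opening,
    reconstruction,
    remove_small_holes,
    remove_small_objects,
)

from .channels import _as_2d
from .errors import (
    DegenerateInputError,
    InvalidInputError,
    InvalidSpecificationError,
)

__all__ = [
    "MatchedKernel",
    "KernelBank",
    "VesselMask",
    "SegmentationParams",
    "build_kernel_bank",
    "enhance",
    "correct_illumination",
    "threshold_global",
    "segment_vessels",
]

DEFAULT_N_ORIENT = 12
# geometric ladder of vessel half-width scales; spans widths of roughly
# 3-18 px, i.e. 50-290 um at the default 16 um/px pitch
DEFAULT_SIGMAS = tuple(np.geomspace(1.5, 9.0, 10))
DEFAULT_LENGTH_FACTOR = 6.0


@dataclass
class MatchedKernel:
    """One oriented line-detector stencil of the bank."""

    weights: np.ndarray
    orientation_index: int
    scale_index: int
    sigma_px: float
    theta_deg: float


@dataclass
class KernelBank:
    kernels: list[MatchedKernel]
    n_orient: int
    n_scale: int
    sigmas: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def thetas_deg(self) -> tuple[float, ...]:
        return tuple(i * 180.0 / self.n_orient for i in range(self.n_orient))

    @property
    def max_footprint(self) -> int:
        return max(k.weights.shape[0] for k in self.kernels)


@dataclass
class VesselMask:
    """Binary vessel map plus the provenance of how it was thresholded."""

    pixels: np.ndarray  # bool H x W
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)


def _single_kernel(sigma: float, theta_deg: float, length_factor: float) -> np.ndarray:
    half_len = 0.5 * max(1.0, round(length_factor * sigma) // 2 * 2 + 1)
    half_cross = 3.0 * sigma
    radius = int(math.ceil(math.hypot(half_len, half_cross)))
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    th = math.radians(theta_deg)
    u = xx * math.cos(th) + yy * math.sin(th)  # along the vessel axis
    v = -xx * math.sin(th) + yy * math.cos(th)  # across the vessel
    support = (np.abs(u) <= half_len) & (np.abs(v) <= half_cross)
    k = np.zeros_like(u, dtype=np.float64)
    k[support] = np.exp(-(v[support] ** 2) / (2.0 * sigma**2))
    k[support] -= k[support].mean()
    # normalise by the positive mass so the response reads as a local
    # average contrast: a vessel matched in scale and orientation responds
    # with ~its own contrast regardless of sigma, which keeps the max
    # projection comparable across scales and makes thresholds physical
    k /= k[k > 0].sum()
    return k


def build_kernel_bank(
    n_orient: int = DEFAULT_N_ORIENT,
    sigmas=None,
    length_factor: float = DEFAULT_LENGTH_FACTOR,
) -> KernelBank:
    """Build the oriented Gaussian matched-filter bank.

    Defaults give 12 orientations (15 deg apart) x 10 scales = 120 kernels.
    Each kernel has a Gaussian profile exp(-v^2 / 2 sigma^2) across the
    vessel axis, constant support of length ``length_factor * sigma``
    (rounded to odd pixels) along it, truncated at 3 sigma across, and is
    mean-subtracted over its support so constant regions give zero
    response.
    """
    if n_orient < 1:
        raise InvalidSpecificationError("n_orient must be >= 1")
    sigmas = tuple(float(s) for s in (DEFAULT_SIGMAS if sigmas is None else sigmas))
    if any(s <= 0 for s in sigmas):
        raise InvalidSpecificationError("all sigmas must be positive")
    if any(b <= a for a, b in zip(sigmas, sigmas[1:])):
        raise InvalidSpecificationError("sigmas must be strictly increasing")
    if length_factor <= 0:
        raise InvalidSpecificationError("length_factor must be positive")
    kernels = [
        MatchedKernel(
            weights=_single_kernel(sigma, i * 180.0 / n_orient, length_factor),
            orientation_index=i,
            scale_index=j,
            sigma_px=sigma,
            theta_deg=i * 180.0 / n_orient,
        )
        for j, sigma in enumerate(sigmas)
        for i in range(n_orient)
    ]
    return KernelBank(
        kernels=kernels, n_orient=n_orient, n_scale=len(sigmas), sigmas=sigmas
    )


def _convolve_reflect(image: np.ndarray, kernel: np.ndarray, method: str) -> np.ndarray:
    if method == "direct":
        return ndimage.convolve(image, kernel, mode="reflect")
    pad = kernel.shape[0] // 2
    padded = np.pad(image, pad, mode="symmetric")
    out = signal.fftconvolve(padded, kernel, mode="same")
    return out[pad : pad + image.shape[0], pad : pad + image.shape[1]]


def enhance(
    green, bank: KernelBank, invert: bool = True, method: str = "auto"
) -> np.ndarray:
    """Maximum-intensity projection of all kernel responses.

    Each kernel is convolved with the (negated) green channel with
    reflective boundary handling and the pixel-wise maximum over the bank
    is returned.  ``method`` selects direct spatial convolution or
    FFT-based convolution (numerically identical to rounding error);
    ``auto`` uses FFT on images larger than 64 px a side.
    """
    img = _as_2d(green)
    if min(img.shape) <= bank.max_footprint:
        raise InvalidInputError(
            f"image {img.shape} not larger than the largest kernel footprint "
            f"({bank.max_footprint} px)"
        )
    if invert:
        img = -img  # zero-mean kernels make -g equivalent to (const - g)
    if method == "auto":
        method = "fft" if min(img.shape) > 64 else "direct"
    response = None
    for k in bank.kernels:
        r = _convolve_reflect(img, k.weights, method)
        response = r if response is None else np.maximum(response, r)
    return response


def correct_illumination(response, radius: int) -> np.ndarray:
    """White top-hat: response minus its morphological opening by a disc.

    Removes any background structure wider than the disc, flattening
    smooth illumination drift while passing vessels (thin, bright after
    enhancement) almost unchanged.  The radius must exceed the widest
    vessel's half-width.
    """
    img = _as_2d(response)
    if radius <= 0:
        raise InvalidSpecificationError("top-hat radius must be positive")
    opened = opening(img, footprint=disk(int(radius)))
    return img - opened


def threshold_global(image, method="otsu") -> VesselMask:
    """Binarise the corrected response with one global threshold.

    ``method`` is ``"otsu"`` or ``("fixed", t)``.  The threshold actually
    used is recorded in the mask's provenance.
    """
    img = _as_2d(image)
    if isinstance(method, (tuple, list)) and method[0] == "fixed":
        t = float(method[1])
        prov = {"threshold_method": "fixed", "threshold_value": t}
    elif method == "otsu":
        # also treat numerically-constant images (e.g. zero-mean filter
        # residue at machine precision) as degenerate
        if np.ptp(img) <= 1e-9 * (np.abs(img).max() + 1.0):
            raise DegenerateInputError(
                "constant image: Otsu is undefined; use ('fixed', t) instead"
            )
        t = float(threshold_otsu(img))
        prov = {"threshold_method": "otsu", "threshold_value": t}
    else:
        raise InvalidSpecificationError(f"unknown threshold method {method!r}")
    return VesselMask(pixels=img > t, provenance=prov)


def refine_extent(
    response: np.ndarray,
    detection: np.ndarray,
    crest_window_px: int = 31,
    crest_fraction: float = 0.5,
) -> np.ndarray:
    """Grow a detection mask out to the local half-crest of the response.

    A single global threshold detects vessels reliably but clips
    weak-contrast vessels narrower than strong ones, because it sits at a
    different fraction of each vessel's response crest.  This refinement
    re-cuts every detected vessel at ``crest_fraction`` of its own crest
    (the local response maximum within ``crest_window_px``) — the full
    width at half maximum when ``crest_fraction`` is 0.5 — keeping only
    half-crest regions connected to the detection mask (binary
    reconstruction), so nothing is added away from detected vessels.
    """
    crest = ndimage.grey_dilation(response, size=(crest_window_px, crest_window_px))
    wide = response > crest_fraction * crest
    seed = detection & wide
    if not seed.any():
        return seed
    return reconstruction(seed, wide, method="dilation").astype(bool)


@dataclass
class SegmentationParams:
    """All stage parameters of the segmentation chain."""

    n_orient: int = DEFAULT_N_ORIENT
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    length_factor: float = DEFAULT_LENGTH_FACTOR
    tophat_radius: int = 27  # ~3 x largest default sigma
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    refine_extent: bool = True
    crest_window_px: int = 31
    crest_fraction: float = 0.5
    min_object_px: int = 64  # drop speckle components below this size
    convolution_method: str = "auto"


def segment_vessels(green, params: SegmentationParams | None = None) -> VesselMask:
    """Full chain: matched filtering -> max projection -> top-hat -> threshold.

    With ``params.refine_extent`` (default) the thresholded mask is re-cut
    at the local half-crest of the response (see :func:`refine_extent`) so
    mask width tracks true vessel width for weak and strong vessels alike.
    Small disconnected components (noise speckle) below
    ``params.min_object_px`` are removed at the end; set it to 0 to
    disable.  Provenance records every stage parameter and the threshold
    value used.
    """
    params = params or SegmentationParams()
    bank = build_kernel_bank(params.n_orient, params.sigmas, params.length_factor)
    response = enhance(green, bank, method=params.convolution_method)
    corrected = correct_illumination(response, params.tophat_radius)
    method = (
        ("fixed", params.fixed_threshold)
        if params.threshold_method == "fixed"
        else params.threshold_method
    )
    mask = threshold_global(corrected, method=method)
    if params.refine_extent:
        mask.pixels = refine_extent(
            corrected, mask.pixels, params.crest_window_px, params.crest_fraction
        )
    if params.min_object_px > 0:
        mask.pixels = remove_small_objects(
            mask.pixels, max_size=params.min_object_px - 1
        )
        # pinholes inside vessels would punch loops into the skeleton
        mask.pixels = remove_small_holes(mask.pixels, max_size=params.min_object_px)
    mask.provenance.update(
        {
            "n_orient": params.n_orient,
            "n_scale": len(params.sigmas),
            "sigmas": [float(s) for s in params.sigmas],
            "length_factor": params.length_factor,
            "tophat_radius": params.tophat_radius,
            "refine_extent": params.refine_extent,
            "crest_window_px": params.crest_window_px,
            "crest_fraction": params.crest_fraction,
            "min_object_px": params.min_object_px,
        }
    )
    return mask
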