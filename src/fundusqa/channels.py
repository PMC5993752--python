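"""Image I/O, channel separation and digital red/green balancing.

Fundus photographs taken with long-wavelength-dominated illumination are
strongly red-predominated (red channel mean several times the green, an
order of magnitude above the blue).  For visualisation and for downstream
vessel analysis the red and green channels are digitally balanced — the
green channel is rescaled so its mean matches the red mean — and the blue
channel, which carries essentially no signal, is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import DegenerateInputError, ImageIOError, InvalidInputError

__all__ = [
    "FundusImage",
    "ChannelImage",
    "read_image",
    "write_image",
    "mean_intensity",
    "mean_intensity_stack",
    "balance_channels",
]


@dataclass
class FundusImage:
    """An H x W x 3 colour fundus raster with physical pixel pitch.

    Channel order is (red, green, blue); intensities live on ``[0, scale_max]``
    (8-bit by default).  ``pixel_pitch_um`` is the physical size of one pixel
    on the retina in micrometres.
    """

    pixels: np.ndarray
    pixel_pitch_um: float
    scale_max: float = 255.0
    channel_order: tuple[str, str, str] = ("red", "green", "blue")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidInputError(
                f"expected an HxWx3 raster, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise InvalidInputError("empty raster")
        if not self.pixel_pitch_um > 0:
            raise InvalidInputError("pixel_pitch_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> "ChannelImage":
        idx = self.channel_order.index(name)
        return ChannelImage(pixels=self.pixels[:, :, idx], name=name)

    @property
    def red(self) -> np.ndarray:
        return self.pixels[:, :, 0]

    @property
    def green(self) -> np.ndarray:
        return self.pixels[:, :, 1]

    @property
    def blue(self) -> np.ndarray:
        return self.pixels[:, :, 2]


@dataclass
class ChannelImage:
    """A single H x W channel extracted from a :class:`FundusImage`."""

    pixels: np.ndarray
    name: str = "green"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InvalidInputError("a channel image must be 2-D")


def _as_2d(image) -> np.ndarray:
    """Accept a ChannelImage or a bare 2-D array."""
    if isinstance(image, ChannelImage):
        return image.pixels
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a 2-D channel, got shape {arr.shape}")
    return arr


def read_image(path, pixel_pitch_um: float = 1.0) -> FundusImage:
    """Read a 3-channel PNG/TIFF/JPEG into a :class:`FundusImage`.

    The pixel pitch is metadata the file format does not carry; it must be
    supplied by the caller (µm per pixel).
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"image file not found: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ImageIOError(f"could not read image {path}: {exc}") from exc
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ImageIOError(
            f"{path}: expected a 3-channel RGB image, got shape {raw.shape}"
        )
    return FundusImage(pixels=raw.astype(np.float64), pixel_pitch_um=pixel_pitch_um)


def write_image(image: FundusImage, path) -> None:
    """Write a :class:`FundusImage` as 8-bit PNG/TIFF/JPEG (by extension)."""
    path = Path(path)
    arr = np.clip(np.rint(image.pixels), 0, image.scale_max).astype(np.uint8)
    try:
        iio.imwrite(path, arr)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ImageIOError(f"could not write image {path}: {exc}") from exc


def mean_intensity(image: FundusImage, per_channel: bool = False):
    """Arithmetic mean intensity of the image.

    With ``per_channel=True`` returns the three channel means
    (red, green, blue); otherwise a single scalar over all pixels and
    channels.  This is the average-intensity statistic used to compare
    acquisitions at constant illumination power.
    """
    if image.pixels.size == 0:
        raise InvalidInputError("empty raster")
    if per_channel:
        return tuple(float(m) for m in image.pixels.mean(axis=(0, 1)))
    return float(image.pixels.mean())


def mean_intensity_stack(images) -> np.ndarray:
    """Mean intensity of each image in a sequence (scan-curve helper)."""
    return np.array([mean_intensity(im) for im in images], dtype=np.float64)


def balance_channels(image: FundusImage) -> FundusImage:
    """Digitally balance red and green channels; drop the blue channel.

    The green channel is rescaled so its mean equals the red channel mean
    (red is left untouched as the reference), the blue channel is zeroed,
    and the result is clipped to the declared intensity scale.
    """
    g_mean = float(image.green.mean())
    if g_mean <= 0:
        raise DegenerateInputError("green channel mean is zero; cannot balance")
    r_mean = float(image.red.mean())
    out = image.pixels.copy()
    out[:, :, 1] = out[:, :, 1] * (r_mean / g_mean)
    out[:, :, 2] = 0.0
    np.clip(out, 0.0, image.scale_max, out=out)
    return FundusImage(
        pixels=out,
        pixel_pitch_um=image.pixel_pitch_um,
        scale_max=image.scale_max,
        channel_order=image.channel_order,
    )
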