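"""Channel image loading and standardization.

Micrographs arrive with heterogeneous objectives and digital resolutions.
Before any spectral or morphological analysis every channel is brought onto
a canonical geometry: resample to 800 x 600 px at 1.6 px/um, then crop the
centered 600 x 600 px window.  All downstream modules assume this geometry
and the fixed physical scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
from skimage.transform import resize

#: canonical analysis geometry (rows, cols)
STANDARD_SHAPE = (600, 600)
#: intermediate resample geometry (rows, cols) == 800 x 600 px (width x height)
RESAMPLE_SHAPE = (600, 800)
#: physical scale of the canonical geometry, pixels per micrometre
PIXELS_PER_UM = 1.6

CHANNEL_ROLES = ("nuclei", "neuron", "astrocyte", "phase")


@dataclass
class ChannelImage:
    """A single-channel intensity raster as read from disk.

    Parameters
    ----------
    pixels
        2-D non-negative intensity array (converted to float64 on load).
    bit_depth
        8 or 16; recorded from the file's dtype.
    role
        One of :data:`CHANNEL_ROLES` — which stain/modality the raster holds.
    """

    pixels: np.ndarray
    bit_depth: int
    role: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("ChannelImage requires a 2-D raster")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")


@dataclass
class StandardizedImage:
    """Co-registered channels on the canonical 600 x 600 grid."""

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_scale: float = PIXELS_PER_UM

    def __post_init__(self) -> None:
        for role, arr in self.channels.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != STANDARD_SHAPE:
                raise ValueError(
                    f"channel {role!r} has shape {arr.shape}, expected {STANDARD_SHAPE}"
                )
            self.channels[role] = arr

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]

    def __contains__(self, role: str) -> bool:
        return role in self.channels


_BIT_DEPTHS = {np.uint8: 8, np.uint16: 16}


def load_channel(path: str | Path, role: str) -> ChannelImage:
    """Read a grayscale 8/16-bit TIFF or PNG as one channel.

    Multi-page TIFFs and RGB files are rejected: a single fluorescence
    channel must be unambiguous, so color or stacked files need an explicit
    channel extraction upstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path} is not a single grayscale plane (shape {arr.shape}); "
            "multi-page or RGB input needs an explicit channel selector"
        )
    depth = _BIT_DEPTHS.get(arr.dtype.type)
    if depth is None:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}, expected uint8/uint16")
    return ChannelImage(pixels=arr, bit_depth=depth, role=role)


def standardize(image: ChannelImage | np.ndarray, *, order: int = 1) -> np.ndarray:
    """Map a raster onto the canonical 600 x 600 geometry.

    The raster is resampled to 800 x 600 (width x height) and the centered
    600-column window (columns ``[100, 700)`` of the 800-wide intermediate)
    is returned.  ``order=1`` (bilinear) is the default interpolant;
    ``order=0`` gives nearest-neighbour.  Input already on the canonical
    600 x 600 grid passes through unchanged (standardization is idempotent
    and never distorts already-standard data).
    """
    pixels = image.pixels if isinstance(image, ChannelImage) else np.asarray(image, float)
    if pixels.ndim != 2 or pixels.shape[0] < 2 or pixels.shape[1] < 2:
        raise ValueError("standardize expects a 2-D raster of at least 2 x 2")
    if pixels.shape == STANDARD_SHAPE:
        return pixels.astype(np.float64, copy=True)
    inter = resize(
        pixels, RESAMPLE_SHAPE, order=order, anti_aliasing=False,
        preserve_range=True, mode="edge",
    )
    return np.ascontiguousarray(inter[:, 100:700])


def standardize_channels(images: dict[str, ChannelImage | np.ndarray],
                         *, order: int = 1) -> StandardizedImage:
    """Standardize every channel of a multi-channel acquisition."""
    return StandardizedImage(
        channels={role: standardize(img, order=order) for role, img in images.items()}
    )


def minmax_normalize(raster: np.ndarray) -> np.ndarray:
    """Linearly rescale intensities to span [0, 1].

    A constant raster carries no contrast; it maps to all zeros (with a
    warning) so that downstream absolute thresholds behave deterministically.
    """
    raster = np.asarray(raster, dtype=np.float64)
    lo, hi = raster.min(), raster.max()
    if hi == lo:
        warnings.warn("constant raster: min-max normalization returns zeros",
                      stacklevel=2)
        return np.zeros_like(raster)
    return (raster - lo) / (hi - lo)
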