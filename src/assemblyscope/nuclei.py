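"""DAPI nucleus detection and neuron/glia classification.

Nuclei in these cultures span 12-18 px in diameter at the canonical
1.6 px/um scale.  Detection is a difference-of-disks band-pass: the
[0,1]-normalized DAPI raster is mean-filtered with 12-px and 18-px diameter
disks and the two results subtracted, which responds maximally to blobs in
the 12-18 px band.  Candidate pixels exceed 0.005 in the band-passed image;
of the 8-connected components they form, only those containing at least one
pixel whose Prewitt gradient magnitude (computed on the band-passed image)
exceeds 0.02 are kept as nuclei.  Each component yields one record whose
centroid is the unweighted component centroid.

Class labels come from channel dominance at the pixel nearest each
centroid: green (beta-III tubulin) above red (GFAP) means neuron, red above
green means astrocyte (glia), exact ties are left unclassified.

Known limitation: contiguous (touching) nuclei merge into one component —
no declumping/watershed step is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgio import minmax_normalize

__all__ = [
    "NucleiParams", "NucleusRecord",
    "disk_kernel", "bandpass_nuclei", "prewitt_magnitude",
    "detect_nuclei", "classify_nuclei",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class NucleiParams:
    disk_small_px: int = 12
    disk_large_px: int = 18
    intensity_threshold: float = 0.005
    gradient_threshold: float = 0.02

    def __post_init__(self) -> None:
        if not self.disk_small_px < self.disk_large_px:
            raise ValueError("disk_small_px must be smaller than disk_large_px")
        if self.intensity_threshold <= 0 or self.gradient_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class NucleusRecord:
    centroid: tuple[float, float]     # (row, col), sub-pixel
    object_area_px: int
    label: str = "unclassified"       # neuron | glia | unclassified


def disk_kernel(diameter_px: int) -> np.ndarray:
    """Normalized (mean-filter) disk of the given pixel diameter.

    The support is the ``d x d`` grid of pixels whose centers lie within
    ``d/2`` of the kernel center; weights sum to 1 so that filtering
    preserves the intensity scale (an area-summing kernel would make the
    0.005 threshold meaningless on [0,1] input).
    """
    d = int(diameter_px)
    if d < 1:
        raise ValueError("diameter must be >= 1")
    c = (d - 1) / 2.0
    yy, xx = np.mgrid[0:d, 0:d]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= (d / 2.0) ** 2
    return mask / mask.sum()


def bandpass_nuclei(dapi_norm: np.ndarray, params: NucleiParams = NucleiParams()) -> np.ndarray:
    """Difference of 12-px and 18-px disk mean filters (symmetric padding)."""
    dapi_norm = np.asarray(dapi_norm, dtype=np.float64)
    small = ndimage.convolve(dapi_norm, disk_kernel(params.disk_small_px), mode="reflect")
    large = ndimage.convolve(dapi_norm, disk_kernel(params.disk_large_px), mode="reflect")
    return small - large


def prewitt_magnitude(image: np.ndarray) -> np.ndarray:
    """Euclidean magnitude of horizontal and vertical Prewitt responses.

    Unit-gain kernels ([-1, 0, 1] x [1, 1, 1] / 3, symmetric padding): the
    smoothing leg is normalized so gradient values live on the same scale as
    the [0, 1] intensities the 0.02 threshold is stated on.
    """
    gy = ndimage.prewitt(image, axis=0, mode="reflect") / 3.0
    gx = ndimage.prewitt(image, axis=1, mode="reflect") / 3.0
    return np.hypot(gy, gx)


def detect_nuclei(dapi: np.ndarray, params: NucleiParams = NucleiParams()) -> list[NucleusRecord]:
    """Locate nuclei in a raw DAPI raster.

    Pipeline: min-max normalize -> difference-of-disks band-pass ->
    candidate mask (band-pass > intensity_threshold) -> keep 8-connected
    components containing at least one pixel with Prewitt gradient
    magnitude > gradient_threshold -> one record per surviving component.

    The two thresholds AND at component level: gradient support lives on
    blob rims, so a per-pixel AND would hollow out interiors and return
    annuli instead of nuclei.
    """
    dapi = np.asarray(dapi, dtype=np.float64)
    if not dapi.any():
        return []
    filtered = bandpass_nuclei(minmax_normalize(dapi), params)
    candidates = filtered > params.intensity_threshold
    if not candidates.any():
        return []
    grad = prewitt_magnitude(filtered)
    labels, n_obj = ndimage.label(candidates, structure=_EIGHT)
    index = np.arange(1, n_obj + 1)
    max_grad = ndimage.maximum(grad, labels=labels, index=index)
    keep = index[max_grad > params.gradient_threshold]
    if keep.size == 0:
        return []
    centroids = ndimage.center_of_mass(candidates, labels=labels, index=keep)
    areas = ndimage.sum_labels(candidates, labels=labels, index=keep)
    return [
        NucleusRecord(centroid=(float(r), float(c)), object_area_px=int(a))
        for (r, c), a in zip(centroids, areas)
    ]


def classify_nuclei(records: list[NucleusRecord], green: np.ndarray,
                    red: np.ndarray) -> list[NucleusRecord]:
    """Assign neuron/glia labels by channel dominance at each centroid.

    At the pixel nearest the centroid: green > red -> neuron,
    red > green -> glia, exact tie -> unclassified.  Records are returned
    as new objects; inputs are not mutated.
    """
    green = np.asarray(green, dtype=np.float64)
    red = np.asarray(red, dtype=np.float64)
    if green.shape != red.shape:
        raise ValueError(f"channel shape mismatch: {green.shape} vs {red.shape}")
    labeled = []
    for rec in records:
        r = int(np.clip(round(rec.centroid[0]), 0, green.shape[0] - 1))
        c = int(np.clip(round(rec.centroid[1]), 0, green.shape[1] - 1))
        g, rd = green[r, c], red[r, c]
        label = "neuron" if g > rd else ("glia" if rd > g else "unclassified")
        labeled.append(NucleusRecord(rec.centroid, rec.object_area_px, label))
    return labeled
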