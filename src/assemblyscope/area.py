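"""Per-class area masks, mean cell area, density and the neuron/glia ratio.

A pixel belongs to the astrocyte mask when its red (GFAP) intensity exceeds
10% of the red channel's maximum AND exceeds the green intensity at that
pixel; the neuron mask is the mirror rule on green (beta-III tubulin).  The
strict dominance inequalities make the two masks disjoint by construction.

Mean per-cell area divides each class's mask pixel total by the number of
nuclei classified into that class, converted to um^2 with the fixed
(1.6 px/um)^2 = 2.56 px^2/um^2 canonical scale; densities are cells per mm^2
of the standardized field (600 x 600 px = 0.140625 mm^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imgio import PIXELS_PER_UM, STANDARD_SHAPE
from .nuclei import NucleusRecord

__all__ = ["AreaParams", "AreaDensitySummary", "astrocyte_mask", "neuron_mask", "summarize"]


@dataclass(frozen=True)
class AreaParams:
    #: per-channel intensity floor as a fraction of that channel's maximum
    fraction_of_max: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.fraction_of_max < 1:
            raise ValueError("fraction_of_max must lie in (0, 1)")


@dataclass
class AreaDensitySummary:
    n_neurons: int
    n_glia: int
    n_unclassified: int
    neuron_area_px: int
    glia_area_px: int
    mean_neuron_area_um2: float | None   # None when n_neurons == 0
    mean_glia_area_um2: float | None
    neuron_density_per_mm2: float
    glia_density_per_mm2: float
    neuron_glia_ratio: float | None      # None when n_glia == 0


def astrocyte_mask(red: np.ndarray, green: np.ndarray,
                   params: AreaParams = AreaParams()) -> np.ndarray:
    """Pixels where red exceeds both its 10%-of-max floor and green."""
    red = np.asarray(red, float)
    green = np.asarray(green, float)
    if red.shape != green.shape:
        raise ValueError("red and green rasters must be co-registered")
    peak = red.max()
    if peak == 0:
        warnings.warn("all-zero red channel: astrocyte mask is empty", stacklevel=2)
        return np.zeros(red.shape, dtype=bool)
    return (red > params.fraction_of_max * peak) & (red > green)


def neuron_mask(green: np.ndarray, red: np.ndarray,
                params: AreaParams = AreaParams()) -> np.ndarray:
    """Pixels where green exceeds both its 10%-of-max floor and red."""
    return astrocyte_mask(green, red, params)


_UM2_PER_PX2 = 1.0 / PIXELS_PER_UM**2        # 1/2.56


def summarize(neuron_mask_px: np.ndarray, glia_mask_px: np.ndarray,
              records: list[NucleusRecord],
              image_shape: tuple[int, int] = STANDARD_SHAPE,
              pixel_scale: float = PIXELS_PER_UM) -> AreaDensitySummary:
    """Combine class masks and labeled nuclei into the per-image summary.

    Classes with zero nuclei get ``None`` for their mean area (and the
    neuron/glia ratio when glia are absent) instead of a division error.
    """
    n_neu = sum(r.label == "neuron" for r in records)
    n_gli = sum(r.label == "glia" for r in records)
    n_unc = sum(r.label == "unclassified" for r in records)
    neu_px = int(np.count_nonzero(neuron_mask_px))
    gli_px = int(np.count_nonzero(glia_mask_px))
    field_mm2 = (image_shape[0] / pixel_scale) * (image_shape[1] / pixel_scale) / 1e6
    um2 = 1.0 / pixel_scale**2
    return AreaDensitySummary(
        n_neurons=n_neu,
        n_glia=n_gli,
        n_unclassified=n_unc,
        neuron_area_px=neu_px,
        glia_area_px=gli_px,
        mean_neuron_area_um2=(neu_px / n_neu * um2) if n_neu else None,
        mean_glia_area_um2=(gli_px / n_gli * um2) if n_gli else None,
        neuron_density_per_mm2=n_neu / field_mm2,
        glia_density_per_mm2=n_gli / field_mm2,
        neuron_glia_ratio=(n_neu / n_gli) if n_gli else None,
    )
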