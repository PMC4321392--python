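"""Ground-truthed synthetic scenes with the statistical structure the
analysis pipeline assumes.

Three calibration fields drive the spectral statistic:

* i.i.d. uniform white noise (spatially random arrangement, NCF anchor 0),
* a single centered Gaussian clump (maximal aggregation, NCF anchor 1),
* a random-phase power-law field whose expected 2-D PSD falls as f^-beta
  (self-similar texture, NCF anchor 0.5 at beta = 2).

Cell scenes emulate three-channel fluorescence fields: DAPI nuclei rendered
as hard disks 12-18 px in diameter (matching the band-pass detector's
design band exactly at zero noise), and neuron/astrocyte body channels with
strict channel dominance inside each cell's footprint.  Centroids are placed
either uniformly at random (poisson) or as a Neyman-Scott/Thomas cluster
process (uniform parents, Gaussian-scattered offspring) to emulate
aggregated cultures.  Soma scenes place annotated somas with known
connected/isolated ground truth for the connectivity metric.

Everything is reproducible under a fixed seed, and every generator returns
its ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .connectivity import Soma, SomaAnnotationSet
from .imgio import StandardizedImage

__all__ = [
    "SceneConfig", "ThomasParams", "SceneGroundTruth",
    "generate_white_noise", "generate_gaussian_clump", "generate_power_law_field",
    "generate_cell_scene", "generate_soma_scene", "render_soma_phase_image",
    "write_scene",
]


# --------------------------------------------------------------------------
# calibration fields

def generate_white_noise(shape: tuple[int, int], seed: int) -> np.ndarray:
    """i.i.d. uniform[0, 1] pixels."""
    if min(shape) < 1:
        raise ValueError("shape must be positive")
    return np.random.default_rng(seed).random(shape)


def generate_gaussian_clump(shape: tuple[int, int], sigma_px: float,
                            center: tuple[float, float] | None = None) -> np.ndarray:
    """Single Gaussian intensity clump, value 1 at its center."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return np.exp(-(rr**2 + cc**2) / (2.0 * sigma_px**2))


def generate_power_law_field(shape: tuple[int, int], exponent_beta: float,
                             seed: int) -> np.ndarray:
    """Random-phase field with expected 2-D PSD proportional to f^-beta.

    Spectral synthesis: white Gaussian noise is Fourier transformed and each
    mode scaled by f^(-beta/2); Hermitian symmetry is inherited from the
    real-valued noise, the DC mode is zeroed, and the inverse transform's
    real part is returned (zero mean by construction).
    """
    if exponent_beta < 0:
        raise ValueError("exponent_beta must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-exponent_beta / 2.0)
    return np.real(np.fft.ifft2(np.fft.fft2(noise) * amp))


# --------------------------------------------------------------------------
# cell scenes

@dataclass(frozen=True)
class ThomasParams:
    """Neyman-Scott (Thomas) cluster-process parameters.

    ``n_parents=None`` derives the parent count from the total cell count
    and ``offspring_per_parent_mean`` (aggregates observed in depolarized
    cultures range from a few cells to a few tens of cells, hence the
    default cluster occupancy of 8).
    """

    n_parents: int | None = None
    offspring_per_parent_mean: float = 8.0
    cluster_sigma_px: float = 15.0


@dataclass
class SceneConfig:
    image_shape: tuple[int, int] = (600, 600)
    n_neurons: int = 20
    n_glia: int = 10
    nucleus_diameter_range: tuple[float, float] = (12.0, 18.0)
    neuron_body_area_px: float = 1300.0   # ~510 um^2 at 1.6 px/um
    glia_body_area_px: float = 3800.0     # ~1480 um^2 at 1.6 px/um
    arrangement: str = "poisson"          # poisson | thomas
    thomas_params: ThomasParams = field(default_factory=ThomasParams)
    noise_sigma: float = 0.0
    seed: int = 0
    #: minimum centroid separation; None -> 19 px for poisson (no nucleus
    #: overlap), 0 for thomas (aggregated somata naturally touch)
    min_separation_px: float | None = None

    def __post_init__(self) -> None:
        if self.n_neurons < 0 or self.n_glia < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.nucleus_diameter_range
        if not (1 <= lo <= hi < min(self.image_shape)):
            raise ValueError("nucleus diameters must lie in [1, min(shape))")
        if self.arrangement not in ("poisson", "thomas"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.arrangement == "thomas" and self.thomas_params.cluster_sigma_px <= 0:
            raise ValueError("cluster_sigma_px must be positive for thomas scenes")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class SceneGroundTruth:
    """Exact generative truth accompanying a synthetic scene."""

    nucleus_centroids: np.ndarray                    # (n, 2) float, (row, col)
    class_labels: list[str]                          # parallel, neuron | glia
    per_class_pixel_area: dict[str, int] = field(default_factory=dict)
    soma_graph: dict[int, set[int]] | None = None    # adjacency over soma ids
    isolated_ids: set[int] | None = None
    dead_ids: set[int] = field(default_factory=set)


_MARGIN = 20  # keep nucleus disks fully inside the field


def _place_poisson(n: int, shape, min_sep: float, rng) -> np.ndarray:
    lo_r, hi_r = _MARGIN, shape[0] - _MARGIN
    lo_c, hi_c = _MARGIN, shape[1] - _MARGIN
    usable = (hi_r - lo_r) * (hi_c - lo_c)
    if min_sep > 0 and n * min_sep**2 > 0.35 * usable:
        raise ValueError(f"packing infeasible: {n} points at {min_sep} px separation")
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n:
        if attempts > 400 * max(n, 1):
            raise ValueError("packing infeasible: dart throwing exhausted")
        attempts += 1
        p = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if min_sep > 0 and any(np.hypot(p[0] - q[0], p[1] - q[1]) < min_sep for q in pts):
            continue
        pts.append(p)
    return np.array(pts).reshape(n, 2)


def _place_thomas(n: int, shape, tp: ThomasParams, min_sep: float, rng) -> np.ndarray:
    n_parents = tp.n_parents or max(1, round(n / tp.offspring_per_parent_mean))
    lo_r, hi_r = _MARGIN, shape[0] - _MARGIN
    lo_c, hi_c = _MARGIN, shape[1] - _MARGIN
    parents = np.column_stack([
        rng.uniform(lo_r, hi_r, n_parents), rng.uniform(lo_c, hi_c, n_parents),
    ])
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n:
        if attempts > 2000 * max(n, 1):
            raise ValueError("packing infeasible: thomas scatter exhausted")
        attempts += 1
        parent = parents[rng.integers(n_parents)]
        p = parent + rng.normal(0.0, tp.cluster_sigma_px, 2)
        if not (lo_r <= p[0] <= hi_r and lo_c <= p[1] <= hi_c):
            continue
        if min_sep > 0 and any(np.hypot(p[0] - q[0], p[1] - q[1]) < min_sep for q in pts):
            continue
        pts.append((p[0], p[1]))
    return np.array(pts).reshape(n, 2)


def _paint_disk(arr: np.ndarray, center, radius: float, value: float,
                mode: str = "max") -> None:
    r0 = max(int(np.floor(center[0] - radius)), 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 1, arr.shape[0])
    c0 = max(int(np.floor(center[1] - radius)), 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 1, arr.shape[1])
    rr = np.arange(r0, r1)[:, None] - center[0]
    cc = np.arange(c0, c1)[None, :] - center[1]
    inside = rr**2 + cc**2 <= radius**2
    region = arr[r0:r1, c0:c1]
    if mode == "max":
        region[inside] = np.maximum(region[inside], value)
    else:
        region[inside] = value


def generate_cell_scene(config: SceneConfig) -> tuple[StandardizedImage, SceneGroundTruth]:
    """Render a three-channel fluorescence scene with exact ground truth.

    The DAPI channel holds unit-intensity hard disks at the nucleus
    centroids (diameters uniform over ``nucleus_diameter_range``); the
    neuron/astrocyte channels hold larger body footprints where the class's
    own channel (0.9) strictly dominates the other (0.3).  Where footprints
    of different cells overlap, each pixel is owned by its nearest centroid,
    so dominance at every nucleus centroid always reflects the true class.
    Additive Gaussian noise (clipped at zero) is applied last; ground-truth
    areas are the painted ownership areas before noise.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.image_shape
    n = config.n_neurons + config.n_glia
    min_sep = config.min_separation_px
    if min_sep is None:
        min_sep = 19.0 if config.arrangement == "poisson" else 0.0
    if config.arrangement == "poisson":
        centroids = _place_poisson(n, shape, min_sep, rng)
    else:
        centroids = _place_thomas(n, shape, config.thomas_params, min_sep, rng)
    labels = np.array(["neuron"] * config.n_neurons + ["glia"] * config.n_glia)
    rng.shuffle(labels)
    labels = labels.tolist()

    dapi = np.zeros(shape)
    lo_d, hi_d = config.nucleus_diameter_range
    for cen in centroids:
        _paint_disk(dapi, cen, rng.uniform(lo_d, hi_d) / 2.0, 1.0)

    body_radius = {
        "neuron": float(np.sqrt(config.neuron_body_area_px / np.pi)),
        "glia": float(np.sqrt(config.glia_body_area_px / np.pi)),
    }
    # nearest-centroid ownership of every painted body pixel
    best_d2 = np.full(shape, np.inf)
    owner = np.full(shape, -1, dtype=np.intp)
    for i, (cen, lab) in enumerate(zip(centroids, labels)):
        rad = body_radius[lab]
        r0 = max(int(np.floor(cen[0] - rad)), 0)
        r1 = min(int(np.ceil(cen[0] + rad)) + 1, shape[0])
        c0 = max(int(np.floor(cen[1] - rad)), 0)
        c1 = min(int(np.ceil(cen[1] + rad)) + 1, shape[1])
        rr = np.arange(r0, r1)[:, None] - cen[0]
        cc = np.arange(c0, c1)[None, :] - cen[1]
        d2 = rr**2 + cc**2
        win = (d2 <= rad**2) & (d2 < best_d2[r0:r1, c0:c1])
        best_d2[r0:r1, c0:c1][win] = d2[win]
        owner[r0:r1, c0:c1][win] = i
    lab_arr = np.array([-1] + [0 if l == "neuron" else 1 for l in labels])
    owner_class = lab_arr[owner + 1]                     # -1 bg, 0 neuron, 1 glia
    green = np.where(owner_class == 0, 0.9, np.where(owner_class == 1, 0.3, 0.0))
    red = np.where(owner_class == 1, 0.9, np.where(owner_class == 0, 0.3, 0.0))
    per_class_area = {
        "neuron": int(np.count_nonzero(owner_class == 0)),
        "glia": int(np.count_nonzero(owner_class == 1)),
    }
    if config.noise_sigma > 0:
        dapi = np.clip(dapi + rng.normal(0, config.noise_sigma, shape), 0, None)
        green = np.clip(green + rng.normal(0, config.noise_sigma, shape), 0, None)
        red = np.clip(red + rng.normal(0, config.noise_sigma, shape), 0, None)

    scene = StandardizedImage(channels={"nuclei": dapi, "neuron": green, "astrocyte": red})
    truth = SceneGroundTruth(
        nucleus_centroids=centroids, class_labels=labels,
        per_class_pixel_area=per_class_area,
    )
    return scene, truth


# --------------------------------------------------------------------------
# soma scenes

def generate_soma_scene(n_somas: int, n_connected_pairs: int,
                        min_sep_px: float = 20.0, seed: int = 0,
                        field_shape: tuple[int, int] = (600, 600),
                        soma_radius: float = 6.0,
                        n_dead: int = 0) -> tuple[SomaAnnotationSet, SceneGroundTruth]:
    """Place annotated somas with known connected/isolated ground truth.

    ``n_connected_pairs`` somas pairs are made connected — two thirds by
    proximity (boundary gap drawn below the 10-px halo threshold) and one
    third by an annotated dendrite link between distant somas; every other
    separation exceeds ``min_sep_px`` boundary-to-boundary, so the remaining
    ``n_somas - 2 * n_connected_pairs`` somas are isolated.  Optional
    ``n_dead`` extra somas (flagged in the ground truth, bright in the
    rendered phase image) exercise the dead-cell exclusion rule.
    """
    if 2 * n_connected_pairs > n_somas:
        raise ValueError("n_connected_pairs must not exceed n_somas / 2")
    if min_sep_px <= 10:
        raise ValueError("min_sep_px must exceed the 10-px proximity threshold")
    rng = np.random.default_rng(seed)
    link_pairs = n_connected_pairs // 3
    prox_pairs = n_connected_pairs - link_pairs
    singles = n_somas - 2 * n_connected_pairs
    n_anchors = prox_pairs + 2 * link_pairs + singles + n_dead

    # jittered grid of anchors: worst-case inter-unit centroid distance must
    # keep boundary gaps above min_sep even after pair-partner offsets
    max_offset = 2 * soma_radius + 9.0
    d_min = min_sep_px + 2 * soma_radius + 2 * max_offset
    margin = 25.0
    usable = min(field_shape) - 2 * margin
    m = int(usable // d_min) + 1
    if m * m < n_anchors:
        raise ValueError(
            f"packing infeasible: {n_anchors} anchors need more than {m}x{m} grid sites"
        )
    g = usable / (m - 1) if m > 1 else 0.0
    jitter = max((g - d_min) / (2 * np.sqrt(2)), 0.0)
    sites = np.array([(margin + i * g, margin + j * g) for i in range(m) for j in range(m)])
    sites = sites[rng.permutation(len(sites))[:n_anchors]]
    if jitter > 0:
        sites = sites + rng.uniform(-jitter, jitter, sites.shape)

    somas: list[Soma] = []
    links: list[tuple[int, int]] = []
    graph: dict[int, set[int]] = {}
    dead_ids: set[int] = set()
    site_iter = iter(sites)

    def add(row, col, excluded=False) -> int:
        sid = len(somas)
        somas.append(Soma(id=sid, row=float(row), col=float(col),
                          radius=float(soma_radius), excluded=excluded))
        graph[sid] = set()
        return sid

    for _ in range(prox_pairs):
        r, c = next(site_iter)
        a = add(r, c)
        gap = rng.uniform(2.0, 9.0)                  # boundary gap < 10 px
        theta = rng.uniform(0, 2 * np.pi)
        dist = 2 * soma_radius + gap
        b = add(r + dist * np.cos(theta), c + dist * np.sin(theta))
        graph[a].add(b); graph[b].add(a)
    for _ in range(link_pairs):
        ra, ca = next(site_iter)
        rb, cb = next(site_iter)
        a, b = add(ra, ca), add(rb, cb)
        links.append((a, b))
        graph[a].add(b); graph[b].add(a)
    isolated = {add(*next(site_iter)) for _ in range(singles)}
    for _ in range(n_dead):
        dead_ids.add(add(*next(site_iter)))

    ann = SomaAnnotationSet(somas=somas, dendrite_links=links)
    truth = SceneGroundTruth(
        nucleus_centroids=np.array([(s.row, s.col) for s in somas]).reshape(len(somas), 2),
        class_labels=["soma"] * len(somas),
        soma_graph=graph, isolated_ids=isolated, dead_ids=dead_ids,
    )
    return ann, truth


def render_soma_phase_image(annotations: SomaAnnotationSet,
                            truth: SceneGroundTruth | None = None,
                            shape: tuple[int, int] = (600, 600)) -> np.ndarray:
    """Schematic phase-contrast field.

    Soma bodies render at 0.5 surrounded by a bright halo rim at 0.7 (the
    phase-contrast halo is the brightest feature of a healthy field); dead
    somas saturate at 1.0 so the brightness-based exclusion rule can find
    them.
    """
    img = np.full(shape, 0.1)
    dead = truth.dead_ids if truth is not None else set()
    for s in annotations.somas:
        _paint_disk(img, (s.row, s.col), s.radius + 3.0, 0.7)   # halo
    for s in annotations.somas:
        _paint_disk(img, (s.row, s.col), s.radius,
                    1.0 if s.id in dead else 0.5, mode="set")
    return img


# --------------------------------------------------------------------------
# on-disk form (per-channel TIFF + ground-truth CSV)

_ROLE_FILES = {"nuclei": "dapi.tif", "neuron": "green.tif", "astrocyte": "red.tif"}


def write_scene(scene: StandardizedImage, truth: SceneGroundTruth,
                outdir: str | Path, prefix: str = "scene") -> dict[str, Path]:
    """Write a cell scene as per-channel 16-bit TIFFs plus a nuclei CSV.

    Intensities are clipped to [0, 1] and scaled to the uint16 range; all
    downstream statistics are intensity-scale invariant or renormalize, so
    the quantization is immaterial at analysis scale.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for role, arr in scene.channels.items():
        path = outdir / f"{prefix}_{_ROLE_FILES.get(role, role + '.tif')}"
        tifffile.imwrite(path, (np.clip(arr, 0, 1) * 65535).astype(np.uint16))
        written[role] = path
    rows = [(i, r, c, lab) for i, ((r, c), lab)
            in enumerate(zip(truth.nucleus_centroids, truth.class_labels))]
    csv_path = outdir / f"{prefix}_nuclei.csv"
    pd.DataFrame(rows, columns=["id", "row", "col", "class"]).to_csv(csv_path, index=False)
    written["ground_truth"] = csv_path
    return written
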