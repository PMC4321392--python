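"""Soma connectivity: isolated-vs-connected status and the total/isolated ratio.

Somas annotated on phase-contrast fields count as *connected* when they are
joined to another soma by an annotated dendrite link, or when their
boundary-to-boundary gap to some other soma is below 10 px (somas that close
share a common phase-contrast halo).  Everything else is *isolated*.  The
field-level metric is the ratio of total somas to isolated somas; higher
means a more connected culture.

Very bright somas (assumed dead cells) can be excluded automatically from a
co-registered phase image before status assignment.  Distance is
boundary-referenced: centroid distance minus the two annotated radii, so
soma size does not masquerade as proximity.  Connectivity is pairwise, not
transitive — no connected-component analysis is implied by the metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .stats import ttest_two_sample

__all__ = [
    "ConnectivityParams", "Soma", "SomaAnnotationSet", "ConnectivityResult",
    "soma_status", "connectivity_ratio", "compare_groups", "auto_exclude_bright",
]


@dataclass(frozen=True)
class ConnectivityParams:
    proximity_threshold_px: float = 10.0
    exclude_bright: bool = True
    bright_floor: float = 0.95         # fraction of the image maximum

    def __post_init__(self) -> None:
        if self.proximity_threshold_px <= 0:
            raise ValueError("proximity threshold must be positive")
        if not 0 < self.bright_floor <= 1:
            raise ValueError("bright_floor must lie in (0, 1]")


@dataclass(frozen=True)
class Soma:
    id: int
    row: float
    col: float
    radius: float
    excluded: bool = False


@dataclass
class SomaAnnotationSet:
    """Manually annotated somas plus dendrite links for one imaged field."""

    somas: list[Soma]
    dendrite_links: list[tuple[int, int]] = field(default_factory=list)
    grid_cell: str | None = None       # 500-um relocation-grid label
    time_point_h: float | None = None
    group: str | None = None           # control | treated

    def __post_init__(self) -> None:
        ids = [s.id for s in self.somas]
        if len(ids) != len(set(ids)):
            raise ValueError("soma ids must be unique")
        known = set(ids)
        for a, b in self.dendrite_links:
            if a not in known or b not in known:
                raise ValueError(f"dendrite link ({a}, {b}) references unknown soma id")

    @classmethod
    def from_csv(cls, soma_csv: str | Path, links_csv: str | Path | None = None,
                 **meta) -> "SomaAnnotationSet":
        df = pd.read_csv(soma_csv)
        somas = [
            Soma(id=int(r.id), row=float(r.row), col=float(r.col),
                 radius=float(r.radius), excluded=bool(getattr(r, "excluded", False)))
            for r in df.itertuples(index=False)
        ]
        links: list[tuple[int, int]] = []
        if links_csv is not None:
            ldf = pd.read_csv(links_csv)
            links = [(int(a), int(b)) for a, b in zip(ldf.id_a, ldf.id_b)]
        return cls(somas=somas, dendrite_links=links, **meta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.id, s.row, s.col, s.radius, s.excluded) for s in self.somas],
            columns=["id", "row", "col", "radius", "excluded"],
        )


@dataclass
class ConnectivityResult:
    n_total: int
    n_isolated: int
    ratio: float | None               # None when n_isolated == 0
    statuses: dict[int, str]          # id -> connected | isolated


def soma_status(annotations: SomaAnnotationSet,
                params: ConnectivityParams = ConnectivityParams()) -> dict[int, str]:
    """Label every non-excluded soma as ``connected`` or ``isolated``.

    Connected iff the soma appears in at least one dendrite link between
    non-excluded somas, or its boundary gap to some other non-excluded soma
    is below ``proximity_threshold_px``.
    """
    active = [s for s in annotations.somas if not s.excluded]
    active_ids = {s.id for s in active}
    linked: set[int] = set()
    for a, b in annotations.dendrite_links:
        if a in active_ids and b in active_ids:
            linked.update((a, b))
        else:
            warnings.warn(f"dendrite link ({a}, {b}) touches an excluded soma; ignored",
                          stacklevel=2)
    status = {s.id: "isolated" for s in active}
    if len(active) >= 2:
        xy = np.array([(s.row, s.col) for s in active])
        radii = np.array([s.radius for s in active])
        gaps = squareform(pdist(xy)) - radii[:, None] - radii[None, :]
        np.fill_diagonal(gaps, np.inf)
        near = (gaps < params.proximity_threshold_px).any(axis=1)
        for s, n in zip(active, near):
            if n:
                status[s.id] = "connected"
    for sid in linked:
        status[sid] = "connected"
    return status


def connectivity_ratio(statuses: dict[int, str]) -> ConnectivityResult:
    """Total/isolated soma ratio; undefined (None) for a fully connected field."""
    if not statuses:
        raise ValueError("empty annotation set: no somas to score")
    n_total = len(statuses)
    n_isolated = sum(v == "isolated" for v in statuses.values())
    ratio = n_total / n_isolated if n_isolated else None
    return ConnectivityResult(n_total, n_isolated, ratio, dict(statuses))


def auto_exclude_bright(image: np.ndarray, annotations: SomaAnnotationSet,
                        params: ConnectivityParams = ConnectivityParams()) -> SomaAnnotationSet:
    """Mark somas sitting on very bright (assumed dead) areas as excluded.

    A soma is excluded when the intensity at the pixel nearest its centroid
    reaches ``bright_floor`` times the image maximum (>=, so a floor of 1.0
    excludes exactly-saturated pixels only).
    """
    image = np.asarray(image, float)
    floor = params.bright_floor * image.max()
    somas = []
    for s in annotations.somas:
        r = int(np.clip(round(s.row), 0, image.shape[0] - 1))
        c = int(np.clip(round(s.col), 0, image.shape[1] - 1))
        somas.append(replace(s, excluded=s.excluded or bool(image[r, c] >= floor)))
    return SomaAnnotationSet(
        somas=somas, dendrite_links=list(annotations.dendrite_links),
        grid_cell=annotations.grid_cell, time_point_h=annotations.time_point_h,
        group=annotations.group,
    )


def compare_groups(ratios: pd.DataFrame, *, control: str = "control",
                   treated: str = "treated", welch: bool = False) -> pd.DataFrame:
    """Per-time-point comparison of connectivity ratios between two groups.

    ``ratios`` is tidy with columns ``group``, ``time_point_h``, ``ratio``.
    For each time point the table reports group means, the percent change of
    the treated group relative to control (100 x (control - treated)/control),
    and a two-sided two-sample Student's t-test p-value (omitted with a flag
    when a cell of the design has fewer than two replicates).
    """
    required = {"group", "time_point_h", "ratio"}
    if not required.issubset(ratios.columns):
        raise ValueError(f"ratios table needs columns {sorted(required)}")
    rows = []
    for tp, sub in ratios.groupby("time_point_h"):
        a = sub.loc[sub.group == control, "ratio"].dropna().to_numpy(float)
        b = sub.loc[sub.group == treated, "ratio"].dropna().to_numpy(float)
        mean_c = a.mean() if a.size else np.nan
        mean_t = b.mean() if b.size else np.nan
        pct = 100.0 * (mean_c - mean_t) / mean_c if mean_c else np.nan
        if a.size >= 2 and b.size >= 2:
            res = ttest_two_sample(a, b, welch=welch)
            t_stat, p_value, flag = res.t, res.p, ""
        else:
            t_stat, p_value, flag = np.nan, np.nan, "insufficient_replicates"
        rows.append((tp, a.size, b.size, mean_c, mean_t, pct, t_stat, p_value, flag))
    return pd.DataFrame(rows, columns=[
        "time_point_h", "n_control", "n_treated", "mean_control", "mean_treated",
        "percent_change", "t_stat", "p_value", "flag",
    ]).sort_values("time_point_h", ignore_index=True)
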