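"""End-to-end orchestration: manifest in, per-stage CSV tables out.

``run_pipeline`` drives standardize -> per-channel NCF -> nucleus
detection/classification -> area/density summary for every image entry, and
the soma-connectivity stage for entries carrying annotation tables.  Each
stage emits one tidy CSV; a JSON run manifest records parameters, seed and
versions so a run is reproducible bit for bit.  Per-image failures are
logged and skipped; the run fails only if every image fails.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import area as area_mod
from .area import AreaParams, summarize
from .connectivity import (ConnectivityParams, SomaAnnotationSet,
                           auto_exclude_bright, compare_groups,
                           connectivity_ratio, soma_status)
from .imgio import load_channel, standardize_channels
from .ncf import ncf_per_channel
from .nuclei import NucleiParams, classify_nuclei, detect_nuclei

log = logging.getLogger("assemblyscope")

__all__ = ["ImageEntry", "RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when no image in the manifest could be processed."""


@dataclass
class ImageEntry:
    image_id: str
    channels: dict[str, Path]                  # role -> path
    group: str | None = None
    time_point_h: float | None = None
    grid_cell: str | None = None
    soma_csv: Path | None = None
    links_csv: Path | None = None


@dataclass
class RunConfig:
    images: list[ImageEntry]
    nuclei_params: NucleiParams = field(default_factory=NucleiParams)
    area_params: AreaParams = field(default_factory=AreaParams)
    connectivity_params: ConnectivityParams = field(default_factory=ConnectivityParams)
    out_dir: Path = Path("assemblyscope_out")
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def resolve(p):
            return None if p is None else (base / p)

        entries = []
        for item in raw.get("images", []):
            channels = {role: base / item[role]
                        for role in ("nuclei", "neuron", "astrocyte", "phase")
                        if role in item}
            entries.append(ImageEntry(
                image_id=str(item["id"]), channels=channels,
                group=item.get("group"), time_point_h=item.get("time_point_h"),
                grid_cell=item.get("grid_cell"),
                soma_csv=resolve(item.get("somas")),
                links_csv=resolve(item.get("links")),
            ))
        params = raw.get("params", {})
        return cls(
            images=entries,
            nuclei_params=NucleiParams(**params.get("nuclei", {})),
            area_params=AreaParams(**params.get("area", {})),
            connectivity_params=ConnectivityParams(**params.get("connectivity", {})),
            out_dir=Path(raw.get("out_dir", "assemblyscope_out")),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )


def _process_image(entry: ImageEntry, config: RunConfig):
    loaded = {role: load_channel(path, role) for role, path in entry.channels.items()}
    fluor = {r: img for r, img in loaded.items() if r != "phase"}
    ncf_rows, nuc_rows, dens_row, conn_row = [], [], None, None

    if fluor:
        std = standardize_channels(fluor)
        for role, res in ncf_per_channel(std).items():
            ncf_rows.append((entry.image_id, role, res.f_bar_log, res.ncf))
        if {"nuclei", "neuron", "astrocyte"} <= set(std.channels):
            records = detect_nuclei(std["nuclei"], config.nuclei_params)
            records = classify_nuclei(records, std["neuron"], std["astrocyte"])
            for i, rec in enumerate(records):
                nuc_rows.append((entry.image_id, i, rec.centroid[0], rec.centroid[1],
                                 rec.object_area_px, rec.label))
            nmask = area_mod.neuron_mask(std["neuron"], std["astrocyte"], config.area_params)
            gmask = area_mod.astrocyte_mask(std["astrocyte"], std["neuron"], config.area_params)
            s = summarize(nmask, gmask, records)
            dens_row = (entry.image_id, entry.group, entry.time_point_h,
                        s.n_neurons, s.n_glia, s.n_unclassified,
                        s.neuron_area_px, s.glia_area_px,
                        s.mean_neuron_area_um2, s.mean_glia_area_um2,
                        s.neuron_density_per_mm2, s.glia_density_per_mm2,
                        s.neuron_glia_ratio)

    if entry.soma_csv is not None:
        ann = SomaAnnotationSet.from_csv(
            entry.soma_csv, entry.links_csv, grid_cell=entry.grid_cell,
            time_point_h=entry.time_point_h, group=entry.group)
        if "phase" in loaded and config.connectivity_params.exclude_bright:
            ann = auto_exclude_bright(loaded["phase"].pixels, ann,
                                      config.connectivity_params)
        res = connectivity_ratio(soma_status(ann, config.connectivity_params))
        conn_row = (entry.image_id, entry.grid_cell, entry.time_point_h, entry.group,
                    res.n_total, res.n_isolated, res.ratio)
    return ncf_rows, nuc_rows, dens_row, conn_row


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage over the manifest and write one CSV per stage.

    Returns the stage tables keyed by name; tables are also written under
    ``config.out_dir`` together with ``manifest.json``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ncf_rows, nuc_rows, dens_rows, conn_rows = [], [], [], []
    failures = []
    for entry in config.images:
        try:
            nr, kr, dr, cr = _process_image(entry, config)
        except Exception as exc:   # per-image isolation is the contract
            log.warning("skipping image %s: %s", entry.image_id, exc)
            failures.append((entry.image_id, str(exc)))
            continue
        ncf_rows.extend(nr)
        nuc_rows.extend(kr)
        if dr is not None:
            dens_rows.append(dr)
        if cr is not None:
            conn_rows.append(cr)
    if config.images and len(failures) == len(config.images):
        raise PipelineError(f"all {len(failures)} images failed: {failures}")

    tables = {
        "ncf": pd.DataFrame(ncf_rows, columns=["image_id", "channel", "f_bar_log", "ncf"]),
        "nuclei": pd.DataFrame(nuc_rows, columns=[
            "image_id", "nucleus_id", "row", "col", "area_px", "label"]),
        "density": pd.DataFrame(dens_rows, columns=[
            "image_id", "group", "time_point_h", "n_neurons", "n_glia",
            "n_unclassified", "neuron_area_px", "glia_area_px",
            "mean_neuron_area_um2", "mean_glia_area_um2",
            "neuron_density_per_mm2", "glia_density_per_mm2", "neuron_glia_ratio"]),
        "connectivity": pd.DataFrame(conn_rows, columns=[
            "image_id", "grid_cell", "time_point_h", "group",
            "n_total", "n_isolated", "ratio"]),
    }
    conn = tables["connectivity"]
    if conn.ratio.notna().any() and conn.group.nunique() >= 2:
        tables["comparison"] = compare_groups(
            conn.rename(columns={})[["group", "time_point_h", "ratio"]])
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)

    try:
        version = metadata.version("assemblyscope")
    except metadata.PackageNotFoundError:
        version = "unknown"
    manifest = {
        "seed": config.seed,
        "params": {
            "nuclei": dataclasses.asdict(config.nuclei_params),
            "area": dataclasses.asdict(config.area_params),
            "connectivity": dataclasses.asdict(config.connectivity_params),
        },
        "images": [{"id": e.image_id,
                    "channels": {r: str(p) for r, p in e.channels.items()},
                    "group": e.group, "time_point_h": e.time_point_h}
                   for e in config.images],
        "failures": failures,
        "versions": {"assemblyscope": version, "numpy": np.__version__},
        "outputs": sorted(f"{name}.csv" for name in tables),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return tables
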