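"""Orchestration: simulate → segment → measure → report as one reproducible run.

Each stage reads and writes plain files (OME-TIFF stacks, 8-bit mask TIFFs,
CSV tables) so stages can be re-run in isolation; ``run_pipeline`` chains them
and records a ``manifest.json`` with the seed, per-stage parameters, package
version and per-cell exclusions.  All randomness flows from one integer seed
through per-cell substreams, so a re-run reproduces every file byte for byte.

``run_in_memory`` performs the same simulate→segment→measure chain without
touching disk; it is the fast path used for population experiments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .configurations import configuration_frequencies
from .metrics import measure_cell
from .popstats import aggregate, translocation_screen
from .segment import SegmentedCell, TerritoryComponents, segment_cell
from .simulate import (
    PROBE_ROLES,
    SimulationParams,
    params_from_dict,
    params_to_dict,
    simulate_population,
)
from .stackio import (
    BinaryMask,
    load_config,
    read_labels,
    read_mask,
    read_stack,
    write_labels,
    write_mask,
    write_stack,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PipelineError",
    "simulate_to_dir",
    "segment_dir",
    "measure_dir",
    "report_cells",
    "run_pipeline",
    "run_in_memory",
]


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    simulation: SimulationParams
    n_cells: int = 20
    seed: int = 0
    segmentation: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = load_config(path)
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        sim = params_from_dict(cfg.get("simulation") or {})
        rc = cls(
            simulation=sim,
            n_cells=int(cfg.get("n_cells", 20)),
            seed=int(cfg.get("seed", sim.seed)),
            segmentation=dict(cfg.get("segmentation") or {}),
            report=dict(cfg.get("report") or {}),
            log_level=str(cfg.get("log_level", "INFO")),
        )
        rc.validate()
        return rc

    def validate(self) -> None:
        self.simulation.validate()
        if self.n_cells < 1:
            raise PipelineError("config", "n_cells must be at least 1")
        seg_channels = self.segmentation.get("paint_channels")
        if seg_channels:
            unknown = set(seg_channels) - set(self.simulation.channel_names)
            if unknown:
                raise PipelineError(
                    "config", f"segmentation channels {sorted(unknown)} not simulated"
                )

    def seg_config(self) -> dict:
        cfg = {"dna_channel": "dna", "spacing": list(self.simulation.voxel_spacing)}
        cfg.update(self.segmentation)
        names = [cfg["dna_channel"]] + self.simulation.channel_names
        if self.simulation.band_probes is not None:
            names += list(PROBE_ROLES)
            cfg.setdefault("probe_roles", {r: r for r in PROBE_ROLES})
        cfg["channels"] = names
        cfg.setdefault("paint_channels_measure", self.simulation.channel_names)
        return cfg


def _truth_row(cell_id: str, truth) -> dict:
    row: dict = {"cell_id": cell_id}
    for (a, b), v in sorted(truth.true_overlap.items()):
        row[f"true_ovf_{a}_given_{b}"] = v
    for ch, paired in truth.true_pairing.items():
        row[f"true_paired_{ch}"] = paired
    if truth.true_configuration is not None:
        row["true_cfg_state"] = truth.true_configuration.state_id
        row["true_cfg_closed"] = truth.true_configuration.closed
    return row


def simulate_to_dir(params: SimulationParams, n_cells: int, seed: int, out_dir) -> pd.DataFrame:
    """Simulate a population; write per-cell OME-TIFF stacks, 8-bit truth masks
    and ``truth.csv``.  Returns the truth table."""
    out_dir = Path(out_dir)
    stacks_dir = out_dir / "stacks"
    truth_dir = out_dir / "truth"
    stacks_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    spacing = tuple(params.voxel_spacing)
    rows = []
    for cell_id, truth, stack in simulate_population(params, n_cells, seed):
        write_stack(stack, stacks_dir / f"{cell_id}.ome.tif")
        write_mask(BinaryMask(truth.nucleus_mask, spacing), truth_dir / f"{cell_id}_nucleus.tif")
        for ch, mask in truth.masks.items():
            write_mask(BinaryMask(mask, spacing), truth_dir / f"{cell_id}_{ch}.tif")
        if truth.band_masks:
            for role, mask in truth.band_masks.items():
                write_mask(BinaryMask(mask, spacing), truth_dir / f"{cell_id}_{role}.tif")
        rows.append(_truth_row(cell_id, truth))
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "truth.csv", index=False)
    return df


def segment_dir(in_dir, config: dict, out_dir) -> dict:
    """Segment every stack in ``in_dir/stacks`` (or ``in_dir``); write label
    TIFFs, nucleus masks, and ``provenance.json``."""
    in_dir = Path(in_dir)
    stacks_dir = in_dir / "stacks" if (in_dir / "stacks").is_dir() else in_dir
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(stacks_dir.glob("*.tif")) + sorted(stacks_dir.glob("*.tiff"))
    if not paths:
        raise PipelineError("segment", f"no TIFF stacks found under {stacks_dir}")
    provenance: dict = {}
    for path in paths:
        stack = read_stack(path, config)
        cell = segment_cell(stack, config)
        cell_dir = out_dir / cell.cell_id
        cell_dir.mkdir(exist_ok=True)
        write_mask(cell.nucleus, cell_dir / "nucleus.tif")
        for ch, comps in cell.territories.items():
            write_labels(comps.labels, cell_dir / f"{ch}_labels.tif")
        provenance[cell.cell_id] = cell.provenance
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=float)
    return provenance


def _load_segmented(cell_dir: Path, spacing) -> SegmentedCell:
    nucleus = read_mask(cell_dir / "nucleus.tif", spacing)
    cell = SegmentedCell(cell_id=cell_dir.name, nucleus=nucleus)
    voxvol = float(np.prod(spacing))
    for label_path in sorted(cell_dir.glob("*_labels.tif")):
        ch = label_path.name[: -len("_labels.tif")]
        labels = read_labels(label_path)
        counts = np.bincount(labels.ravel())[1:]
        cell.territories[ch] = TerritoryComponents(
            labels=labels, volumes=counts * voxvol, voxel_spacing=tuple(spacing)
        )
    return cell


def measure_dir(masks_dir, config: dict, out_csv) -> pd.DataFrame:
    """Measure every segmented cell under ``masks_dir`` into one CSV row each.

    Cells whose nucleus touched the stack border are excluded (never
    silently: the exclusion is logged and recorded in the returned frame's
    ``attrs['exclusions']``).
    """
    masks_dir = Path(masks_dir)
    spacing = tuple(config.get("spacing") or (1.0, 1.0, 1.0))
    probe_roles = config.get("probe_roles") or None
    paint = config.get("paint_channels_measure")
    prov_path = masks_dir / "provenance.json"
    provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}

    rows, exclusions = [], {}
    cell_dirs = sorted(d for d in masks_dir.iterdir() if d.is_dir())
    if not cell_dirs:
        raise PipelineError("measure", f"no segmented cells under {masks_dir}")
    for cell_dir in cell_dirs:
        info = provenance.get(cell_dir.name, {}).get("nucleus", {})
        if info.get("border_touching"):
            exclusions[cell_dir.name] = "nucleus touches stack border"
            logger.info("excluding %s: nucleus touches stack border", cell_dir.name)
            continue
        cell = _load_segmented(cell_dir, spacing)
        cm = measure_cell(cell, spacing, paint_channels=paint, probe_roles=probe_roles)
        rows.append(cm.to_row())
    if not rows:
        raise PipelineError("measure", "every cell was excluded")
    df = pd.DataFrame(rows)
    df.attrs["exclusions"] = exclusions
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def report_cells(cells: pd.DataFrame | str, channels: list[str], out_dir, *, plots: bool = False) -> dict:
    """Aggregate a cells table and write the report files.

    Writes ``overlap_heatmap.csv``, ``contact_heatmap.csv``,
    ``shell_profiles.csv``, ``config_frequencies.csv`` (when configurations
    were measured), ``summary.json``, and optional PNG heatmap/box plots.
    """
    if not isinstance(cells, pd.DataFrame):
        cells = pd.read_csv(cells)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = aggregate(cells, channels)
    summary.overlap_median.to_csv(out_dir / "overlap_heatmap.csv")
    summary.contact_freq.to_csv(out_dir / "contact_heatmap.csv")
    if summary.shell_profiles is not None:
        summary.shell_profiles.to_csv(out_dir / "shell_profiles.csv")

    out: dict = {
        "n_cells": summary.n_cells,
        "channels": channels,
        "overlap_median": {
            f"{a}|{b}": summary.overlap_median.loc[a, b]
            for a in channels for b in channels
            if a != b and np.isfinite(summary.overlap_median.loc[a, b])
        },
        "pairing_frequency": {
            ch: summary.contact_freq.loc[ch, ch]
            for ch in channels if np.isfinite(summary.contact_freq.loc[ch, ch])
        },
        "intermixing_median": (
            summary.intermixing_median.to_dict() if summary.intermixing_median is not None else {}
        ),
    }
    if "cfg_state" in cells.columns:
        states = cells["cfg_state"].dropna().astype(int)
        if len(states):
            freqs = configuration_frequencies(list(states))
            pd.DataFrame(
                {"state_id": range(8), "count": freqs.counts, "fraction": freqs.fractions}
            ).to_csv(out_dir / "config_frequencies.csv", index=False)
            out["configuration"] = {
                "open_fraction": freqs.open_fraction,
                "closed_fraction": freqs.closed_fraction,
                "n": freqs.n,
            }
    if len(channels) >= 3:
        try:
            out["translocation_candidates"] = [
                list(p) for p in translocation_screen(summary)
            ]
        except ValueError:
            pass
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True, default=float)

    if plots:
        _write_plots(summary, cells, channels, out_dir)
    return out


def _write_plots(summary, cells, channels, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (mat, title) in zip(
        axes,
        [(summary.overlap_median, "median overlap O(row|col)"),
         (summary.contact_freq, "contact / pairing frequency")],
    ):
        im = ax.imshow(mat.values, vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(channels)), channels, rotation=45)
        ax.set_yticks(range(len(channels)), channels)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out_dir / "heatmaps.png", dpi=120)
    plt.close(fig)

    volfrac_cols = [f"volfrac_{ch}" for ch in channels if f"volfrac_{ch}" in cells.columns]
    if volfrac_cols:
        fig, ax = plt.subplots(figsize=(1.2 * len(volfrac_cols) + 1.5, 4))
        data = [cells[c].dropna().values for c in volfrac_cols]
        ax.boxplot(data, tick_labels=channels[: len(data)])
        ax.set_ylabel("CT volume / nuclear volume")
        fig.tight_layout()
        fig.savefig(out_dir / "volume_fractions.png", dpi=120)
        plt.close(fig)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute simulate → segment → measure → report; return the output root.

    Every stage failure is re-raised stage-tagged; partial outputs are kept.
    ``manifest.json`` records everything needed to reproduce the run.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seg_cfg = config.seg_config()

    try:
        simulate_to_dir(config.simulation, config.n_cells, config.seed, out_dir)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc
    try:
        segment_dir(out_dir, seg_cfg, out_dir / "masks")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("segment", str(exc)) from exc
    try:
        cells = measure_dir(out_dir / "masks", seg_cfg, out_dir / "cells.csv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("measure", str(exc)) from exc
    try:
        report_cells(
            cells, config.simulation.channel_names, out_dir / "report",
            plots=bool(config.report.get("plots", False)),
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("report", str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_cells": config.n_cells,
        "simulation": params_to_dict(config.simulation),
        "segmentation": seg_cfg,
        "exclusions": cells.attrs.get("exclusions", {}),
    }
    manifest["simulation"]["translocation"] = (
        None if config.simulation.translocation is None
        else vars(config.simulation.translocation)
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out_dir


def run_in_memory(
    params: SimulationParams,
    n_cells: int,
    seed: int,
    seg_config: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, segment and measure a population without touching disk.

    Returns ``(cells, truth)`` data frames with the same column schemes as the
    file-based stages.  Border-touching nuclei are excluded, as in
    :func:`measure_dir`.
    """
    cfg = RunConfig(simulation=params, n_cells=n_cells, seed=seed,
                    segmentation=dict(seg_config or {}))
    cfg.validate()
    seg_cfg = cfg.seg_config()
    probe_roles = seg_cfg.get("probe_roles")
    rows, truth_rows, exclusions = [], [], {}
    for cell_id, truth, stack in simulate_population(params, n_cells, seed):
        truth_rows.append(_truth_row(cell_id, truth))
        cell = segment_cell(stack, seg_cfg)
        if cell.provenance["nucleus"].get("border_touching"):
            exclusions[cell_id] = "nucleus touches stack border"
            continue
        cm = measure_cell(
            cell, params.voxel_spacing,
            paint_channels=params.channel_names, probe_roles=probe_roles,
        )
        rows.append(cm.to_row())
    cells = pd.DataFrame(rows)
    cells.attrs["exclusions"] = exclusions
    return cells, pd.DataFrame(truth_rows)
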