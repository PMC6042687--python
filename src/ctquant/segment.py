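"""Nucleus and territory segmentation of multi-channel 3D FISH stacks.

The nucleus is segmented from the DNA counterstain by global Otsu
thresholding, 3D hole filling and retention of the largest 26-connected
component.  Chromosome paints are segmented by 3D hysteresis thresholding
(high-threshold seeds grown through low-threshold voxels under
26-connectivity, clipped to the nucleus), and point-like foci by 3D
Laplacian-of-Gaussian spot detection.  Homolog pairing is scored from the
retained components of one channel: a paint presenting a single signal is
called paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .metrics import CONNECTIVITY_26
from .stackio import BinaryMask, ImageStack

__all__ = [
    "NoNucleusError",
    "TerritoryComponents",
    "SegmentedCell",
    "segment_nucleus",
    "auto_thresholds",
    "hysteresis_segment",
    "detect_spots_3d",
    "pairing_state",
    "segment_cell",
]


class NoNucleusError(ValueError):
    """Raised when the DNA channel contains no segmentable foreground."""


@dataclass
class TerritoryComponents:
    """Labeled 26-connected components of one channel's territory mask.

    Labels are 1..n, sorted by descending physical volume; 0 is background.
    """

    labels: np.ndarray
    volumes: np.ndarray  # µm³ per label, descending
    voxel_spacing: tuple[float, float, float]

    @property
    def n_components(self) -> int:
        return len(self.volumes)

    @property
    def union_mask(self) -> np.ndarray:
        return self.labels > 0

    def component_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class SegmentedCell:
    """Nucleus mask plus per-channel territory components and foci for one cell."""

    cell_id: str
    nucleus: BinaryMask
    territories: dict[str, TerritoryComponents] = field(default_factory=dict)
    foci: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def segment_nucleus(stack: ImageStack, dna_channel: str) -> tuple[BinaryMask, dict]:
    """Segment the nucleus from the DNA counterstain.

    Global Otsu threshold on the DNA channel, 3D hole filling, then the
    largest 26-connected component.  Returns the mask and a provenance dict
    recording the threshold and whether the nucleus touches the stack border
    (border-touching cells are conventionally excluded downstream).
    """
    img = stack.channel(dna_channel)
    if img.max() == img.min():
        raise NoNucleusError("DNA channel is constant; no nucleus found")
    thr = float(threshold_otsu(np.asarray(img)))
    fg = img > thr
    if not fg.any():
        raise NoNucleusError("no foreground above the DNA threshold")
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg, structure=CONNECTIVITY_26)
    if n == 0:
        raise NoNucleusError("no connected nucleus component")
    sizes = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    border = bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    info = {"dna_threshold": thr, "border_touching": border}
    return BinaryMask(voxels=mask, voxel_spacing=stack.voxel_spacing), info


def auto_thresholds(
    stack: ImageStack,
    channel: str,
    nucleus: BinaryMask,
    *,
    low_factor: float = 0.5,
    override: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Derive (low, high) hysteresis thresholds for a paint channel.

    ``high`` is the Otsu threshold over in-nucleus voxels of the channel and
    ``low = low_factor * high`` (0.5 by default).  An explicit ``override``
    (low, high) is returned verbatim.
    """
    if override is not None:
        low, high = float(override[0]), float(override[1])
        if low > high:
            raise ValueError(f"low threshold {low} exceeds high threshold {high}")
        return low, high
    nuc = nucleus.voxels
    if not nuc.any():
        raise ValueError("empty nucleus mask in auto_thresholds")
    values = np.asarray(stack.channel(channel))[nuc]
    if values.max() == values.min():
        raise ValueError(f"channel {channel!r} is constant inside the nucleus; thresholds degenerate")
    t = float(threshold_otsu(values))
    # threshold_otsu follows the "foreground = value > t" convention, so on a
    # gappy histogram t sits on the lower class; move it to the gap midpoint
    # so that the >= seed rule never floods the background class.
    below = values[values <= t]
    above = values[values > t]
    if len(above):
        high = (float(below.max()) + float(above.min())) / 2.0
    else:
        high = t
    return low_factor * high, high


def hysteresis_segment(
    stack_or_image,
    channel: str | None = None,
    *,
    low: float,
    high: float,
    min_volume: float = 0.0,
    nucleus: BinaryMask | None = None,
    voxel_spacing=None,
) -> TerritoryComponents:
    """3D hysteresis segmentation of one channel.

    Voxels ≥ ``high`` seed the segmentation; components are grown through
    voxels ≥ ``low`` under 26-connectivity, clipped to the nucleus, and
    components smaller than ``min_volume`` µm³ are discarded.  Surviving
    components are relabeled 1..n by descending volume.
    """
    if low > high:
        raise ValueError(f"low threshold {low} exceeds high threshold {high}")
    if isinstance(stack_or_image, ImageStack):
        img = stack_or_image.channel(channel)
        spacing = stack_or_image.voxel_spacing
    else:
        img = np.asarray(stack_or_image)
        if voxel_spacing is None and nucleus is not None:
            voxel_spacing = nucleus.voxel_spacing
        spacing = tuple(voxel_spacing or (1.0, 1.0, 1.0))
    voxvol = float(np.prod(spacing))

    mask_low = img >= low
    seeds = img >= high
    lab_low, n_low = ndi.label(mask_low, structure=CONNECTIVITY_26)
    if n_low:
        seeded = np.unique(lab_low[seeds])
        seeded = seeded[seeded > 0]
        grown = np.isin(lab_low, seeded)
    else:
        grown = np.zeros_like(mask_low)
    if nucleus is not None:
        grown &= nucleus.voxels

    labels, n = ndi.label(grown, structure=CONNECTIVITY_26)
    if n == 0:
        return TerritoryComponents(
            labels=np.zeros(img.shape, dtype=np.int32), volumes=np.empty(0), voxel_spacing=spacing
        )
    counts = np.bincount(labels.ravel())[1:]
    volumes = counts * voxvol
    keep = np.flatnonzero(volumes >= min_volume) + 1
    # descending volume; ties broken by original label order (stable)
    keep = keep[np.argsort(-volumes[keep - 1], kind="stable")]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return TerritoryComponents(
        labels=remap[labels],
        volumes=volumes[keep - 1],
        voxel_spacing=spacing,
    )


def detect_spots_3d(
    stack: ImageStack,
    channel: str,
    scale_sigma,
    *,
    peak_threshold: float | None = None,
    mad_multiplier: float = 8.0,
    nucleus: BinaryMask | None = None,
) -> np.ndarray:
    """3D Laplacian-of-Gaussian spot detection.

    The negated LoG response at ``scale_sigma`` (µm per axis) is computed and
    local maxima over the 26-neighborhood above ``peak_threshold`` (inside the
    nucleus, if given) are returned as (n, 3) physical coordinates in µm.
    When ``peak_threshold`` is None it defaults to ``mad_multiplier`` times
    the scaled median absolute deviation of the in-nucleus response.
    """
    scale_sigma = np.asarray(scale_sigma, dtype=float)
    if scale_sigma.ndim == 0:
        scale_sigma = np.repeat(scale_sigma, 3)
    if np.any(scale_sigma <= 0):
        raise ValueError("scale_sigma must be positive on every axis")
    spacing = np.asarray(stack.voxel_spacing)
    sigma_vox = scale_sigma / spacing
    img = np.asarray(stack.channel(channel), dtype=float)
    resp = -ndi.gaussian_laplace(img, sigma=sigma_vox)

    inside = nucleus.voxels if nucleus is not None else np.ones(img.shape, bool)
    if peak_threshold is None:
        vals = resp[inside]
        mad = np.median(np.abs(vals - np.median(vals)))
        peak_threshold = mad_multiplier * 1.4826 * mad

    local_max = resp == ndi.maximum_filter(resp, size=3, mode="nearest")
    peaks = local_max & (resp > peak_threshold) & inside
    if not peaks.any():
        return np.empty((0, 3))
    # a blurred pair closer than the scale produces a flat plateau of tied
    # maxima: collapse each 26-connected plateau to its strongest voxel
    lab, n = ndi.label(peaks, structure=np.ones((3, 3, 3), bool))
    coords = []
    for i in range(1, n + 1):
        idx = np.argwhere(lab == i)
        best = idx[np.argmax(resp[tuple(idx.T)])]
        coords.append(best)
    return np.asarray(coords, dtype=float) * spacing


def pairing_state(components: TerritoryComponents, relative_min: float = 0.1) -> tuple[int, bool | None]:
    """Count FISH signals and call homolog pairing for one channel.

    Signals are components with volume ≥ ``relative_min`` × the largest
    component's volume (speck filter); a channel presenting a single signal is
    called paired.  With zero components the pairing call is missing (None).
    """
    if components.n_components == 0:
        return 0, None
    vols = components.volumes
    n_signals = int(np.count_nonzero(vols >= relative_min * vols[0]))
    return n_signals, n_signals == 1


def segment_cell(stack: ImageStack, config: dict) -> SegmentedCell:
    """Segment one cell end to end from a stack and a channel config.

    Config keys: ``dna_channel`` (required), ``paint_channels`` (default: all
    non-DNA channels), ``thresholds`` ({channel: [low, high]} overrides),
    ``min_volume`` (µm³, default 0.05), ``low_factor`` (default 0.5),
    ``spot_channels`` ({channel: {"sigma": µm or [z,y,x]}}).
    """
    dna = config.get("dna_channel")
    if dna is None:
        raise ValueError("config must name a dna_channel")
    if dna not in stack.channel_names:
        raise ValueError(f"dna_channel {dna!r} not in stack channels {stack.channel_names}")
    nucleus, nuc_info = segment_nucleus(stack, dna)

    paint_channels = config.get("paint_channels") or [c for c in stack.channel_names if c != dna]
    min_volume = float(config.get("min_volume", 0.05))
    low_factor = float(config.get("low_factor", 0.5))
    overrides = config.get("thresholds") or {}

    cell = SegmentedCell(cell_id=stack.cell_id, nucleus=nucleus)
    cell.provenance = {"nucleus": nuc_info, "channels": {}, "min_volume": min_volume}

    for ch in paint_channels:
        override = overrides.get(ch)
        try:
            low, high = auto_thresholds(
                stack, ch, nucleus, low_factor=low_factor,
                override=tuple(override) if override else None,
            )
        except ValueError as exc:
            cell.territories[ch] = TerritoryComponents(
                labels=np.zeros(stack.spatial_shape, dtype=np.int32),
                volumes=np.empty(0),
                voxel_spacing=stack.voxel_spacing,
            )
            cell.provenance["channels"][ch] = {"error": str(exc)}
            continue
        comps = hysteresis_segment(
            stack, ch, low=low, high=high, min_volume=min_volume, nucleus=nucleus
        )
        cell.territories[ch] = comps
        cell.provenance["channels"][ch] = {
            "low": low, "high": high, "n_components": comps.n_components,
        }

    for ch, opts in (config.get("spot_channels") or {}).items():
        sigma = opts.get("sigma", 0.3)
        cell.foci[ch] = detect_spots_3d(
            stack, ch, sigma,
            peak_threshold=opts.get("peak_threshold"),
            mad_multiplier=float(opts.get("mad_multiplier", 8.0)),
            nucleus=nucleus,
        )
        cell.provenance["channels"].setdefault(ch, {})["n_foci"] = len(cell.foci[ch])

    return cell
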