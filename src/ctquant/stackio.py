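"""Image stack and mask I/O, plus the unit and axis conventions used package-wide.

Conventions
-----------
* Axis order is ``(channel, z, y, x)`` for stacks and ``(z, y, x)`` for masks.
* Voxel indices are 0-based and refer to voxel centers; the physical position
  of index ``(k, j, i)`` is ``(k*sz, j*sy, i*sx)`` in micrometres.
* Volumes are reported in µm³ (voxel count × sz·sy·sx), distances in µm.
* 16-bit unsigned is the canonical intensity dialect; float data read from
  disk is accepted and kept as-is.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "BinaryMask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "load_config",
]


@dataclass
class ImageStack:
    """A multi-channel 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (C, Z, Y, X)
        Non-negative intensities.
    voxel_spacing : tuple of float
        (z, y, x) spacing in µm; all components > 0.
    channel_names : list of str
        One name per channel, in axis order.
    cell_id : str
        Identifier of the cell/field this stack images.
    """

    voxels: np.ndarray
    voxel_spacing: tuple[float, float, float]
    channel_names: list[str]
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) voxels, got shape {self.voxels.shape}")
        if self.voxels.shape[0] < 1:
            raise ValueError("stack must contain at least one channel")
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"channel name count {len(self.channel_names)} does not match "
                f"channel axis length {self.voxels.shape[0]}"
            )
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be three positive lengths, got {self.voxel_spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack intensities must be finite")

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        sz, sy, sx = self.voxel_spacing
        return sz * sy * sx

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the (Z, Y, X) intensity grid of a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in stack (have {self.channel_names})") from None
        return self.voxels[idx]


@dataclass
class BinaryMask:
    """A boolean (Z, Y, X) voxel grid with physical spacing."""

    voxels: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected (Z, Y, X) mask, got shape {self.voxels.shape}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be three positive lengths, got {self.voxel_spacing}")

    @property
    def voxel_volume(self) -> float:
        sz, sy, sx = self.voxel_spacing
        return sz * sy * sx

    @property
    def volume(self) -> float:
        """Physical volume of the foreground in µm³."""
        return float(np.count_nonzero(self.voxels)) * self.voxel_volume


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with spacing and channel metadata."""
    data = stack.voxels
    if data.dtype.kind in "ui" and data.dtype != np.uint16:
        data = data.astype(np.uint16)
    axes = "CZYX"
    # tifffile's OME writer squeezes singleton leading axes; keep axes in sync
    while data.ndim > 2 and data.shape[0] == 1:
        data = data[0]
        axes = axes[1:]
    sz, sy, sx = stack.voxel_spacing
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": axes,
            "PhysicalSizeZ": sz,
            "PhysicalSizeY": sy,
            "PhysicalSizeX": sx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def _ome_spacing(ome_xml: str) -> tuple[float, float, float] | None:
    """Extract (z, y, x) physical voxel sizes from OME-XML, if all are present."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    for elem in root.iter():
        if elem.tag.endswith("Pixels"):
            try:
                return (
                    float(elem.attrib["PhysicalSizeZ"]),
                    float(elem.attrib["PhysicalSizeY"]),
                    float(elem.attrib["PhysicalSizeX"]),
                )
            except KeyError:
                return None
    return None


def _ome_channel_names(ome_xml: str) -> list[str] | None:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    names = [
        elem.attrib["Name"]
        for elem in root.iter()
        if elem.tag.endswith("Channel") and "Name" in elem.attrib
    ]
    return names or None


def read_stack(path, config: dict | None = None) -> ImageStack:
    """Read a multi-page TIFF / OME-TIFF into an :class:`ImageStack`.

    The axis order is normalised to (channel, z, y, x).  Voxel spacing is taken
    from OME metadata when present; if the config also states a spacing and it
    disagrees, the config wins with a logged warning.

    Parameters
    ----------
    path : path-like
    config : dict, optional
        Keys used: ``channels`` (list of names, page order), ``spacing``
        ((z, y, x) µm).
    """
    config = config or {}
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        ome_xml = tif.ome_metadata

    # Normalise to CZYX. tifffile uses 'Q'/'S'/'I' for unknown axes.
    axes = axes.replace("Q", "C").replace("S", "C").replace("I", "Z")
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        cfg_channels = config.get("channels")
        if axes.startswith("C") and not axes.startswith("CZ"):
            # pages are channels (one plane each)
            if cfg_channels is not None and len(cfg_channels) != data.shape[0]:
                raise ValueError(
                    f"channel count mismatch for {path.name}: file has {data.shape[0]} "
                    f"pages but config names {len(cfg_channels)} channels"
                )
            data = data[:, None, :, :]
        elif cfg_channels is None or len(cfg_channels) == 1:
            data = data[None]
        elif len(cfg_channels) == data.shape[0]:
            # plain multi-page TIFF, one page per channel
            data = data[:, None, :, :]
        else:
            raise ValueError(
                f"channel count mismatch for {path.name}: file has {data.shape[0]} "
                f"pages but config names {len(cfg_channels)} channels"
            )
    elif data.ndim == 4:
        if axes == "ZCYX":
            data = np.moveaxis(data, 1, 0)
        elif axes != "CZYX":
            # fall back: assume channel axis is the shortest leading axis
            if data.shape[1] < data.shape[0]:
                data = np.moveaxis(data, 1, 0)
    else:
        raise ValueError(f"cannot interpret TIFF with {data.ndim} dimensions as a 3D multi-channel stack")

    n_channels = data.shape[0]
    channel_names = config.get("channels")
    if channel_names is None and ome_xml:
        channel_names = _ome_channel_names(ome_xml)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_channels)]
    if len(channel_names) != n_channels:
        raise ValueError(
            f"channel count mismatch for {path.name}: file has {n_channels} "
            f"channels but config names {len(channel_names)} ({channel_names})"
        )

    ome_spacing = _ome_spacing(ome_xml) if ome_xml else None
    cfg_spacing = config.get("spacing")
    if cfg_spacing is not None:
        spacing = tuple(float(s) for s in cfg_spacing)
        if ome_spacing is not None and not np.allclose(ome_spacing, spacing):
            logger.warning(
                "spacing mismatch for %s: OME metadata %s vs config %s; using config",
                path.name,
                ome_spacing,
                spacing,
            )
    elif ome_spacing is not None:
        spacing = ome_spacing
    else:
        raise ValueError(f"no voxel spacing in OME metadata or config for {path.name}")

    return ImageStack(
        voxels=data,
        voxel_spacing=spacing,
        channel_names=list(channel_names),
        cell_id=path.stem.replace(".ome", ""),
    )


def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as 8-bit multi-page TIFF (255 = foreground)."""
    tifffile.imwrite(str(path), mask.voxels.astype(np.uint8) * 255, photometric="minisblack")


def read_mask(path, voxel_spacing) -> BinaryMask:
    """Read an 8-bit TIFF mask written by :func:`write_mask`."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return BinaryMask(voxels=data > 0, voxel_spacing=voxel_spacing)


def write_labels(labels: np.ndarray, path) -> None:
    """Write a labeled component grid as 16-bit multi-page TIFF."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 components cannot be stored as 16-bit labels")
    tifffile.imwrite(str(path), labels.astype(np.uint16), photometric="minisblack")


def read_labels(path) -> np.ndarray:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return data.astype(np.int32)
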