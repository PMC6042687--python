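"""Per-cell chromosome-territory metrics computed from binary voxel masks.

All quantities the pipeline reports per cell live here: volumes and volume
fractions, pairwise overlap (voxel colocalization as a fraction of the
reference territory), intermixing against the union of all other territories,
contact calls, minimal edge-to-edge distances, mesh-based sphericity
("compacity"), and the five-shell radial distribution.

Masks are (Z, Y, X) boolean grids on a common voxel lattice; spacing is the
(z, y, x) physical voxel size in µm.  26-connectivity is used for every 3D
adjacency decision in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as skmeasure

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)

__all__ = [
    "CellMeasurements",
    "volume_fraction",
    "overlap_fraction",
    "intermixing_fraction",
    "in_contact",
    "min_edge_distance",
    "compacity",
    "shell_partition",
    "shell_distribution",
    "measure_cell",
]


def _as_bool(mask) -> np.ndarray:
    arr = np.asarray(getattr(mask, "voxels", mask))
    return arr.astype(bool)


def volume_fraction(ct_mask, nucleus_mask) -> float:
    """Territory volume as a fraction of nuclear volume (spacing cancels)."""
    ct = _as_bool(ct_mask)
    nuc = _as_bool(nucleus_mask)
    if ct.shape != nuc.shape:
        raise ValueError(f"grids differ: {ct.shape} vs {nuc.shape}")
    n_nuc = int(np.count_nonzero(nuc))
    if n_nuc == 0:
        raise ValueError("empty nucleus mask")
    return float(np.count_nonzero(ct)) / n_nuc


def overlap_fraction(mask_a, mask_ref) -> float:
    """|A ∩ ref| / |ref| — the overlap of A expressed as a fraction of the
    reference territory's volume.  Asymmetric by design; store both directions.
    """
    a = _as_bool(mask_a)
    ref = _as_bool(mask_ref)
    if a.shape != ref.shape:
        raise ValueError(f"grids differ: {a.shape} vs {ref.shape}")
    n_ref = int(np.count_nonzero(ref))
    if n_ref == 0:
        raise ValueError("empty reference mask in overlap_fraction")
    return float(np.count_nonzero(a & ref)) / n_ref


def intermixing_fraction(target_mask, other_masks) -> float:
    """Fraction of the target territory colocalizing with the union of all others."""
    target = _as_bool(target_mask)
    others = list(other_masks)
    if not others:
        raise ValueError("need at least one other mask")
    n_target = int(np.count_nonzero(target))
    if n_target == 0:
        raise ValueError("empty target mask in intermixing_fraction")
    union = np.zeros_like(target)
    for m in others:
        union |= _as_bool(m)
    return float(np.count_nonzero(target & union)) / n_target


def in_contact(mask_a, mask_b, *, adjacency: bool = True) -> bool:
    """Whether two structures touch: they overlap, or (by default) some voxel
    of A is 26-adjacent to a voxel of B.

    Diffraction-limited signals from abutting domains overlap after PSF blur,
    so a pure-intersection rule would under-call contact by one voxel layer;
    set ``adjacency=False`` for intersection-only contact.
    """
    a = _as_bool(mask_a)
    b = _as_bool(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"grids differ: {a.shape} vs {b.shape}")
    if bool(np.any(a & b)):
        return True
    if not adjacency:
        return False
    if not a.any() or not b.any():
        return False
    dil = ndi.binary_dilation(a, structure=CONNECTIVITY_26)
    return bool(np.any(dil & b))


def min_edge_distance(mask_a, mask_b, spacing) -> float:
    """Minimal edge-to-edge distance between two structures in µm.

    0 if the masks intersect; otherwise the minimum anisotropic Euclidean
    distance between voxel centers of A and B (exact, via the Euclidean
    distance transform of A evaluated at B's voxels).
    """
    a = _as_bool(mask_a)
    b = _as_bool(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"grids differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("min_edge_distance requires two non-empty masks")
    if np.any(a & b):
        return 0.0
    dist_to_a = ndi.distance_transform_edt(~a, sampling=spacing)
    return float(dist_to_a[b].min())


def compacity(mask, spacing) -> float:
    """Sphericity Ψ = π^(1/3)·(6V)^(2/3) / S, in (0, 1]; 1 for a ball.

    V is the physical voxel volume of the mask and S the surface area of a
    marching-cubes isosurface at level 0.5.  Meshing the raw binary grid
    staircases smooth boundaries (inflating S of a digital ball by ~8%), so
    the mask is first smoothed with an isotropic *physical* Gaussian of sigma
    = half the finest voxel size, which flattens the staircase while leaving
    planar faces essentially in place.  Objects too thin to survive a one-
    voxel erosion cannot be smoothed without eroding the level set and fall
    back to the raw mesh.  Discretization can push Ψ slightly above 1 for
    small objects; the value is clamped.  Masks of fewer than 8 voxels give
    unreliable surfaces and raise a warning, but a value is still returned.
    """
    m = _as_bool(mask)
    n = int(np.count_nonzero(m))
    if n == 0:
        raise ValueError("compacity of an empty mask is undefined")
    if n < 8:
        warnings.warn(f"compacity of a {n}-voxel object is unreliable", stacklevel=2)
    spacing = np.asarray([float(s) for s in spacing])
    vol = n * float(np.prod(spacing))
    thin = not ndi.binary_erosion(m, structure=CONNECTIVITY_26).any()
    field = None
    if not thin:
        sigma_vox = 0.5 * spacing.min() / spacing
        field = ndi.gaussian_filter(np.pad(m, 2).astype(float), sigma_vox)
        if not (field.min() < 0.5 < field.max()):
            field = None
    if field is None:
        field = np.pad(m, 1).astype(float)
    verts, faces, _, _ = skmeasure.marching_cubes(field, level=0.5, spacing=tuple(spacing))
    surf = float(skmeasure.mesh_surface_area(verts, faces))
    psi = np.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / surf
    return float(min(psi, 1.0))


def shell_partition(nucleus_mask, n_shells: int = 5, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Partition the nucleus into concentric equal-volume shells.

    Nucleus voxels are ranked by their anisotropic Euclidean distance to the
    nearest background voxel (ties broken by flat voxel index) and split into
    ``n_shells`` equal-count groups.  Shell 1 is the periphery, shell
    ``n_shells`` the center.  Returns an integer grid with 0 outside the
    nucleus and shell labels 1..n_shells inside.
    """
    nuc = _as_bool(nucleus_mask)
    n_vox = int(np.count_nonzero(nuc))
    if n_vox < n_shells:
        raise ValueError(f"nucleus of {n_vox} voxels cannot be split into {n_shells} shells")
    dist = ndi.distance_transform_edt(nuc, sampling=spacing)
    flat_idx = np.flatnonzero(nuc.ravel())
    d = dist.ravel()[flat_idx]
    # sort by (distance, voxel index); flat_idx is already ascending so a
    # stable sort on distance implements the tie-break
    order = np.argsort(d, kind="stable")
    groups = np.array_split(flat_idx[order], n_shells)
    labels = np.zeros(nuc.size, dtype=np.int8)
    for shell, idx in enumerate(groups, start=1):
        labels[idx] = shell
    return labels.reshape(nuc.shape)


def shell_distribution(ct_mask, shell_labels) -> np.ndarray:
    """Fraction of territory voxels falling in each shell; sums to 1 exactly."""
    ct = _as_bool(ct_mask)
    labels = np.asarray(shell_labels)
    if ct.shape != labels.shape:
        raise ValueError(f"grids differ: {ct.shape} vs {labels.shape}")
    n_ct = int(np.count_nonzero(ct))
    if n_ct == 0:
        raise ValueError("empty territory mask in shell_distribution")
    if np.any(labels[ct] == 0):
        raise ValueError("territory mask extends outside the shell-labeled nucleus")
    n_shells = int(labels.max())
    counts = np.bincount(labels[ct], minlength=n_shells + 1)[1:]
    return counts / n_ct


@dataclass
class CellMeasurements:
    """Every per-cell quantity the pipeline reports.

    Per-channel entries are ``None`` when that channel was empty in the cell
    (field-level missing markers rather than an aborted cell).  Pair keys are
    ordered ``(a, b)`` tuples for overlap and sorted tuples for the symmetric
    quantities.
    """

    cell_id: str
    nucleus_volume: float
    channels: list[str]
    ct_volume: dict = field(default_factory=dict)
    volume_fraction: dict = field(default_factory=dict)
    n_signals: dict = field(default_factory=dict)
    paired: dict = field(default_factory=dict)
    compacity: dict = field(default_factory=dict)
    shell_fractions: dict = field(default_factory=dict)
    intermixing: dict = field(default_factory=dict)
    intersection_volume: dict = field(default_factory=dict)  # sorted pair -> µm³
    overlap: dict = field(default_factory=dict)  # ordered pair (a, b) -> O(a|b)
    contact: dict = field(default_factory=dict)  # sorted pair -> bool
    min_distance: dict = field(default_factory=dict)  # sorted pair -> µm
    probe_distance: dict = field(default_factory=dict)  # sorted probe-role pair -> µm
    configuration: object | None = None  # ConfigurationState or None
    excluded: bool = False
    notes: list[str] = field(default_factory=list)

    def to_row(self, n_shells: int = 5) -> dict:
        """Flatten into one CSV row (column scheme used by ``cells.csv``)."""
        row: dict = {"cell_id": self.cell_id, "nucleus_volume": self.nucleus_volume}
        for ch in self.channels:
            row[f"vol_{ch}"] = self.ct_volume.get(ch)
            row[f"volfrac_{ch}"] = self.volume_fraction.get(ch)
            row[f"nsig_{ch}"] = self.n_signals.get(ch)
            row[f"paired_{ch}"] = self.paired.get(ch)
            row[f"compacity_{ch}"] = self.compacity.get(ch)
            row[f"intermix_{ch}"] = self.intermixing.get(ch)
            fr = self.shell_fractions.get(ch)
            for s in range(1, n_shells + 1):
                row[f"shell{s}_{ch}"] = None if fr is None else float(fr[s - 1])
        for (a, b), v in sorted(self.overlap.items()):
            row[f"ovf_{a}_given_{b}"] = v
        for (a, b), v in sorted(self.intersection_volume.items()):
            row[f"ivol_{a}_{b}"] = v
        for (a, b), v in sorted(self.contact.items()):
            row[f"contact_{a}_{b}"] = v
        for (a, b), v in sorted(self.min_distance.items()):
            row[f"dist_{a}_{b}"] = v
        for (a, b), v in sorted(self.probe_distance.items()):
            row[f"pdist_{a}_{b}"] = v
        if self.configuration is not None:
            row["cfg_state"] = self.configuration.state_id
            row["cfg_closed"] = self.configuration.closed
        else:
            row["cfg_state"] = None
            row["cfg_closed"] = None
        return row


def measure_cell(
    segmented,
    spacing=None,
    *,
    paint_channels: list[str] | None = None,
    probe_roles: dict[str, str] | None = None,
    n_shells: int = 5,
    contact_adjacency: bool = True,
) -> CellMeasurements:
    """Compute a full :class:`CellMeasurements` record from a segmented cell.

    Parameters
    ----------
    segmented : SegmentedCell
        Output of :func:`ctquant.segment.segment_cell`; per-channel masks are
        taken as the union of that channel's retained components.
    spacing : tuple, optional
        (z, y, x) µm; defaults to the nucleus mask's spacing.
    paint_channels : list of str, optional
        Channels treated as chromosome territories (pairwise overlap/contact,
        intermixing).  Defaults to all segmented channels not named as probes.
    probe_roles : dict, optional
        ``{"cen": name, "mid": name, "tel": name}`` — band-probe channels used
        for the fold-configuration call and probe distances.
    """
    from .configurations import classify_configuration  # local: avoids import cycle

    nucleus = segmented.nucleus
    spacing = tuple(spacing or nucleus.voxel_spacing)
    voxvol = float(np.prod(spacing))
    nuc = nucleus.voxels
    nucleus_volume = float(np.count_nonzero(nuc)) * voxvol
    if nucleus_volume == 0:
        raise ValueError("cannot measure a cell with an empty nucleus")

    probe_roles = dict(probe_roles or {})
    probe_names = set(probe_roles.values())
    all_channels = list(segmented.territories)
    if paint_channels is None:
        paint_channels = [c for c in all_channels if c not in probe_names]

    masks = {ch: segmented.territories[ch].labels > 0 for ch in all_channels}

    cm = CellMeasurements(
        cell_id=segmented.cell_id,
        nucleus_volume=nucleus_volume,
        channels=all_channels,
    )

    shell_labels = shell_partition(nuc, n_shells=n_shells, spacing=spacing)

    from .segment import pairing_state  # local: avoid import cycle

    for ch in all_channels:
        m = masks[ch]
        n_vox = int(np.count_nonzero(m))
        n_sig, paired = pairing_state(segmented.territories[ch])
        cm.n_signals[ch] = n_sig
        cm.paired[ch] = paired
        if n_vox == 0:
            cm.notes.append(f"channel {ch} empty")
            for d in (cm.ct_volume, cm.volume_fraction, cm.compacity, cm.shell_fractions, cm.intermixing):
                d[ch] = None
            continue
        cm.ct_volume[ch] = n_vox * voxvol
        cm.volume_fraction[ch] = volume_fraction(m, nuc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm.compacity[ch] = compacity(m, spacing)
        cm.shell_fractions[ch] = shell_distribution(m & nuc, shell_labels)

    # intermixing over paint channels only
    for ch in paint_channels:
        others = [masks[o] for o in paint_channels if o != ch]
        if masks[ch].any() and others:
            cm.intermixing[ch] = intermixing_fraction(masks[ch], others)
        else:
            cm.intermixing[ch] = None

    # pairwise quantities over paint channels
    dilated: dict[str, np.ndarray] = {}
    for a, b in combinations(paint_channels, 2):
        ma, mb = masks[a], masks[b]
        key = tuple(sorted((a, b)))
        if not ma.any() or not mb.any():
            cm.intersection_volume[key] = None
            cm.overlap[(a, b)] = None
            cm.overlap[(b, a)] = None
            cm.contact[key] = None
            cm.min_distance[key] = None
            continue
        inter = int(np.count_nonzero(ma & mb))
        cm.intersection_volume[key] = inter * voxvol
        cm.overlap[(a, b)] = inter / int(np.count_nonzero(mb))  # O(a|b)
        cm.overlap[(b, a)] = inter / int(np.count_nonzero(ma))  # O(b|a)
        if inter > 0:
            touching = True
        elif contact_adjacency:
            if a not in dilated:
                dilated[a] = ndi.binary_dilation(ma, structure=CONNECTIVITY_26)
            touching = bool(np.any(dilated[a] & mb))
        else:
            touching = False
        cm.contact[key] = touching
        cm.min_distance[key] = min_edge_distance(ma, mb, spacing)

    # band probes: distances and fold configuration
    if probe_roles:
        roles = ("cen", "mid", "tel")
        have = {r: masks.get(probe_roles.get(r, ""), None) for r in roles}
        for ra, rb in combinations(roles, 2):
            ma, mb = have[ra], have[rb]
            if ma is None or mb is None or not ma.any() or not mb.any():
                cm.probe_distance[(ra, rb)] = None
            else:
                cm.probe_distance[(ra, rb)] = min_edge_distance(ma, mb, spacing)
        try:
            cm.configuration = classify_configuration(
                have["cen"], have["mid"], have["tel"], adjacency=contact_adjacency
            )
        except (ValueError, AttributeError):
            cm.configuration = None
            cm.notes.append("configuration unclassifiable (empty probe)")

    return cm
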