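"""Synthetic interphase nuclei with known ground truth.

Each simulated cell is an ellipsoidal nucleus containing one labeled
bead-chain territory per chromosome paint channel.  Chains are anchored
biased random walks: every step adds a random unit displacement of fixed
length plus a pull of strength ``confinement`` toward the chain's anchor, and
positions are reflected at the nuclear boundary.  The confinement fraction is
the axial-compaction dial — high confinement collapses a chain into a
compact, spherical territory; low confinement lets it spread and intermix
with its neighbours, mimicking loss of large-scale chromosome folding.

Homolog pairing is modeled at the anchor level: with probability
``pairing_prob`` a channel's two chains share one anchor (a single FISH
signal); otherwise they fold around well-separated anchors.  A translocation
relocates a fraction of terminal beads of a donor channel into the acceptor's
territory while keeping the donor's label, reproducing the elevated pairwise
overlap signature of a stable translocation.  Optional band probes mark three
bead-index intervals (cen/mid/tel) of one channel's chains and are rendered
as extra channels.

Rendering convolves each true mask with an anisotropic Gaussian PSF, applies
Poisson shot noise, and adds Gaussian read noise and a constant background,
producing 16-bit stacks like a widefield microscope would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

from .configurations import ConfigurationState, classify_configuration
from .stackio import ImageStack

__all__ = [
    "ChannelSpec",
    "TranslocationSpec",
    "BandProbeSpec",
    "SimulationParams",
    "SimulationTruth",
    "generate_territory_chain",
    "simulate_cell",
    "render_microscopy",
    "simulate_population",
    "cell_rng",
    "params_from_dict",
]

DNA_CHANNEL = "dna"
PROBE_ROLES = ("cen", "mid", "tel")


@dataclass
class ChannelSpec:
    """One paint channel: a territory made of ``n_chains`` bead chains."""

    name: str
    n_chains: int = 2
    beads_per_chain: int = 80
    bead_radius: float = 0.45  # µm
    step_length: float = 0.8  # µm


@dataclass
class TranslocationSpec:
    """Relocate a fraction of the donor's terminal beads into the acceptor territory."""

    donor: str
    acceptor: str
    fraction: float = 0.3


@dataclass
class BandProbeSpec:
    """Three disjoint bead-index ranges (half-open) of one channel's chains."""

    channel: str
    cen: tuple[int, int] = (0, 15)
    mid: tuple[int, int] = (32, 44)
    tel: tuple[int, int] = (65, 80)

    def ranges(self) -> dict[str, tuple[int, int]]:
        return {"cen": tuple(self.cen), "mid": tuple(self.mid), "tel": tuple(self.tel)}


def _default_channels() -> list[ChannelSpec]:
    return [ChannelSpec("chrX"), ChannelSpec("chr2L"), ChannelSpec("chr2R")]


@dataclass
class SimulationParams:
    """Full description of one simulated-cell condition.

    Lengths in µm, intensities in camera counts.  ``confinement`` is the
    compaction dial in [0, 1]; ``pairing_prob`` the probability that a
    channel's homolog chains share one anchor.
    """

    nucleus_radii: tuple[float, float, float] = (2.5, 3.5, 3.5)  # (z, y, x) semi-axes
    voxel_spacing: tuple[float, float, float] = (0.25, 0.1, 0.1)
    grid_shape: tuple[int, int, int] = (64, 128, 128)
    channels: list[ChannelSpec] = field(default_factory=_default_channels)
    confinement: float = 0.3
    pairing_prob: float = 0.9
    translocation: TranslocationSpec | None = None
    band_probes: BandProbeSpec | None = None
    psf_sigma: tuple[float, float, float] = (0.1, 0.05, 0.05)  # deconvolved-widefield-like
    photon_scale: float = 200.0
    read_noise_sd: float = 3.0
    background: float = 20.0
    shot_noise: bool = True
    dna_texture: float = 0.15
    anchor_margin: float = 0.6  # anchors sampled inside this fraction of the ellipsoid
    anchor_min_separation: float = 2.5  # µm, between any two territory anchors
    unpaired_homolog_separation: float = 4.0  # µm, between unpaired homolog anchors
    seed: int = 0

    def validate(self) -> None:
        for name in ("nucleus_radii", "voxel_spacing", "psf_sigma"):
            vals = getattr(self, name)
            if len(vals) != 3:
                raise ValueError(f"{name} must have three components, got {vals}")
        if any(s <= 0 for s in self.voxel_spacing) or any(r <= 0 for r in self.nucleus_radii):
            raise ValueError("nucleus radii and voxel spacing must be positive")
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma components must be non-negative")
        for frac_name in ("confinement", "pairing_prob"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1], got {v}")
        if not self.channels:
            raise ValueError("at least one channel is required")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"channel names must be unique, got {names}")
        reserved = set(names) & ({DNA_CHANNEL} | set(PROBE_ROLES))
        if reserved:
            raise ValueError(f"channel names {sorted(reserved)} are reserved")
        max_spacing = max(self.voxel_spacing)
        for c in self.channels:
            if c.bead_radius < max_spacing:
                raise ValueError(
                    f"bead_radius {c.bead_radius} of channel {c.name!r} is below the "
                    f"largest voxel spacing {max_spacing}; beads would not render"
                )
            if c.n_chains < 1 or c.beads_per_chain < 1 or c.step_length <= 0:
                raise ValueError(f"invalid chain spec for channel {c.name!r}")
        if self.translocation is not None:
            t = self.translocation
            if t.donor not in names or t.acceptor not in names or t.donor == t.acceptor:
                raise ValueError(f"translocation channels {t.donor!r}→{t.acceptor!r} invalid")
            if not 0.0 <= t.fraction <= 1.0:
                raise ValueError("translocation fraction must be in [0, 1]")
        if self.band_probes is not None:
            b = self.band_probes
            if b.channel not in names:
                raise ValueError(f"band probe channel {b.channel!r} not among channels")
            spec = next(c for c in self.channels if c.name == b.channel)
            ranges = sorted(b.ranges().values())
            for lo, hi in ranges:
                if not 0 <= lo < hi <= spec.beads_per_chain:
                    raise ValueError(f"band probe range ({lo}, {hi}) out of chain bounds")
            for (_, hi), (lo, _) in zip(ranges, ranges[1:]):
                if lo < hi:
                    raise ValueError("band probe index ranges must be disjoint")
        half_extent = (np.array(self.grid_shape) - 1) * np.array(self.voxel_spacing) / 2.0
        if np.any(np.array(self.nucleus_radii) > half_extent):
            raise ValueError(
                f"nucleus radii {self.nucleus_radii} do not fit inside the grid "
                f"(half extents {tuple(half_extent)})"
            )

    @property
    def center(self) -> np.ndarray:
        """Physical coordinates of the nucleus center (grid center)."""
        return (np.array(self.grid_shape) - 1) * np.array(self.voxel_spacing) / 2.0

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cell."""

    nucleus_mask: np.ndarray
    masks: dict[str, np.ndarray]  # per paint channel, bool
    band_masks: dict[str, np.ndarray] | None  # cen/mid/tel, bool
    bead_coordinates: dict[str, list[np.ndarray]]  # per channel, per chain (n, 3) µm
    true_overlap: dict[tuple[str, str], float]  # ordered (a, b) -> |A∩B|/|B|
    true_pairing: dict[str, bool]  # single signal in the true mask (the observable)
    anchors_shared: dict[str, bool]  # whether the homolog chains shared an anchor
    true_configuration: ConfigurationState | None
    voxel_spacing: tuple[float, float, float]
    cell_id: str = ""


def _inside_ellipsoid(point, center, radii) -> bool:
    w = (np.asarray(point) - center) / radii
    return float(w @ w) <= 1.0


def _reflect_into_ellipsoid(point, center, radii) -> np.ndarray:
    """Reflect a position at the nuclear boundary (in normalized coordinates)."""
    w = (point - center) / radii
    r = float(np.linalg.norm(w))
    if r <= 1.0:
        return point
    r_new = max(2.0 - r, 0.0)
    r_new = min(r_new, 0.999)
    if r == 0:
        return center.copy()
    return center + w * (r_new / r) * radii


def _random_unit_vectors(rng, n) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return v / norms


def generate_territory_chain(
    anchor,
    n_beads: int,
    step_length: float,
    confinement: float,
    rng: np.random.Generator,
    *,
    nucleus_radii,
    nucleus_center,
) -> np.ndarray:
    """Generate one anchored biased random-walk chain inside the nucleus.

    Each step is ``previous + step_length·(random unit vector) +
    confinement·(anchor − previous)``, reflected at the ellipsoid boundary.
    Deterministic given the generator state.
    """
    anchor = np.asarray(anchor, dtype=float)
    center = np.asarray(nucleus_center, dtype=float)
    radii = np.asarray(nucleus_radii, dtype=float)
    if not _inside_ellipsoid(anchor, center, radii):
        raise ValueError(f"anchor {tuple(anchor)} lies outside the nucleus ellipsoid")
    beads = np.empty((n_beads, 3))
    beads[0] = anchor
    if n_beads > 1:
        steps = _random_unit_vectors(rng, n_beads - 1) * step_length
        pos = anchor.copy()
        for i in range(1, n_beads):
            pos = pos + steps[i - 1] + confinement * (anchor - pos)
            pos = _reflect_into_ellipsoid(pos, center, radii)
            beads[i] = pos
    return beads


def _sample_anchor(rng, center, radii, margin) -> np.ndarray:
    """Uniform sample inside the margin-scaled nucleus ellipsoid (rejection)."""
    scaled = np.asarray(radii) * margin
    while True:
        p = rng.uniform(-1.0, 1.0, size=3)
        if float(p @ p) <= 1.0:
            return center + p * scaled


def _voxelize_balls(points, radius, grid_shape, spacing) -> np.ndarray:
    """Union of digital balls: voxels whose centers lie within ``radius`` of a bead."""
    mask = np.zeros(grid_shape, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    shape = np.asarray(grid_shape)
    r_vox = radius / spacing
    for p in np.atleast_2d(points):
        idx = p / spacing
        lo = np.maximum(np.ceil(idx - r_vox).astype(int), 0)
        hi = np.minimum(np.floor(idx + r_vox).astype(int), shape - 1)
        if np.any(lo > hi):
            continue
        kk, jj, ii = np.ogrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        d2 = (
            ((kk - idx[0]) * spacing[0]) ** 2
            + ((jj - idx[1]) * spacing[1]) ** 2
            + ((ii - idx[2]) * spacing[2]) ** 2
        )
        mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= d2 <= radius**2
    return mask


def _single_signal(mask: np.ndarray, relative_min: float = 0.1) -> bool:
    """Pairing ground truth: does the true mask present one dominant signal?

    Same rule the measurement uses — components of at least ``relative_min``
    of the largest component's volume count as signals.  Shared anchors make a
    single signal by construction; independent anchors usually, but not
    always, make two (chains can wander into contact inside a small nucleus),
    and the truth records what the mask shows.
    """
    lab, n = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return True
    sizes = np.bincount(lab.ravel())[1:]
    return int(np.count_nonzero(sizes >= relative_min * sizes.max())) == 1


def _nucleus_mask(params: SimulationParams) -> np.ndarray:
    shape = params.grid_shape
    spacing = np.asarray(params.voxel_spacing)
    center = params.center
    radii = np.asarray(params.nucleus_radii)
    kk, jj, ii = np.ogrid[: shape[0], : shape[1], : shape[2]]
    w2 = (
        ((kk * spacing[0] - center[0]) / radii[0]) ** 2
        + ((jj * spacing[1] - center[1]) / radii[1]) ** 2
        + ((ii * spacing[2] - center[2]) / radii[2]) ** 2
    )
    return w2 <= 1.0


def cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    """Per-cell substream: ``default_rng(SeedSequence((seed, cell_index)))``.

    One global integer seed reproduces every cell of a population
    individually, independent of generation order.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(cell_index))))


def simulate_cell(params: SimulationParams, rng: np.random.Generator | None = None,
                  cell_id: str = "") -> SimulationTruth:
    """Simulate one nucleus and return its ground truth.

    Draw order is fixed (per channel: pairing, anchors, chains; then the
    translocation redraw), so outputs are pure functions of (params, rng state).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    center = params.center
    radii = np.asarray(params.nucleus_radii, dtype=float)
    spacing = tuple(params.voxel_spacing)

    nucleus = _nucleus_mask(params)

    def place_anchor(placed, homolog_anchors=()) -> np.ndarray:
        """Rejection-sample an anchor respecting the separation rules:
        ``anchor_min_separation`` from every placed anchor (territories are
        spatially partitioned) and ``unpaired_homolog_separation`` from the
        same channel's anchors (unpaired homologs present two distinct
        signals).  Falls back to the best candidate after 200 tries."""
        best, best_score = None, -np.inf
        for _try in range(200):
            cand = _sample_anchor(rng, center, radii, params.anchor_margin)
            if not placed:
                return cand
            sep = min(float(np.linalg.norm(cand - p)) for p in placed)
            hsep = (
                min(float(np.linalg.norm(cand - p)) for p in homolog_anchors)
                if len(homolog_anchors) else np.inf
            )
            if sep >= params.anchor_min_separation and hsep >= params.unpaired_homolog_separation:
                return cand
            score = min(sep - params.anchor_min_separation,
                        hsep - params.unpaired_homolog_separation)
            if score > best_score:
                best, best_score = cand, score
        return best

    chains: dict[str, list[np.ndarray]] = {}
    anchors: dict[str, list[np.ndarray]] = {}
    shared: dict[str, bool] = {}
    placed_anchors: list[np.ndarray] = []
    # place channels in random order: sequential placement under the
    # separation rule squeezes later channels into leftover space, which
    # would otherwise bias specific channel pairs toward higher overlap
    order = rng.permutation(len(params.channels))
    for idx in order:
        spec = params.channels[int(idx)]
        paired = bool(rng.random() < params.pairing_prob) if spec.n_chains > 1 else True
        shared[spec.name] = paired
        if paired:
            a = place_anchor(placed_anchors)
            placed_anchors.append(a)
            ch_anchors = [a] * spec.n_chains
        else:
            ch_anchors = []
            for _ in range(spec.n_chains):
                a = place_anchor(placed_anchors, homolog_anchors=ch_anchors)
                placed_anchors.append(a)
                ch_anchors.append(a)
        anchors[spec.name] = ch_anchors
        chains[spec.name] = [
            generate_territory_chain(
                a, spec.beads_per_chain, spec.step_length, params.confinement, rng,
                nucleus_radii=radii, nucleus_center=center,
            )
            for a in ch_anchors
        ]

    if params.translocation is not None:
        t = params.translocation
        donor_spec = next(c for c in params.channels if c.name == t.donor)
        n_reloc = int(round(t.fraction * donor_spec.beads_per_chain))
        if n_reloc > 0:
            acceptor_anchor = anchors[t.acceptor][0]
            for ci, chain in enumerate(chains[t.donor]):
                reloc = generate_territory_chain(
                    acceptor_anchor, n_reloc, donor_spec.step_length, params.confinement,
                    rng, nucleus_radii=radii, nucleus_center=center,
                )
                chain = chain.copy()
                chain[-n_reloc:] = reloc
                chains[t.donor][ci] = chain

    masks: dict[str, np.ndarray] = {}
    pairing: dict[str, bool] = {}
    for spec in params.channels:
        pts = np.vstack(chains[spec.name])
        masks[spec.name] = _voxelize_balls(pts, spec.bead_radius, params.grid_shape, spacing) & nucleus
        pairing[spec.name] = _single_signal(masks[spec.name])

    band_masks = None
    true_configuration = None
    if params.band_probes is not None:
        b = params.band_probes
        spec = next(c for c in params.channels if c.name == b.channel)
        band_masks = {}
        for role, (lo, hi) in b.ranges().items():
            pts = np.vstack([chain[lo:hi] for chain in chains[b.channel]])
            band_masks[role] = _voxelize_balls(pts, spec.bead_radius, params.grid_shape, spacing) & nucleus
        try:
            true_configuration = classify_configuration(
                band_masks["cen"], band_masks["mid"], band_masks["tel"]
            )
        except ValueError:
            true_configuration = None

    names = params.channel_names
    true_overlap = {}
    for a in names:
        for b_ in names:
            if a == b_:
                continue
            n_ref = int(np.count_nonzero(masks[b_]))
            inter = int(np.count_nonzero(masks[a] & masks[b_]))
            true_overlap[(a, b_)] = inter / n_ref if n_ref else float("nan")

    return SimulationTruth(
        nucleus_mask=nucleus,
        masks=masks,
        band_masks=band_masks,
        bead_coordinates=chains,
        true_overlap=true_overlap,
        true_pairing=pairing,
        anchors_shared=shared,
        true_configuration=true_configuration,
        voxel_spacing=spacing,
        cell_id=cell_id,
    )


def render_microscopy(truth: SimulationTruth, params: SimulationParams,
                      rng: np.random.Generator | None = None) -> ImageStack:
    """Render a truth object as a noisy multi-channel 16-bit stack.

    Per channel: intensity = photon_scale·mask (the DNA channel is the
    nucleus with a smooth nucleoplasm texture), convolved with the anisotropic
    Gaussian PSF, Poisson shot noise applied, then Gaussian read noise and a
    constant background added and the result clipped to 16 bits.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    spacing = np.asarray(truth.voxel_spacing)
    psf_sigma = np.asarray(params.psf_sigma, dtype=float)
    if np.any(psf_sigma < 0):
        raise ValueError("psf_sigma must be non-negative")
    if np.any((psf_sigma > 0) & (psf_sigma < spacing / 4.0)):
        warnings.warn(
            f"PSF sigma {tuple(psf_sigma)} is under a quarter of the voxel spacing "
            f"{tuple(spacing)}: the render is undersampled",
            stacklevel=2,
        )
    sigma_vox = psf_sigma / spacing

    names = [DNA_CHANNEL] + list(truth.masks)
    planes = [truth.nucleus_mask.astype(float)]
    if params.dna_texture > 0:
        texture = 1.0 + params.dna_texture * ndi.gaussian_filter(
            rng.standard_normal(truth.nucleus_mask.shape), sigma=3.0
        )
        planes[0] = planes[0] * np.clip(texture, 0.2, None)
    planes.extend(truth.masks[ch].astype(float) for ch in truth.masks)
    if truth.band_masks is not None:
        names += list(truth.band_masks)
        planes.extend(truth.band_masks[r].astype(float) for r in truth.band_masks)

    out = np.empty((len(planes),) + truth.nucleus_mask.shape, dtype=np.uint16)
    for i, plane in enumerate(planes):
        img = params.photon_scale * plane
        if np.any(sigma_vox > 0):
            img = ndi.gaussian_filter(img, sigma=sigma_vox)
        if params.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if params.read_noise_sd > 0:
            img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
        img = img + params.background
        out[i] = np.clip(np.round(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    return ImageStack(
        voxels=out,
        voxel_spacing=tuple(truth.voxel_spacing),
        channel_names=names,
        cell_id=truth.cell_id,
    )


def simulate_population(params: SimulationParams, n_cells: int, seed: int | None = None):
    """Yield ``(cell_id, truth, stack)`` for a reproducible population.

    Cell *i* uses the substream :func:`cell_rng`\\ ``(seed, i)`` for both the
    geometry and the render, so any cell can be regenerated in isolation.
    """
    if seed is None:
        seed = params.seed
    for i in range(n_cells):
        rng = cell_rng(seed, i)
        cell_id = f"cell{i:04d}"
        truth = simulate_cell(params, rng=rng, cell_id=cell_id)
        stack = render_microscopy(truth, params, rng=rng)
        yield cell_id, truth, stack


def params_from_dict(cfg: dict) -> SimulationParams:
    """Build :class:`SimulationParams` from a YAML-style dict (field-for-field)."""
    cfg = dict(cfg)
    if "channels" in cfg and cfg["channels"] is not None:
        cfg["channels"] = [
            c if isinstance(c, ChannelSpec) else ChannelSpec(**c) for c in cfg["channels"]
        ]
    if cfg.get("translocation") is not None and not isinstance(cfg["translocation"], TranslocationSpec):
        cfg["translocation"] = TranslocationSpec(**cfg["translocation"])
    if cfg.get("band_probes") is not None and not isinstance(cfg["band_probes"], BandProbeSpec):
        bp = dict(cfg["band_probes"])
        for key in ("cen", "mid", "tel"):
            if key in bp:
                bp[key] = tuple(bp[key])
        cfg["band_probes"] = BandProbeSpec(**bp)
    for key in ("nucleus_radii", "voxel_spacing", "grid_shape", "psf_sigma"):
        if key in cfg and cfg[key] is not None:
            cfg[key] = tuple(cfg[key])
    params = SimulationParams(**cfg)
    params.validate()
    return params


def params_to_dict(params: SimulationParams) -> dict:
    """Serialize :class:`SimulationParams` to a YAML-friendly dict."""
    d = asdict(params)
    for key in ("nucleus_radii", "voxel_spacing", "grid_shape", "psf_sigma"):
        d[key] = list(d[key])
    return d
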