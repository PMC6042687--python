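# Methods

## Scope and model

`ctquant` quantifies chromosome territories (CTs) in 3D fluorescence
microscopy stacks of interphase nuclei: a DNA counterstain channel plus one
channel per chromosome paint (and optionally three sub-arm band probes). The
pipeline has four stages — simulate, segment, measure, report — each usable in
isolation, all driven by one integer seed.

### Conventions

Axis order is `(channel, z, y, x)`; voxel indices are 0-based and refer to
voxel centers, so the physical position of index `(k, j, i)` is
`(k·sz, j·sy, i·sx)` µm. Volumes are voxel counts × `sz·sy·sx` (µm³),
distances are in µm, and 26-connectivity is used for every 3D adjacency
decision (component labeling, hysteresis growth, contact).

## Segmentation

* **Nucleus** — global Otsu threshold on the DNA channel, 3D hole filling,
  largest 26-connected component. Nuclei touching the stack border are
  flagged in the provenance record and excluded from measurement (standard
  practice for clipped cells); exclusions are listed in `manifest.json`,
  never silent.
* **Territories** — 3D hysteresis thresholding: voxels ≥ `high` seed the
  segmentation and are grown through voxels ≥ `low` under 26-connectivity,
  clipped to the nucleus; components below `min_volume` µm³ (default 0.05)
  are discarded and the survivors relabeled by descending volume. By default
  `high` is the Otsu threshold of the in-nucleus intensities of that channel
  (moved to the midpoint of the histogram gap when the histogram is gappy, so
  the seed rule never floods the background class) and `low = 0.5·high`; both
  are configurable per channel.
* **Foci** — negated Laplacian-of-Gaussian response at a user scale, 26-
  neighborhood local maxima above a threshold (default: 8× the scaled MAD of
  the in-nucleus response). Tied maxima on a blurred plateau are collapsed to
  one focus per connected plateau, so a pair of spots closer than the scale
  counts once.
* **Pairing** — a channel "presents a single signal" when exactly one
  component has volume ≥ 10% of the largest component (`relative_min`
  configurable); one signal is scored as paired homologs.

## Per-cell metrics

* **Volume fraction** `V_CT / V_nucleus` (voxel-count ratio).
* **Overlap fraction** `O(A|B) = |A∩B| / |B|` — asymmetric; both directions
  are always stored, and `O(A|B)·V_B = O(B|A)·V_A` holds exactly.
* **Intermixing** of a territory: `|T ∩ ∪(others)| / |T|`.
* **Contact**: overlap or 26-adjacency (one-voxel tolerance). Diffraction
  blur makes truly abutting domains overlap, so intersection-only contact
  would under-call by one voxel layer; intersection-only mode is available.
* **Minimal edge-to-edge distance**: 0 when the masks intersect, else the
  exact minimum anisotropic Euclidean distance between voxel centers
  (distance transform of one mask evaluated at the other's voxels).
* **Compacity** (sphericity) `Ψ = π^(1/3)·(6V)^(2/3)/S ∈ (0, 1]`. `S` is the
  area of a marching-cubes isosurface. Meshing the raw binary grid staircases
  curved boundaries (a digital ball would read Ψ ≈ 0.92), so the mask is
  pre-smoothed with an isotropic physical Gaussian of σ = half the finest
  voxel size — planar faces are essentially fixed points of that convolution
  while the staircase averages out. Objects too thin to survive a one-voxel
  erosion fall back to the raw mesh. With this estimator a radius-20 digital
  ball reads Ψ ≈ 0.96 and a 30³ cube ≈ 0.83 (analytic 0.806). At strong
  anisotropy the z staircase cannot be fully smoothed without distorting
  shape, so absolute values carry a few points of bias there; comparisons at
  fixed spacing (the intended use) are unaffected.
* **Radial shells**: nucleus voxels are ranked by distance to the nearest
  background voxel (anisotropic EDT; ties broken by flat voxel index) and
  split into five equal-count groups — equal volume by construction, shell 1
  peripheral, shell 5 central. A territory's shell profile is the fraction of
  its voxels per shell and sums to 1 exactly.
* **Fold configuration**: the cen/mid/tel band probes define a 3-bit contact
  state (cen–mid, mid–tel, cen–tel; cen–tel is the high bit, giving state ids
  0–7). A configuration is *closed* iff the cen and tel probes touch,
  regardless of the other two bits; four states are closed, four open. Probe
  contact reuses the territory contact rule; multi-component probes are used
  as their union. A cell with an empty probe mask is unclassifiable
  (missing), never silently open.

## Population statistics

Aggregation is median-of-cells (not pooled voxels): the overlap heatmap holds
per-entry medians of `O(row|col)`, the contact heatmap symmetric contact
frequencies with per-channel pairing frequencies on the diagonal. Missing
per-cell fields are excluded entry-wise with the contributing n reported.
Box summaries use linear-interpolation quartiles and 1.5·IQR whiskers; R² is
the ordinary least-squares coefficient of determination (constant y defined
as 0); group tests are the two-sided Mann-Whitney rank sum and Fisher's exact
test, with no multiple-testing correction. The translocation screen scores
each channel pair by the mean of its two directional median overlaps and
flags pairs exceeding 1.5× the median of all pair scores (≥3 pairs required).

## Synthetic nuclei

The simulator provides ground truth for every measurement. A cell is an
ellipsoidal nucleus (default semi-axes (2.5, 3.5, 3.5) µm — z is the short
axis — on a 64×128×128 grid at (0.25, 0.1, 0.1) µm spacing, i.e. anisotropic
like a widefield z-stack). Each paint channel is `n_chains` bead chains
(default 2 homologs × 80 beads of radius 0.45 µm). Chains are **anchored
biased random walks**: step = previous + `step_length`·(random unit vector) +
`confinement`·(anchor − previous), reflected at the nuclear boundary in
normalized ellipsoid coordinates. No physical polymer mechanics is claimed;
`confinement ∈ [0, 1]` is a qualitative compaction dial — the stationary
spread of a chain scales like `step_length/√(2c−c²)` — standing in for
condensin II activity (high = compact, spherical, spatially separated
territories; low = diffuse, intermixed ones).

Anchors are sampled uniformly in the 0.6-scaled nucleus with a minimum
separation of 2.5 µm between any two anchors (territories are spatially
partitioned) and 4 µm between unpaired homolog anchors. **Pairing** is
modeled at the anchor level: with probability `pairing_prob` (default 0.9)
the two homolog chains share one anchor. The recorded `true_pairing` is,
however, the *observable*: whether the true mask presents a single dominant
signal under the same ≥10%-of-largest rule the measurement uses. In a ~7 µm
nucleus independently anchored homolog territories occasionally touch, and no
segmenter could recover the anchor draw in those cells; the draw itself is
kept as `anchors_shared`. **Translocations** relocate a fraction of the
donor channel's terminal beads onto the acceptor's anchor while keeping the
donor's label, reproducing the elevated donor–acceptor overlap signature of a
stable rearrangement. **Band probes** are three disjoint bead-index
intervals of one channel's chains (defaults ~15/12/15 beads with ~17-bead
gaps, mimicking 3–4 Mb probes separated by ~4 Mb along a ~23 Mb arm),
rendered as three extra channels; the true fold configuration is computed
from the true probe masks with the same contact rule as the measurement.

**Rendering**: each true mask is scaled by `photon_scale` (the DNA channel is
the nucleus with a smooth ±15% nucleoplasm texture), convolved with an
anisotropic Gaussian PSF, subjected to Poisson shot noise, Gaussian read
noise (σ = 3 counts) and a constant background (20 counts), and clipped to 16
bits. The default PSF σ of (0.10, 0.05, 0.05) µm emulates *deconvolved*
widefield stacks — the data this kind of pipeline is normally run on — which
matters because hysteresis growth to `low = 0.5·high` places the measured
boundary near the 0.2·max intensity contour, i.e. dilates masks by roughly
0.84·σ per side. With the default PSF the segmented volumes stay within ±10%
of truth and measured overlap fractions within ±0.05; wider raw-widefield
PSFs (e.g. (0.35, 0.13, 0.13) µm) are available as parameters and produce the
correspondingly inflated masks.

Default chain geometry (80 beads, 0.8 µm steps, confinement 0.3, the anchor
separations above) was calibrated once so that a default population
reproduces the ranges reported for cultured *Drosophila* cells: arm territory
volume fractions around 15% of the nucleus, pairwise overlap medians of
~5–15% of the reference territory, >90% of channels presenting a single
signal. These defaults are the package's study conditions and are not
adjusted per analysis.

**Reproducibility**: cell *i* of a population uses the substream
`default_rng(SeedSequence((seed, i)))` for both geometry and rendering, so
any cell can be regenerated in isolation and a full pipeline re-run
reproduces `cells.csv` byte for byte.

### What the simulator does and does not emulate

It emulates: territory-scale geometry and its population variability,
homolog pairing as a single-signal observable, compaction-dependent
intermixing/shape/radial shifts, translocation overlap signatures, PSF blur
and camera noise on an anisotropic grid. It does not emulate: chromatin
polymer mechanics or loop extrusion, Hi-C-style contact frequencies,
sequential-hybridization registration error, optical aberrations beyond a
Gaussian PSF, cell-to-cell nuclear size variation, mitotic figures, or
autofluorescence. Passing recovery tests therefore demonstrates that the
measurement chain is faithful to known geometry under realistic blur and
noise — not that segmentation parameters transfer untouched to any real
dataset.

## Numerical choices and degenerate inputs

* Equal-volume shells are equal-count by sorted ranking (exact by
  construction); distance-quantile binning was rejected because plateaus make
  it inexact.
* Distances use voxel centers under anisotropic spacing; sub-voxel surface
  interpolation was rejected for testability (the brute-force oracle is then
  exact, not approximate).
* `low > high` thresholds, empty reference masks, empty nuclei, constant
  channels, and anchors outside the nucleus raise errors; an empty *channel*
  in one cell marks that cell's per-channel fields missing rather than
  aborting the cell; a <8-voxel mask yields a compacity with a warning.
* Components tied in volume keep their discovery order when relabeled.
* Population sizes used by the shipped validation runs (20–100 cells per
  condition, 25–50 per dial arm) are the package's demonstration scale; all
  statistics are per-cell medians, so they scale to larger populations
  unchanged.

## Known limitations

* Compacity is comparable across conditions at fixed voxel spacing but
  carries estimator bias at strong anisotropy or for objects a few voxels
  thick.
* The hysteresis boundary sits below half-max by construction; on wide-PSF
  (non-deconvolved) data, absolute volumes and overlaps are systematically
  inflated even though all comparisons between conditions remain valid.
* Under the anchored-walk folding model the three band probes sample the
  same stationary cloud around the chain anchor, so simulated arms are almost
  always fully closed (state 7); open configurations have to be produced with
  constructed geometries (as the tests do), not by the default simulator.
* The translocation screen is a population-level flag (median fold change);
  it does not call individual rearranged cells.
* Touching nuclei are not split; border-touching cells are excluded, not
  rescued.
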