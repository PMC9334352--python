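# Methods

## The relative-enrichment measure

Given two sets of molecular localizations in nm — a reference set `R` and a
primary set `P` — the reference is Voronoï-tessellated: each localization
`L_r` seeds the region of all points closer to it than to any other
reference localization. The primary localizations are assigned to regions by
nearest reference seed, which is exactly Voronoï-cell membership (exact ties
go to the lower seed index, a deterministic convention that matters only on
contrived integer geometries).

Each included region is scored

    expected_r = (measure_r / total_measure) · n_primary_retained
    RE_r       = observed_r / expected_r ,

where `total_measure` is the sum of included-region measures (or a
user-supplied ROI measure — see below) and `n_primary_retained` counts the
primaries surviving the edge discard. RE is dimensionless and directional:
swapping the two channels gives a different (and differently interpretable)
result.

### Edge handling

Edge treatment is the one place where a naive implementation goes badly
wrong, so it is worth being precise. Regions are subsets of the *analysed
field*, an axis-aligned box defaulting to the bounding box of the reference
seeds:

* Cells that are unbounded in the Qhull sense (at least one vertex at
  infinity; equivalently cells of seeds on the convex hull of the cloud)
  are discarded outright, together with every primary localization inside
  them.
* Bounded cells may still spill far outside the field: the Voronoï vertices
  of near-edge seeds are circumcentres of sliver triangles and can lie many
  field-widths away. Such cells are kept but **clipped** — their analysis
  `measure` is the measure of cell ∩ field (shapely polygon intersection in
  2D, halfspace intersection in 3D), with the raw hull measure retained as
  `measure_full`. Without clipping, the expected-count denominator counts
  space no primary can occupy; on a 5000-point uniform field we measured the
  summed "bounded" areas at ~40× the field area and a median per-region RE
  of ~27 instead of ~1.

With this rule the accounting is exact: expected and observed totals both
equal `n_primary_retained`, the measure-weighted mean RE over included
regions is identically 1, and for two independent uniform fields the
per-region RE has expectation 1 in every density bin (each included cell's
measure is precisely its capture area for a uniformly placed primary).

The clipping also preserves a subtle but real 3D signal: cells near the
cloud boundary can be *dense* in neighbour distance yet *large* in clipped
volume. A species hugging the boundary of the reference cloud (e.g. a
membrane-plane protein under docked vesicles) accumulates expected counts in
those cells and scores depleted in 3D even though its projected 2D picture
is indistinguishable from a lumenal species — the core reason a 3D analysis
resolves axial organisation that 2D cannot.

### Density binning

Mean neighbour distance (NND) — the arithmetic mean of distances from a
seed to its Voronoï-adjacent seeds (natural neighbours, a parameter-free
choice; adjacency to seeds of discarded regions still counts) — serves as a
one-dimensional density proxy, inversely related to region measure
(`nnd ~ measure^(1/d)`). Profiles bin included regions by NND (default:
40 uniform bins on [0, 99th percentile]) or by log10 measure, and report the
unweighted mean RE per bin plus each bin's share of regions. Empty bins are
absent (NaN), never zero. For multi-image studies the bin edges must be
fixed globally so bins are comparable; profiles are computed per image first
and then aggregated (mean, SEM over images) — error bars reflect
image-to-image variability, matching how replicate SMLM experiments are
reported.

A dense-region summary (mean RE over regions with NND at or below a
threshold, default 10 nm) condenses a profile's high-density end into one
number per image for condition comparisons.

### Statistics

Condition differences are tested per bin (or per dense-region summary) with
unpaired two-sample t-tests by image; one-sided tests require an explicit
direction and are never inferred from the data. Familywise error across the
tested bins is controlled with Holm's step-down adjustment
(statsmodels implementation; closed-form families and a Monte-Carlo FWER
calibration are pinned in the test suite). Bins with fewer than two images
per condition are skipped with a warning and excluded from the family.

Tessellation-based Spearman and Mander's-style coefficients are provided
for benchmarking against coefficient-based tools only: Spearman rank
correlation of each localization's own first-rank Voronoï density (1/cell
measure) against the density of the other species' cell containing it, and
the fraction of localizations lying in other-species cells above a density
threshold (default: the other channel's mean cell density — a heuristic,
flagged as such). They are approximations of definitions external to this
package and are not part of the RE measure.

### ROI support

A polygonal ROI (2D) or box (3D) filters both channels (boundary-inclusive)
and can override `total_measure` in the expected-count formula — useful when
the biologically meaningful area (e.g. a segmented neuron) is known and the
tessellated field under-covers it. With an ROI override the conservation
identity intentionally no longer holds: RE values are then relative to the
stated area, not to the tessellation.

## Simulation module

The generators state the validation worlds explicitly; all randomness flows
through a seeded generator and equal configs give bit-identical scenes.
Ground truth (cluster centres, vesicle centres, docked flags, unjittered
positions) is always emitted for test oracles.

* **Cluster scenes** (5×5 µm default field, 5000 points per species):
  a `background_fraction` (default 0.5) of points uniform, the rest split
  evenly over 10 Gaussian clusters of sd 50 nm (fixed counts for
  reproducibility; Poisson counts optional). Offset clusters displace the
  primary's centres by a fixed vector; anti-colocalized clusters
  rejection-sample primary centres at least 4 cluster-sd from every
  reference centre (the exclusion distance is a package convention). These
  parameter values are fixtures chosen once for realism — cluster scales of
  tens of nm and a substantial non-clustered background are typical of
  membrane-protein dSTORM — not reproductions of any published scene.
* **Vesicle scene** (1×1 µm field): 20 spherical vesicles of radius 20 nm
  (synaptic-vesicle scale), half docked with their surface touching the
  membrane plane, the rest floating strictly above it. 60 membrane points
  uniform on each sphere (normalized Gaussian deviates — uniform surface
  measure), 40 cargo points uniform in each lumen, and, under each docked
  vesicle only, an active-zone cluster of 50 points Gaussian in-plane with
  sd 10 nm. The AZ sd makes the patch laterally coincident with the
  vesicle's projected footprint (a uniform ball of radius r projects with
  marginal sd r/√5 ≈ 9 nm), so the AZ and cargo species differ *only
  axially* — the cleanest probe of what a 3D analysis adds over 2D.
  Localization uncertainty is Gaussian jitter of sd 5 nm laterally and
  10 nm axially (doubled in z, reflecting the poorer axial precision of
  astigmatic 3D SMLM; 5 nm is an optimistic but attainable dSTORM lateral
  precision, and keeping jitter below the vesicle radius preserves the
  geometry the scene is meant to exhibit).

What the generators do *not* emulate: camera frames, PSF shape,
photophysics and multi-blinking (duplicate localizations are an error by
default, with an explicit dedupe option), drift, or localization-precision
heterogeneity. A green test on these scenes therefore establishes the
correctness and calibration of the *analysis*, not robustness to raw-data
artefacts, which must be corrected upstream.

## Numerical choices

* Voronoï geometry, Delaunay adjacency and convex-hull measures come from
  scipy.spatial (Qhull); cell measures use the convex hull of the cell's
  vertices, exact because cells are convex.
* Duplicate seeds raise by default (`dedupe=True` merges them); fewer than
  d + 2 seeds or collinear/coplanar geometry raise a degeneracy error.
* Vertices exactly on the field boundary count as inside (closed-region
  convention, tolerance 1e-9 of the field size); boundary points are inside
  ROIs for the same reason.
* A 3D clipped cell whose halfspace intersection fails numerically (seed on
  the field boundary) is excluded from the analysis rather than guessed.
* The RE colour scale is symmetric in log (0.5 and 2 equidistant from the
  centre at RE = 1), limits at the 2nd–98th percentile of log RE; a
  diverging map centred elsewhere would visually overstate one side.

## Statistical validity limits

Per-bin mean RE is a ratio estimator: in bins whose regions expect far
fewer than one primary each, the bin mean is almost surely exactly 0 (with
rare large excursions), so Gaussian error bars and z-type checks are
undefined rather than violated there. The acceptance suite requires a
pooled expected count of ~1 per replicate in a bin before applying its
3-SE calibration check; users should read profile tails with the region
histogram in view. The measure-weighted grand mean is exact regardless.

## Known limitations

* The analysed field is an axis-aligned box; arbitrary 3D meshes are not
  supported (3D ROIs are boxes).
* RE ignores where inside a region a primary falls; sub-region distance
  weighting is out of scope by design.
* No periodic boundary conditions, power diagrams, or density-threshold
  cluster segmentation — the region table export exists so users can
  segment downstream as their biology warrants.
* Absolute RE values in 3D need care when a species is confined to
  structures (organelle membranes): enrichment is measured against a
  uniform-volume null, which may not be the biologically relevant
  reference.
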