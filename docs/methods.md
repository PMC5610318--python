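# Methods

This note documents the models and numerical choices behind
`paintcluster`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Synthetic acquisition model (`simulate`)

**Receptor field.** Receptors of each species follow a Thomas-type cluster
process. Cluster centres ("parents") are a homogeneous Poisson process
with intensity `parent_intensity` (default 7 µm⁻²). Each parent hosts each
species independently with a base probability q, derived so that the
expected clustered receptor count per channel equals
(1 − `background_fraction`) × `receptors_per_channel`:

    q = (1 − background_fraction) · receptors_per_channel
        / (E[parents] · mean_per_cluster)

Hosted species contribute Poisson(`mean_per_cluster`) receptors scattered
isotropically with `cluster_sigma` = 25 nm, so ~95 % of a cluster falls
within a 100 nm diameter — the characteristic receptor-cluster scale on
these membranes. A `background_fraction` (default 0.05) of each species is
uniform over the field.

**Pairwise co-clustering.** For a coupled pair (a, b) with coupling c, each
parent's hosting decisions for a and b are, with probability c, a single
shared Bernoulli(q) draw (the species co-occupy or co-avoid the cluster)
and otherwise independent. This raises the joint hosting probability from
q² to c·q + (1 − c)·q² while leaving both marginals — and hence each
channel's expected totals — unchanged. The design is deliberate: a
condition difference in coupling changes only the co-occupancy structure,
mirroring ligand-induced receptor association without a change in
single-receptor density, and keeping the generator's totals contract
intact. c = 0 reduces exactly to independence. With multiple couplings
sharing a channel, pairs are processed in canonical channel order; the
slight order dependence is irrelevant for the single-pair experiments used
here.

**Imaging.** Each receptor is labelled by an antibody–DNA conjugate with
probability `p_label`. A conjugate carries `strands_per_conjugate` = 6
docking strands; each strand yields Poisson(`per_strand_rate` = 7.2)
localizations per imaging round, sampled as one Poisson(7.2 × 6) draw per
antibody (Poisson superposition — distributionally identical to per-strand
draws). Every localization is displaced by (i) a *fixed per-antibody*
linkage offset, uniform in a disk of radius `linkage_radius` = 20 nm (the
worst-case antibody + streptavidin + oligonucleotide geometry; only the
worst case is known, so uniform-in-disk is a choice), and (ii) isotropic
Gaussian fit noise `sigma_loc` = 3.9 nm. Frames are uniform within the
channel's imaging round; rounds are sequential per channel with a single
global frame index, so one drift trace (linear by default) spans all
rounds. Fiducials emit one localization per frame in every round under the
reserved channel label `fiducial`.

**Default scale.** The defaults (20 × 20 µm field, 2950 receptors per
channel, q ≈ 0.5, `mean_per_cluster` = 2, `p_label` = 0.6) produce
~3.8 × 10⁵ localizations and ~2300 retained clusters per cell, with
~150 localizations per cluster — a desk-scale cell with per-cluster and
per-cell statistics in the regime the analysis is designed for (10⁵–10⁶
localizations and thousands to tens of thousands of clusters per real
cell).

**Not emulated:** binding-event photophysics (a strand's localizations are
not correlated in time), camera noise and PSF rendering, 3-D structure,
cell-shaped masks (the synthetic "cell" fills the field of view), and
repeated imaging of one target across rounds. Passing tests therefore
demonstrate correctness of the estimators under the stated statistical
model, not robustness to every artefact of real acquisitions.

## Drift correction and registration (`correct`)

Fiducial tracks are greedily linked frame-to-frame by nearest neighbour
within `radius` (default 100 nm, the marker size); tracks present in
< `min_presence_fraction` (default 0.8) of frames are discarded, which
excludes transiently binding imagers. Each track's displacement is taken
relative to its first observation; per-frame displacements are averaged
over tracks, gaps linearly interpolated, and smoothed with a centred
moving average (`smoothing_window` = 100 frames; 1 disables smoothing —
use that when the trace must be exact at the movie ends, since a moving
average biases a ramp's endpoints). Correction subtracts the trace and is
exactly inverted by the negated trace.

Channel registration works at localization level: a marker's position is
the mean of its localizations (the estimand of fitting a Gaussian to the
rendered marker, without re-rendering), markers are matched to the
reference channel by nearest neighbour (within 250 nm), and the applied
correction is the mean displacement (the least-squares translation).
Translation only — no rotation or scale.

DNFL pairs each localization with its nearest neighbour in the next frame
within `pairing_radius`; for a static emitter with per-axis error σ the
pair distance is Rayleigh with scale σ√2, so σ̂ = mean(d)/√π. The
estimator is consistent to < 2 % bias at 10⁴ pairs. FWHM = 2√(2 ln 2)·σ;
σ = 3.9 nm gives 9.18 nm.

## Ripley statistics (`spatialstats`)

Minus-sampling edge handling: at scale r only points at distance ≥ r from
the ROI boundary act as circle centres, so no circle leaks outside. The
estimator

    K̂(r) = A / (n(r) · N) · Σ_{i: edge ≥ r} Σ_{j ≠ i} 1(d_ij < r)

normalizes by both the interior count n(r) and the total ROI count N; this
is the normalization under which E[L(r) − r] = 0 for CSR (verified by
simulation to < 0.2 nm over 20 × 10⁴-point replicates), which is the
defining property of the statistic. Self-pairs are excluded. Entries with
n(r) = 0 are NaN, not errors, and are skipped when averaging curves.
Implementation: one neighbour-pair enumeration at r_max, then interval
bookkeeping over the r grid; exact point-to-boundary distances via the
polygon geometry.

## Mean-shift clustering (`cluster`)

The window is a square of half-width = bandwidth (Chebyshev
neighbourhood, boundary inclusive), as the box-window formulation
specifies — not a Euclidean disk. Each localization's trajectory moves to
the mean of the *original* points in the window until the shift is below
`conv_tol` (0.01 nm) or `max_iter` (500) is reached; exhaustion flags the
point `converged=False` rather than raising (flat-window mean shift can
enter 2-cycles). Trajectories whose final positions lie within `merge_tol`
(1 nm, single linkage) form one cluster. 1 nm is far below the 48 nm
bandwidth and far above floating-point jitter; "converged to the same
point" is not otherwise quantified. Assignments are independent of input
order (components are set-determined; labels are canonicalized by first
member).

The 48 nm bandwidth is derived, not fitted: 2 × (10 nm antibody arm + 3 nm
biotin-site offset + 3 nm ssDNA + 4 nm dye-fit uncertainty) + 8 nm
receptor separation. Clusters whose spatial extent approaches the window
size can fragment into multiple modes; the parent-count recovery guarantee
applies when cluster scatter is well below the bandwidth.

Scale: neighbour queries use a uniform-grid index keyed by the bandwidth
(cell side = bandwidth, ≤ 3 × 3 cells per window) with a compiled kernel,
and trajectories that have reached bitwise-identical positions are
deduplicated — both exact optimizations; equality of assignments with a
naive index-free implementation is property-tested on ≥ 100 small
instances. 4 × 10⁵ localizations cluster in a few seconds.

Cluster records carry per-channel counts, convex-hull area (zero for < 3
or collinear points; such hulls are discarded as degenerate rather than
given infinite density), densities = count/area, and the minimum distance
from any *member* localization (a conservative choice; centroids were the
alternative) to the cell-mask boundary and to the field-of-view rectangle.
The mask is supplied when clusters are built, because that is where member
coordinates live; without one, the field-of-view rectangle alone is used
and a warning logged. Filtering discards (with reasons kept): total count
< 12, degenerate hull, boundary distance < 100 nm. The 12-count cutoff is
justified by `min_count_poisson`: with λ = 7.2 × 6 = 43.2 localizations
per antibody per round, P(X = 12) ≈ 1.5 × 10⁻⁸ and P(X ≤ 12) ≈ 2 × 10⁻⁸
(computed in log space), so a sub-12 cluster is essentially never a real
antibody.

## Feature construction and forests (`discriminate`)

Features per retained cluster: the 5 per-channel densities, then the 15
unique pairwise products d(Ri)·d(Rj) for i ≤ j in canonical order —
squares included, since homodimer density is as meaningful as heterodimer
density. Labels: 0 unstimulated, 1 stimulated.

The importance procedure repeats, for each of `n_forests` = 100 rounds:
(1) a class-balanced subsample — ⌊0.66·n₀⌋ unstimulated rows and exactly
as many stimulated rows, both without replacement (an imbalance too large
to satisfy is an error, never silently sampled with replacement); (2) a
bagged ensemble of 50 decision trees (Gini, `min_samples_leaf` = 300,
√20 ≈ 4 features per split — the base tool's unstated default, made
configurable) with per-tree bootstrap and out-of-bag row sets; (3) per
tree and feature, the OOB correct-classification rate minus the rate after
permuting that feature's OOB values, averaged over trees. "Delta error" is
oriented so that informative features are positive (the underlying
quantity is a correct-classification percentage). Permutation is per tree,
the literal reading of the per-tree OOB procedure. Ensemble OOB accuracy
is the majority-vote accuracy over trees not trained on each row.

Bagging, OOB bookkeeping and permutation importance are implemented here
(over scikit-learn's `DecisionTreeClassifier`) rather than taken from
`RandomForestClassifier`, because the procedure needs per-tree OOB sets
and per-tree permutation, which the library ensemble does not expose.
Per-forest seeds derive from the master seed by spawn keys
(`forest_seed(master, i)`), so any single forest is re-runnable in
isolation and a 2-forest ensemble equals two manual runs (tested).

Note `min_samples_leaf` = 300 means the forest needs thousands of rows
before trees can split at all; with fewer rows the procedure degrades to
chance-level output rather than failing. A feature whose informative rows
number fewer than ~300 in a subsample cannot be used by any split — at
the default scale the planted-coupling experiments provide ~450 such rows
per subsample.

## Validation experiments

- **CSR null:** mean L(r) − r over 20 seeded CSR replicates (10⁴ points,
  5 × 5 µm) stays within 3 nm of zero at every r ≤ 500 nm (observed
  < 0.2 nm).
- **Oracle equivalence:** mean-shift partitions, hull areas and Ripley
  double sums match naive references on 100 random ≤ 50-point instances.
- **Parameter recovery:** in 20 independent two-condition experiments
  (one cell per condition, 16 × 16 µm at default densities, ≥ 2000
  retained clusters per condition) differing only in EGFR–Met coupling
  (0.8 vs 0), d(EGFR)·d(Met) attains importance rank 1 in ≥ 18 of 20.
- **Chance-level control:** permuting labels yields OOB accuracy ≈ 0.5 and
  importances ≈ 0.

Quantities that require the original cell data — the real-data
classification accuracy, Fourier-ring-correlation resolution, re-imaging
cross-correlation, and the measured cluster-size/density shifts — are out
of desk-scale reach; the synthetic suites above are the substitute and say
nothing about those numbers.

## Known limitations

- Localization-file schemas vary by upstream software; the CSV dialect
  here (frame, x_nm, y_nm, channel) is a repository convention with a
  configurable column mapping and pixel-to-nm scale.
- The fiducial linking is greedy nearest-neighbour; markers closer than
  the linking radius to each other can swap identities (real gold-bead
  fields are sparse enough that this does not arise).
- Boundary handling tests member localizations, not hull polygons; a
  cluster whose hull crosses the boundary between members is not caught.
- The simulator's "cell" is the full field of view; cell-mask handling is
  exercised through explicit polygon masks in tests, not by the generator.
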