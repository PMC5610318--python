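# paintcluster

Cluster analysis of multiplexed Exchange-PAINT single-molecule localization
data.

In Exchange-PAINT, dye-labelled imager oligonucleotides transiently bind
docking strands on antibody-labelled targets; sequential imager exchange
multiplexes many targets with one fluorophore. Imaging five receptor
tyrosine kinases (EGFR, ErbB2, ErbB3, IGF1R, Met) this way yields, per
cell, 10⁵–10⁶ localizations whose spatial organization encodes how the
receptors co-cluster in the plasma membrane — and how that organization
changes after ligand stimulation. `paintcluster` provides the full
quantitative path from localization tables to a ranked list of the
receptor-density features that distinguish stimulated from unstimulated
cells, plus a seeded synthetic-acquisition simulator with known ground
truth for validating every stage.

## What it computes

- **Drift correction & registration** — fiducial (gold-nanoparticle)
  tracks are linked frame-to-frame, averaged into one drift trace
  subtracted from all localizations; channels are registered to a
  reference channel by the least-squares x–y translation over matched
  markers. Precision QC via the distance between neighbouring-frame
  localizations (DNFL; mean distance = σ√π for a static emitter) and
  FWHM = 2√(2 ln 2)·σ.
- **Spatial statistics** — minus-sampling Ripley estimate
  K̂(r) = A/(n(r)·N) Σ_{i interior} Σ_{j≠i} 1(d_ij < r), with
  L(r) = √(K̂/π); L(r) − r has expectation 0 under complete spatial
  randomness and is positive at scales where points cluster.
- **Mean-shift clustering** — flat square-window mean shift on the merged
  five-channel localizations. The bandwidth is not tuned: it is the
  worst-case separation of two localizations from one receptor dimer,
  2·(antibody arm 10 + biotin site 3 + ssDNA 3 + dye fit 4) + receptor
  separation 8 = **48 nm**. Clusters are summarized by convex-hull area,
  per-channel composition, and densities (count/area).
- **Cluster filtering** — one bound antibody carries 6 docking strands at
  7.2 localizations per strand per round, so its yield is Poisson with
  λ = 43.2; P(≤ 12 localizations) ≈ 2×10⁻⁸, hence clusters with < 12
  localizations are discarded as noise, along with degenerate-hull
  clusters and clusters within 100 nm of the cell or image boundary.
- **Random-forest importance** — 20 features per retained cluster (5
  densities d(R) + 15 pairwise products d(Ri)·d(Rj), i ≤ j), rows
  labelled 0/1 for condition. 100 forests (50 trees, min leaf 300) on
  class-balanced 66 % subsamples; per-feature importance is the mean
  out-of-bag delta error (per-tree OOB correct rate minus the rate after
  permuting that feature), reported mean ± SD with ranks.

## Worked example

A synthetic two-condition experiment in which the only difference between
conditions is EGFR–Met co-clustering (shared-cluster probability 0.8 vs 0):

```python
import paintcluster as pc

base = dict(fov_width=16000.0, fov_height=16000.0, receptors_per_channel=1888.0)
cfg_unstim = pc.SceneConfig(**base)
cfg_stim = pc.SceneConfig(coupling={("EGFR", "Met"): 0.8}, **base)
cells = pc.simulate_experiment(cfg_unstim, cfg_stim, 1, seed=0)

bandwidth = pc.derive_bandwidth()          # 48.0 nm
tables = []
for i, (table, label, truth) in enumerate(cells):
    merged = table.without_fiducials()
    result = pc.mean_shift(merged.xy, bandwidth)
    clusters = pc.filter_clusters(
        pc.build_cluster_table(merged, result, cell_id=f"cell{i}", condition=label))
    tables.append(clusters)

matrix = pc.build_features(tables)
report = pc.importance_ensemble(matrix, pc.ForestConfig(n_forests=25, seed=0))
print(report.to_frame().head(3))
```

Output:

```
bandwidth: 48.0 nm
cell 0 (label 0): 251478 localizations, 2495 clusters, 2212 retained
cell 1 (label 1): 259278 localizations, 2470 clusters, 2205 retained
OOB accuracy: 0.543 +/- 0.010
     feature  mean_delta_error  sd_delta_error  rank
d_EGFR*d_Met          0.012981        0.002995     1
      d_EGFR          0.005768        0.002038     2
       d_Met          0.005756        0.001817     3
```

The planted pairwise product d(EGFR)·d(Met) ranks first: the forest
recovers the co-clustering difference even though neither channel's
marginal density differs between conditions (accuracy is modest by design
— only the pair structure carries signal).

The same pipeline runs from the shell:

```sh
paintcluster simulate --config config.yaml --seed 1 --out run/
paintcluster cluster  --input run/localizations.csv --out run/
paintcluster pipeline --config config.yaml --seed 1 --out run/
```

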