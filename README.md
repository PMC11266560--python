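# leaflet-smlm

Quantitative analysis of single-molecule localization microscopy (SMLM) and
single-particle tracking of membrane-leaflet lipid probes: Voronoi-based
domain segmentation, the degree-of-colocalization (DoC) statistic with its
randomized null, MSD / effective-diffusion analysis, and detection of
transient confinement (TALL — Temporary Arrest of LateraL diffusion) events
— all driven by a synthetic-data generator so every stage can be verified
against ground truth without raw imaging data.

## Why

Lipid nanodomains in the plasma membrane are below the diffraction limit;
SMLM resolves them as clustered localization point patterns, and fast
single-molecule tracking resolves how probes move through them. The
questions this package answers are statistical ones:

* **Are the localizations clustered, and how large are the domains?**
  Per-localization density is estimated from Voronoi cell areas; a
  Monte-Carlo threshold against complete spatial randomness (CSR) segments
  domains, and domain size is the median circle-equivalent diameter.
* **Do two probes occupy the same domains?** The DoC statistic correlates
  the radial density gradients of the two channels around every
  localization (Spearman over radius bins, weighted by the nearest-neighbor
  distance): −1 segregated, 0 independent, +1 colocalized. A random-shift
  control calibrates what "no colocalization" looks like on the same data.
* **How do probes diffuse, and do they pause?** Overlapping-window MSD
  curves, window-fit effective diffusion coefficients, classification
  against a simulated Brownian envelope, and TALL event detection with
  mobile / TALL / immobile time fractions.

Every analysis has a matching generator (`leaflet_smlm.simulate`) producing
clustered scenes, coupled two-channel scenes, and Brownian / confined /
hop / immobile trajectories with known ground truth.

## Worked example

```python
import leaflet_smlm as ls

roi = ls.ROI.default()  # 9360 x 9360 nm analysis crop (120 px at 78 nm)

# two coupled channels: every channel-B domain shares a center with channel A
cfg = ls.SceneConfig(n_clusters=20, cluster_radius_sd=45.0, locs_per_cluster=100,
                     background_locs=2000, localization_precision_sd=22.0, seed=0)
a, b, truth = ls.gen_paired_channels(cfg, cfg, coloc_fraction=1.0, roi=roi, seed=0)

# degree of colocalization vs. its random-shift control
result = ls.doc_scores(a, b)
control = ls.doc_control(a, b, seed=1, roi=roi)
print("DoC index (coupled):", round(ls.coloc_index(result)["pooled"]["index"], 3))
print("DoC index (control):", round(ls.coloc_index(control)["pooled"]["index"], 3))

# Voronoi domain segmentation of channel A
thr = ls.csr_threshold(a, roi, n_simulations=50, seed=2)
seg = ls.segment_clusters(ls.voronoi_densities(a, roi), thr)
summary = ls.cluster_summary(seg)
print("domains:", summary["n_clusters"],
      "median diameter:", round(summary["median_diameter_nm"], 1), "nm")

# diffusion of a simulated Brownian probe at 4 ms/frame
params = ls.TrajectoryModelParams(model="brownian", D=1.0, frame_interval=0.004,
                                  n_frames=50, localization_precision_sd=22.2, seed=3)
tracks = ls.gen_trajectories(params, 500)
est = ls.fit_deff(ls.ensemble_msd(tracks), "24ms@4ms")
print("D_eff:", round(est.d_eff, 3), "um^2/s  intercept:", round(est.intercept, 5), "um^2")

from leaflet_smlm.tall import analyze_set
s = ls.tall_summary(analyze_set(tracks))
print("TALL fraction (Brownian control):", round(s.fraction_tall, 4))
```

Output:

```
DoC index (coupled): 0.958
DoC index (control): 0.532
domains: 20 median diameter: 228.9 nm
D_eff: 0.981 um^2/s  intercept: 0.00338 um^2
TALL fraction (Brownian control): 0.0
```

The coupled channels score far above their shifted control; all 20 planted
domains are recovered; the fitted D is within 2 % of the generator's
1 μm²/s with the localization-error offset showing up in the intercept
(≈ 4σ², never silently subtracted); and free Brownian motion produces no
spurious confinement events.

## Command line

```sh
leaflet-smlm simulate --out-dir scene --seed 0
leaflet-smlm cluster  --localizations scene/channel_a.csv --out clusters.csv
leaflet-smlm doc      --channel-a scene/channel_a.csv --channel-b scene/channel_b.csv \
                      --control-seed 1 --out-prefix doc
leaflet-smlm track    --trajectories scene/trajectories.csv --out-prefix track
leaflet-smlm tall     --trajectories scene/trajectories.csv --out tall_events.csv
leaflet-smlm run      --config configs/default.yaml --out-dir results/pipeline
```

`run` executes the full chain (simulate → cluster → DoC → track → TALL)
from one YAML config with a single global seed; every output is listed in a
`manifest.json` with the config hash, derived per-stage seeds and per-file
checksums, and re-running the same config reproduces every file
bit-for-bit.

## Repository layout

```
src/leaflet_smlm/   the package (all computation lives here)
  simulate.py       synthetic scenes, coupled channels, trajectory models
  io.py             ThunderSTORM-style CSV I/O, duplicate removal, subsampling
  cluster.py        Voronoi densities, Monte-Carlo CSR threshold, segmentation
  doc.py            radial density gradients, DoC scores, index, control
  tracking.py       MSD, effective diffusion, Brownian-envelope classification
  tall.py           TALL event detection and time fractions
  pipeline.py       config-driven end-to-end runs with a provenance manifest
analysis/           numbered driver scripts writing tables to results/
configs/            shipped default pipeline configuration
docs/methods.md     model, conventions, numerical choices, limitations
scripts/acceptance.py   recomputes the acceptance statistics from scratch
tests/              pytest suite incl. tests/test_acceptance.py
```

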