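# Methods

This note documents the statistical model behind every analysis in
`leaflet_smlm`, the parameter conventions, the scope of the synthetic-data
generators, the numerical choices that are this package's own (where the
published method descriptions are silent), and the known limitations. All
coordinates are in nanometres, all times in seconds, diffusion coefficients
in μm²/s.

## 1. Synthetic data (`leaflet_smlm.simulate`)

### Point patterns

* **CSR** (`gen_csr`): *n* i.i.d. uniform points in an axis-aligned ROI, the
  homogeneous-Poisson null for cluster thresholding and colocalization
  controls. Frame numbers are drawn uniformly over a configurable range
  (default 1–2000, mirroring 4 ms/frame over 2000 frames).
* **Clustered scenes** (`gen_clustered_scene`): cluster centers uniform in
  the ROI; members isotropic Gaussian (`cluster_radius_sd`) around their
  center, generated by rejection so all true positions lie inside the ROI
  (a warning is raised if under 1 % of draws land inside); plus a CSR
  background. Multi-blink overcounting re-emits every true position
  `1 + Poisson(mean_blink_repeats − 1)` times; each emission gets fresh
  Gaussian localization error (`localization_precision_sd`). Localizations
  pushed out of the ROI by that error are cropped, exactly as an image crop
  would do; the cropped count is reported in the ground-truth dict
  (`n_rejected`). Preset precisions: 26.3 nm (mEos4b-class probe), 22.0 nm
  (SF650B-class), 22.2 nm (tdStayGold-class).
* **Coupled channels** (`gen_paired_channels`): a fraction `coloc_fraction`
  of channel-B cluster centers coincides with randomly chosen channel-A
  centers; members, blinking and error are drawn independently per channel.
* **Random shift** (`random_shift`): every localization is translated by an
  angle ~ U(0, 2π) and a distance ~ U(0, `max_shift`, default 1000 nm), then
  wrapped toroidally into the ROI. Wrapping (rather than discarding) keeps
  the localization count and mean density identical to the input — a
  declared choice; the published control only says "random directions by
  random distances".

### Trajectories (`gen_trajectories`)

All models take per-axis Gaussian steps of variance 2·D·Δt (nm², with D
converted from μm²/s):

* **brownian** — free cumulative sum;
* **confined** — steps radially reflected back into a circle of
  `confinement_radius` around the start (reflection clamped for steps larger
  than the zone, which keeps the walk inside at any D);
* **hop** — a square compartment grid of side `compartment_size`
  (default 58 nm); each axis-wise boundary crossing is transmitted with
  probability `hop_probability`, otherwise reflected (the published picket
  model is schematic; the square grid with per-encounter transmission is
  this package's concrete instantiation);
* **immobile** — a static point.

Localization error is added to every emitted position afterwards. All
generators are pure functions of their parameters and seed.

**Generator scope.** No photophysics (on/off kinetics), no camera noise,
no 3-D, no raw-frame synthesis, no drift. The generators reproduce the
*statistical* structure the analyses assume — nothing more.

## 2. Voronoi cluster segmentation (`leaflet_smlm.cluster`)

Per-localization density is the **first-rank** estimate 1/area of its
Voronoi cell. Cells are clipped to the ROI exactly by tessellating the point
set together with its mirror images across the four ROI edges: every
original cell is then finite and bounded by the ROI, and the clipped areas
tile the ROI exactly (conservation holds to ~1e-15 relative; the invariant
is tested at 1e-6). Areas are computed with the shoelace formula on the
cell vertices. `neighbor_averaged=True` replaces the density with
(1 + #neighbors)/(own + neighbor cell areas); on the synthetic recovery
scenes this raises member recall (≈0.87 → 0.90) but inflates the recovered
median diameter by ~20–26 % versus the ground-truth oracle (first-rank:
+1–7 %), so first-rank remains the default.

The **threshold** is Monte-Carlo: the density histogram of the observed map
is compared with the mean histogram of `n_simulations` CSR maps of equal
count and ROI over 50 shared bins (range capped at the pooled 99.9th
percentile). The threshold is the lower edge of the first bin above the CSR
mode where the observed histogram meets or exceeds the CSR mean *and* the
observed tail mass beyond that edge exceeds the simulated tail mass by more
than three simulation SDs; the tail guard prevents histogram noise on
unclustered input from producing a spurious threshold (false-positive
member fraction ≈0.02 on CSR input). If no bin qualifies the threshold is
+∞ with `clusters_detectable = False`.

Clusters are connected components (shared-Voronoi-edge adjacency) of
localizations with density ≥ threshold; components with ≤ 5 members are
eliminated. Cluster area is the sum of member cell areas; the equivalent
diameter is 2·√(area/π); the headline size statistic is the **median**
diameter with lower interpolation for even counts.

**Calibration.** With 50 members/cluster, 22-nm localization error and a
Gaussian spread of 37 nm, the ground-truth convex-hull oracle median
diameter is ≈180 nm and the recovered median lies within 15 % of it. With
the first-rank estimator the member recall on such scenes plateaus around
0.87 (≈ the Gaussian mass inside the density capture radius); recall ≥ 0.9
requires denser clusters (≈200 members at spread 30 nm).

## 3. Degree of colocalization (`leaflet_smlm.doc`)

For each focal localization, counts N(r) of both channels are taken in
closed disks at radii r = dR, 2dR, …, R_max (defaults 50…500 nm; the r = 0
term of the printed sum is taken as absent since D(r) is undefined there)
and normalized as

    D(r) = [N(r) / N(R_max)] · [R_max² / r²],

so a uniform pattern has expected D(r) = 1 everywhere and D(R_max) = 1
exactly. The per-localization score is C = S · exp(−E/R_max) with S the
Spearman rank correlation of the two gradient vectors over the radius bins
(average ranks for ties) and E the nearest cross-channel neighbor distance.
A localization is excluded when **both** within-R_max counts are below
`min_total_localizations` (default (R_max/dR)·10 = 100), when either
N(R_max) is zero ("undefined gradient"), or when either gradient vector is
rank-constant ("degenerate gradient" — Spearman is undefined there). The
colocalization index is the fraction of scored localizations with
C ∈ [0.7, 1]; the raw count is reported alongside. Histograms use bin width
0.1 over [−1, 1].

**Counting convention (this package's choice).** The focal localization is
not counted in its own channel, and a cross-channel localization at exactly
zero distance from the focal (the registration image of the same emitter,
as when one channel is a coordinate copy of the other) is excluded from the
gradient counts but not from E. This pair of rules is forced jointly by two
printed statements: a uniform pattern must give mean D(r) = 1 at every r
(self-inclusion adds +1 at all radii and inflates small-r bins), and an
identical channel copy must score C = +1 exactly (counting the coincident
copy makes N_B(r) = N_A(r) + 1 and breaks the rank equality). The rule has
measure-zero effect on continuous data.

**Boundary bias of the null.** D(r) assumes a full disk of radius R_max
around the focal. On a bounded field without edge correction, focals within
R_max of the boundary have clipped disks: N(R_max) is deflated while small-r
counts are not, inflating D(r) at small radii in *both* channels at once,
which correlates their gradients and biases C upward (≈ +0.11 for edge
focals on CSR–CSR input). Pooled over all focals at the default field and
density this leaves a mean null score of ≈ +0.02–0.03; restricted to
interior focals (full disk inside the ROI) the residual is ≈ +0.006 ± 0.003,
attributable to the shared area-correction geometry of the statistic
itself. Consequences in this package: `mean_density_gradient` uses only
interior focals by default (configurable `edge_margin`), and null-mean
checks on `doc_scores` should either restrict to interior focals or allow
for the documented positive offset. No edge correction is applied to the
scored statistic, matching the printed formula.

**Control.** `doc_control` scores channel A against a random-shifted copy of
B (seed recorded in the result).

## 4. MSD and effective diffusion (`leaflet_smlm.tracking`)

Single-trajectory MSD uses overlapping windows:

    MSD(nΔt) = (1/(N−n)) Σ_{j=1..N−n} |r((j+n)Δt) − r(jΔt)|²,  1 ≤ n ≤ N−1.

The divisor is N−n (the number of n-step displacements available from N
positions); a published variant prints N−n+1, which is inconsistent with
its own definition (an n-step displacement needs n+1 positions) and with
the two-point identity MSD(Δt) = d². Ensemble curves average per-lag MSD
values over trajectories, weighted by the number of contributing
displacement pairs (plain mean by flag); standard errors are computed
across trajectories, never across the strongly correlated overlapping
windows of one trajectory.

Effective diffusion coefficients are OLS slopes over named windows divided
by 4 (two dimensions): `12ms@4ms` fits the 8/12/16-ms points, `24ms@4ms`
fits 8–40 ms, `3ms@1ms` fits 2–10 ms. The intercept — which absorbs the
localization-error offset 4σ² — is reported and never subtracted. A negative
fitted slope yields D_eff = 0 with a `non_diffusive` flag.

**Motion classification** is a documented stand-in (the source literature
defers to earlier work without formulas): the relative deviation
RD = MSD(n*Δt) / (slope_short · n*Δt) compares the observed long-lag MSD to
the extrapolation of a short-lag fit. The short-lag slope is least squares
*through the origin* — a free intercept makes the slope sign-indefinite on
strongly confined trajectories whose MSD saturates within one frame. RD is
scale-free in D, so the 2.5th/97.5th percentile envelope calibrated from
≥1000 simulated Brownian trajectories of matched length and frame interval
applies at any D: below the envelope → suppressed, above → directed,
inside → simple-Brownian. On 50-frame sets at 4 ms this classifies ~95 % of
Brownian, 100 % of strongly confined (radius 50 nm at D = 1) and 100 % of
strongly drifting trajectories correctly.

## 5. TALL detection (`leaflet_smlm.tall`)

A TALL candidate is a maximal run of consecutive positions all within the
detection radius (default 50 nm) of the run's own centroid, grown greedily
from each start with the centroid recomputed as the run grows; candidates
shorter than the threshold trapped period (32 ms at 4-ms resolution, 8 ms
at 1-ms resolution) are discarded and surviving events separated by fewer
than 2 frames are merged. Trajectories not longer than 10 frames are
skipped with a reason (not an error). A trajectory whose single merged
event spans ≥ 90 % of its frames *and* whose overall radius of gyration is
at most √2 × 22.2 nm (the expected 2-D gyration radius of a stationary
emitter at the fixed-probe localization precision) is classified immobile.
Set-level fractions pool per-frame states over analyzed trajectories and
always sum to 1; τ_TALL is the mean merged-event duration. The run rule is
this package's concrete substitute for an event algorithm the source
literature cites but does not print; measured behavior: Brownian controls
at D = 1 μm²/s show a TALL time fraction < 0.01, and planted 64-ms
confinements of ≤ 30-nm radius are recovered with ≥ 95 % event recall.

## 6. Pipeline (`leaflet_smlm.pipeline`)

A YAML config with one global seed drives simulate → subsample → cluster →
DoC → track → TALL. Per-stage seeds are `(seed XOR crc32(stage)) mod 2³¹`,
so any stage re-run standalone with its derived seed reproduces its
pipeline output bit-for-bit. Validation constructs every enabled stage's
parameter objects before anything runs (fail-fast, no partial outputs on
config errors). The manifest records a SHA-256 hash of the canonicalized
config, the derived seeds and a SHA-256 checksum of every output file;
identical configs produce identical manifests.

## 7. Limitations

* The DoC statistic carries the boundary bias described in §3; quantitative
  comparisons of C between images of different sizes or densities should
  use matched controls (as the randomized-shift control does).
* The cluster threshold rule (histogram intersection with a 3-SD tail
  guard, 50 bins) and the density estimator choice affect recall and size
  bias in opposite directions; both conventions are stated above and
  alternatives are exposed as flags, but results depend on them.
* The motion classifier and the TALL run rule are declared substitutes for
  algorithms the source literature references without printing; results
  that depend on them should be labeled as such.
* Blinking is modeled as i.i.d. re-localizations of a static emitter —
  no dark-state kinetics, so temporal correlations of real blinking are
  absent.
* All analyses are 2-D and assume a single, uniform localization precision
  per channel.
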