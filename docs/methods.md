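# Methods

## The statistics

`paintscope` scores a well-profile table with two resampling statistics.

**Percent replicating.** For each compound `c` with at least two profiled
wells, the foreground statistic is `r_c`, the median of all pairwise Pearson
correlations (computed across feature columns) among its replicate wells.
The null distribution is built from `K` (default 10,000) random groups of
wells of the same size as a replicate group (the modal replicate count, 4
for JUMP-MOA layouts), each group constrained to contain all-distinct
compounds, and each summarized by its median pairwise correlation.  The
threshold `t` is the `q`-th percentile of the null (default `q` = 95, linear
interpolation, NumPy's default convention).  Percent replicating is
`100 · #{c : r_c > t} / #evaluated`; the inequality is strict, so ties count
as failures.

**Percent matching.** For each compound whose MOA class contains at least
one other compound, the foreground statistic `m_c` is the median correlation
over all (well of `c`) × (well of a same-MOA *different* compound) pairs.
The null draws pairs of compounds with distinct MOAs and summarizes each
draw by the median of its cross-compound well-pair correlations — the same
functional as the foreground, applied to non-matching compound pairs.  This
group-level null is the package default (`null_unit="group"`) because it
makes null and foreground exchangeable under the no-signal model, which is
what gives both metrics their nominal (100 − q)% false-positive rate; a
simpler single-well-pair null is available as `null_unit="pair"`, but note
it is *not* calibrated against the median-of-pairs foreground (a median over
~16 dependent correlations is more concentrated than a single correlation,
so the pair null is conservative).  Singleton-MOA compounds are excluded
and reported.

Per-compound medians are the default foreground aggregation
(`foreground_aggregate="median"`); pooling all foreground pairs into one
distribution and scoring the pooled fraction above threshold is available
as `"pooled"`.  Negative-control wells are excluded from foreground and
null alike (a flag admits them to the null only).  Rejection sampling
enforces group distinctness; draws are without replacement within a group
and with replacement across groups, and are reproducible from a seed.

**Percent score and leaderboards.**  Percent score is the arithmetic mean
of the two metrics.  Leaderboards mean-aggregate duplicate setting labels,
sort descending (ties ordered by label), and normalize the best setting to
100.

## The synthetic plate model

The generator emulates the statistical structure the metrics rely on, not
images.  For a plate map with compounds `c` in MOA classes `m`:

* **Effects.**  `beta_c = a (√ρ · u_m + √(1−ρ) · v_c)` with `u_m`, `v_c`
  seeded unit directions.  `a` (`effect_magnitude`, default 1.0) is the
  length of an active compound's effect vector in robust-z units spread
  over all features; `ρ` (`moa_sharing`, default 0.5) is the expected
  cosine similarity of two same-MOA effect vectors.  A seeded subset of
  `active_fraction` (default 0.9) of compounds is active; the rest get
  `beta = 0`, emulating compounds without a detectable phenotype.
* **Cross-channel effect redundancy.**  Within `u_m` and `v_c`, the
  single-channel features occupying the same slot in different channels
  (e.g. mean intensity of ER and of RNA) share a latent component with
  weight `channel_effect_sharing` (default 0.5).  Biologically, organelle
  responses co-occur; operationally, this is what makes dropping one
  channel's features nearly information-neutral, as observed for RNA and
  brightfield dropout.
* **Brightfield.**  Features of the brightfield channel carry a reduced
  effect loading (`brightfield_effect_loading`, default 0.25) — transmitted
  light carries less perturbation-specific signal than fluorescence — so
  dropping brightfield is near-neutral by construction; the loading is a
  knob, not a claim.
* **Nuisance layers.**  Additive per-row and per-column plate effects
  (`sigma_plate`, default 0.1 per feature), a per-site offset
  (`sigma_site`, 0.1), and unit-variance Gaussian cell noise
  (`sigma_cell`, 1.0) with one latent factor per channel per cell
  (loading `√r_chan`, `channel_corr` default 0.3) so features within a
  channel correlate — which is what makes correlation-threshold feature
  selection non-trivial.  Two-channel correlation features load `√(r/2)`
  on each parent channel.
* **Cells per site.**  Poisson with magnification-dependent means
  (default 10X → 600, 20X → 150, 40X → 40 cells/site), preserving the
  inverse relationship between magnification and field-of-view cell count;
  `sites_per_well` defaults to 9.  A well drawing zero cells emits zero
  rows and a logged warning.
* **Feature names** follow the `Compartment_Group_Measure[_Channel[_Channel2]]`
  convention (per channel: `n_features_per_channel` single-channel
  features; one correlation feature per unordered channel pair; plus
  channel-free `AreaShape` features), so channel attribution is always
  recoverable by name parsing.

What the generator does **not** emulate: pixel-level content, bleedthrough
spectra, optics (NA, binning and z-planes are representable only as
user-chosen noise-scale changes), non-Gaussian feature distributions,
cell-cycle or density covariance structure, and segmentation failure modes.
Tests passing on synthetic plates therefore validate the *analysis* — its
calibration, invariances and bookkeeping — not any claim about a specific
instrument.

## Profiling pipeline

* **Aggregation** is the arithmetic mean of all cells per well — a
  cell-weighted mean over sites, never a mean of site means; per-well and
  per-plate cell counts are recorded in provenance.
* **Normalization** is per-plate robust standardization
  `(x − median) / (1.4826 · MAD + ε)` with `ε = 1e−18`; the 1.4826
  consistency constant makes the scale comparable to an SD for Gaussian
  data.  MAD-zero (constant) features become missing and are left for
  selection to remove.  The normalization population is all wells on the
  plate; `negcon`-only normalization would be a straightforward variant but
  whole-plate is the default.
* **Feature selection** runs, in order: `drop_na` (missing fraction >
  0.05), `variance_threshold` (most/second-most-common frequency ratio
  > 19 **and** unique-value fraction < 1%), and `correlation_threshold`
  (cutoff 0.9): while any |r| exceeds the cutoff, remove the involved
  feature with the largest mean |r| to all remaining features, ties dropping
  the lexicographically later name — deterministic and order-independent.
  The removal trace is kept in provenance.
* **Channel dropping** removes every feature whose parsed channel set
  contains the token (including two-channel correlation features) and must
  precede feature selection, mirroring how channel-dropout analyses are
  run on real profiles.

## Experiments

Site subsampling draws `target_sites` site labels per well independently
(seeded, without replacement) and re-aggregates cells to wells; one draw per
(plate, target) by default.  The cell-count curve sweeps magnifications and
subsampled site counts, re-running the pipeline and metrics per condition.
Channel dropout runs the pipeline twice from the same simulated cells (with
and without the channel, dropped before selection) and reports both results
and their difference without asserting a direction.  `run_experiment`
writes profiles, per-setting metric JSONs and null CSVs, a normalized
leaderboard and a manifest (config hash, seed, version, per-stage status)
that marks failed stages if a run is interrupted.

## Numerical choices and degenerate inputs

Percentiles use linear interpolation with inclusive endpoints.  Pearson
correlations between well profiles use all post-selection features;
zero-variance profile rows (correlation undefined) are excluded with a
warning, as are wells with missing features (e.g. zero-cell wells).
Thresholding is strict (`>`).  Rejection sampling raises when distinctness
is unsatisfiable (e.g. a single compound).  Feature selection raises if it
would remove every feature.  Robustization requires ≥ 2 wells per plate.

## Problem sizes

The default simulator (10 single-channel features × 6 channels, 9 sites,
λ(20X) = 150) produces ~520k cells per plate.  The test suite and the
acceptance script use `desk_scale_config` — 6 features/channel, 6
channel-free features, 3 sites/well, λ = {10X: 160, 20X: 40, 40X: 10} —
about 46k cells and 57 features per plate, which keeps a full
simulate-profile-score cycle under a second while preserving every
structural property the analyses measure (the resampling calibration and
trend statistics are insensitive to these sizes).  Calibration runs use 20
plates; trend and dropout analyses use 10 seeds per condition.

## Known limitations

* Effect directions are isotropic apart from the slot-sharing structure;
  real morphological effect spectra are far from isotropic.
* The matching null assumes MOA classes are mostly pairs (as in JUMP-MOA);
  for many-compound classes the foreground pools more wells than the
  two-compound null draw mirrors exactly.
* Feature selection's near-zero-variance rule rarely fires on continuous
  synthetic data; it exists for real profile tables with quantized or
  clipped features.
* No multiple-testing-corrected or mAP-style profile-quality variants.
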