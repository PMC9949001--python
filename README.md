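# paintscope

Tools for grading Cell Painting imaging configurations from morphological
feature tables.

Cell Painting is a multiplexed fluorescence assay that stains eight cellular
compartments across (typically) five imaging channels — DNA, endoplasmic
reticulum (ER), nucleoli/cytoplasmic RNA (RNA), actin + Golgi + plasma
membrane (AGP) and mitochondria (Mito) — from which thousands of per-cell
morphological features are extracted and aggregated into per-well *profiles*.
When choosing microscope settings (magnification, site count, channel set,
binning, ...) a lab needs a quantitative way to compare configurations.
`paintscope` implements the standard benchmark for that comparison:

* **Percent replicating** — the fraction of compounds whose replicate wells
  correlate more strongly than chance:

  `PR = 100 · #{c : r_c > t} / #compounds`, where `r_c` is the median
  pairwise Pearson correlation (across features) of compound *c*'s replicate
  wells and `t` is the 95th percentile of a null distribution built from
  10,000 random groups of non-replicate wells.

* **Percent matching** — the analogous fraction for compounds correlating
  with *different* compounds annotated with the same mechanism of action
  (MOA), against a null of random distinct-MOA compound pairs.

* **Percent score** — the arithmetic mean of the two, which setting
  leaderboards rank (best setting normalized to 100).

These statistics are designed around the JUMP-MOA positive-control plate: a
384-well layout carrying 90 compounds from 47 MOA classes with 4 replicate
wells each, so that MOA-matched pairs are measurable on a single plate.

Because raw Cell Painting image sets are terabyte-scale, the package ships a
synthetic-data module that emulates the statistical structure of a JUMP-MOA
plate — compound- and MOA-level effect vectors, plate row/column gradients,
site effects, channel-correlated cell noise, and magnification-dependent
cells-per-site — so the whole analysis runs desk-side in seconds and every
pipeline stage is testable without images.

## What's in the box

| module | contents |
| --- | --- |
| `paintscope.plate` | JUMP-MOA-style plate-map generation, CSV IO, validation |
| `paintscope.simulate` | channel registry, feature schema, effect library, single-cell plate simulation |
| `paintscope.profiles` | well aggregation, per-plate MAD robustization, feature selection, channel dropping |
| `paintscope.metrics` | `ProfileStrength` model / `ProfileStrengthResults`, resampled nulls, leaderboards |
| `paintscope.experiments` | site subsampling, cell-count curves, channel-dropout experiments, full runs |
| `paintscope.cli` | `paintscope simulate / aggregate / normalize / select / drop-channel / subsample / metrics / leaderboard / run` |

## Worked example

```python
import paintscope as ps

# simulate one desk-scale JUMP-MOA plate (90 compounds / 47 MOAs / 4 reps)
platemap, schema, library, cells = ps.simulate_experiment_plate(
    ps.desk_scale_config(seed=1))

# cells -> well means -> per-plate robustize -> feature selection
profile = ps.profile_pipeline(cells)

# percent replicating / matching with a 10,000-draw null
res = ps.ProfileStrength(profile, platemap).fit(seed=1)
print(res.summary())
```

prints

```
                     Profile Strength
==========================================================
Setting:                base
Null size / percentile: 10000 / 95
Replicating: 90 compounds evaluated, 0 excluded (group size 4)
Matching:    86 compounds evaluated, 4 excluded (singleton MOA)
----------------------------------------------------------
Percent replicating     90.0   (null threshold r > 0.1154)
Percent matching        51.2   (null threshold r > 0.1138)
Percent score           70.6
==========================================================
```

Reading: 90% of the simulated compounds have replicate wells that correlate
above the 95th-percentile chance threshold (r > 0.115), and 51% correlate
with their MOA partner compound above the matching threshold — the matching
rate is lower because, at the default MOA-sharing weight of 0.5, only half
of a compound's effect vector is shared with its MOA partner.  The 4
excluded compounds belong to singleton MOA classes with no partner to match.

`res.replicating.null`, `res.replicating.per_compound` and
`res.plot_null("replicating")` expose the underlying distributions;
`ps.channel_dropout_experiment`, `ps.cellcount_curve` and
`ps.run_experiment` drive the setting-perturbation analyses and write
leaderboard CSVs plus a manifest.

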