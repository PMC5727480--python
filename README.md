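# dispartime

Diversity and disparity through time for fossil clades, from mixed
discrete + continuous morphological character matrices.

Paleobiologists ask *when* in a clade's history its morphological variety
was concentrated: early ("bottom-heavy", the classic early-burst
signature), late, or symmetrically about the midpoint.  Answering that for
an extinct clade takes a chain of steps that are usually scattered across
several programs: a parsimony tree from the character matrix, node ages
from stratigraphy, a morphospace (one from discrete characters, one from
continuous measurements), per-time-bin disparity with a correction for
lineages the fossil record missed, and a summary statistic for the shape
of the resulting profile.  `dispartime` implements the whole chain as one
tested Python library, aimed at datasets like the Paleozoic amniote
matrices that motivated it (~30 taxa, ~75 discrete + ~30 ratio
characters, stage-level Permian stratigraphy).

The core quantities:

- **Tree length** — Fitch parsimony for unordered discrete characters
  (polymorphism and missing data as state sets), Farris interval lengths
  for continuous characters treated as additive; ensemble fit indices
  CI = Σm/Σs, HI = 1 − CI, RI = (Σg − Σs)/(Σg − Σm); random-addition +
  SPR heuristic search and symmetric-resampling node support.
- **Node ages** — outgroup-based Bayesian calibration: successive
  divergences uniform between bounding ages, propagated on an age grid;
  joint root-to-tip draws with parent ≥ child in every sample.
- **Morphospaces** — log-ratio + mean imputation + covariance PCA for the
  continuous characters; MORD (maximum observable rescaled distance) +
  uncorrected PCoA for the discrete characters.
- **Disparity profiles** — sum of variances / sum of ranges per time bin,
  taxon-bootstrap CIs, ghost-lineage pseudo-taxa inferred under Brownian
  motion at bin midpoints, and taxic vs phylogenetic diversity.
- **Clade shape** — the scaled center of gravity CGS = Σdᵢtᵢ/Σdᵢ of a
  disparity profile on the clade's [0, 1] time axis, with a
  flat-profile null (exactly 0.5 for equal bins) and a bootstrap test.
- **Cross-track agreement** — phylogenetic independent contrasts of
  paired PCA/PCoA axes, correlated through the origin.

A synthetic-data module generates clade-shaped fixtures (birth–death
trees with extinct tips, Mk discrete characters, log-Brownian ratios,
Poisson fossil sampling, trait-linked diets) with full ground truth, so
every stage is testable end to end without any external data.

## Worked example

The repository is organised as an analysis project: numbered drivers
under `analysis/` run the full study on the synthetic fixture and write
tables under `results/`.

```bash
python analysis/01_simulate_dataset.py
python analysis/02_parsimony_search.py
python analysis/03_time_calibration.py
python analysis/04_morphospaces.py
python analysis/05_disparity_through_time.py
python analysis/06_axis_correlations.py
```

Step 02 prints, for the seed-1 fixture:

```
best length 496.72 (1 MPT(s), 20 SPR replicates)
discrete partition: 262 steps, CI 0.385, HI 0.615, RI 0.541
symmetric resampling (100 reps): 12/27 nodes at >= 70%
```

— the mixed-matrix search found a single shortest tree; on its discrete
partition 262 steps with CI 0.385 means substantial homoplasy (the Mk
simulation produces roughly one change per character per root-to-tip
path), and 12 of 27 ingroup nodes survive character-weight resampling at
the 70% level.  Step 05 then reports the eight disparity curves:

```
continuous_sov_raw: CGS 0.606 (null 0.481, p = 0.016)
...
discrete_sor_ghost: CGS 0.605 (null 0.532)
taxic diversity per bin: {'Asselian-Sakmarian': 4, 'Artinskian': 4,
                          'Kungurian': 9, 'Guadalupian': 11, 'Lopingian': 5}
```

CGS above the flat-profile null on every curve says this particular
simulated clade is top-heavy — its morphospace filled late — and the raw
vs ghost-corrected pairs agree, as do the discrete and continuous tracks.
Step 06 closes the loop: per-axis PIC correlations between the two
morphospaces are weak (median |r| ≈ 0.23), so the two character types
place individual taxa differently even while their per-bin disparity
curves tell the same story.

The same pipeline runs on real data from the command line:

```bash
dispartime run --config pipeline.yaml
dispartime parsimony --matrix matrix.nex --outgroup Protorothyris \
    --replicates 100 --seed 1 --out search/
```

with NEXUS (discrete or continuous blocks), TNT `xread`, newick and CSV
taxon tables as input formats.

## Layout

```
src/dispartime/     library (datamodel, io, stages, parsimony, timescale,
                    ordination, disparity, contrasts, simulate, pipeline, cli)
analysis/           numbered drivers for the full synthetic study
tests/              pytest suite (oracle-based; see docs/methods.md)
scripts/            acceptance script
docs/methods.md     models, numerical choices, generator realism, limits
```
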