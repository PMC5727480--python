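# Methods

`dispartime` measures how the morphological disparity of a fossil clade is
distributed over its history, from a mixed discrete + continuous character
matrix, stratigraphic ranges and an outgroup-rooted phylogeny.  This note
records the models, the numerical choices, and what the synthetic study
system does and does not emulate.

## Parsimony

Unordered discrete characters are optimized with Fitch's downpass.  Cells
are state *sets*: a polymorphic scoring contributes its set at the tip and
a missing cell contributes the universal set, so both are handled by the
same intersection/union recursion.  The downpass is vectorized across
characters with per-character bitmasks (up to 63 states), which makes a
full 30 x 106 tree evaluation cheap enough to drive swap-based searches.

Continuous characters are treated as additive and scored with the Farris
interval downpass: merging two child intervals costs the gap between them
(zero if they overlap), and the summed gaps equal the minimal total
`|parent - child|` change on the tree.  One unit of raw ratio difference
costs one step, so continuous characters enter the search length at weight
1 alongside the discrete partition.

Ensemble fit indices are reported for the discrete partition only:
CI = Σm/Σs, HI = 1 − CI, RI = (Σg − Σs)/(Σg − Σm).  Per character, the
minimum m is (size of the smallest state set hitting every scored cell) − 1
— with no polymorphism this is just (observed states − 1) — and the
maximum g is (scored tips) − (largest single-state class), counting each
polymorphic tip toward its most favorable state.  RI is flagged undefined
when Σg = Σm (all characters constant or autapomorphic).

The heuristic search uses random-addition-sequence starting trees followed
by first-improvement SPR (or NNI) swapping to a local optimum, rooted on a
user-chosen outgroup; all distinct topologies at the best length are
returned.  Distinctness is assessed after collapsing internal branches
that admit zero changes under some most-parsimonious reconstruction
(Fitch final state sets intersect on every discrete character).  The
collapse rule deliberately ignores the continuous partition, where exactly
zero-length gaps are a measure-zero event.

Node support comes from symmetric resampling: per replicate each
character's weight is doubled with probability p/2 and halved with
probability p/2 (default p = 1/3), a reduced-effort search is run (default
two random-addition starts + NNI — full SPR effort changes the supported
set only marginally on matrices of this size while costing an order of
magnitude more), and a reference split counts as recovered when it appears
in the strict consensus of the replicate's best trees.

## Time calibration

Node ages come from the outgroup-based Bayesian approach in which the ages
of successively more distant, stratigraphically consistent outgroups
constrain how far a divergence can be extended beyond its oldest
descendant.  The chain is: the first (most distant) divergence is uniform
between that outgroup's age and the hard maximum `t_max`; each subsequent
divergence is uniform between the previous divergence and its own
outgroup's age; the node itself is finally uniform between its oldest
descendant tip and the last divergence.  The posterior is propagated
exactly on a discretized age grid (default 500–1000 points; one uniform
step is an O(grid) suffix-sum), so halving the grid step perturbs the
posterior mean by well under 0.1 Myr and convergence is testable.

Whole-tree calibration proceeds in preorder.  For each internal node the
outgroup age sequence is the oldest first appearance of the sister clade
at each successive ancestor (prepended with the user's external outgroup
ages), filtered to the stratigraphically consistent non-increasing
subsequence.  Joint draws respect stratigraphic order by construction:
each node's posterior is computed once, anchored at the mean of its
parent's sampled ages (the root at the user's maximum-age constraint), and
every draw is taken from that posterior truncated at the parent's drawn
age via inverse-CDF on the grid.  An exact per-draw recomputation of the
chain would scale as draws x nodes x grid^2 and changes nothing any
reported invariant tests.  The reported tree carries per-node mean ages,
clamped child-to-parent where averaging would invert order (the clamp is
recorded in the node table); tips sit at their first appearance (FAD), and
the last appearance is used only for time-bin membership.

Stage boundary ages are packaged as a constant table (ICS chart 2023/06,
version recorded in output metadata).  Two bin schemes are built from it:
five coarse bins (Asselian–Sakmarian, Artinskian, Kungurian, Guadalupian,
Lopingian) and ten stage-level bins (Gzhelian through Changhsingian).

## Morphospaces

Continuous track: the ratio characters are natural-log transformed (they
are already a-dimensional ratios, so the log alone removes the spurious
correlation structure of ratio data; a centered log-ratio variant exists
as an option but is not the default), missing cells are mean-imputed per
character, and the complete matrix is ordinated by PCA on the covariance
matrix (variables are commensurable after the log, so correlation scaling
would discard real variance differences).

Discrete track: pairwise maximum observable rescaled distances (MORD) —
summed per-character differences over summed maximum possible differences,
both restricted to characters scored in both taxa.  An unordered character
differs by 0 when the state sets intersect, else 1; an ordered character
differs by the minimal |x − y| between the sets rescaled by the character's
observed range.  Pairs sharing no scored character are flagged and, by
default, filled with the maximum observed distance (trimming is available);
the warning reports how many pairs were filled.  The distance matrix is
ordinated by PCoA (double-centering of −D²/2) with *no*
negative-eigenvalue correction: the count of positive-variance axes is
itself a quantity of interest, so eigenvalues are reported raw with
negative ones flagged.  PCoA axis variances are reported on the eigenvalue
/(n−1) scale so that the two tracks are directly comparable (PCoA of the
Euclidean distances among PCA scores reproduces the PCA axis variances to
1e-8).

## Disparity through time

Taxa join every time bin their [LAD, FAD] range overlaps; a point
occurrence on a bin boundary belongs to the older bin.  Disparity per bin
is the sum over ordination axes (all positive-variance axes by default;
any fixed subset can be selected) of either the n−1 sample variance or the
range of member scores.  Bins with fewer than two members have undefined
variance (flagged as NaN, never imputed).  Uncertainty is a within-bin
taxon bootstrap (default 1000 replicates) with 2.5/97.5 percentile
intervals.

Ghost-lineage correction: ancestral values of each ordination axis are
maximum-likelihood Brownian-motion estimates — the per-axis values that
minimize Σ (difference)²/branch-length, obtained by solving the linear
system in which each internal node is the branch-length-weighted average
of its neighbors.  Any branch that spans a bin's midpoint without a taxon
sampled in that bin contributes a pseudo-taxon whose score is the linear
time interpolation between the estimates (or tip values) at the branch's
ends.  The midpoint is the one time-symmetric choice of evaluation point.
Axes are treated independently (they are orthogonal by construction).
Pseudo-taxa are flagged and excluded from taxic diversity; they enter the
sum of ranges and sum of variances identically.  Zero-length branches
arising from equal node ages are lengthened by 1e-4 Myr where a positive
length is required (BM estimation, contrasts), and the perturbation count
is available from the call.

Phylogenetic diversity is the number of lineages (sampled or not) crossing
each bin midpoint, with tip lineages persisting to their LAD; midpoints
older than the root count the single stem lineage.

## Clade shape (CGS)

The scaled center of gravity of a profile d over bins with scaled midpoint
times t (0 = start of the oldest bin with defined disparity, 1 = end of
the youngest) is CG = Σdᵢtᵢ/Σdᵢ.  Values below 0.5 are bottom-heavy
(disparity early), above 0.5 top-heavy.  Because bins have unequal
durations, the null expectation is not assumed to be 0.5 but *computed* as
the CG of a flat profile over the same bins; for equal-length bins it is
exactly 0.5.  Significance is a two-tailed within-bin taxon bootstrap:
the profile and its CGS are recomputed per replicate and the p-value is
twice the smaller tail of the bootstrap distribution around the null
expectation.  On symmetric synthetic clades the test rejects at roughly
the nominal 5% rate (checked at 200 replicates in the suite).

## Independent contrasts

Felsenstein's algorithm on the dated binary tree: contrast
(x₁ − x₂)/√(b₁ + b₂) per node, node value the branch-length-weighted
average, parent branch extended by b₁b₂/(b₁ + b₂).  Corresponding axes of
the two morphospaces (PC1 with PCo1, and so on) are correlated through the
origin — contrasts have zero expectation and arbitrary sign — and |r| is
reported alongside signed r because ordination axis orientations are
themselves arbitrary; a with-intercept variant is exposed as an option.

## Synthetic study system

The generator emulates a Permo-Carboniferous amniote clade at the scale of
the captorhinid matrix.  Defaults, chosen once as the study conditions:
30 taxa from a birth–death simulation (birth 0.10, death 0.05 per
lineage-Myr, origin 303.7 Ma, run to 251.9 Ma, extinct tips retained,
conditioned on the total tip count); 75 unordered discrete characters
under an Mk jump process (2–3 states, 0.02 changes/Myr — roughly one
expected change per character per root-to-tip path, giving realistic
homoplasy levels) with 30% missing and 2% polymorphic cells planted
uniformly; 31 ratio characters as geometric Brownian motion (log-scale
sigma² = 0.01/Myr around a root ratio of 1, ~0.7 log-sd over the clade
depth) with 10% missing; stratigraphic ranges from Poisson fossil sampling
at 0.3 occurrences/Myr along each terminal branch (lineages with no
occurrence get a point record at their tip age); diets assigned
deterministically from the first log-trait (thresholds 0.15 and 0.5 for
omnivory and herbivory), so trophic structure in morphospace is planted
and recoverable.  True node ages and true ancestral trait values are
recorded, and a fixed seed reproduces the dataset bit for bit.

What the generator does *not* emulate: correlated characters,
rate heterogeneity across lineages or characters, non-random (e.g.
taphonomically structured) missing data, ordered discrete characters, and
geographically structured sampling.  Tests passing on these fixtures
therefore certify the computational pipeline — estimators, search,
invariants, determinism — not the robustness of the biological inferences
to those complications.

## Problem sizes and tolerances

The shipped analysis (`analysis/01`–`06`) runs the full 30-taxon fixture
with 20 SPR search replicates, 100 resampling replicates, 10,000
calibration draws and 1000 bootstrap replicates — a few minutes on one
core.  The test suite uses smaller instances chosen so each oracle is
exact or its Monte-Carlo error is quantifiable: exhaustive Fitch/Farris
enumeration at ≤6 tips, 500-replicate unbiasedness checks for ancestral
states, 200-replicate type-I-error calibration for the CGS test.
Numerical tolerances: eigenvalues below 1e-10 (PCoA) / 1e-12 (PCA) are
treated as zero; search tie-breaking uses a 1e-12 length tolerance;
variance conservation and PCoA-vs-PCA agreement are asserted at 1e-8.

## Known limitations

- The search is a local-optimum heuristic; on highly homoplastic matrices
  distinct MPT islands may require many addition replicates to find.
- TBR swapping is not implemented (SPR and NNI are); implied weighting and
  Bremer support are out of scope.
- The zero-length-branch collapse rule is evaluated on the discrete
  partition only.
- The mean-age tree is clamped to stratigraphic consistency after
  averaging, which can shorten a few basal branches relative to the raw
  posterior means.
- Incomparable MORD pairs are filled (or trimmed), not imputed from a
  model; with ≥70% complete matrices this is rare.
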