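# Methods

This note documents the models, conventions and parameter choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the known limitations.

## Combination index and dose-response

Cell viability is computed from CCK-8 absorbances as
`100 * (test - blank) / (control - blank)`; values outside [0, 100] are
reported as-is.

IC50s are estimated by a four-parameter logistic
`v(c) = bottom + (top - bottom) / (1 + (c / e)^h)` fitted by nonlinear
least squares with the bottom asymptote constrained to be non-negative
(top bounded in [40, 300]%, Hill slope in [0.05, 20]).  The reported IC50
is the *absolute* 50%-viability crossing of the fitted curve, not the
inflection parameter `e`; the two coincide only when top = 100 and
bottom = 0.  When the optimizer fails, or the fitted asymptotes do not
bracket 50%, the crossing is interpolated linearly in log10 concentration
between the bracketing observed points and the fit is flagged
(`converged=False` / `extrapolated=True`).

The combination index for a fixed-ratio mixture with fractions `f_i`
(molar for compounds, volume for equal-strength extract stocks) is the
mutually-nonexclusive Chou-Talalay sum generalized to k components:

    CI = sum_i (IC50_mix * f_i) / IC50_i.

This convention is validated by exact agreement, to the printed 2 decimal
places, with all 23 published CI cells across the extract-blend,
equimolar, actual-ratio and extended-combination assay tables.  CI is
scale-invariant in concentration units.  Verdicts use a +/-0.05 band
around 1 for "additive" in text summaries; the raw CI is always kept.
Ratio-string mixtures take their fractions from the printed integer
ratios, matching how the published CI values were derived.

## Interaction space

Compound and target descriptor blocks are standardized column-wise
(constant columns dropped) and reduced by PCA (full SVD, deterministic).
Study-scale defaults retain 42 compound and 237 target components,
auto-shrunk to the data rank; a cumulative-variance target (e.g. 0.99)
may be given instead.

The published method leaves two choices open, resolved as follows:

* **Shared geometry.** Targets and compounds do not naturally share a
  space, so a target's position is defined as the centroid of its known
  ligands in the *compound* component space.  The target block's own
  projection is fitted and stored but not used for inference.
* **"95% confidence interval" threshold.** Implemented as the one-sided
  95% upper empirical quantile (linear-interpolation convention) of known
  ligand-to-centroid distances, which is distribution-free and reproduces
  the intended inclusion behavior.  Whether the original thresholds were
  two-sided intervals or used pairwise rather than centroid distances is
  not stated; this choice is documented rather than guessed further.

Targets with fewer than two known ligands get a pooled global quantile
and are flagged.  A compound is linked to every target whose threshold it
falls inside; merged networks keep known provenance on duplicates.

By construction the held-out recall of this rule on the synthetic
ligand-ball world is about 95% per target (the coverage of an empirical
95% quantile), and the suite checks recall >= 0.90 on held-out true
edges.  The published recall figure for the original 50,564-pair corpus
is not reproducible because that corpus is not available; the synthetic
check is a qualitative analogue only.

## Within-groups clustering

Compounds are clustered on binary expanded-target membership vectors
(the only per-compound numeric data the pipeline carries; Euclidean
distance on such vectors is the square root of the Hamming distance).
The linkage is the SPSS-style *within-groups* criterion: each step merges
the pair whose union minimizes the mean over all pairwise distances
inside the merged cluster — distinct from UPGMA, which averages only
between-cluster distances.  Because this criterion is not guaranteed
monotone, the cut is defined operationally: merges replay in execution
order and stop at the first merge whose criterion exceeds the threshold.
This makes the partition coarsen monotonically with the threshold.  Ties
(frequent on binary data) break on the rounded criterion value, then on
the sorted member ids, so partitions are fully deterministic; the
implementation is verified against an exhaustive oracle that recomputes
every candidate merge from the raw distance matrix for n <= 8.

The study-scale cut threshold of 5 applies to ~1,093-dim binary profiles
(distance 5 ~ 25 differing targets).  Demo-scale runs use ~12-dim
profiles, where the same absolute cut would merge everything; the demo
default is 1.2, chosen once to separate distinct profiles at that scale.
Representative selection keeps, per cluster, the compound with the most
targets, ties to the lexicographically smaller id.

## Enumeration and featurization

Sizes default to 1-5 *including singletons*: the closed form
`sum_{k=1..5} C(n,k)` exactly reproduces both published screen sizes
(55,454 for 24 compounds; 16,663 for 19), which fixes the interpretation.
The published joint PVL-TH count of 87,222 over 36 compounds matches no
contiguous size range and is deliberately not reproduced.

Target aggregation over a combination is logical OR (union rule) — the
standard convention for combined target coverage.  Feature vectors are
the target bits followed by the cell line's genomic block; enumeration is
streamed so memory stays constant.

## Synergy model

The ranker is a two-hidden-layer feed-forward network (200/100 units,
ReLU, inverted dropout) with a linear regression head for the pseudo-IC50
and a sigmoid head for positive/negative synergy, trained with Adam on
`MSE + w * cross-entropy` (w = 0.5).  Class labels default to
thresholding the pseudo-IC50 at the corpus median, since no class
boundary is published.  The pseudo-IC50 is treated as a standardized
log-scale potency (hence negative values for the strongest combinations);
the synthetic corpus emits the same scale.  Initialization (He), batch
shuffling and dropout masks all derive from the config seed, so training
is bit-deterministic.

Study-scale defaults follow the published setup (learning rate 1e-5,
batch 128, 200 epochs, input 1,308).  Desk-scale tests use learning rate
1e-3 and a reduced 80-feature schema (64 targets + 16 genomic) with a
5,000-sample noiseless corpus — problem sizes chosen so the suite trains
in seconds while leaving wide margins: held-out Spearman against the
latent oracle is ~0.99 at the 0.8 acceptance bar, and the oracle-optimal
combination ranks first among ~2,300 candidates.  The published absolute
pseudo-IC50 values are *not* reproducible (the trained weights and the
201,405-sample training corpus are unpublished); the published score
tables enter the suite only as supplied-value ordering fixtures.

How SGD and Adam were jointly used in the original training is
unspecified; Adam is the implemented optimizer.

## Synthetic data

* **Descriptor world.** Target ligand centroids are drawn at ~10x the
  ligand-ball radius; each target gets one guaranteed ligand, further
  compounds are ligands of a random target with probability 0.6 (default)
  or background points rejection-sampled to lie > 2x the radius from every
  centroid.  True ligands lie uniformly inside the ball.  This plants a
  recoverable geometry; it does not mimic real MOE/ProFeat descriptor
  distributions.
* **Dose-response.** Viability follows a decreasing Hill curve.  Mixture
  curves use the Loewe-additive IC50 `1 / sum_i (f_i / IC50_i)` scaled by
  `exp(-lambda)`; lambda = 0 is exact additivity (downstream CI = 1),
  lambda > 0 synergy, lambda < 0 antagonism.  Dose grids are 8 log-spaced
  points spanning 0.01-100x the smallest single-agent IC50.  Noise is
  Gaussian in percent viability, clipped at 3 sd so viabilities stay in
  [bottom - 3 sd, top + 3 sd].
* **Synergy corpus.** Each synthetic compound hits 1 + Poisson(2) random
  schema targets; samples are random 1-5-compound subsets paired with one
  of 5 standard-normal genomic cell profiles.  Labels come from a latent
  additive + pairwise-interaction function of target bits plus a genomic
  term, standardized over the corpus; the latent function is exposed so
  tests can recompute labels exactly.  This is a stand-in labelling
  process, not a reconstruction of the unpublished training corpus, so
  passing tests demonstrate that the *pipeline* recovers a known signal,
  not that it reproduces MCF-7 biology.

All generators are bit-reproducible from the config seed.

## Formulation

`uM = content[mg/g] * dose[mg/mL] / MW[g/mol] * 1000`.  Ratio components
are rounded half-away-from-zero to integers for display; molar fractions
are taken from the unrounded values; the total is the sum of the rounded
components (this matches the published totals).  Extract blends are
volume blends of equal-strength stocks, so blended contents are
parts-weighted means.  A combination containing a compound not detected
in an extract is marked infeasible for that solvent (e.g. scopoletin is
absent from the water extract, so T1685 can only be formulated from 50%
ethanol).  The molecular-weight table ships as editable data since the
original values used are not stated.

Known drift: the 50%-ethanol core rows reproduce exactly (64:305:4:5 /
378 µM; 30:106:50 / 186 µM; the 2:1 blend rows 10:203:6 / 219 and
59:12:9:4:203 / 287), but a few published components differ by +/-1 µM
from direct recomputation (water-extract rows; rutin 14 vs 13 and
luteolin 27 vs 26 in the extended rows), and some published per-origin
totals differ by 1 from the sum of their own printed components.  These
are printing/rounding artifacts of unknown upstream precision and are
asserted only to within +/-1.

## Network report

Pathway enrichment is consumed as an input mapping, never computed, so
the module is independent of external database versions.  Node classes
for targets are single-pathway (<= 1 pathway; pathway-less targets are
grouped here for display), two-pathway, and multi-pathway (>= 3).  The
node-count identity |compounds| + |targets| + |pathways| is asserted on
every build.  The published target lists behind the 53/51/55-target
networks are unpublished, so study-sized checks use synthetic fixtures
with the same cardinalities.

## Pipeline and CLI

The CLI is a thin veneer over library calls (`demo`, `golden-tables`,
`enumerate`, `ci`).  `run_pipeline` executes the stages in dependency
order at demo scale (40 compounds, 12 targets, 80-feature schema, 1,500
corpus samples, 30 epochs — sized to finish in seconds) and writes a
manifest with the seed, config, stage counts and SHA-256 hashes of every
output; reruns with the same seed are byte-identical.
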