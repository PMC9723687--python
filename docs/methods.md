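# Methods

This note documents the models implemented in `rarescape`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Inference pipeline

The pipeline consumes a rarefied ASV × sample count table, sample metadata
(stage / time / replicate), and a rooted phylogeny with branch lengths, and
runs: rarefaction → rarity cutoffs → biosphere partition → rarity typing →
per-component βNTI and RC_bray → five-process classification → aggregation.

### Rarefaction and richness

Rarefaction subsamples each sample to a common depth **without
replacement** (multivariate hypergeometric draw), the standard ecological
convention; samples below the target depth are dropped with a warning
rather than left at unequal depth, since every downstream relative
abundance assumes a common denominator. Chao1 richness is
`S_obs + F1²/(2·F2)` from singleton/doubleton counts, switching to the
bias-corrected `S_obs + F1(F1−1)/(2(F2+1))` when no doubletons exist so the
estimator stays finite; it is always ≥ S_obs.

### Rarity cutoffs and types

A taxon is *rare* in a sample when its relative abundance is **no greater
than** the cutoff (boundary inclusive on the rare side; an off-by-one here
changes every downstream count) and *common* when strictly above it.
Besides the fixed set 0.2 % / 0.1 % / 0.05 %, a sample-specific cutoff is
derived from the rank abundance curve by an h-index-style crossing rule:
counts are sorted descending and the cutoff count h\* is the abundance at
the first rank r with abundance(r) ≤ r; when several ranks share the
crossing abundance the abundance itself (not a rank index) is used. The
raw fraction h\*/total is optionally **multiplied** by the completeness
ratio S_obs/S_Chao1 (≤ 1), shrinking the cutoff for under-sampled
communities; the division variant is exposed as a config switch for users
who prefer the opposite reading of "recalibrated by sampling depth".

Across samples, detected ASVs are typed: *permanently common* (common in
every sample), *conditionally rare/common* (common somewhere, rare
somewhere), *permanently rare* (never common, rare in ≥ 2 samples),
*transiently rare* (never common, rare in exactly one sample). ASVs common
in some samples and merely undetected in all others fall outside the four
rules; they are labelled conditionally rare/common — absence is treated as
sub-detection rarity — and flagged in the output. Because a smaller cutoff
can only flip a per-sample status from rare to common, the never-common
types can only shrink and permanently common can only grow as the cutoff
tightens; the rare biosphere's total abundance share is monotone
non-increasing. Both directions are enforced by tests.

### βMNTD / βNTI

βMNTD is abundance-weighted (the presence/absence variant is available but
off by default), and relative abundances are renormalized within the
analyzed component, so when a rare or common submatrix is analyzed each
community's weights sum to one inside that component. The null shuffles
the taxon → tip assignment of the tree **pruned to the analyzed table's
taxa** (preserving null richness and abundance structure exactly; the
full-tree shuffle is an option). One permutation per null replicate is
shared across all pairs — per pair this is the same marginal null, and it
vectorizes. The z-score uses the sample standard deviation (n−1). Pairs
with zero null sd (degenerate tree or identical communities) yield NaN
and are excluded from classification denominators, counted separately.

### RC_bray

Null communities preserve each sample's observed richness and read total:
identities are drawn without replacement with probability ∝ metacommunity
occurrence frequency, each drawn taxon is seeded with one read, and the
remaining reads are distributed with replacement ∝ metacommunity relative
abundance (both weightings are config-exposed). The metacommunity is the
analyzed table itself unless an external pool is supplied. Nulls are
simulated independently for each pair (999 by default). Ties between null
and observed Bray–Curtis count at half weight. Bray–Curtis is computed on
counts, not renormalized — rarefaction has already equalized totals.

### Classification and aggregation

βNTI > +2 → variable selection; βNTI < −2 → homogeneous selection;
otherwise RC_bray > +0.95 → dispersal limitation, RC_bray < −0.95 →
homogenizing dispersal, else undominated. Boundary values (βNTI = ±2,
RC = ±0.95) fall to the weaker claim: all comparisons are strict, so the
measure-zero boundary never asserts selection or dispersal. Temporal
aggregation uses same-stage pairs; spatial aggregation uses same-time,
different-stage pairs; percentages are per-group pair fractions and sum to
100 within every report row. The whole-community component does not depend
on any cutoff and is analyzed once per run.

### Sloan neutral model

Detection frequency is predicted as `1 − BetaCDF(d/N_T; N_T·m·p,
N_T·m·(1−p))` with N_T fixed to the rarefaction depth and detection limit
d = 1 read (configurable). m is fitted by bounded scalar least squares of
observed occurrence frequencies on this curve; fit quality is R² on
frequencies, set to 0 with a warning when the response has no variance.
Per-ASV deviation classes (above / within / below) use a Wilson score
interval around the prediction at n = number of samples (95 % by default).
The model is fitted only to whole communities — its occurrence-abundance
relationship is distorted on rare/common subsets — and the deviation
classes are cross-tabulated against rarity types with empty classes kept
as zero rows. The formula is a threshold approximation: it treats a taxon
as detected when its local relative abundance reaches d/N_T. With an extra
multinomial read-sampling layer on top, detection of very scarce taxa is
slightly more frequent than the formula predicts, which biases a fitted
N_T·m upward; the parameter-recovery harness therefore generates data in
which detection is exactly threshold crossing (Dirichlet local abundances,
floored reads), i.e. the model as the formula defines it.

### Ordination and PERMANOVA

PCoA is classical scaling of −½ D² double-centered; negative eigenvalues
(non-Euclidean distances) are reported, never silently dropped, and axis
percentages are relative to the positive spectrum. PERMANOVA is one-factor:
`SS_total = (1/N) Σ_{i<j} d²`, within-group sums analogous, pseudo-F from
among/within mean squares, and the p-value uses the add-one convention
`(1 + #{F_perm ≥ F_obs}) / (n_perm + 1)` (9 999 permutations by default).
Both are implemented in-package; scikit-bio's implementations serve as
independent cross-checks in the test suite.

## Synthetic data generator

The generator emulates the *post-processing* state of an amplicon survey —
a rarefied count table over a stage × time × replicate design (default
5 × 4 × 3 = 60 samples at 31 500 reads) with a matching phylogeny — not
sequences, chimeras, or denoising artifacts.

**Tree.** Real 16S gene trees concentrate divergence between deep lineages:
long stems separate clusters of nearly identical sequences. The generator
therefore builds a two-level phylogeny — a pure-birth (Yule) backbone over
"crowns" and a very shallow radiation (1 % of backbone depth) inside each
crown, with crown sizes of one to a few tips. This scale separation is what
gives a nearest-taxon statistic its contrast: a plain Yule tree has
near-uniform tip-to-tip distances (almost every pair coalesces deep), and
on such a tree habitat filtering is invisible to βNTI at desk scale no
matter how strong it is. A plain Yule + Brownian-trait simulator is also
exposed (`simulate_tree_and_traits`) for property tests.

**Niches.** A trait evolves by Brownian motion over the whole tree
(covariance = shared branch length), so crown-mates are ecologically
near-equivalent while crowns differ — phylogenetic niche conservatism by
construction, which is the inference's stated assumption.

**Assembly.** Expected crown shares follow a Gaussian filter
`exp(−(z_c − E_s)²/(2σ_w²))` on the crown trait, times per-sample lognormal
crown fluctuations (σ = 0.25) and optional static lognormal crown
capacities (default off — even crown capacities keep the effective number
of community members high, which the null-model z-scores need at 200-taxon
scale). Within each crown, sisters split the crown's share by a symmetric
Dirichlet draw with concentration 0.05: a largely arbitrary winner takes
most of the share in each sample. This within-crown winner-take-most
competition is the generator's key mechanism — under a shared environment
it produces turnover among ecologically equivalent close relatives, the
fingerprint of homogeneous selection; it also gives every sample a
long-tailed abundance distribution and hence a rare biosphere. Counts are
one multinomial draw per sample at the target depth, so generated tables
are already rarefied (a deeper-generation + rarefy mode is exercised via
the rarefaction API).

Scenario wiring:

* *homogeneous_selection* — one environment for all samples, at the median
  crown trait, niche width 0.5 × crown-trait spread.
* *variable_selection* — stage environments at evenly spaced crown-trait
  quantiles (so every stage has crowns available), niche width set from the
  adjacent spacing so stages sit `env_separation` (default 4) niche widths
  apart. *mixed* halves the separation.
* *dispersal_limitation* — whole crowns are partitioned into disjoint
  regional pools at random with respect to the phylogeny; each stage draws
  only from its pool, so cross-pool pairs show complete taxonomic turnover
  without a phylogenetic signal.
* *neutral_drift* — uniform fitness over a long-tailed lognormal pool
  (σ = 2), samples generated as a serial multinomial resampling chain,
  i.e. drift under full connectivity.

**What passing these tests shows — and does not.** Parameter recovery on
these scenarios demonstrates that the statistics respond to the processes
they are designed to detect, with correct sign and calibrated nulls, at
sizes (hundreds of taxa, dozens of samples) far below a real survey. It
does not validate the ecological interpretation of any particular field
dataset: real communities mix processes, real trees violate strict niche
conservatism at some depths, and detection power grows with richness, so
absolute percentages from desk-scale runs are not comparable to
study-scale ones.

## Numerical conventions and degenerate inputs

* Every stochastic routine takes a seed or `numpy.random.Generator`;
  identical seeds give bit-identical outputs (tested).
* Rarity boundary: rare uses ≤ cutoff, common uses >.
* βNTI with null sd = 0 → NaN + warning; empty communities are errors.
* RC ties count at half weight; RC is exactly ±1 when the observed value
  is beyond every null draw.
* Chao1 of an all-zero vector is 0; `predict_frequency` rejects p ∈ {0, 1}
  (degenerate Beta).
* PCoA eigenvalues below `max(λ) × 1e−12` are treated as null axes.
* The acceptance harness and defaults use 199–999 null replicates and
  desk-scale community sizes (≈ 200 taxa, 12–60 samples, depth 2 000 for
  scenario recovery); these sizes were chosen so the full battery runs on a
  laptop-class single core in minutes while leaving the statistics enough
  power.

## Known limitations

* Diversification is not modelled or quantified; the five-process scheme
  attributes all turnover to selection, dispersal, and drift.
* The PERMANOVA is one-factor (no sequential sums of squares /
  interactions).
* The Sloan fit provides no confidence interval on m beyond the planned
  bootstrap flag; the threshold-approximation bias described above applies
  to any data with true multinomial read sampling.
* The βNTI power analysis above implies results on very small trees
  (< ~100 taxa) or very shallow samples should be read with caution: the
  null standard deviation is large and homogeneous selection is
  systematically harder to detect than variable selection.
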