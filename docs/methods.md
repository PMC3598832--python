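# Methods

This note records the statistical models implemented in `phylodiet`, the
conventions and defaults chosen where the methodology left genuine latitude,
and what the synthetic-data tests do and do not establish about real data.

## Data model and transforms

A dataset is a rooted bifurcating tree with branch lengths, a per-species
table of mean standard length (SL, mm), mean intestinal length (IL, mm), and
volumetric percent animal prey, and a categorical adult intestinal
configuration.  Lengths are log10-transformed before any regression.  Diet
percentages are arcsine-transformed; the package implements both
conventions in use:

* `arcsine_sqrt=True` (package default): arcsin(√(p/100)), the standard
  variance stabiliser for proportions;
* `arcsine_sqrt=False`: arcsin(p/100), a plain-arcsine variant that some
  published analyses applied.

Both are in radians (degrees available).  **Reproducibility note.**  From the
packaged species means, the naive RMA analysis gives r² = 0.716,
slope = −2.34 under plain arcsine and r² = 0.778, slope = −2.07 under
arcsine-sqrt.  The published analysis reports r² = 0.72, slope = −1.50.
Plain arcsine therefore reproduces the published variance explained at its
printed precision and is the convention the acceptance script documents and
reports; the published slope is not recoverable from the printed species
means under any transform convention we examined (degrees, natural logs,
relative intestinal length, swapped axes, OLS-variant slopes).  The pattern
across the published sensitivity fits — slope magnitude rising as r² falls —
implies a residual spread about 50% larger than the printed means produce,
consistent with residuals derived from specimen-level measurements that were
not published.  The slope discrepancy is reported as-is rather than adjusted.

Relative intestinal length (RIL = IL/SL) is computed for comparison with the
older descriptive literature but enters no inference.

## Phylogenetic size correction

Intestinal length is size-corrected by GLS regression of log10 IL on log10
SL with error covariance the Brownian matrix **C** of the tree (entry (i, j)
= root-to-MRCA shared path length).  Residuals are raw (y − Xβ̂), not
studentized, because they are reused downstream as a trait in their own
right.  On a star phylogeny this reduces exactly to OLS, and the residuals
are invariant to uniform rescaling of branch lengths (both are asserted in
tests).  The GLS r² is computed in the C⁻¹ metric and is diagnostic only.
By default the sensitivity analyses reuse the residuals estimated on the
input tree rather than re-estimating them under each arbitrary branch-length
scheme (`recompute_residuals=True` switches this), since the scheme
transforms are a robustness probe for the contrasts, not a rival estimate of
the allometry.

## Independent contrasts

The pruning recursion: at an internal node with child values (x₁, v₁),
(x₂, v₂), the contrast x₁ − x₂ has variance v₁ + v₂; the node value is the
variance-weighted average and the parent branch is lengthened by
v₁v₂/(v₁+v₂).  Contrast signs are arbitrary, so paired contrasts are
analysed through the origin: r = Σu_xu_y/√(Σu_x²Σu_y²), RMA slope
sign(r)·√(Σu_y²/Σu_x²), and the t test uses df = n_contrasts − 1.  The
published count of negative contrasts is well-defined only under a sign
convention; `positivize` flips each pair so the intestinal-length contrast
is ≥ 0, after which counting negative diet contrasts equals counting
opposite-sign pairs (r and |slope| are invariant).  The branch-length
adequacy diagnostic correlates |standardized contrast| with contrast SD;
p > 0.05 is reported as adequate.  Zero-length branches below a node make
standardization impossible and raise an error; no epsilon padding is
applied.

Orientation: diet is the response (y) and size-corrected intestinal length
the predictor (x), matching the "variance in diet explained" phrasing of the
study; both orientations are exposed and RMA slopes are reciprocal under the
swap.

## Phylogenetic signal

Blomberg's K uses the standard ratio estimator with the GLS root estimate â:
K = [(eᵀe)/(eᵀC⁻¹e)] ÷ [(tr C − n/(1ᵀC⁻¹1))/(n−1)], e = y − â1.  K is
affinely invariant and equals 1 exactly on a star tree.  Significance comes
from shuffling trait values across tips (default 1000 permutations, +1
correction so p > 0).  Two tails are reported because the literature states
the test both ways: the upper-tail test on K itself ("observed K greater
than 95% of randomizations") and the standard lower-tail test on the
variance of standardized contrasts (Σu²/(n−1), the "observed PIC variance").
The two agree in direction on signal-bearing data.  The permutation seed
defaults to 20130225 and is always recorded in the output.

Pagel's λ multiplies the off-diagonal entries of C.  The profile
log-likelihood (analytic in the mean and rate) is maximized by bounded
scalar search (tolerance 1e-8) on [0, λ_max], where λ_max keeps every tip
variance at least as large as the largest shared covariance — this permits
λ > 1 on trees where that bound exceeds 1.  The optimizer is checked against
a 2001-point grid oracle in the tests.  LRTs against λ = 0 and λ = 1 use
χ²(1).

## Ancestral state reconstruction

Adult intestinal configuration is coded as a seven-state unordered character
(two_loop, six_loop, pingalla_type, scortum_type, syncomistes_type,
aheneus_type, helotes_type), with a binary collapse (complex vs two_loop)
for counting origins.  The seven-state alphabet is a faithful reading of the
described coiling patterns; the exact state list used in the original
character matrix was not published.

*Parsimony*: Sankoff dynamic programming with unit costs; MPR sets from the
down-pass plus up-pass (state s is in the set iff some most-parsimonious
labeling places s at that node); |set| > 1 is equivocal.  Gains/losses of
the binary character are counted on one most-parsimonious labeling resolved
by preferring the parent's state at equivocal nodes (accelerated-
transformation flavour; the root prefers the ancestral state).  For binary
characters gains + losses equals the tree length, which the enumeration
oracle verifies on all small cases.

*Likelihood*: the Mk1 model (single symmetric rate q among k states) with
the closed-form transition probability P_ii(t) = 1/k + (k−1)/k·e^(−kqt),
P_ij(t) = (1 − e^(−kqt))/k, uniform root prior (the conventional default for
this model), and q fitted by bounded search on a log scale.  Marginal state
likelihoods at each node combine the subtree partials with the complementary
partials of the rest of the tree (equivalent to rerooting, which the
symmetric model's reversibility licenses).  A state is assigned only when
its log-likelihood beats every alternative by ≥ 2 natural-log units (e² ≈
7.39 ≈ "7.4 times more probable"); otherwise equivocal.  Natural logs are
used for the rule, which is what makes the 7.4 gloss come out.

*Trace over trees*: each reference-tree node is matched across the tree set
by exact equality of descendant tip sets (no partial matching); over the
trees containing the clade, the frequency of each uniquely best state
(singleton MPR set, or 2-log-unit ML winner) and of equivocal
reconstructions is reported, with n = 0 flagged for nodes present in no
tree.

## Branch-length schemes

Four arbitrary schemes for sensitivity analysis: all branches 1.0
(speciational); and three "contemporaneous tips" schemes assigning node
heights — 1 + maximum internode count to a tip; number of descendant tips
− 1; log of number of descendant tips — with branch length = parent height −
child height (positive by construction, ultrametric by construction).  The
log-tips scheme uses natural log by default (the naming of these schemes in
the literature is not perfectly consistent; the mapping used here is the one
documented above, and the log base is configurable).

## Synthetic data

The generator emulates the study's structure: a birth-death tree conditioned
on n extant tips (default 29, pure birth), extended past the n-th
speciation by the waiting time to the next event so the Yule depth
expectation Σ_{k=2..n} 1/(λk) holds, and rescaled to unit height; log10 SL
by Brownian motion (σ² = 0.05, tip SD ≈ 0.22, matching the real table);
log10 IL = −0.79 + 1.46·log10 SL + Brownian residual (coefficients from the
packaged table's OLS fit); diet generated on the arcsine scale as
base + b·residual + noise, clipped to [0, π/2] and back-transformed, so
percentages respect [0, 100] without truncation artifacts.  With b = −1.2
and noise SD 0.2 the implied tip-level RMA slope is −√(1.2² + 0.2²/0.05) =
−1.50 with ≈ 0.64 of diet variance explained — the scale of the real
analysis.  Configuration states evolve by the symmetric jump process
(default 3 states, rate 0.3 per unit height: rare transitions).  A
"posterior" stand-in applies nearest-neighbour-interchange jitter and
lognormal branch-length noise to the generating tree; it makes no attempt
to mimic a real Bayesian posterior's geometry.  All generators are pure
functions of (config, seed); per-stage child seeds derive deterministically
from the single configuration seed.

What passing the synthetic suite shows: the estimators recover their
generating parameters at the study's scale (slope coverage, K and λ
calibration, nominal type-I error of the permutation test) and the discrete
reconstructions agree exactly with enumeration oracles on small trees.  What
it does not show: robustness to measurement error in species means, to
non-Brownian trait evolution, to diet distributions more U-shaped than the
generator's, or to posterior tree sets with realistic correlation structure.

## Problem sizes and numerical choices

Simulation-based tests use 100–500 replicates at 12–29 tips, chosen to pin
Monte-Carlo standard errors well below the tolerances being asserted;
enumeration oracles cover all trees ≤ 6 tips and ≤ 3 states (500 random
cases).  The λ optimizer tolerance is 1e-8; GLS solves go through
statsmodels with an explicit condition-number guard (> 1e12 raises, with a
hint to check for duplicated or zero-length tips).  Ties in parsimony
resolution and the root-state preference are deterministic and stated in
the output metadata.  Reports are byte-reproducible given identical inputs
and seed.

## Known limitations

* The fixture topology is a transcription of a published figure; its marine
  grade's internal arrangement is constrained only loosely by the source
  text.  The comparative conclusions asserted in tests (origin counts, sign
  and strength of the diet association) are robust to that uncertainty; the
  branch-length-dependent statistics (K, λ, PIC r² on the chronogram) are
  not reproducible without the archived tree and are tested as such.
* Species means are taken as given; no specimen-level aggregation is
  performed (specimen data unpublished), which is also the likely source of
  the naive-slope discrepancy documented above.
* No λ-style joint optimization inside the size-correction GLS, no
  asymmetric Mk models, and no stochastic character mapping.
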