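# Methods

`landbridge` implements a land-bridge-calibrated Bayesian coalescent dating
analysis for intraspecific mitochondrial data: a single non-recombining
locus, contemporaneous samples, and node-age calibrations derived from the
opening and closing of post-glacial land connections.  This note records the
models, the numerical choices, the synthetic world the tests run in, and
what a passing test does and does not establish.

## The probabilistic model

The joint density targeted by the sampler factorizes as

```
p(D, T, phi) = L(D | T, r, phi_subst)^beta
               x p_coal(T | phi_demog)
               x p_cal(T)
               x p(phi)
               x p_UCLN(branch multipliers)
```

with `beta = 1` for posterior sampling, `beta = 0` (or no data) for
prior-only sampling, and intermediate values for power posteriors.

**Sequence likelihood.**  Partitioned HKY+Γ: codon positions 1+2 share one
HKY matrix, gamma shape and relative rate; position 3 has its own.  Rate
heterogeneity uses 4 discrete gamma categories with *category means*
(renormalized to average exactly 1), the common default in Bayesian dating
software; medians are not offered.  Partition relative rates are constrained
to a site-weighted mean of 1 so the clock rate keeps its units.  The pruning
recursion runs over compressed site patterns; partial likelihoods are
rescaled per pattern and the scaling logs accumulated, so hundreds of taxa
do not underflow.  Branch substitution lengths are
`duration_years x mean_rate x branch_multiplier`; under the strict clock all
multipliers are 1, under the UCLN relaxed clock they are iid lognormal with
real-space mean 1 (log-mean `-sigma^2/2`).

**Tree prior.**  Population size is the composite `N_ef x T` (female
effective size times generation time), in years, because that is the only
quantity a single maternal locus identifies; the pairwise coalescence rate
at time `t` is `1/N(t)` per year.  Three forms: constant; "expansion"
`N(t) = theta0 (f + (1-f) e^{-g t})` backwards in time, where `f = 0` is
pure exponential growth and `f > 0` adds an ancestral asymptote (both common
readings of the name "expansion growth" are therefore available; inference
defaults to `f = 0`); and the classic Bayesian skyline: piecewise-constant
`N` over groups of coalescent intervals, with the group boundaries at
coalescent events.  All coalescent integrals are closed-form.

**Calibrations.**  Two families, in years BP:

* truncated normal on a clade's tMRCA with hard bounds — the land-bridge
  window.  Defaults encode the southern-Scandinavian colonization window:
  hard bounds 9 200 and 13 100 years BP.  The location of the normal is not
  determined by the geology; the default is the window midpoint (11 150)
  with sd 1 000 years, which puts ~95% of the untruncated mass inside the
  window.  Sensitivity to this choice is a config knob, not a resolved
  question.
* offset gamma on the root age with a hard minimum (default 14 685 years BP,
  the post-glacial warming) and shape 2, with the scale chosen so the mode
  sits at a stated peak — presets at 145 000 (default), 24 000 and 450 000
  years BP.

Monophyly of a calibrated taxon set is enforced by default (states violating
it have zero prior mass); this is configurable because the original analysis
does not state whether it constrained monophyly.

**Parameter priors** (all proper, as required for marginal likelihoods):
lognormal on the clock rate (median 5e-7, log-sd 1.5), lognormal on kappa
(BEAST-style 1.0/1.25), exponential(mean 1) on the gamma shapes, lognormal
on the partition rate ratio, lognormal on theta (median 20 000 years,
log-sd 2), exponential(mean 2e-4 /year) on the growth rate, exponential
(mean 1/3) on the UCLN sd.  All are configurable on `ModelConfig`.

## The sampler

Single-site Metropolis–Hastings with these operators: uniform node-age moves
within the parent/children bracket; root and whole-tree scaling; a
rate-versus-ages "updown" move and a ridge "updown" that also scales theta
(the rate–age–theta ridge is the slow direction of this posterior; without a
joint move desk-scale chains do not mix); a symmetric subtree-exchange
topology move (an ordered node pair is drawn uniformly, their parents
swapped, invalid proposals rejected — symmetric by construction, so the
Hastings ratio is 1); multiplicative scale moves for scalars; a two-state
frequency shuffle; UCLN multiplier scale and swap moves; skyline group-theta
scale and group-boundary shift moves.  Scale factors are tuned toward 23%
acceptance during burn-in only (Robbins–Monro), so the retained chain
satisfies detailed balance; tuned values, acceptance counts and any
zero-acceptance warnings are recorded in the trace metadata.  Every chain is
a pure function of (config, data, seed): identical inputs give bit-identical
traces.

The three-tip prior-sampling test (root age against the hypoexponential
closed form) is the detailed-balance smoke test for the age and topology
moves jointly; the prior-only single-calibration test checks that hard
bounds and the calibration density are honoured exactly.

**Induced joint priors.**  With more than one node calibration the joint
prior induces marginals that differ from the individually specified
densities.  `induced_prior_report` quantifies this divergence (specified vs
sampled mean/sd, KS distance) from a prior-only run; it deliberately reports
rather than asserts, since the divergence is a property of the model, not a
bug.  The posterior-vs-prior KS test establishes that the data, not the
calibration geometry, drive the posterior root age.

## Marginal likelihoods and model comparison

Power posteriors along `beta_k = (k/(K-1))^{1/0.3}` (quantiles of
Beta(0.3, 1); the second Beta parameter is not stated in the source analysis
and 1.0 is the conventional choice that gives this closed form).  Chains
descend from `beta = 1`, each rung starting at the previous rung's final
state, with extra burn-in on the first rung.  Path sampling integrates the
mean log-likelihood over beta by the trapezoid rule; stepping-stone
multiplies importance ratios estimated at the lower rung of each pair, in
log-sum-exp arithmetic.  The agreement of the two estimators is the
convergence diagnostic, mirroring the original analysis.  Bayes factors are
reported as natural logs with the conventional interpretation bands
((0,1] barely worth mentioning, (1,3] positive, (3,5] strong, >5 very
strong; boundary values take the weaker label; negative values favour the
second model with the mirrored label).

Desk-scale ladders (10–24 steps x around a thousand generations) reproduce
sign-level and band-level conclusions in the acceptance tests; they are two
to three orders of magnitude below a production run (1 000 steps x 100 000
generations), and absolute log-ML values at desk scale carry Monte Carlo
error of order 1.

## Neutrality statistics and their null

Nucleotide diversity is the mean Jin–Nei gamma-corrected K2P distance over
all sequence pairs (shape 0.1705 by default), with a standard error from
resampling alignment *columns* with replacement (the MEGA convention; the
source text does not say which axis was resampled, and this choice is
flagged, not attributed).  Saturated pairs raise an error naming the pair
rather than being dropped.

Tajima's D and Fu's F_S intentionally use uncorrected difference counts:
their variance theory is infinite-sites.  F_S uses the Ewens sampling
formula with unsigned Stirling numbers of the first kind computed by the
log-space recurrence (exact to double precision for any n used here);
haplotype counting is literal string identity after uppercasing, so
sequences differing only in ambiguity codes are distinct haplotypes.

Significance conditions on the observed number of segregating sites S: S
mutations are dropped onto simulated constant-size genealogies with
probability proportional to branch length, the statistic is recomputed per
replicate, and the p-value is the lower-tail proportion (negative values
signal expansion; a two-tailed variant doubles the smaller tail).  The D
null path computes the statistic directly from subtree sizes — exactly
equivalent to materializing infinite-sites alignments, and fast enough to
calibrate the test's type-I error over 2 000 datasets in the suite.  A
p-value of zero is reported with the label `<1/n_sims`.

## The synthetic world

The generator emulates the study system: six monophyletic clades founded
near-contemporaneously at 12 000 years BP from a root at 23 000 years BP,
contemporaneous tips, 1 143 sites with codon-position rate structure
(kappa 8 and 20, gamma shapes 0.5, third positions 8x faster, mitochondrial
base composition), strict clock at 4.5e-7 substitutions/site/year.  Within a
clade, the population holds at `N_ef x T = 30 000` years until 800 years
before the radiation and then drops to a founder phase of 250 years — a
founder bottleneck at the radiation.  This makes the clade gene TMRCAs pile
up just below 12 000 BP, which is what "near-contemporaneous radiation"
means at the gene level; an earlier smooth-expansion parameterization let
TMRCAs drift to 5–9 ka and contradicted the stated world.  The calibrated
clade's TMRCA is additionally conditioned into the land-bridge window
(rarely binding under the bottleneck world); this mirrors the calibration's
own premise — the analysis assumes the window statement is true.  Backbone
splits fall within 1 000 years above the radiation; the root age is exact.

What the generator does **not** emulate: heterochronous sampling (museum
specimens span decades; the spec's assumption that this is negligible at
~1% of node ages is adopted), geographic structure within clades, selection,
rate time-dependence, sequencing error and alignment gaps (ambiguity
handling is exercised by dedicated unit tests instead).  A green recovery
test therefore establishes internal consistency of simulator + likelihood +
sampler under the stated world, not robustness to those real-data features.

Recovery experiments fix the topology at truth (a documented fast path; the
topology move is validated separately), fix the substitution nuisance
parameters at truth, and use the 24 ka root-peak calibration variant because
the synthetic root is at the LGM — choosing among the source analysis's own
sensitivity presets on scientific grounds.  The demographic-model-recovery
and skyline experiments similarly fix rate and substitution parameters so
the Bayes factor and the skyline isolate demography.

## Numerical notes

* HKY transition probabilities come from the symmetric eigendecomposition of
  `D^{1/2} Q D^{-1/2}`; tiny negative entries from roundoff are clamped to 0.
* The pruning inner loop is numba-compiled (with an equivalent vectorized
  numpy fallback); both paths agree to 1e-14.
* ESS uses FFT autocovariances truncated at the first non-positive
  autocorrelation; constant series report ESS = N with a degeneracy flag.
* HPD intervals are the shortest window of `ceil(p N)` sorted samples, ties
  broken toward the lower start.
* The MCC tree maximizes the sum of log clade frequencies over sampled
  trees; node ages are annotated with the median and 95% HPD over the
  samples containing that clade.
* Skyline curves are pointwise (per-grid-time) summaries on a grid from 0 to
  the posterior median root age; stepwise (piecewise-constant) variant only.
  The API default group count is 10 with `m <= n-1` enforced; desk-scale
  runs in the tests use 4–8 groups.
* Degenerate inputs raise typed errors (`InvalidInputError`,
  `SaturationError`, `UndefinedStatisticError`, `DegenerateComparisonError`)
  rather than returning sentinel values.

## Known limitations

* Single-site MH with full likelihood recomputation: production-scale data
  (hundreds of taxa, 10^8 generations) is out of reach; chain lengths here
  are desk-scale and the headline numbers of the original study are not
  reproduced, only the methodology.
* The subtree-exchange topology move mixes slowly on large trees; recovery
  tests use fixed topologies and topology inference is validated only on
  small trees.
* No invariant-sites category, no GTR family, no structured coalescent,
  no recombination, no serially sampled tips.
* Marginal-likelihood estimates at desk scale have O(1) Monte Carlo error;
  only band-level Bayes-factor conclusions are meaningful there.
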