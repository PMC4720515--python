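# Methods

## Drift and drift-variance

Expression is depth-normalized to counts per million (CPM); gene length is
not corrected because drift only ever compares the same gene across samples.
Transcriptional drift of gene *g* at age *t* is

    td_g(t) = log_b( (cpm_g(t) + c) / (ref_g + c) )

with log base *b* ∈ {2, e, 10} (default 2) and pseudocount *c* (default
0.5 cpm). Changing *b* rescales every td by a constant and drift-variance by
its square; all dispersion-test p-values are invariant to it, so the choice
only affects plot scales. Drift-variance of a group of *n* drift values is
the *n−1*-denominator sample variance. When a group pools several replicate
samples, all of their per-gene td values enter one pooled variance.

**Young reference.** Two constructions are supported. *Pooled-mean* averages
all replicates at the reference age per gene; it is the more robust
denominator but makes the reference-age group self-referential, so those
groups are flagged and the API refuses to use them in dispersion tests
rather than trusting the caller. *Holdout* sets aside named samples (or,
deterministically, the first reference-age sample) as the reference; held-out
samples are removed from all downstream analysis, and the remaining
reference-age replicates yield an honest young-age variance. For designs
whose young samples span a range of ages (e.g. human donors under 30), the
reference pool may be defined by a maximum age instead of an exact one.

**Zero handling.** Genes not detected (zero) in every reference-constituent
sample are dropped, not imputed — a minimum-detection filter recorded in the
drift matrix's provenance. The pseudocount guards residual zeros at later
ages. With pseudocount 0 the computation refuses zero ratios. Both knobs are
recorded in the result object.

**Box-plot convention.** Tukey summaries use type-7 (linear interpolation)
quartiles and whiskers at the most extreme observations within 1.5·IQR of
the box. Outliers beyond the whiskers are counted for display only; the
variance is always computed over all values.

**Age binning** is half-open ([lo, hi), overflow bin above the last edge);
an age below the first edge is an error rather than a silent drop.

**Sample distances.** The MDS view uses leading log-fold-change distances:
for each sample pair, the root-mean-square of the top-*n* (default 500)
largest absolute log2 fold-changes, followed by classical (Torgerson)
metric scaling. Coordinates are defined only up to rotation/reflection, so
tests compare distance matrices, not raw coordinates.

## Statistical tests

**Robust Levene.** Each observation is replaced by its absolute deviation
from a robust center of its group; a one-way ANOVA F on the deviations gives
W and p. The default center is a 10% trimmed mean — 10% trimmed from *each*
tail before averaging — which removes large outliers from the center
estimate while keeping every observation in the deviations. `trim=0` with a
mean center reduces exactly to classical Levene, with a median center to
classical Brown–Forsythe (both verified against scipy). Levene-family tests
are mildly anti-conservative in small groups (~6.5% type-I at n=30,
α=0.05); drift comparisons pool hundreds to thousands of per-gene values
per group, where calibration is accurate.

**t-tests** default to Welch (unequal variance, Welch–Satterthwaite df);
back-computing published worked examples from their printed replicate
values matches the Welch form, not the pooled form, which remains available.
Two groups with zero variance and equal means return p = 1, flagged
degenerate.

**Exact binomial test.** Tails are summed in log space (gammaln +
logsumexp), so extreme results (e.g. 15,095 successes of 19,169 at p₀=0.5)
never underflow; reported p-values are floored at 1e-300 and never 0. The
two-sided p doubles the smaller tail (capped at 1), which at p₀ = 0.5
coincides with the sum of all outcomes no more likely than the observed one.

**Attenuation calls.** A gene is *attenuated* when the treated arm stays
closer to the young reference than age-matched controls. The default rule
compares the per-age |mean td| averaged over shared ages
(`mean_abs_td`); a `per_age_majority` alternative requires the treated
magnitude to be smaller at a majority of ages. The attenuated count k of n
genes is tested against the coin-flip null with the exact binomial test.
The choice of aggregation rule moves individual boundary genes but not the
orders-of-magnitude binomial significance these analyses produce.

## Mortality

The Gompertz hazard h(t) = A·e^{Gt} (A baseline hazard in 1/day, G the
rate of aging in 1/day) has survival S(t) = exp(−(A/G)(e^{Gt}−1)) and mean
lifespan (1/G)·e^{A/G}·E₁(A/G); G → 0 degenerates to the exponential
distribution. Fitting is by maximum likelihood on death times with
right-censoring, parameterized on (log A, log G) so positivity is
structural, with multiple starts; the smoothed log-hazard regression route
is retained as a diagnostic only, because MLE is markedly more stable in
small cohorts. Fits are refused below 20 uncensored deaths.

Empirical hazard curves are deaths per animal-day at risk on the recorded
scoring grid, smoothed by a centered moving average (default window 3 days,
matching thrice-weekly scoring; a window no wider than the scoring interval
is the identity).

Treatment effects are modelled as an *additive day-shift* of death times —
two cohorts aging at the same rate but offset in time, which displaces the
log-mortality curve horizontally without changing its slope. A
hazard-ratio alternative is not the default because observed long-lived
cohorts show parallel, not steeper/shallower, log-mortality.

**Power.** Monte-Carlo: each replicate simulates a control and a shifted
cohort by inverse-CDF sampling and applies the Mantel–Haenszel log-rank
test (lifelines implementation; hypergeometric tie variance); power is the
detection fraction with a Wilson 95% interval. The acceptance computation
uses G = 0.35/day with A solved so mean lifespan is 19.8 days, 1,500 animals
per arm, a 1-day effect, α = 0.01 and 500 replicates — about ten seconds of
compute; the ≥90% power conclusion is insensitive to G anywhere in
[0.2, 0.5]/day.

## Synthetic data

The generator emulates the structure the analysis assumes. Each gene has a
direction s_g ∈ {−1, +1} (P(+) = 0.5 by default: balanced opposing
directions) and rate r_g = |N(0.10, 0.05)| log2-units per day; systematic
drift follows the clock u(t) = (t − t_ref)^γ (γ = 1 by default — roughly
linear growth on the day scale; the true growth law is unknown, and γ is
exposed), so td is exactly 0 at the reference age as the definition
requires. Replicate noise is Gaussian (sd 0.10). A treatment started at age
t_s scales drift accrued after t_s by (1 − a), a ∈ [0, 1]. Expected
expression is baseline·2^td with baselines log-normal (log2 cpm ~ N(4, 2));
counts are negative-binomial (dispersion 0.05; 0 = Poisson) at log-normal
library sizes around 25 million reads. Default design: 19,196 genes, ages
1/3/5/10 days in triplicate, mirroring a worm adult time course. All
randomness flows from one seed through named, crc32-keyed child streams, so
sub-results are independently reproducible.

Closed-form truth: untreated drift-variance at age t is
Var(s·r)·u(t)² + noise_sd² plus a count-noise term that shrinks with depth.
Recovery tests that compare against this truth run at deep coverage and
pseudocount 0, where the neglected count-noise and shrinkage terms are
negligible; default-noise behavior is exercised by calibration and ordering
tests instead.

A `random_walk` mode replaces the deterministic trend with accumulating
noisy increments of the same mean path, for analyses that should not depend
on whether drift is a program or a stochastic walk.

What the generator does *not* emulate: compositional coupling beyond the
CPM constraint, gene–gene correlation within pathways, batch effects,
age-dependent library quality, or egg/germline contamination of whole-animal
samples. Passing recovery tests therefore demonstrate internal consistency
of the pipeline under the stated noise model, not robustness to those
real-data artifacts.

## Numerical choices and limitations

- Variances use two-pass (numpy) summation; the drift-variance contract is
  agreement with a brute-force two-pass oracle to 1e-12.
- Text matrix round-trips use Python's shortest round-tripping float repr,
  so write∘read is bit-identical.
- Power and calibration numbers are Monte-Carlo estimates; suites pin seeds
  and use bands sized to the replicate counts they run.
- The reproduction recipes for published external data sets execute the
  documented preprocessing (reference construction, binning, two-channel
  ratios) but necessarily inherit any unstated upstream filtering of those
  data sets; gene universes may differ slightly from published counts.
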