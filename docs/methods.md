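# Methods

`abcsnp` implements likelihood-free (ABC) inference of demographic history
from a matrix of biallelic SNP genotypes whose individuals are assigned to a
small number of genetic groups. This note records the model, the numerical
choices, and what the synthetic study conditions do and do not establish.

## Demographic model and scenarios

A scenario is a rooted history of five sampled demes plus an ancestor,
expressed as a backward-time event list. Two event kinds are supported:
divergence (all lineages of one deme join another at time `t`) and admixture
(each lineage of a dissolving deme joins parent 1 with probability `ra`,
else parent 2). Deme sizes are constant between events; the surviving deme
takes the ancestral size `NA` at the final event. Continuous migration,
growth, and bottleneck size changes are deliberately out of scope.

The shipped registry holds eight scenarios over the groups SOUTHERN (Pop1),
LOWER-CENTRAL (Pop2), UPPER-CENTRAL (Pop3), EASTERN (Pop4), NORTHERN (Pop5).
Scenario 1 — the history the synthetic observed dataset is generated from —
splits LOWER-CENTRAL from an UPPER-CENTRAL trunk at `t1`, NORTHERN at `t2`,
EASTERN at `t3`, and the basal SOUTHERN group at `t4`, where the trunk takes
size `NA`. Scenario 2 swaps the NORTHERN/EASTERN split order. Scenarios 3-4
replace the `t1` divergence with an admixture origin of LOWER-CENTRAL from
the trunk and SOUTHERN (rate `ra`); scenarios 5-8 mirror 1-4 with
LOWER-CENTRAL as the trunk. Only the topologies of scenarios 1 and 2 are
fixed by design; the others are provisional defaults, declared in a
config-file DSL (JSON/YAML) so they can be replaced without code changes.
Across the registry the parameter union is exactly
{NA, N1-N5, t1-t4, ra} — eleven parameters.

Note that scenarios 3 and 7 nest their divergence counterparts (`ra -> 1`
recovers a pure split), so scenario choice among these candidates is
intrinsically hard; this is visible in the prior error rates below.

## Priors

Uniform priors: effective sizes `N ~ U(10, 6e5)` diploid individuals,
divergence times `t ~ U(10, 1e3)` generations with the order constraint
`t1 < t2 < t3 < t4`, admixture rate `ra ~ U(1e-3, 0.999)`. The order
constraint is enforced by jointly redrawing the four times until ordered,
which is exactly uniform on the order polytope (acceptance probability
1/4! — rejection cannot stall for non-degenerate bounds). Sizes and times
are sampled as continuous values; at these scales the distinction from
integer sampling is immaterial.

One reconciliation deserves emphasis. The default time prior tops out at
1e3 generations, yet the assumed truth used by the synthetic observed
dataset places `t4` at 1.26e3 generations — the posterior-mean value the
package's recovery tests treat as the generating truth. A posterior mean can
only exceed a prior bound if the analysis that produced it used a wider
prior, so for every run that treats those values as truth (the recovery
tests and the acceptance script) the package uses `t ~ U(10, 2.5e3)`. This
is a self-consistency requirement, not a tuning decision: with the narrower
default prior the truth would lie outside the support of any posterior and
no estimator could cover it.

## Coalescent simulator

Each locus is an independent structured-coalescent genealogy: within a deme
of diploid size `N`, each lineage pair coalesces at rate `1/(2N)` per
generation (continuous-time exponential approximation — standard at these
`N` and `t` scales — rather than generation-by-generation Wright-Fisher).
One mutation per locus is placed uniformly over total branch length with the
root branch excluded, so every locus segregates in the pooled sample; no
additional minor-allele-frequency rejection is applied (an optional knob
exists for sensitivity analysis). Gene copies are paired into diploids in
sampling order within demes, which by exchangeability is equivalent to
random pairing. Derived/ancestral polarity is tracked internally but every
shipped statistic is polarity-invariant, so unpolarized data are handled
identically.

The per-tree algorithm is O(n) in the sample size per locus and is compiled
with numba; a 124-individual, 693-locus dataset simulates in ~20 ms, which
is what makes reference tables of 10^4-10^5 rows practical on one core. The
simulator is cross-checked in the test suite against closed forms (E[T2] =
2N, E[L] = 4N·H(n-1), the 1/i site-frequency spectrum) and against msprime
on a two-deme split model.

## Summary statistics

The observed or simulated dataset is reduced to a fixed-order vector:

* per-group mean gene diversity `H = n/(n-1)(1 - Σp²)` over **all** loci
  ("complete distribution" — monomorphic loci contribute 0);
* per-pair mean Weir & Cockerham (1984) θ̂ = a/(a+b+c), from the variance
  components with observed (not HWE-expected) heterozygote frequencies, over
  loci whose value is defined and non-zero. Negative estimates are retained:
  the non-zero rule is read literally, and zeroing them would bias the mean;
* per-pair mean Nei (1972) standard distance `-ln(Jxy/√(JxJy))` over defined
  non-zero loci (undefined when no allele is shared);
* per-trio mean frequency-interpolation admixture estimate
  `(pA - pP2)/(pP1 - pP2)`, unclipped, over defined non-zero loci.

With five groups and the default single trio (admixed LOWER-CENTRAL,
parents UPPER-CENTRAL and SOUTHERN — chosen to match the central-group
admixture hypothesis the scenario set encodes; configurable) the vector has
5 + 10 + 10 + 1 = 26 components. Undefined per-locus values propagate as
NaN sentinels and an empty contributing set raises rather than returning a
placeholder; table builders redraw such degenerate rows (essentially
impossible at 693 loci, routine in tiny toy tables) and count them.

## QC cascade

Raw matrices pass, in order: biallelic-only; individual missingness (< 30%
kept); pooled MAF (> 5% kept); an exact conditional Hardy-Weinberg test
(p ≤ .01 removed) on the pooled sample by default — the literal reading of
testing "each locus" — with a per-group mode available because pooled
testing under population structure rejects for the Wahlund effect; global
multi-group θ̂ outliers (θ̂ > 0.1 removed — the removal direction is the
interpretation consistent with unbiased demographic inference, and is
configurable); greedy all-pairs LD pruning at r² ≥ 0.8 on 0/1/2 dosages
with pairwise-complete correlation (GBS tags carry no genomic order, so no
windowing), dropping the higher-missingness member (ties: lower MAF, then
later locus id). Complete-case locus selection is a separate step used to
prepare the ABC input. Every stage returns a telescoping report.

## Scenario choice

The reference table holds one row per prior-predictive simulation:
scenario id, parameter draw, statistic vector. All statistics are
standardized by their reference-table standard deviation (MAD optional;
zero-variance columns are dropped with a warning) before Euclidean
distances.

*Direct approach*: posterior probability of a scenario = its share among the
k = 500 nearest rows; ties at the k-th distance break by row order. 95% CIs
are Clopper-Pearson on the counts — a convention, since the upstream method
does not state its interval construction.

*Logistic approach*: the closest 1% of rows is projected onto linear
discriminant axes (LDA refit within the subset); a multinomial logistic
regression of scenario label on the discriminant scores, weighted by an
Epanechnikov kernel with bandwidth equal to the largest accepted distance,
is evaluated at the observed point. The regression is fitted by Newton
iteration with a weak L2 penalty (λ = 1) on the coefficients: accepted
subsets at desk scale hold only tens of rows per scenario on up to seven
axes, where quasi-complete separation is routine and the unpenalized MLE
diverges; at production subset sizes the penalty is negligible relative to
the information matrix. 95% CIs come from the inverse penalized information
via the delta method.

*Prior error rate*: fresh pseudo-observed datasets (never resampled table
rows) are drawn from the prior under the true scenario; the error is the
fraction in which that scenario fails to attain the strictly highest
probability, with ties counted as errors (the conservative reading).

## Posterior estimation and model checking

Within the chosen scenario's rows, the closest 1% (at least 50 rows) is
retained. Each parameter is mapped by `logit((θ-a)/(b-a))` against its prior
bounds, regressed linearly on the standardized statistics with Epanechnikov
weights, and the weighted residuals are translated to the fitted value at
the observed point before back-transforming — adjusted draws therefore
always respect the prior bounds. Summaries are kernel-weighted: mean,
quantiles (.025, .05, .5, .95, .975), and a mode from a weighted Gaussian
KDE with Silverman bandwidth evaluated on a 512-point grid of the
back-transformed scale. Divergence times (generations) convert to years by
multiplying with the generation time, 8 years with a 6-10 year range.

A `rejection` adjustment mode skips the regression step and summarizes the
kernel-weighted accepted draws directly (classic rejection ABC); it is the
recommended diagnostic when the observed point lies outside the accepted
cloud, where the 27-coefficient local-linear fit must extrapolate and the
logit back-transform can saturate the adjusted draws onto a prior bound.

Model checking resamples parameter vectors from the weighted adjusted
posterior, simulates datasets, and locates the prior cloud, the
posterior-predictive cloud and the observed point in a PCA fitted on the
reference statistics standardized by their reference SD (all components, so
variance proportions sum to 1),
alongside per-statistic two-sided posterior-predictive tail probabilities.
The "less biased" variant restricts to a statistic family disjoint from the
ones driving estimation; the default split uses FST + gene diversities for
estimation and Nei + admixture statistics for checking.

## Synthetic study conditions

`make_observed` emulates the target study design: 124 diploids pooled from
nine populations of 12-15 individuals into five groups (28/41/27/14/14),
693 fully observed biallelic SNPs, simulated under scenario 1 with the
posterior-mean truth (NA = 5.98e5; N1..N5 = 3440, 2710, 2600, 681, 365;
t1..t4 = 261, 351, 629, 1260 generations). Using the inferred posterior
means as truth makes recovery tests double as a plausibility check of the
inference. `make_raw` plants known QC violations (low-MAF columns,
heterozygote-deficit columns, one-group-all-heterozygous high-FST columns
that deliberately pass the pooled HWE test, duplicated blocks, and
beta-distributed per-individual missingness with three high-missingness
individuals) on a base of loci rejection-sampled — under the same
missingness the filters will see — to pass every filter with a margin, so
each stage's removal set is known exactly. Every fixture regenerates
bit-identically from its truth record.

What the generator does **not** emulate: genotyping error, allele dropout,
linkage between GBS tags, within-group substructure beyond labels, or
ascertainment of the SNP panel. Passing tests therefore demonstrate the
correctness and internal calibration of the pipeline under its own model,
not robustness to real-data artifacts.

## Problem sizes and statistical power

The tests and the acceptance script run the analysis at desk scale,
chosen as the package's own default study conditions: reference tables of
2×10^4 rows for the estimation scenario and 1.5-2×10^3 rows per scenario
for model choice (the original analysis used ~10^6 per scenario), 100-200
pseudo-observed datasets, and 693-locus simulated observations. One
consequence is worth stating plainly: the synthetic observed dataset —
generated from small effective sizes under a prior whose mass lies at much
larger sizes — sits in the far tail of the prior predictive: the truth
corner (all five sizes near the 0.5% lower prior quantile with matching
ordered times) has joint prior mass of order 1e-10, so even the nearest of
2×10^4 reference rows is ~25 standardized units away. Three measured
consequences follow. The direct approach returns near-uniform scenario
probabilities. The logistic regression evaluates at an extrapolated point
and concentrates probability on the flexible admixture-bearing scenarios.
And posterior estimation cannot be calibrated at this truth: rejection
intervals miss it (the sampler never reaches the neighbourhood) while the
local-linear adjustment extrapolates into logit saturation and pins the
time posterior at the prior bound. All three shrink as the table grows, and
none arises when truth parameters are drawn from the prior (the setting in
which ABC coverage is guaranteed); at desk scale they are reported as
measured, not corrected.

Also note one distributional fact about the simulator that matters for
frequency-spectrum expectations: with exactly one mutation placed uniformly
per genealogy, the probability that the derived allele is a singleton is
E[external/total branch length] (0.3769 at n = 10, by independent
simulation), not the ratio-of-expectations 1/(i·H(n-1)) form (0.3535),
which describes mutation counts pooled over length-weighted trees.

## Known limitations

* Scenarios 3-8 topologies are provisional defaults (see above).
* The HWE pooled-sample default will flag structure-induced heterozygote
  deficits (Wahlund effect) as violations; use per-group mode when the
  group labels are trusted.
* The logistic CIs are asymptotic delta-method intervals from a penalized
  fit and are approximate in small subsets.
* No recombination or linked-locus support; loci are exchangeable and
  independent by construction.
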