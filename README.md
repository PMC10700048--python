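# abcsnp

Approximate Bayesian computation (ABC) for demographic-history inference
from biallelic SNP genotype matrices, built for small-population
phylogeography: a handful of genetic groups, a few hundred loci, and a set
of competing divergence/admixture histories to choose among and to date.

The package provides, end to end:

* a declarative **scenario DSL** (population splits and admixtures at
  symbolic times over five sampled demes plus an ancestor) with uniform
  priors `N ~ U(10, 6×10⁵)` diploids, `t ~ U(10, 10³)` generations under
  `t1 < t2 < t3 < t4`, and `ra ~ U(10⁻³, 0.999)`, plus a built-in registry
  of eight candidate histories exposing exactly eleven parameters;
* a fast Hudson-style **coalescent SNP simulator** (numba-compiled; one
  mutation per locus uniform on the genealogy, so every locus segregates);
* the 26-component **summary-statistic vector**: per-group mean gene
  diversity `H = n/(n−1)(1 − Σp²)`, pairwise Weir–Cockerham
  `θ̂ = a/(a+b+c)` and Nei distance `D = −ln(J_xy/√(J_x J_y))` averaged
  over non-zero loci, and a three-sample admixture estimate
  `(p_A − p_P2)/(p_P1 − p_P2)`;
* **scenario choice** by the direct approach (class share among the k = 500
  nearest reference rows, Clopper–Pearson CIs) and the logistic-regression
  approach (weighted multinomial regression on discriminant scores of the
  closest 1%, delta-method CIs), both exposed as a scikit-learn-style
  `ScenarioClassifier`;
* **prior error rates** from fresh pseudo-observed datasets;
* **posterior estimation** by Beaumont-style local-linear regression with
  logit transforms against the prior bounds (`PosteriorRegressor`),
  posterior-predictive **model checking** in PCA statistic space, and
  divergence-time **recalibration** into years via the generation time
  (8 years, range 6–10);
* a **QC cascade** for raw matrices (biallelic → individual missingness
  < 30% → MAF > 5% → exact Hardy–Weinberg p ≤ .01 → global θ̂ > 0.1
  outliers → LD pruning at r² ≥ 0.8, plus complete-case selection) with a
  telescoping report;
* a **synthetic-data generator** reproducing the target study design
  (124 individuals from 9 populations pooled into 5 groups × 693 SNPs)
  with exact planted-violation bookkeeping for the QC fixtures.

See `docs/methods.md` for the model, numerical choices, and limitations.

## Worked example

Simulate the synthetic observed dataset, build a small reference table, and
run scenario choice and parameter estimation:

```python
import numpy as np
import abcsnp as a

# 124 individuals x 693 SNPs generated under scenario 1
G, truth = a.make_observed(seed=7)
obs = a.compute_sumstats(G)          # 26 named statistics
print(G.genotypes.shape, len(obs))   # (124, 693) 26

priors = a.PriorSpec(t_bounds=(10, 2500))  # prior must contain the truth t4
ref = a.build_reference_table(a.builtin_scenarios(), priors,
                              a.default_groups(), n_loci=693,
                              n_per_scenario=500, seed=1)
res = a.direct_pp(ref, obs, k=500)
for sid, pp, (lo, hi) in zip(res.scenario_ids, res.pp, res.ci):
    print(f"scenario {sid}: PP = {pp:.3f} [{lo:.3f}-{hi:.3f}]")

est = a.estimate_parameters(ref, obs, scenario_id=1, fraction=0.2)
yrs = a.recalibrate_time(est.mean["t4"])
print(f"t4 = {est.mean['t4']:.0f} generations "
      f"= {yrs[0]:,.0f} years ({yrs[1]:,.0f}-{yrs[2]:,.0f})")
```

prints (seeds as above):

```
(124, 693) 26
scenario 1: PP = 0.126 [0.098-0.158]
scenario 2: PP = 0.122 [0.095-0.154]
scenario 3: PP = 0.122 [0.095-0.154]
scenario 4: PP = 0.120 [0.093-0.152]
scenario 5: PP = 0.136 [0.107-0.169]
scenario 6: PP = 0.144 [0.114-0.178]
scenario 7: PP = 0.112 [0.086-0.143]
scenario 8: PP = 0.118 [0.091-0.150]
t4 = 2491 generations = 19,930 years (14,948-24,913)
```

These numbers illustrate the scale sensitivity of ABC rather than a tidy
success story: at 500 rows per scenario the eight candidate histories are
indistinguishable (probabilities hover around 1/8 — the competitors differ
only in the order and nature of two splits), and the basal divergence time
overshoots its generating value of 1260 generations toward the prior's
upper bound, because the strongly drifted observed dataset lies in the far
tail of the prior predictive and the regression adjustment must
extrapolate (see `docs/methods.md`, "Problem sizes and statistical power";
`estimate_parameters(..., adjust="rejection")` is the recommended
diagnostic in that regime). The same pipeline
is available from the shell: `abcsnp synth observed`, `abcsnp refstable`,
`abcsnp modelchoice`, `abcsnp prior-error`, `abcsnp estimate`,
`abcsnp check`, and `abcsnp calibrate 1260`.

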