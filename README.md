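# devallometry

Allometric scaling of minimum development time in insects.

Ectotherm development speeds up with temperature until it reaches a minimum
development time (T_dev) at some optimal temperature (T_opt), beyond which
it slows again. The ontogenetic growth model of metabolic theory predicts
that development time scales with body mass as *t* ∝ *m*^0.25 — the
quarter-power law. Testing that prediction across hundreds of insect
species requires a pipeline of steps that each carry their own statistical
pitfalls, and this package implements all of them as a tested, reusable
library for comparative physiologists:

1. **Reaction-norm extraction** — reduce each species' development-time ×
   temperature measurements to the empirical minimum (T_dev, in days) and
   the temperature attaining it (T_opt, °C). No curve is fitted.
2. **Ensemble length→mass conversion** — convert body length (mm) to dry
   mass (mg) with every published order-specific power-law equation
   *m* = *a·L^b* and average the estimates; the spread feeds error
   propagation.
3. **Bivariate allometry** — fit ln T_dev on ln *m* by ordinary least
   squares (OLS) and standardized major axis (SMA, slope = sign(r)·s_y/s_x),
   each with a robust (Huber) variant, analytic 95% CIs, and a test of the
   hypothesized exponent *b*₀ = 0.25.
4. **Phylogenetic GLS** — refit with residual covariance induced by a
   phylogeny under four evolutionary models: {Brownian motion,
   Ornstein–Uhlenbeck exp(−α·d)} × branch lengths {all = 1, Grafen's
   transformation}, with α optimized by REML and the winner chosen by AIC;
   R² by the likelihood-ratio formula 1 − exp(−2ΔlnL/n).
5. **Factorial inference** — full-factorial models of ln T_dev on
   ln *m* × T_opt × order (OLS and PGLS), backward elimination of
   nonsignificant interactions by partial F-tests, sequential (Type-I)
   partial R², standardized predictions for a 1 mg insect at T_opt 25/35 °C,
   T_opt-binned SMA slopes, and a mass–T_opt independence check.
6. **Measurement-error resampling** — redraw each species' mass from
   Normal(mean, sd of the model ensemble) 10,000 times and refit, giving
   the distribution of scaling exponents under length→mass conversion error.
7. **Synthetic-data generation** — a seeded generator producing all three
   inputs (species table, equation table, Newick tree) from a known
   generative model, so every stage is testable end to end.

## Inputs

* a long-format species CSV: `species, order, family, length_mm,
  temperature_C, development_days, source` (lengths may be `min-max`
  ranges, stored as midpoints; column names are remappable via a dialect);
* a length–mass equation CSV: `scope, ln_intercept, exponent, source_id`
  with `scope` an order name or `general`;
* a Newick phylogeny whose tips match the species names (polytomies and
  missing branch lengths allowed).

## Worked example

```python
from devallometry import GeneratorConfig, generate_study, run_study

config = GeneratorConfig(n_species=120, n_orders=8, seed=42)
study = generate_study(config)                 # quarter-power ground truth
paths = study.write_inputs("demo_study")
res = run_study(paths["species"], paths["models"], paths["tree"],
                n_resample=1000, seed=42)
```

Printing the headline quantities of `res` gives:

```
species analysed: 120
OLS   slope 0.215  (95% CI 0.125-0.304, R2 0.16)
SMA   slope 0.536  (95% CI 0.454-0.633)
PGLS  slope 0.215  under BM(unit_branches)  (R2 0.58)
candidate AICs: BM/unit_branches=284.6, OU/unit_branches=302.0, BM/grafen=308.6, OU/grafen=298.3
resampled OLS slope 0.213 (95% CI 0.206-0.220)
final OLS model terms: ['ln_mass', 't_opt', 'order']
  ln_mass        partial R2 0.16
  t_opt          partial R2 0.04
  order          partial R2 0.62
```

Reading this: the OLS exponent (0.215) is attenuated below the generative
0.25 by phylogenetically correlated noise and its CI still covers it; the
SMA slope overshoots because SMA divides the OLS slope by |r| and the fit
is noisy (R² = 0.16); AIC correctly identifies the generating Brownian
motion / unit-branch structure (margin ≈ 14 AIC units); mass-conversion
error barely moves the exponent (0.215 → 0.213); and the factorial model
attributes most variance to clade membership, as expected with strong
phylogenetic noise.

The same analysis runs from a shell:

```sh
devallometry simulate --seed 42 --n-species 120 --n-orders 8 --out demo_study
devallometry run demo_study/species.csv demo_study/lengthmass_models.csv \
    demo_study/tree.nwk --n-reps 1000 --seed 42 --out demo_results
```

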