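# hissbrn

Behavioural reaction norms, repeatability and path analysis for
nest-defence (hissing) behaviour in breeding female great tits
(*Parus major*).

When a predator appears at the nest hole, some incubating or brooding
females produce loud hissing calls — a risky anti-predator display.
Repeated 60-second predator-presentation trials across the nesting cycle
yield, per female, a behavioural reaction norm: an **intercept** (her
average hissing level, a "nest-defence personality") and a **slope** (her
plastic adjustment as the offspring age). This package provides the full
analysis chain for such data, aimed at behavioural ecologists working
with repeated individual measurements:

1. **Synthetic data** (`hissbrn.simulate`) — trial schedules matching the
   reference field design (104 females, up to five trials at centred days
   −10, −7, −3, +2, +5; 448 trials with the observed missingness
   histogram), reaction-norm responses with configurable variance
   components, and per-female reproductive traits drawn from an arbitrary
   causal diagram (DAG) by path tracing.
2. **Random regression** (`hissbrn.brn`) — the Bayesian mixed model

   ```
   y_ij = x_ij' β + u0_i + u1_i · day_ij + e_ij ,   (u0, u1) ~ N(0, G)
   ```

   fitted by a blocked Gibbs sampler (collapsed fixed-effect update,
   inverse-Wishart / inverse-gamma conjugate steps), with convergence
   diagnostics and per-female posterior-mean effects.
3. **Variance inference** (`hissbrn.repeatability`) — adjusted
   repeatability `R_adj = V_id / (V_id + V_e)` per posterior draw,
   stage-specific repeatabilities, and permutation tests for variance
   components (response reshuffled across observations, model refitted,
   p = exceedance proportion of the null posterior means).
4. **Multivariate partition** (`hissbrn.multivariate`) — a five-trait
   random-intercept model splitting phenotypic (co)variances of hissing,
   lay date, clutch size, fledgling number and fledgling mass into
   among-individual (**ID**) and residual (**R**) matrices, with residual
   variances of single-record traits constrained to be essentially zero.
5. **Path analysis** (`hissbrn.paths`) — recursive path models fitted to
   every posterior ID correlation matrix by minimizing the ML discrepancy
   `F_ML = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p`, compared via
   `AIC = (n−1)F_ML + 2k` and ΔAIC; plus the preliminary logistic
   regression of nest success on behaviour and reproductive decisions.
6. **Pipeline + CLI** (`hissbrn.pipeline`, `hissbrn` command) — config-
   driven, seeded, end-to-end orchestration with a hash manifest and a
   report (Table-style summaries and the reaction-norm figure).

## Worked example

```python
from hissbrn import (build_design, simulate_brn, ReactionNormParams,
                     fit_random_regression, adjusted_repeatability)

design = build_design(104, "paper", seed=1)
params = ReactionNormParams()          # reference-study generative defaults
trials = simulate_brn(design, params, seed=2)
print(f"{design.n_trials} trials on {design.n_females} females")

post = fit_random_regression(trials, seed=3)
print(post.summary().round(3).to_string(index=False))

r = adjusted_repeatability(post)
print(f"R_adj = {r.r:.2f} [{r.lower95:.2f}; {r.upper95:.2f}]")
```

prints

```
448 trials on 104 females
       parameter   mean  lower95  upper95  supported
  beta_intercept -0.103   -0.372    0.161      False
        beta_day  0.015   -0.008    0.040      False
beta_julian_date  0.001   -0.169    0.185      False
  beta_time_mean  0.060   -0.114    0.228      False
   beta_time_dev -0.018   -0.065    0.027      False
  beta_age_adult  0.014   -0.346    0.360      False
beta_age_unknown  0.787    0.137    1.405       True
   var_intercept  0.775    0.553    1.069      False
       var_slope  0.014    0.010    0.018      False
   cov_int_slope  0.020   -0.001    0.044      False
       var_resid  0.190    0.161    0.225      False
R_adj = 0.80 [0.74; 0.85]
```

The generator put in an among-individual intercept variance of 0.85, a
residual variance of 0.19 and a day slope of 0.02; the posterior means
recover them within sampling noise (one 104-female dataset carries
limited information, so single-replicate estimates scatter around the
generating values — the acceptance experiments average over replicates).
`R_adj ≈ 0.80` matches the generating ratio 0.85/(0.85+0.19) = 0.82:
hissing behaviour is highly repeatable, i.e. females have consistent
nest-defence personalities. Variance components are never "significant"
by credible interval (they cannot cross zero), which is what the
permutation test is for.

Run the whole pipeline from the shell:

```bash
hissbrn all --out results/run1 --seed 42
# or stage by stage, with a YAML config:
hissbrn simulate --out results/run1 --config config.yaml
```

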