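# hscdiv

Quantifying the age-dependent balance of symmetric and asymmetric
hematopoietic stem cell (HSC) divisions in mice.

## The problem

HSC numbers rise with age, but a census alone cannot tell *how*: by
symmetric self-renewal (S-S, two stem daughters), asymmetric division
(S-P), or symmetric differentiation (P-P)? This package implements a
quantitative pipeline that infers the age-dependent fractions of the three
division modes by combining two experiments:

* **ex vivo** — single HSCs expanded per well for 14 days; each well yields
  a proportion x ∈ [0, 1] of functional HSCs (CD201+CD150+KSL) among the
  expanded cells. At age t these proportions are modelled as
  x ~ Beta(α(t), β(t)), with each shape parameter following a biexponential
  decay in age, e.g. α(t) = b₁e^(−a₁(t−t₀)) + b₂e^(−a₂(t−t₀)), t₀ = 4 wk.
* **in vivo** — counts of HSCs (CD34−CD150+KSL) and of the KSL compartment
  per bone at ages 6–72 weeks, modelled by a two-compartment ODE

      dS/dt = r·p(t)·S − r·pp(t)·S
      dP/dt = r·q(t)·S + 2r·pp(t)·S − d·P,     KSL = S + P.

Two thresholds c₁ < c₂ on a 0.1 grid cut the beta distribution into the
division fractions via the discretized CDF P_c (= the regularized
incomplete beta I_c by telescoping):

    p(t) = 1 − P_c₂ (S-S),  q(t) = P_c₂ − P_c₁ (S-P),  pp(t) = P_c₁ (P-P).

The pipeline estimates (α_t, β_t) per age by maximum likelihood, fits the
biexponential trajectories, grid-searches all 36 threshold pairs with
nonlinear least squares over (r, S0, P0) against the census (d fixed at
0.1/week with a sensitivity scan), and samples posteriors by adaptive
Metropolis MCMC. A synthetic-data module generates complete studies with
known ground truth so every stage is testable without external data.

Intended users: quantitative stem-cell biologists and modellers analyzing
single-cell expansion + census designs, or benchmarking division-mode
inference on simulated studies.

## Worked example

```python
from hscdiv import *
from hscdiv.inference import FitConfig, grid_search_thresholds, run_mcmc
from hscdiv.synthetic_data import paper_like_spec

spec = paper_like_spec(seed=11)         # truth: c1=0.3, c2=0.8, r=0.172
wells = generate_wells(spec)            # 1800 wells, 11 ages, 4-52 wk
census = generate_census(spec)          # 63 records, 3 bones, 6-72 wk

traj = fit_trajectory(fit_all_ages(wells))

cfg = FitConfig(seed=11, n_chains=4, n_steps=20_000, n_burn=5_000)
fit = grid_search_thresholds(traj, census, cfg)
post = run_mcmc(fit.thresholds, traj, census, cfg, fit.params_point)

print(f"thresholds: c1={fit.thresholds.c1}, c2={fit.thresholds.c2}  (SSR={fit.ssr:.4f})")
r = post.summaries.loc["r"]
print(f"division rate r = {r['mean']:.3f}/week  (95% CI {r['ci_lo']:.3f}-{r['ci_hi']:.3f})")
f10 = division_fractions_at(traj, 10.0, fit.thresholds)
f70 = division_fractions_at(traj, 70.0, fit.thresholds)
print(f"S-S fraction: {100*f10.p:.1f}% at 10 wk -> {100*f70.p:.1f}% at 70 wk")
print(f"P-P fraction: {100*f10.pp:.1f}% at 10 wk -> {100*f70.pp:.1f}% at 70 wk")
```

Output:

```
thresholds: c1=0.1, c2=0.9  (SSR=0.0476)
division rate r = 0.162/week  (95% CI 0.154-0.170)
S-S fraction: 43.6% at 10 wk -> 28.5% at 70 wk
P-P fraction: 14.8% at 10 wk -> 40.7% at 70 wk
```

The division rate lands within 6% of the generating value (0.172/week) and
the qualitative picture — S-S dominance early, P-P rising with age — is
reproduced. The selected thresholds differ from the generating pair
(0.3, 0.8): the SSR landscape over threshold pairs is nearly flat because
the underlying beta distributions are U-shaped, so little probability mass
separates neighbouring pairs; `docs/methods.md` quantifies this
identifiability limit. Re-running with other seeds moves the selected pair
around the flat valley while r stays stable.

The same analysis runs from the shell:

```sh
hscdiv simulate --seed 11 --out data/
hscdiv fit --wells data/wells.csv --census data/census.csv \
           --d 0.1,0.05,0.2 --seed 11 --out fit/
```

writing `shapes.csv`, `trajectory.json`, `ssr_grid.csv` (the 36-row audit
table), `fit_summary.csv`, `posterior.csv`, `fractions.csv`,
`sensitivity.csv` and a reproducibility manifest.

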