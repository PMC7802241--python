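# pammkit

Piece-wise exponential additive mixed models (PAMMs) for **recurrent
events** — built for epidemiological cohort studies in which subjects can
experience the same outcome repeatedly (the motivating setting is repeated
pneumonia episodes in a birth cohort followed over the first two years of
life) and in which both the baseline risk and the relative effects of risk
factors may change with age.

Classical tools force a choice: mixed-effects Poisson regression assumes a
constant underlying rate, and Cox-type frailty models never estimate the
baseline hazard at all, while both usually assume proportional (time
constant) hazard ratios.  PAMMs keep the full likelihood and relax all of
that: follow-up is split at the unique event times into intervals on which
the hazard is constant, and the resulting pseudo-observations are fitted as
a **penalized Poisson model** with log-exposure offsets,

* model 1: λ(t | x, z) = exp(β₀ + β₁x + f₀(t_j) + z)  — constant HR,
* model 2: λ(t | x, z) = exp(β₀ + β₁x + f₀(t_j) + x·f₁(t_j) + z) — time-varying HR(t) = exp(β₁ + f₁(t_j)),
* model 3: λ(t | doy, z) = exp(β₀ + g(t_j, doy) + z) — age × season surface,

where f₀, f₁ are penalized thin plate regression splines, g is a cubic ×
cyclic-cubic tensor product (periodic over the calendar year), and
z ~ N(0, σ²) is a per-subject frailty inducing correlation between a
subject's episodes.  Smoothing parameters and σ² are chosen by restricted
maximum likelihood (Laplace approximation), coefficients by penalized
IRLS.  From a fit the package derives per-interval hazards and yearly
incidence (×365.25), time-varying hazard ratios with 95% bands, cumulative
incidence of first and recurrent episodes, season×age heat-map grids, and
an automatic choice between models 1 and 2 based on the test of f₁ = 0.

A synthetic-cohort module generates ground-truth recurrent-event data in
continuous time (thinning), including the 14-day episode-merging rule used
for real surveillance data, so every estimator here is testable without any
study data.

## Worked example

`python examples/02_fit_binary_covariate.py` simulates 1000 children whose
exposure multiplies the hazard by 1.5 at every age, fits models 1 and 2,
and applies the selection rule:

```
model 1 HR: 1.55 (95% CI 1.33-1.81), truth 1.50
incidence, unexposed: 0.25 episodes/child-year (truth 0.30)
f1 (time-varying deviation) p = 0.794, EDF = 1.00
selected: model1  (model 1 expected: the simulated HR is constant)
frailty SD estimate: 0.51 (truth 0.50)
```

The HR and frailty SD recover the simulated truth; the f₁ p-value correctly
finds no evidence of a time-varying effect, so the constant-HR model is
kept.  The other scripts in `examples/` walk through interval splitting
(01), recovery of a declining HR(t) (03), seasonal tensor surfaces (04) and
cumulative incidence against a Kaplan-Meier check (05).

## Library tour

| module | provides |
| --- | --- |
| `pammkit.events` | `SubjectHistory`, `StudyWindow`, episode gap rule, CSV round trip |
| `pammkit.ped` | cutpoints, interval splitting to PED, seasonal day-of-year column |
| `pammkit.basis` | thin plate / cubic / cyclic-cubic bases, tensor products, sum-to-zero constraints, frailty blocks |
| `pammkit.model` | `ModelSpec`, `fit` (P-IRLS + REML), EDF, smooth tests |
| `pammkit.effects` | hazard / HR / cumulative-incidence curves, season grids, model selection |
| `pammkit.simulate` | scenarios, thinning-based cohort generation, truth curves |
| `pammkit.pipeline` | file-based split / fit / simulate steps with JSON sidecars |

See `docs/methods.md` for the statistical details, defaults, and
limitations.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end pipeline from scratch — simulating the
default 1137-subject cohort, splitting it, fitting the constant and
time-varying hazard-ratio models with frailty, running the selection rule
and deriving effect curves — and writes its results JSON to `--out`.
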