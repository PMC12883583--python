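# riclpm

Random-intercept cross-lagged panel modelling of two co-developing
constructs — for example depressive symptoms (SMFQ totals, 0–26) and a
cardio-metabolic marker such as fat mass index (kg/m²) measured six times
each between ages ~10 and ~25 in a birth cohort.

The package is aimed at epidemiologists and psychometricians who want a
self-contained, testable implementation of this analysis: a synthetic-data
generator that emulates the cohort's statistical structure, the cleaning
pipeline used for such data, a from-scratch full-information maximum
likelihood (FIML) estimator for the RI-CLPM and its ALT-SR extension,
standard SEM fit indices, and reporting with time-adjusted estimates for
uneven wave schedules.

## The model

For constructs $x$ and $y$ observed at waves $t = 1..T$, the RI-CLPM
decomposes each score as

$$x_{it} = \mu^{x}_{t} + \eta^{x}_{i} + w^{x}_{it},$$

where $\eta_i$ is a person-specific random intercept (loading 1 on every
wave; stable between-person differences) and $w_{it}$ is a within-person
fluctuation with lag-1 dynamics

$$\begin{pmatrix} w^{x}_{i,t+1} \\ w^{y}_{i,t+1} \end{pmatrix} =
\begin{pmatrix} a^{x}_{t} & c^{\,y\to x}_{t} \\ c^{\,x\to y}_{t} & a^{y}_{t} \end{pmatrix}
\begin{pmatrix} w^{x}_{it} \\ w^{y}_{it} \end{pmatrix} + \varepsilon_{i,t+1}.$$

Diagonal entries $a_t$ are auto-regressive (persistence) coefficients;
off-diagonal entries $c_t$ are cross-lagged coefficients, the basis for
Granger-style directional inference. The random intercepts covary freely,
innovations $\varepsilon_t$ have wave-specific covariances (their
correlations are the cross-sectional residual associations), and the mean
structure is saturated. With $T = 6$ waves the model has 53 free parameters
against 90 observed moments: **df = 37**.

Estimation maximizes the FIML likelihood over missingness patterns
(valid under MAR), with analytic gradients, standardized coefficients
($\beta = b \cdot \mathrm{sd}_\text{pred}/\mathrm{sd}_\text{out}$ on
model-implied within-component SDs), Huber–White sandwich standard errors,
and χ²/RMSEA/CFI/TLI/SRMR fit evaluation. Because waves are unevenly spaced,
every lagged estimate is also reported per year of lag ($\beta/\Delta t$).

## Worked example

Simulate a cohort-like panel (6 uneven waves, right-skewed raw scores,
missingness rising from ~15% to ~54%), preprocess it (5-IQR outlier
masking, sqrt/ln transforms, min-max normalization), fit the RI-CLPM and
report:

```bash
riclpm run --n 2000 --seed 7 --out runs/demo
```

prints

```
chi2(37) = 54.49, RMSEA = 0.015, CFI = 0.998, TLI = 0.997, SRMR = 0.018
artifacts in runs/demo
```

— the model fits well (RMSEA ≤ 0.05, CFI/TLI ≥ 0.95, SRMR < 0.08), as it
should on data simulated from (approximately) the fitted model class. The
rendered table (`riclpm report --fit-dir runs/demo`) starts

```
ar_dep
  lag 1: +0.17 [+0.10; +0.23]*  10.6 -> 12.8 y (dt = 2.2)  yearly +0.08 [+0.05; +0.10]
  lag 2: +0.33 [+0.27; +0.39]*  12.8 -> 13.8 y (dt = 1.0)  yearly +0.33 [+0.27; +0.39]
  ...
ar_cm
  lag 1: +0.82 [+0.76; +0.88]*  9.8 -> 11.8 y (dt = 2.0)  yearly +0.41 [+0.38; +0.44]
```

Each row is a standardized lagged coefficient with its 95% CI (`*` marks
CIs excluding zero), the median ages it spans, the lag duration, and the
yearly (time-adjusted) estimate. The generating truth has depressive-symptom
AR paths of 0.12–0.38 and adiposity AR paths of 0.54–0.84, which the fit
recovers within sampling error.

The same pipeline runs on your own wide CSV
(`id, dep_1..dep_T, cm_1..cm_T` plus a schedule sidecar) via
`riclpm fit --data panel.csv --out runs/mydata`, and
`riclpm compare --variants riclpm,altsr` contrasts the RI-CLPM with the
autoregressive latent trajectory model with structured residuals (random
linear slopes on top of the random intercepts).

Library use mirrors the CLI:

```python
from riclpm import (alspac_like_truth, simulate_panel, preprocess_panel,
                    build_riclpm, fit, compute_fit_indices)

truth = alspac_like_truth()            # six-wave cohort-like truth
panel = simulate_panel(truth, n=2000, seed=7)
model = preprocess_panel(panel)        # mask -> transform -> normalize
result = fit(build_riclpm(6), model)
print(result.paths().head())
print(compute_fit_indices(result, model).to_dict())
```

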