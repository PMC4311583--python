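# mediaopt

Statistical optimization of fermentation media, in two classical
design-of-experiments stages:

1. **Plackett–Burman screening** — an orthogonal two-level fractional
   factorial that ranks many candidate medium components and process
   settings by their main effects, using unassigned ("dummy") design
   columns to estimate experimental error.
2. **Response-surface modelling** — a rotatable central composite design
   (CCD) over the factors the screen retained, fitted with a full
   second-order polynomial, analysed by ANOVA with a lack-of-fit /
   pure-error split, and optimized over the explored region.

The package is aimed at microbiologists and bioprocess engineers who
optimize enzyme or metabolite production (activity in U/mL, titer in
g/L, …) and want the full screening → surface → optimum pipeline as
reproducible, scriptable code rather than point-and-click software. It
ships the complete design and response tables of a published cellulase
optimization for a soil isolate of *Bacillus amyloliquefaciens* (carbon
source CMC, i.e. carboxymethylcellulose), so every statistic below can
be recomputed offline.

## The statistics

For a balanced ±1 column of an *N*-run Plackett–Burman design, the main
effect of factor *X*ᵢ is

    E(Xᵢ) = 2 (ΣM₊ − ΣM₋) / N

(the mean response at the high level minus the mean at the low level).
The dummy-column effects *E*d estimate pure error,

    V_eff = Σ E_d² / n_dummy,   E_s = √V_eff,

and each factor is screened with t = E(Xᵢ)/E_s on `n_dummy` degrees of
freedom; factors with confidence 100·(1 − p) ≥ 95 % are retained.

The CCD stage fits, in coded variables (actual = center + step·coded),

    y = β₀ + Σᵢ βᵢxᵢ + Σᵢ<ⱼ βᵢⱼxᵢxⱼ + Σᵢ βᵢᵢxᵢ²

by ordinary least squares, with axial distance α = (2ᵏ)^¼ for
rotatability. The ANOVA partitions the total sum of squares into model,
per-term, lack-of-fit and pure-error components; diagnostics include R²,
the coefficient of variation `CV = 100·√MS_res / ȳ`, and adequate
precision (fitted-value range over the average prediction standard
error). The optimum is reported two ways: the analytic stationary point
(gradient zero, classified by the eigenvalues of the quadratic-form
matrix) and the constrained maximum over the explored coded box or
sphere.

## Worked example

```python
from mediaopt import pb_analyze, fit_quadratic, anova, fit_stats, stationary_point
from mediaopt.datasets import load_pb_study, load_ccd_study

design, response = load_pb_study()          # 12-run screen, 8 factors + 3 dummies
screen = pb_analyze(design, response, confidence_threshold=95.0)
print(screen.table[["factor", "effect", "t", "confidence_pct", "significant"]]
      .round(3).to_string(index=False))
```

```
      factor  effect      t  confidence_pct  significant
         CMC  17.490  4.412          97.840         True
     Sucrose  -8.990 -2.268          89.187        False
YeastExtract  -2.770 -0.699          46.503        False
     Peptone  -2.897 -0.731          48.218        False
      K2HPO4   0.643  0.162          11.861        False
       MgSO4  18.473  4.660          98.136         True
 Temperature  -9.230 -2.329          89.772        False
          pH  16.333  4.121          97.409         True
```

CMC, MgSO₄ and pH clear the 95 % confidence bar (dummy-column standard
error E_s = 3.963858), so they advance to the 20-run CCD:

```python
ccd, activity = load_ccd_study()
model = fit_quadratic(ccd, activity)
aov = anova(model, ccd, activity)
diag = fit_stats(model, aov, activity)
print(f"model F = {aov.model_f:.2f}, lack-of-fit F = {aov.lack_of_fit_f:.2f}")
print(f"CV = {diag.cv_pct:.2f} %, adequate precision = {diag.adequate_precision:.3f}")
sp = stationary_point(model, ccd.factors)
print(f"{sp.nature} at {dict((k, round(v, 3)) for k, v in sp.actual.items())}, "
      f"predicted {sp.predicted:.2f} U/mL")
```

```
model F = 3.79, lack-of-fit F = 1.08
CV = 9.51 %, adequate precision = 6.553
maximum at {'CMC': 1.469, 'MgSO4': 0.279, 'pH': 7.735}, predicted 28.51 U/mL
```

The model is significant (F = 3.79, p ≈ 0.025), its lack of fit is not
(F = 1.08 against pure error from the six replicated centre runs), and
the fitted surface is concave with an interior maximum: predicted
cellulase activity 28.51 U/mL at 1.47 g% CMC, 0.28 g% MgSO₄, pH 7.7.

The same pipeline is available from the shell:

```sh
mediaopt reproduce --out-dir report      # bundled study, full report bundle
mediaopt pb-design --runs 12 --factors 8 --dummies 3 --out pb.csv
mediaopt pb-screen --design pb.csv --response resp.csv --threshold 95 --out table.csv
mediaopt ccd-design --spec spec.json --out ccd.csv
mediaopt rsm-fit --design ccd.csv --response resp.csv --out-prefix fit
mediaopt rsm-optimize --fit fit.json --region box --out optimum.json
mediaopt rsm-surface --fit fit.json --pairs all --resolution 50
mediaopt simulate --kind ccd --truth truth.json --design ccd.csv --seed 42 --out resp.csv
```

`mediaopt.simulate` generates screening and CCD responses from known
ground truth (factor effects, quadratic coefficients, Gaussian noise),
which is how the test suite checks parameter recovery, type-I error
rates and power without any external data.

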