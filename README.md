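# healthineq

Income-related inequality in health-care utilization, measured and
decomposed from survey micro-data.

Health-interview surveys often record whether a respondent used outpatient
care in the last month (a binary outcome), a set of Andersen-model
determinants (needs, predisposing, enabling, and environmental factors), a
sampling weight — and income only as one of ten currency bands. `healthineq`
implements the full chain an equity analyst needs for such data:

1. **Banded-income imputation.** A weighted interval regression (interval-
   censored Gaussian MLE on the log scale) turns income bands into
   continuous predictions, floored at one currency unit, equivalised with
   the modified OECD scale (1 + 0.5 per extra adult + 0.3 per child) and
   rescaled to a base year's price level with consumer price indices.
2. **Concentration indices.** Weighted fractional ranks
   R<sub>i</sub> ∈ (0, 1); the concentration index
   CI = 2 cov<sub>w</sub>(y<sub>i</sub>, R<sub>i</sub>)/ȳ; Erreygers'
   correction for bounded outcomes
   E = 4ȳ CI/(y<sup>max</sup> − y<sup>min</sup>), which attains ±1 under
   perfect concentration of a binary outcome; robust standard errors from
   the convenient-regression formulation; and two-sample z-tests for
   cross-wave index differences.
3. **Decomposition.** A weighted probit P(y=1|x) = Φ(x′β) with partial
   effects at the sample means β<sub>k</sub><sup>m</sup> = β<sub>k</sub>
   φ(x̄′β) yields the additive decomposition
   E = 4 Σ<sub>k</sub> (β<sub>k</sub><sup>m</sup> x̄<sub>k</sub>)
   CI<sub>k</sub> + GCI<sub>ε</sub>: each covariate's contribution combines
   its effect on utilization (elasticity) with its income gradient
   (CI<sub>k</sub>); the residual is the unexplained generalized CI.
4. **Synthetic survey generator.** Because real national health-interview
   files are restricted, a generator reproduces their structure — covariate
   marginals matched to published elderly-sample descriptives, log-normal
   banded income with education/age/region gradients, probit-generated
   outcomes calibrated to the published outpatient rates (53.8% and 46.5%
   for the two wave profiles) — so every stage is testable with known
   ground truth.

The estimators follow scikit-learn conventions (`fit`, `predict`,
`get_params`, trailing-underscore fitted attributes):
`IntervalIncomeRegressor`, `ProbitRegression`, `ErreygersDecomposition`.

## Worked example

```python
import pandas as pd
from healthineq import AnalysisConfig, default_config, generate_population, run_full_analysis

frames = []
for profile, seed in (("2005-like", 1), ("2009-like", 2)):
    cfg = default_config(profile, n_respondents=2500, seed=seed)
    frames.append(generate_population(cfg))
pd.concat(frames, ignore_index=True).to_csv("survey.csv", index=False)

config = AnalysisConfig(input_path="survey.csv", output_dir="out",
                        cpi={2005: 95.3, 2009: 100.0}, base_year=2009, seed=1)
outputs = run_full_analysis(config)
print(pd.read_csv(outputs["indices"]).round(4).to_string(index=False))
```

```
   sex  index_2005  se_2005  index_2009  se_2009  difference  difference_se      z  p_value
female      0.0741   0.0342      0.1962   0.0309      0.1221         0.0461 2.6480   0.0081
  male      0.0525   0.0338      0.2232   0.0345      0.1707         0.0483 3.5346   0.0004
```

Each row compares one sex across the two synthetic waves: `index_*` are
Erreygers-corrected concentration indices of outpatient use over equivalised
income (positive = pro-rich utilization), with robust standard errors; the
difference is tested assuming independent cross-sections. The "2009-like"
profile generates a stronger income effect, so its indices are markedly
pro-rich and the change is significant. The per-stratum decomposition files
show where that inequality comes from — for the 2005-like women's stratum:

```
      covariate  coefficient stars  elasticity    ci_k  contribution
         lpinco       0.0782            0.2877  0.0538        0.0619
      age_65_74      -0.2041    **     -0.0510  0.0129       -0.0026
        married       0.0078            0.0021 -0.0107       -0.0001
 edu_elementary       0.1076            0.0179  0.0637        0.0046
edu_junior_plus       0.3095    **      0.0263  0.1868        0.0197
total E: 0.0741   residual: -0.0008
```

`contribution = 4 × elasticity × ci_k` for every row, and the contributions
plus the residual reproduce the total corrected index exactly.

The same pipeline is available from the shell:

```bash
healthineq simulate --profile 2005-like --n 2500 --seed 1 --out survey.csv
healthineq ci --input survey.csv --out indices.csv
healthineq decompose --input survey.csv --stratum female,2005 --out dec.csv
healthineq run-all --config config.yaml
```

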