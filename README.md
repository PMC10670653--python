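# setuperr

Scalarization and statistics of six-degree-of-freedom patient setup
errors in image-guided radiotherapy.

Modern treatment couches correct patient position in 6 DOF — three
translations x, y, z (mm) and three rotations yaw α, roll β, pitch γ
(deg) — but plan-robustness settings are one-dimensional ("±3 mm").
Rotations displace a target by an amount that grows with its distance R
from the treatment isocenter, so the question "how large is the setup
uncertainty, in mm?" has no answer without R. This package answers it
the way a setup-uncertainty study would: it folds the six per-DOF error
variances into three R-dependent translational variances,

    p̄ᵢ²(R) = σᵢ² + (R²/3) · Σ_{j ∉ axis i} σⱼ²,

samples the scalar error ‖(X, Y, Z)‖ with X ~ N(x, p̄x²) etc. centred on
each measured error, and reports the 95th percentile of that norm as a
function of R with patient-level bootstrap confidence bands. Around
this core it provides the cohort statistics such a study runs — paired
planar-vs-volumetric Wilcoxon and variance-equality tests with Holm
correction, and mixed-model / quantile-regression contrasts of
intrafractional motion by anesthesia status and timepoint — plus a
seeded synthetic cohort generator so the entire pipeline is testable
without clinical data.

Intended users: medical physicists and biostatisticians analysing
couch-correction logs (CBCT or planar image guidance), and anyone who
needs a defensible scalar uncertainty number from 6-DOF residuals.

## Worked example

```python
import numpy as np
from setuperr import (GeneratorConfig, generate, percentile_curve,
                      representative_error_table, fit_group_contrast)

cohort, truth = generate(GeneratorConfig(seed=1))   # 165 synthetic patients
curve = percentile_curve(cohort, "postcorrection", random_state=1)
print(curve.to_frame().to_string(index=False))
```

prints

```
 R_mm  estimate_mm  lower_mm  upper_mm
  0.0     1.381278  1.310669  1.508238
 25.0     1.395630  1.324597  1.523275
 50.0     1.435646  1.365854  1.561000
 75.0     1.509160  1.433858  1.626071
100.0     1.593579  1.525627  1.714958
```

— after image-guided correction, the 95th percentile of the scalar
setup error of this synthetic cohort is ≈1.4 mm for a target at the
isocenter, rising to ≈1.6 mm at R = 100 mm because residual rotations
(≈0.2° SD) displace distant targets; the lower/upper columns are the
95% patient-bootstrap band. Contrasting intrafractional motion by
anesthesia status:

```python
tab = representative_error_table(cohort, "posttreatment", random_state=1)
fit = fit_group_contrast(
    tab.value_mm,
    np.where(tab.anesthesia == "awake", "awake", "anesthetized"),
    tab.patient_id, target="quantile95", random_state=1)
print(round(fit.effect, 2), fit.conf_int)
```

gives `0.29 (0.19, 0.33)`: awake patients' 95th-percentile motion is
≈0.3 mm higher than anesthetized patients' in this synthetic cohort
(generator truth: intrafractional SD ratio 0.6).

The same pipeline is scriptable from the shell:

```sh
setuperr simulate --seed 1 --out cohort.csv
setuperr curves   --seed 1 --cohort cohort.csv --timepoint postcorrection --out curve.csv
setuperr compare  --seed 1 --cohort cohort.csv --contrast anesthesia --target quantile95 --out report.json
```

Every command writes a JSON run manifest (config, seed, versions,
content hashes) sufficient to reproduce its outputs byte-for-byte.

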