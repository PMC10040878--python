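# aortastress

In-vivo mechanical analysis of the human abdominal aortic wall from
simultaneous pressure and diameter recordings.

Clinically, wall stress of the abdominal aorta matters: peak wall stress
predicts aneurysm rupture risk, and the balance between the elastin-borne
and collagen-borne shares of the load changes with age and differs between
the sexes.  Measuring stress in vivo is impossible directly, but with a
thin-walled (membrane) model the equilibrium stresses follow from pressure
and geometry alone, and fitting a constitutive model to the measured
pressure-radius loop splits them into isotropic and anisotropic parts.
This package implements that pipeline for physiologists and vascular
biomechanics researchers: signal preprocessing, model identification,
derived clinical metrics, a perturbation sensitivity test, and a synthetic
cohort generator so every stage is testable without patient data.

## The model

The aorta is an incompressible thin-walled cylinder with inner radius
r₀, wall cross-sectional area A and lumen pressure P.  Membrane
equilibrium (Laplace's law) gives, independently of material properties,

    σθ_lp = (4π r₀² + A) P / (2A),        σz_lp = (π r₀² P + F) / A,

where the in-situ axial force F follows in closed form from assuming a
known longitudinal-to-circumferential stress ratio γ = 0.59 at a reference
pressure of 13.3 kPa.  The wall itself is modelled by the
Holzapfel–Gasser–Ogden (HGO) strain energy — a neo-Hookean matrix plus an
exponential term for two symmetric collagen-fiber families:

    ψ = c (I₁ − 3) + (k₁/k₂) (exp(k₂ (I − 1)²) − 1)

with I₁ = λθ² + λz² + (λθλz)⁻² and I = λθ² cos²β + λz² sin²β.  Enforcing
zero radial stress fixes the incompressibility multiplier and yields total
stresses that split exactly into an isotropic (matrix, mainly elastin) and
an anisotropic (fiber, mainly collagen) component in each direction.  The
six parameters κ = (c, k₁, k₂, β, R₀, λz) are identified per subject by
bounded nonlinear least squares matching the constitutive stresses to the
Laplace stresses over the averaged pressure-radius loop; fit quality is
summarised by R² per direction.

## Worked example

```python
from aortastress import AnalysisConfig, run_subject
from aortastress.synthetic import representative_subject, generate_subject_series

# noise-free synthetic subject built from the published mean parameters
series = generate_subject_series(representative_subject("male"))
row = run_subject(series, AnalysisConfig())
for key in ("sbp_mmhg", "dbp_mmhg", "map_mmhg", "c_kpa", "k1_kpa", "beta_deg",
            "r0_mm", "lambda_z", "r2_theta", "r2_z",
            "sigma_theta_iso_sbp_kpa", "sigma_theta_aniso_sbp_kpa",
            "f_theta_iso_sbp"):
    print(f"{key:28s} {row[key]:.6g}")
```

prints

    sbp_mmhg                     133.998
    dbp_mmhg                     70.9705
    map_mmhg                     91.9797
    c_kpa                        130.461
    k1_kpa                       13.0593
    beta_deg                     37.2366
    r0_mm                        7.73755
    lambda_z                     1.01391
    r2_theta                     0.999955
    r2_z                         0.99995
    sigma_theta_iso_sbp_kpa      88.1663
    sigma_theta_aniso_sbp_kpa    42.0016
    f_theta_iso_sbp              0.677327

Reading the output: systolic/diastolic/mean pressures of the averaged loop
in mmHg; the identified stiffness (c, k₁ in kPa), fiber angle β (degrees
from circumferential), unloaded radius R₀ (mm) and axial pre-stretch λz;
R² per direction between Laplace and fitted stresses; and at systole a
total circumferential stress of 130 kPa of which 88 kPa (68%) is carried
isotropically (elastin-like) and 42 kPa anisotropically (collagen-like);
total stress at systole is the sum, 130 kPa.

The same pipeline runs from the shell:

    aortastress simulate --out-dir cohort --seed 1
    aortastress batch --input-dir cohort --metadata cohort/metadata.csv --out-dir results
    aortastress summarize --results results/results.csv --out-dir results

`summarize` writes group mean ± SD tables (sex × below/above 40 years) and
per-sex regressions of every metric on age with the squared Pearson
correlation.

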