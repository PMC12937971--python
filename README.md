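# corneafluor

Desk-scale toolkit for **non-invasive estimation of advanced glycation end
products (AGEs) from corneal autofluorescence**.

AGEs are stable adducts formed by non-enzymatic glycation of proteins and
lipids; they accumulate under chronic hyperglycemia and are an attractive
long-term marker of metabolic imbalance. A portable reader excites the
cornea with a 365 nm UV source and measures the emitted fluorescence, which
rises with tissue AGE content. Two practical obstacles stand between that
raw signal and a serum-grade AGE estimate:

1. **Interference.** Corneal fluorescence is weak, so ambient and reflected
   light corrupt the corneal channel, and iris pigment attenuates both
   excitation and emission. The device records a second, much stronger
   fluorescence signal from the **eyelid**, which shares the illumination
   environment: over clean stretches the two channels drift together, while
   during an interference episode the corneal channel trends *against* the
   eyelid channel. The package's quality filter slides a window over both
   channels, computes the within-window Pearson correlation, and discards
   anti-correlated windows before averaging.
2. **Calibration.** Corrected fluorescence intensity is mapped to serum AGE
   concentration (µg/mL, ELISA reference) by a fixed-weight hybrid of
   multiple linear regression (ordinary least squares) and RBF-kernel
   support vector regression (C = 10, γ = 0.1, ε = 0.01), with BMI available
   as a metabolic covariate:

   ```
   ŷ(x) = w_mlr · MLR(x) + w_svr · SVR(x),   (w_mlr, w_svr) = (0.7, 0.3)
   ```

   Features are screened beforehand by a variance floor and a Pearson
   correlation threshold (|r| ≥ 0.3 with the serum reference).

Because the clinical recordings behind the device are restricted, the
package ships a **synthetic-data generator** that reproduces the assumed
statistical structure — fluorescence affine in true concentration, shared
illumination drift, episodic opposite-trend interference with a ground-truth
mask, Beer–Lambert pigment attenuation, lognormal assay noise, and a
diet → (AGE, BMI) coupling — so every processing claim can be validated
end to end on data with known truth. A bundled 20-pair serum vs device
comparison dataset carries the method-agreement statistics (Pearson r,
Bland–Altman bias and 95% limits of agreement, relative errors).

Audience: biomedical-optics and biostatistics researchers prototyping
non-invasive AGE readers, and anyone needing a worked, tested example of
reference-channel artifact rejection plus method-comparison statistics.

## Worked example

```python
from corneafluor import load_clinical_pairs, agreement_report
from corneafluor.pipeline import PipelineConfig, run_pipeline

# 1. Agreement statistics of the bundled serum vs device dataset
pairs, table = load_clinical_pairs()
print(agreement_report(pairs).render_text())

# 2. Full synthetic pipeline: simulate -> QC -> fit -> held-out agreement
result = run_pipeline(PipelineConfig(global_seed=1))
print(result.agreement.render_text())
print("hybrid held-out MARE: %.1f%%"
      % result.evaluation["hybrid"]["mare_percent"])
```

prints

```
Method agreement over n = 20 pairs
(differences are reference - test; relative error is
 100 * (test - reference) / reference; limits at 1.96 SD)
  Pearson r:              0.991
  Bland-Altman bias:      -0.029
  SD of differences:      0.162
  Limits of agreement:    -0.347 to 0.290
  Mean |relative error|:  3.7%
Method agreement over n = 60 pairs
(differences are reference - test; relative error is
 100 * (test - reference) / reference; limits at 1.96 SD)
  Pearson r:              0.984
  Bland-Altman bias:      0.050
  SD of differences:      0.234
  Limits of agreement:    -0.409 to 0.509
  Mean |relative error|:  4.1%
hybrid held-out MARE: 4.1%
```

The first block says the device's predicted concentrations track the serum
ELISA reference almost perfectly on the bundled clinical pairs (r = 0.991),
read 0.029 µg/mL high on average, and that 95% of between-method differences
are expected within −0.347 to 0.290 µg/mL. The second block shows the same
statistics for a fully synthetic 200-subject cohort (held-out 30% split):
the hybrid model recovers serum AGE with a 4.1% mean absolute relative
error, comfortably inside the 8% target that defines acceptable field
performance.

A command-line interface mirrors the library:
`corneafluor simulate | qc | fit | predict | evaluate | report |
safety-check` (the last validates planned UV exposures against the strict
single-exposure limits: dose < 3.9 mJ/cm², duration < 10 s, beam spot
> 7 mm).

## Layout

| Module | Contents |
| --- | --- |
| `corneafluor.simulate` | cohort + two-channel recording generator with interference ground truth |
| `corneafluor.optics` | Beer–Lambert pigment/skin attenuation, interference ranking |
| `corneafluor.qc` | windowed trend-consistency filter, corrected measurements |
| `corneafluor.estimator` | feature screening, `HybridAGERegressor` (scikit-learn API), JSON model documents |
| `corneafluor.agreement` | Pearson / Bland–Altman / relative-error statistics, bundled clinical pairs |
| `corneafluor.pipeline` | end-to-end runner, config handling, exposure safety validator |
| `corneafluor.validation` | seed-grid simulation studies used by tests and the acceptance script |
| `corneafluor.cli` | `corneafluor` command-line entry point |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
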