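# pdacolor

Colorimetric quantification of dopamine from images of polydopamine-darkened
culture media.

Dopamine (DA) self-oxidises at basic pH to polydopamine (PDA), a dark polymer
whose accumulation browns cell-culture media in proportion to the starting DA
concentration. That makes an ordinary brightfield microscope a quantitative
instrument: photograph the wells, measure how much each channel has darkened
relative to an untreated control, and invert a calibration curve. `pdacolor`
implements that pipeline for the assay's two workflows — *dopamine-first*
(DA added to media before plating cells) and *cells-first* (DA added to
growing cultures) — for people running plate-based colorimetric assays who
want concentration estimates without a spectrophotometer or HPLC.

## The models

Let C be the vector of n known calibration concentrations (µM) and
I = [I_r, I_g, I_b] the channel intensities, normalized so the 0 µM control
maps to 1. With Ī_i the 3×n matrix of natural-log intensities for replicate
trial i, the pooled multivariate calibration finds the row vector
A = (a_r, a_g, a_b) minimising

    Σ_i ‖ C − A·Ī_i ‖²

via the Moore-Penrose pseudo-inverse construction
f(I) = (Σ_i Ī_i Ī_iᵀ)(Σ_i Ī_iᵀ)⁺, A = C·f(I)⁺, which coincides with the
pooled normal-equations solution on any full-rank design. Unknowns are then
estimated intercept-free:

    Ĉ = a_r ln(I_r) + a_g ln(I_g) + a_b ln(I_b)

so control intensities (1, 1, 1) give Ĉ = 0 identically. The inverse
direction — intensity as a function of concentration — is an exponential
decay per channel and for grayscale,

    I_j(C) = α_j exp(−β_j C),    Ĉ = ln(α/I_gray)/β

fitted by log-linear least squares (with optional nonlinear refinement), with
closed-form inversion for grayscale readings.

A synthetic-data generator emulates the assay design (3 trials × 6
concentrations, 0–125 µM, 3 regions of interest per well), either as
intensity tables or as rendered PNG well images with per-pixel noise and
dark "colloidal PDA" speckles, alongside a ground-truth manifest — so the
whole pipeline is testable end to end without experimental data.

## Worked example

```python
import numpy as np
from pdacolor import SyntheticConfig, generate_intensity_table
from pdacolor.images import normalize_to_control
from pdacolor.models import RGBCalibrationModel, ExponentialDecayModel

samples, truth = generate_intensity_table(SyntheticConfig(seed=1))
normalized = normalize_to_control(samples)

res = RGBCalibrationModel.from_dataframe(normalized).fit()
print(res.summary())

conc = np.sort(normalized["concentration_uM"].unique())
gray = normalized.groupby("concentration_uM")["gray"].mean().reindex(conc)
gres = ExponentialDecayModel(conc, gray.to_numpy(), channel="gray").fit()
print(gres.summary())

unknown = (0.62, 0.55, 0.58)   # normalized RGB reading of an unknown well
print(f"estimated concentration: {res.predict([unknown])[0]:.1f} uM")
print(f"gray inversion of I=0.60: {gres.invert(0.60):.1f} uM")
```

prints

```
Pooled RGB calibration (intercept-free log-linear model)
  trials: 3   conditions per trial: 6
  coefficients (uM per log-intensity unit):
     a_r =     -17.2314
     a_g =     -75.9270
     a_b =     -23.5489
  per-trial R^2 of estimated vs known concentration:
    trial 0: 0.9997
    trial 1: 0.9996
    trial 2: 0.9997
Exponential decay fit, channel 'gray'
  I(C) = alpha * exp(-beta C)
  alpha = 1.00334 (normalized intensity at C = 0)
  beta  = 0.00824361 per uM
  R^2   = 0.9999 over 6 conditions
estimated concentration: 66.5 uM
gray inversion of I=0.60: 62.4 uM
```

The per-trial R² ≈ 0.9997 says the pooled linear model explains the
calibration concentrations almost perfectly on this synthetic dataset; the
fitted grayscale decay rate β ≈ 0.0082 /µM recovers the generator's
configured value; and a well whose channels have darkened to ~55–62 % of
control is estimated at ~60–66 µM by the two model families. Note the RGB
coefficients themselves are not individually meaningful — the three
channels darken almost in lockstep, so the design is near-collinear and
only the fitted linear map (the predictions) is stable across noise draws.

The same pipeline runs from the shell:

```sh
pdacolor simulate  --seed 1 --mode both --out ds
pdacolor calibrate ds --out cal
pdacolor estimate  ds --calibration cal/calibration.json --out est
pdacolor validate  ds --calibration cal/calibration.json --out val
```

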