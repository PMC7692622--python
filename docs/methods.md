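# Methods

## The measurement model

Dopamine polymerises to polydopamine in culture media, and the resulting
browning attenuates transmitted light. We treat the mean channel intensity
of a well image, normalized against the 0 µM control of the same trial, as
an exponential function of the dopamine concentration C that seeded the
polymerisation:

    I_j(C) = α_j · exp(−β_j · C),   j ∈ {r, g, b, gray}

with α_j the (dimensionless) normalized intensity at C = 0, expected ≈ 1 by
construction, and β_j the decay rate in 1/µM. This is a Beer–Lambert-like
attenuation law on the mean pixel intensity; taking logarithms makes each
channel linear in C, which motivates the inverse model used for estimation:
an intercept-free multivariate regression of concentration on the three
log-intensities,

    Ĉ = a_r ln I_r + a_g ln I_g + a_b ln I_b.

No intercept is included even though a general-purpose regression would add
one: with control-normalized intensities the model must, by design, return
Ĉ = 0 at control readings, and the omission is what makes that exact. The
cost is that any systematic offset in normalization propagates directly
into Ĉ; the package therefore refuses to mix normalization conventions
between calibration and estimation.

## Pooled estimation across trials

The assay design repeats the full concentration series in three independent
trials. Rather than averaging trials before fitting, the calibration
minimises the pooled criterion Σ_i ‖C − A·Ī_i‖² over the coefficient row
vector A, where Ī_i is trial i's 3×n log-intensity matrix. The
implementation uses the pseudo-inverse construction

    f(I) = (Σ_i Ī_i Ī_iᵀ)(Σ_i Ī_iᵀ)⁺,   A = C · f(I)⁺ ,

which on any design of rank 3 equals the pooled normal-equations solution
A = C(Σ Ī_iᵀ)(Σ Ī_i Ī_iᵀ)⁻¹ (the pseudo-inverse product rule applies
because the 3×3 moment matrix has full column rank and the pseudo-inverse
of the summed transpose has full row rank). The test suite verifies this
equivalence against an independently coded stacked least-squares oracle on
randomized designs, rather than re-deriving it symbolically.

Singular values below 1e-10 of the largest are treated as zero, and the
rank of the stacked design is checked before solving; a channel that is
constant across all conditions (log-row of zeros) raises a degenerate-design
error instead of returning garbage coefficients.

A consequence worth knowing: data generated *exactly* from three per-channel
exponential models are themselves degenerate for the RGB calibration — every
log-intensity row is a multiple of C (rank ≤ 2 even with per-trial gain
factors), so the rank-3 precondition fails by construction. Real (noisy)
data are full-rank; this is why the RGB round-trip is validated under the
default noise model while the grayscale round trip is exact algebra. The
near-collinearity of the three channels also means the individual
coefficients a_r, a_g, a_b are ill-conditioned — what is stable, and what
the tests check, is the fitted linear map and its concentration estimates.

## Fitting the exponential models

"Least squares" for an exponential response is ambiguous about the fitting
domain. The default here is log-linear regression of ln(response) on C,
which is deterministic, closed-form, and exact on noiseless model-generated
data; `refine=True` follows it with nonlinear least squares
(`scipy.optimize.curve_fit`) on the original intensity scale, seeded at the
log-linear solution, for users who prefer errors weighted on that scale.
`fix_amplitude=True` pins α = 1, the value the normalization convention
implies for a perfectly clean control. A constant response fits as β = 0
(flat decay) and is then rejected by the inversion as non-invertible.

Grayscale inversion is Ĉ = ln(α/I_gray)/β. Estimates can be negative when a
well reads brighter than control; both the RGB and grayscale estimators
return such values unmodified with a `NegativeConcentrationWarning` —
clipping is a presentation choice that would bias downstream statistics.

## Intensities from images

Pixels are rescaled to [0, 1] by bit depth at load (8- and 16-bit PNG/TIFF).
Channel means are taken over rectangular ROIs in 0-based half-open
coordinates; the default layout is three equal squares along the image
diagonal, each covering ≥ 10 % of pixels, echoing the three-regions-per-well
sampling of the assay. Grayscale defaults to the BT.601 luma
(0.299 R + 0.587 G + 0.114 B), the common convention of desktop image
software; an unweighted `mean` alternative is exposed, and the method used
is stamped into every output since the two differ on colored media.
Normalization divides each channel mean by the same trial's control mean
per channel (per-trial, not global: it cancels trial-to-trial illumination
gain exactly, which pooling then exploits). Normalized means are floored at
ε = 1e-6 in the ingestion path only; the math core raises on non-positive
inputs instead. No background or blank-well subtraction is applied.

## The synthetic generator

The generator emulates only the optical signal the method reads: per-channel
means following the decay law, a per-trial multiplicative gain
(lognormal-like jitter, sd 0.02) standing in for plate-to-plate illumination
differences, and additive Gaussian noise (sd 0.01 on the normalized scale)
per ROI — the minimal variance structure that makes three-trial pooling
meaningful. Defaults are the assay's design: concentrations
(0, 25, 50, 75, 100, 125) µM, 3 trials, 3 ROIs per well, dopamine-first
reference coefficients. Generated values are truncated to (1e-6, 1.5].

Rendered well images (96×96 px, 8-bit PNG) place the channel means on a raw
brightness scale with control base levels (0.82, 0.80, 0.76) of full scale —
rendering at normalized ≈ 1.0 would saturate 8-bit pixels once noise is
added — and add per-pixel Gaussian texture (sd 0.02) plus dark circular
speckles whose count grows deterministically with concentration, standing
in for settled colloidal PDA particles. Speckles are cosmetic: they are
excluded from the ground-truth means and exist to exercise the robustness
of ROI averaging (they bias extracted means darker by ~1–3 % at the top
concentration, i.e. a couple of µM). Randomness derives from one root seed
with independent child streams per (trial, well), so extending a dataset
never perturbs earlier draws and identical configurations are byte-identical.

What passing tests on synthetic data do *not* show: the generator has no
spatial illumination gradients, no cell debris or meniscus artifacts, no
channel cross-talk, and Gaussian rather than heavy-tailed noise, so
recovery results here bound performance on idealised, not real, images.

## Numerical and design choices

- Problem sizes: the test and validation suites use the native assay scale
  (3 trials × 6 concentrations × 3 ROIs; 96×96 px images), which the
  package's methods resolve in seconds; the Monte-Carlo check of the noise
  model uses 10⁴ replicate draws of a single condition.
- Estimator equivalence tolerance 1e-8 relative; printed-coefficient
  recovery on noiseless data 1e-6 relative; grayscale round trip 1e-9.
- The RGB round trip (calibrate under default noise, then push noiseless
  forward-model intensities through Ĉ) is documented to 10 µM, the same
  scale as the end-to-end recovery requirement (median |Ĉ − 60| ≤ 10 µM on
  held-out wells); observed errors are typically 1–3 µM.
- Trial aggregation for the decay fits defaults to the mean of
  control-normalized trials (keeping α ≈ 1); a literal-sum mode is
  available and simply scales α by the trial count.
- Workflow labels (`dopamine_first`, `cells_first`) are dataset tags: both
  run identical code and differ only in which reference coefficients the
  generator uses and how artifacts are stamped.

## Limitations

- No uncertainty intervals on Ĉ: the calibration is a point estimator, and
  inverse-prediction intervals would require a variance model the assay
  does not supply.
- The RGB coefficients are not interpretable channel weights (collinearity;
  see above); compare calibrations by their predictions, not coefficients.
- Quantification assumes the control well shares the unknown well's optics;
  estimation refuses tables without an in-trial control rather than guess a
  reference.
- 8-bit rendering quantises intensities to ~0.4 % of scale, a floor on how
  exactly the image route can recover configured models.
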