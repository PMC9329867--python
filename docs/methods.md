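# Methods

This note documents the models implemented in `caroraman`, their
assumptions, the synthetic world the tests run in, and the numerical
choices a maintainer would want to know. Nothing here states a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The measurement model

A 532 nm solution measurement of a carotenoid:BSA complex is modelled as

```
I(Δν) = g · T(u(Δν)) · [ Σᵢ cᵢ·refᵢ(Δν) + w·water(Δν) + b·BSA(Δν) + base(Δν) ]
        · (1 + ε_mult(Δν)) + ε_add(Δν)
```

- `refᵢ` — unit-maximum pure-component spectra (sums of Lorentzian
  fundamentals and broad overtone bands);
- `water`, `BSA` — fixed-amplitude interferent spectra (same solvent in
  every sample);
- `base` — a smooth positive stray-light baseline, decreasing with
  wavenumber (degree-5 polynomial; the EMSC fit deliberately
  over-parameterizes with order 7);
- `g` — a per-spectrum collection gain (lognormal, 5% sd), the
  variability that water normalization exists to cancel;
- `T(u)` — Beer–Lambert self-absorption (below);
- `ε_mult`, `ε_add` — channel-wise Gaussian noise, 1% sd multiplicative
  and 0.5% of the spectrum maximum additive.

### Self-absorption

Both the incident laser and the Stokes-scattered light are attenuated by
the absorbing solution. Integrating the Beer–Lambert decay over the
(normalized) sampled depth gives

```
I_meas = I₀ · T(u),   T(u) = (1 − e^(−u)) / u,
u(Δν)  = α_L·d₁ + α_R(λ_R(Δν))·d₂,
λ_R    = 1 / (1/λ_L − Δν·10⁻⁷)  [nm],
α      = ln(10) · A'(λ) · c / c_ref.
```

`A'` is the visible absorbance after subtracting its 700 nm value (the
Mie-like scattering background), measured at reference concentration
`c_ref`; extinction scales linearly with concentration (verified by
`absorbance_linear_fit`). `d₁`, `d₂` are dimensionless path factors that
absorb the different effective path lengths of the absorbance and Raman
geometries; printed defaults are d₁ = 1.3, d₂ = 1.75, and the generator
uses the same values, so correction with the defaults is exact on
synthetic data. `T` is evaluated as `-expm1(-u)/u` with the analytic
limit T(0)=1 below u = 1e-8; it matches numerical quadrature of the
depth integral to 1e-9 (asserted).

**Identifiability.** In a dilution series both α_L and α_R are
proportional to c, so d₁ and d₂ enter only through the identifiable
combination `u_slope = α_L(1)·d₁ + α_R(1)·d₂`. `fit_path_factors`
reports the pair found, the u_slope, and a collinearity flag; parameter
recovery is asserted on u_slope (≤1%), not on the individual factors.
The fit uses bounded (d ∈ [0, 20], k > 0) Levenberg–Marquardt/TRF with
8 seeded log-uniform multistarts and tight tolerances (1e-14).

### Internal standard under attenuation — a caveat

The EMSC water coefficient is estimated from attenuated water bands. In
this world the water bend (1640 cm⁻¹ → 582 nm Stokes) sits at almost the
same wavelength as ν₁ (579 nm), so the water coefficient shrinks with
concentration nearly in step with the ν₁ band: water-normalized peak
heights are close to linear in concentration even before any explicit
correction, while the unnormalized (EMSC-corrected) response shows the
full saturation. Consequences adopted in the pipeline:

- the path-factor fit runs on the **unnormalized** corrected peak
  response, where saturation is manifest;
- PLSR runs on the **normalized** spectra; the latent variables absorb
  the smooth residual attenuation curvature exactly (noise-free CV
  R² = 1.0, asserted indirectly by the twin) and normalization cancels
  the gain jitter;
- the **unmixing** pathway uses corrected but unnormalized spectra for
  both the admixture and the basis spectra: per-spectrum water
  coefficients embed component-specific attenuation, so dividing each
  basis spectrum by its own coefficient would put them on inconsistent
  scales (observed to bias noise-free 100:50:10 recovery from
  (62.5, 31.25, 6.25) to (47, 45, 7)). Normalization remains available
  via `PreprocessConfig(normalize=...)`.

## Preprocessing

Order of operations: crop to 400–3100 cm⁻¹ → Savitzky–Golay (order 5,
window 9, polynomial edge handling) → EMSC → optional water
normalization. Cropping **before** the EMSC fit is a deliberate
deviation from fitting the full range and cropping after: it avoids the
negative-dip artifact beyond 3100 cm⁻¹ and is better conditioned. The
reference and interferents are smoothed with the same settings as the
data so the linear model stays exact on noise-free input. The EMSC
baseline uses Chebyshev polynomials on the axis rescaled to [−1, 1];
coefficients are reported in that basis. Rank deficiency of the design
raises an error naming the collinear pair. For admixtures (analyte
unknown) the reference column is the sum of the three carotenoid
references; the reference column only needs to span analyte signal so
the baseline cannot absorb it.

## Calibration

PLS1 (`sklearn` NIPALS, mean centering, no scaling). Repeated K-fold
cross-validation (default 10-fold × 100, seeded random partitions)
reports RMSECV per LV count; each fold is fitted once at the maximum LV
count and smaller counts are read off the nested NIPALS coefficient
path (equivalence to per-LV refits is asserted against sklearn). The
reported cross-validated R² is the squared Pearson correlation between
repeat-averaged held-out predictions and the targets; LOD = 3.3 × RMSECV.
LV selection policies: first LV reaching 99.9% cumulative Y-variance, or
the smallest LV within one SE (or 5%) of the RMSECV minimum.

## Differentiation and unmixing

PCA vector-normalizes rows, mean-centers columns, and takes the SVD;
signs are fixed by making the largest-magnitude loading element
positive, so score plots are reproducible. The three classes differ by
the ν₁ position (defaults 1516/1521/1524 cm⁻¹ for Beta Carotene /
Zeaxanthin / Lutein — the ordering is the documented constraint, the
exact values are package choices), by the relative ν₂/ν₃ strength
(larger in Beta Carotene) and by the overtone region (strongest and
slightly shifted in Zeaxanthin).

Admixture fitting minimizes `‖meas − T(u_mix)·Σ Aᵢ·refᵢ‖²` with
`u_mix = Σ Aᵢ·(α_L,i d₁ + α_R,i(Δν) d₂)` — mixture optical depth is
weight-additive per Beer's law — over Aᵢ ∈ [0, 2] with 8 seeded
multistarts. With absorbance disabled this reduces to bounded
non-negative linear least squares (asserted against
`scipy.optimize.lsq_linear`). Fit window defaults to the full
400–3100 cm⁻¹ range; restricted windows are supported. The all-zero
input returns zero weights with a degenerate flag rather than an
undefined percentage.

## What the generator does and does not emulate

Emulated: band structure and ν₁ ordering; water/BSA interference; the
stray-light background; self-absorption with the exact T(u) the
correction assumes (the embedded extinction is, by construction, the
background-subtracted absorbance an analyst would derive from the
simulated 1 mg/mL absorbance spectrum, so round trips are exact to
interpolation error); gain jitter; channel noise. Not emulated:
instrument response curves (the study did not correct for them either),
cosmic spikes, wavenumber-calibration drift, Poisson shot noise (counts
scale unknown), spectral changes of water upon solute interaction, and
any excitation-profile physics of resonance enhancement. A green test
therefore establishes the correctness of the analysis chain under the
stated statistical structure, not instrument-level fidelity.

## Known limitations and honest numbers

- With the default noise levels the synthetic-twin cross-validated R²
  sits at ≈0.9992–0.9997 depending on seed: noise-free and
  gain-jitter-only runs give exactly 1.0, so this is the propagated
  channel-noise floor of the stated world, not a pipeline defect. The
  corresponding acceptance check (≥ 0.9995 at seed 0) is left to report
  whatever the stated world produces.
- Noisy admixture recovery shows Lutein/Zeaxanthin cross-talk (their ν₁
  bands are 3 cm⁻¹ apart at 12 cm⁻¹ FWHM); the noise-free battery
  recovers nominal percentages to ≤0.25 points, the noisy battery shows
  variable fitted ratios — qualitatively the same behaviour reported
  for measured spectra.
- d₁/d₂ are individually unidentifiable in a single-analyte dilution
  series (see above); downstream corrections only ever use the
  identifiable combination.
- The grid step (2 cm⁻¹) and the 41 × 2 replicate layout of the
  82-spectrum calibration series are package choices; the source
  measurements' channel spacing and replicate structure are not stated.
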