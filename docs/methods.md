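# Methods

## Reference dose model

The dose engine treats the away-along table as the authority for absorbed
dose rate to water per unit air-kerma strength around the source. Because
the field falls off almost as 1/r² and grids are coarse (1 cm spacing near a
source at 1–6 cm), raw bilinear interpolation is biased high between nodes.
The engine therefore interpolates `value × r²` bilinearly and divides by r²
at the query point. Two consequences: grid nodes are reproduced to machine
precision, and any exact inverse-square field is represented *exactly*
everywhere inside the hull (the flattened surface is constant) — which is
what the 1e-9 interpolation oracle in the tests checks. Queries outside the
tabulated rectangle raise `OutOfRangeError`; silent clamping would hide
set-up errors in exactly the region (near the edge) where they matter.

The TG-43 line-source geometry function uses the subtended-angle form
`G_L = β/(L·r·sinθ)` with the on-axis limit `1/(r² − L²/4)`, and collapses to
`1/r²` at `L = 0`. It is validated against a quadrature oracle (the mean
inverse-square distance over the active line).

Decay uses `2^(−Δt/T½)` with T½ = 73.83 d for Ir-192 (standard reference
value; source certificates vary in the fourth digit, irrelevant over
session-length intervals).

## Calibration chain

All operations are exact algebra on Monte Carlo dose ratios and TRS-398
constants; nothing is simulated here. The Co-60 denominator
`[s_w,air·p] = 1.112` is a tabulated constant stored in `TRS398Constants` so
a simulated alternative can be swapped in. The absolute numerator ratio
`(D_w,full/D̄_air,PMMA)_Ir-192` ships in the fixture as a derived value
(F × 1.112) and is flagged as such. The combined k=1 uncertainty of F is the
quadrature of the numerator's Monte Carlo uncertainty (2.4%) with the 0.8%
assigned to the TRS-398 denominator, giving 2.5% after rounding. Chamber
readings are corrected to 20 °C / 101.325 kPa (the dry-air reference of the
underlying simulations) unless overridden.

## Signal processing

Acquisitions carry Poisson Type A uncertainty `1/√N` (N = total counts) by
default; repeated-acquisition SD should replace it when ≥3 repeats exist
(`type_a`). Stem subtraction pairs PSD and dummy acquisitions by geometry
within 0.1 mm / 0.5°, combines their absolute uncertainties in quadrature,
and keeps negative net rates (clamping would bias means of repeated
low-signal measurements) while flagging anything below −3σ. Decay
normalization is skipped when the maximum RAKR variation across a session is
under 0.2% (configurable) — the short-session regime where the correction
would only add noise to the bookkeeping. Normalization anchors the measured
grid to the reference table at one point (default y = 4 cm, z = 0, the
source reference plane); the anchor choice means any measured-vs-reference
comparison is blind to a global sensitivity factor, by design.

## Characterization summaries

Percent-difference summaries (energy and angular dependence) report the mean
and SD of the *magnitudes* of per-point deviations; the signed values are
preserved in `per_point` for plotting. Angular deviations are taken about
the sweep mean — no angle is privileged as a reference. The away-along
comparison additionally reports the z = 0 radial-profile statistics and the
maximum |deviation| of each z-profile per away distance, so both common
readings of "maximum difference at a radius" are available.

The temperature model is an unweighted OLS of signal on temperature,
reparameterized to `(s0 at t0, a = slope/s0)` with t0 = 25 °C. The slope
uncertainty combines the fit standard error with a Type B term
`|slope|·u_T/√Sxx` for the temperature-measurement uncertainty (per-set
`|ΔT|/√12 ⊕ u_cal`); covariance between slope and intercept is neglected in
the conversion to `a` (second-order at the observed magnitudes). The OLS
uses closed-form expressions rather than a polynomial-fit helper because
the minimum supported design is three points, below what generic covariance
routines accept. The fit is unweighted; a weighted variant can be obtained
by passing repeat means, but repeats at each set point enter as individual
points by default.

The correction factor is `1/(1 + a·ΔT)`, with a warning when applied more
than 5 °C outside the fitted range and a hard error if the linear model
predicts a non-positive response.

## Uncertainty engine

Relative components (percent, k=1) combine as `√Σu²`; budgets recompute the
total on every access. Display rounding is one decimal, half-up; internal
values stay full precision. The uniform-interval rule uses `amplitude/√12`
(the GUM rule for a rectangular distribution; the factor 12 applies to the
variance, not the standard deviation). Type A is reported as the SD of the
set, with SD-of-the-mean behind a flag.

## Synthetic generator

The generator emulates the three measurement set-ups with every dependence
injected explicitly, so zero-noise round trips through the pipeline must
recover the injected parameters to numerical precision — that, not
reproduction of any physical detector's numbers, is what the tests
establish. Headline dependence values of a real probe are properties of the
hardware; the pipeline reproduces them only when fed equivalent
measurements.

Model: `psd = sensitivity · dose_rate · ε(r) · A(φ) · (1 + a(T−25)) + stem`,
`dummy = stem`, with the stem proportional to the inverse-square-weighted
irradiated fiber length (closed-form integral along the fiber). This makes
the azimuthal stem peak toward the fiber-axis angles and stay constant in
the axial plane — the qualitative behaviour any monotone-in-proximity stem
model must show; no published numeric stem amplitudes exist to match.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| exposure | 10 s | typical dwell-scale acquisition; not stated by the protocol |
| sensitivity | 1.4×10⁴ counts/cGy | gives ~10³ counts/100 ms at 4 cm from a 38.3 mGy·m²/h source, the observed rate scale |
| stem coefficient | 0.004 counts/100 ms per U·cm⁻¹ | ~5% stem fraction at the normalization point |
| temp. slope | −0.0019 /°C | the measured BCF-12 coefficient |
| noise | Poisson on counts | counting statistics; 0.3% Gaussian mode mirrors the temperature-study repeatability |
| fiber length | 15 cm | in-phantom irradiated portion of the 1.5 m probe |
| thermometer u_cal | 0.045 °C | certificate 0.09 °C (k=2) at k=1 |
| sensor drift | 0.1 °C | initial/final reading spread exercising the uniform-interval rule |

What the generator does **not** emulate: spectral (Cherenkov vs
fluorescence) composition of the stem, optical-coupling drift, afterloader
dwell-time jitter, catheter-connection offsets, or scatter deficits of
finite phantoms. Tests passing on synthetic sessions therefore validate the
*pipeline arithmetic*, not the physics of any particular probe.

Determinism: every generator call takes its seed from the config; identical
config ⇒ bit-identical sessions. Seeds are never global state.

## Problem sizes

The stochastic recovery check uses 200 independent synthetic temperature
sessions (6 temperatures × 5 repeats, 0.3% noise), enough to resolve a slope
bias an order of magnitude below the reported uncertainty; the interpolation
oracle uses 500 random in-hull points. Both choices keep the full suite in
the low seconds.

## Known limitations

- No correlated-uncertainty propagation (GUM sensitivity coefficients) and
  no Monte Carlo uncertainty propagation; budgets assume independence.
- The away-along toy table is a geometry-function-times-attenuation model,
  not consensus data; it is a stand-in with the right structure, not the
  right values.
- The energy/angular comparison assumes the measured grid lies on reference
  nodes or inside the hull; no regridding of scattered points.
- The temperature fit's Type B slope term treats temperature errors as
  independent per set; a common calibration offset would instead shift all
  temperatures and leave the slope untouched (the shift-equivariance the
  tests verify).
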