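# Methods

`muakit` implements a complete analysis chain for broadband tissue
absorption spectroscopy: from integrating-sphere measurements to an
absorption coefficient spectrum, from that spectrum to chromophore
weights, and from the weights to volumetric physiology. This note
records the models, the tunable parameters, and the design choices made
where the procedure was genuinely open.

## Direct calculation of μ_a(λ)

In the thin-sample, photon-diffusion regime the absorption coefficient
follows directly from the measured total transmittance and total
reflectance:

    μ_a(λ) = (1 − (T_t(λ) + R_t(λ))) / d

with `d` the sample thickness in cm (0.5 mm samples → `d = 0.05`, so
μ_a emerges in cm⁻¹). The relation treats every photon that neither
crosses nor returns from the sample as absorbed; specular losses and
scattering escape are not modeled separately, which is why measured
spectra retain a flat residual floor between the chromophore bands (see
below). `T_t + R_t > 1` is nonphysical and raises an error by default;
values within 1e-9 of 1 are treated as floating-point dust and clamped.
For *synthetic* noisy ensembles, where zero-mean measurement noise can
push the sum marginally above 1 at weakly absorbing wavelengths, the
`allow_nonphysical` option keeps the raw sum so the noise stays
zero-mean on μ_a and ensemble averages stay unbiased; individual values
may then dip slightly below zero.

Ensemble statistics use the pointwise mean and the sample standard
deviation (n−1 denominator; zero for a single sample).

## Wavelength grid and normalization

All fitting happens on a single uniform grid, canonically 200–1000 nm at
1 nm (801 points), matching the usual UV–VIS–NIR acquisition range.
Component spectra from heterogeneous sources are resampled by linear
interpolation — extrapolation is always an error, never a silent clamp —
and normalized onto [0, 1] by shift-then-scale: subtract the minimum,
divide by the new maximum. Normalization is idempotent and preserves
rank order. Because components are normalized, fitted weights `p_i`
carry the cm⁻¹ scale and are only comparable *within* a reconstruction.

## Synthetic component library

No spectral data ship with the package, so a parametric six-component
library emulates the chromophores of lung tissue:

| component  | shape | key defaults |
|------------|-------|--------------|
| melanin    | exp(−(λ−200)/τ) | τ = 175 nm |
| lipofuscin | exp(−(λ−200)/τ) | τ = 250 nm (slower decay than melanin) |
| proteins   | Gaussian + shoulder | 230 nm (σ 9) + 0.25 × 278 nm |
| DNA        | Gaussian + UV background | 260 nm (σ 10) + 0.02 × exp decay (τ 30 nm) |
| HbO        | four Gaussians | 275 (amp 0.25), 412 Soret (1.0, σ 8), 540 (0.22), 576 (0.25) |
| water      | Gaussian + weak tail | 974 nm (σ 20) + 0.01 × exp decay (τ 40 nm) |

Amplitudes are relative within a component (normalization rescales
them); the 0.25 ratio of the HbO 275 nm band to the Soret band matches
tabulated HbO extinction ratios. Band widths are kept narrow (σ 7–10 nm,
somewhat narrower than real hemoglobin bands) so that between-band
wavelengths are genuinely pigment-dominated — the separability
assumption that the two-step reconstruction itself relies on. What the
library does **not** emulate: literature-accurate band shapes or
absolute magnitudes, temperature/pH band shifts, oxygenation mixtures
(a single HbO spectrum stands for hemoglobin), or instrument stray
light. Passing tests therefore demonstrate the correctness of the
*procedure* under the stated model, not quantitative agreement with any
real tissue.

The measurement generator inverts the direct-calculation relation:
`T_t + R_t = 1 − μ_a·d` with a free `transmit_fraction` (default 0.5)
splitting the non-absorbed light, since the relation only constrains
the sum. Additive Gaussian noise (sd in fraction units) is applied
independently to T_t and R_t — noise lives on the measured quantities,
not on μ_a — and each spectrum is clipped to [0, 1]. The default study
conditions are 10 samples, 0.5 mm thickness, and the reference lung
weight vector {water 0.67, melanin 2.85, lipofuscin 2.85, DNA 3.53,
proteins 2.90, HbO 12.62}. Configurations with `μ_a·d > 1` anywhere are
rejected as infeasible. An optional `flat_offset` (cm⁻¹) adds the flat
residual absorption floor that measured spectra retain between bands;
the lung-like fixture uses 0.8 cm⁻¹, the scale of residual floors seen
in soft-tissue measurements.

## Pigment baseline

Aging tissue accumulates melanin and lipofuscin whose broadband,
λ-decreasing absorption forms a baseline under the chromophore bands:

    μ_a-baseline(λ) = p_Mel·μ_a-Mel(λ) + p_Lip·μ_a-Lip(λ)

The two weights are fitted by nonnegative least squares (NNLS) over a
**band-free window**: 300–900 nm minus ±35 nm around 235, 261, 275,
412, 540 and 570 nm. Rationale for each choice:

* fitting through absorption bands would inflate the pigment weights,
  so band neighbourhoods are excluded;
* below 300 nm the protein/DNA/pigment UV structure overlaps
  irreducibly, and above 900 nm the water band dominates;
* the ±35 nm half-width keeps Gaussian band tails out of the window.
  The melanin and lipofuscin curves are strongly collinear, so even
  percent-level band leakage rotates the fitted split between them by
  several percent; at ±35 nm the end-to-end weight recovery error on
  noiseless mixtures is below 0.5% per component.

The baseline is evaluated and subtracted on the full grid. Negative
residuals are reported, not clipped — clipping would bias the residual
floor upward. The floor itself is the minimum of the corrected spectrum
over 800–850 nm, a band-free near-infrared window.

## Two-step unmixing

The full reconstruction follows the two-step procedure: (1) fit and
subtract the pigment baseline on the band-free window; (2) fit the
structural components (water, DNA, HbO, proteins) to the corrected
spectrum by NNLS on the **full** grid, where every wavelength carries
information. The reconstructed spectrum is the six-component weighted
sum; residuals are summarized as full-grid RMS and max-absolute. NNLS
was chosen because it is deterministic, reproducible, and enforces the
physical nonnegativity of weights; a joint six-component NNLS fit
(`method="joint"`) is provided for comparison but the two-step path is
the reference. Rank-deficient designs produce a collinearity warning
and a deterministic (but non-unique) solution.

## Fold-ratios

The fold-ratio of a chromophore — spectrum value at the band peak
divided by the baseline value at the same wavelength — proxies its
content. Peaks are *searched* within ±15 nm of the nominal centre
(band maxima drift by a few nm between tissues; the protein band sits
at 235 nm in lung against a 230 nm nominal), with ties broken toward
the nominal centre and then toward shorter wavelength. Before baseline
removal the divisor is the fitted pigment-baseline curve; after removal
it is the scalar flat floor. Removing the baseline raises the
fold-ratios of the sub-600 nm bands (the pigments were camouflaging
them) and lowers the water-band ratio (pigments barely absorb at
974 nm, while the corrected floor is comparatively high).

## Concentrations and blood volume

Weights have no concentration scale of their own, so they are anchored
to the known water content of lung tissue (80% by volume is a good
estimate): water is pinned at the anchor and each non-water component
receives a share of the remaining 20% proportional to its weight
(water's own weight does not enter the rescaling). Concentrations
therefore always sum to exactly 100%.

Concentration SDs are propagated by refitting: the mean-plus-SD
spectrum is run through the same two-step reconstruction (baseline
refitted, not reused) and converted to concentrations; the
per-component absolute difference from the mean-spectrum concentrations
is the SD. The water anchor is fixed, so its SD is zero by construction.

The blood-volume back-calculation uses a volumetric blood model:
hematocrit (cells as % of blood), the WBC+platelet share (1%), the
hemoglobin share of RBC volume (95%), plasma protein content (7%) and
albumin's share of plasma protein (55%). Two presets ship:
`rabbit42` (hematocrit 42%, the midpoint of the adult-rabbit 33–50%
range) and `textbook45` (the textbook 45% composition, which yields
41.8% hemoglobin, 2.2% RBC membranes and 2.1% albumin in whole blood).
With hemoglobin at `f_hb` percent of blood (38.95% for `rabbit42`,
conventionally carried as 39%), a tissue hemoglobin content `c_Hb`
implies `c_Hb·(100−f_hb)/f_hb` of non-hemoglobin blood; the sum is the
blood volume concentration (BVC). The non-hemoglobin part splits into
the cellular remainder and plasma, and subtracting plasma from the
tissue's water anchor gives the non-plasma ("bloodless") water. The
library computes the chain at full precision (identities hold exactly);
`rounded_blood_volume_chain` reproduces the figures of the conventional
hand calculation in which each intermediate is written at one decimal
and reused — there the non-hemoglobin term is truncated (15.95 → 15.9)
rather than rounded, which keeps the chained sums consistent with the
written intermediates (10.2 + 15.9 = 26.1, 15.9 − 0.8 = 15.1,
80 − 15.1 = 64.9).

## Numerical choices and degenerate inputs

* NNLS via `scipy.optimize.nnls` everywhere; no regularization.
* Linear interpolation only; off-grid wavelengths and extrapolation are
  errors.
* Constant spectra cannot be normalized (degenerate-spectrum error);
  all-zero non-water weights cannot be rescaled (degenerate error).
* Fit windows with fewer than two points are underdetermined errors.
* Fold-ratio divisors must be positive; nonpositive baselines raise a
  division-undefined error naming the band.
* Every stochastic operation takes an explicit integer seed
  (`numpy.random.default_rng`); equal seeds give bit-identical output.
* Test and acceptance problem sizes: 801-point grid, 10-sample
  ensembles, 200 Monte-Carlo replicates at 1% noise, 50 replicates per
  noise level for the degradation curve.

## Known limitations

* The direct-calculation relation lumps scattering escape into
  absorption; the package follows that convention rather than
  correcting for it.
* Fitted weights depend on the component normalization convention;
  only weight *ratios* and anchored concentrations are interpretable.
* The synthetic library's band shapes are idealized; quantitative
  fold-ratio magnitudes on synthetic data are not comparable to real
  tissue, only their qualitative behaviour under baseline removal is.
* The melanin/lipofuscin split is ill-conditioned by nature; its
  reliability degrades quickly if band absorption leaks into the fit
  window (hence the conservative window defaults).
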