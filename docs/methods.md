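# Methods

This note documents the models implemented in `heliovis`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real recordings.

## Visual-pigment templates

Two standard nomogram families evaluate rhodopsin relative absorbance from
λmax alone:

* **Govardovskii A1** (default): α band
  `S_α(x) = 1/(e^{A(a−x)} + e^{B(b−x)} + e^{C(c−x)} + D)` with
  `x = λmax/λ`, A = 69.7, B = 28, C = −14.9, D = 0.674, b = 0.922,
  c = 1.104 and `a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940)`; β band a
  Gaussian with amplitude 0.26, peak `189 + 0.315·λmax` nm and width
  `−40.5 + 0.195·λmax` nm.
* **Stavenga 1993**: modified lognormal in `x = log10(λ/λmax)`,
  `exp(−a·x²(1 + b·x + c·x²))` with a = 380, b = 6.09, c = 3b²/8; β band
  the same form at 340 nm (a = 247, b = 3.59) with amplitude 0.29.

α and β are summed and jointly max-normalized on a 0.1 nm grid, so the
evaluated curve peaks at exactly 1. **β-band validity:** the β band is
added only for λmax ≥ 410 nm. For UV/violet pigments the two bands merge
and the published β parameterizations no longer describe a separate band;
adding them there shifts the joint peak several nm short of λmax, which
would make the template's nominal λmax and its actual peak disagree.

Shape diagnostics: full width at half maximum (FWHM) is computed after
linear-interpolation resampling onto a ≤1 nm grid, with the two
half-maximum crossings located by linear interpolation. On the 1 nm
300–700 nm grid the default A1 template at λmax = 570 nm has FWHM
115.1 nm (Stavenga: 114.3 nm); the two families agree within 1 nm. Note
that in the wavelength domain the long-wavelength cutoff of these
templates is *steeper* at half maximum than the short-wavelength limb —
the UV tail and β region broaden the short side.

## Intensity–response model

`V/Vmax = Iⁿ/(Iⁿ+Kⁿ)`. Intensities are relative photon flux derived from
neutral-density attenuation (`I = reference_flux · 10^(−OD)`, OD 0–3.5);
no radiometric calibration is assumed, so K is in relative units and only
intensity ratios matter (the model is exactly scale-equivariant).

Fitting uses bounded nonlinear least squares (trust-region reflective, on
(Vmax, log10 K, n)) multi-started over n ∈ {0.6, 1.0, 1.5} with K started
at the interpolated half-maximum intensity; the lowest residual sum of
squares wins, ties toward the lower n, and a user-supplied initial guess
is never returned worse than it was given. VlogI fits are a known
multi-modal risk; the tests verify the optimizer reaches the brute-force
grid-search optimum. Degenerate inputs: an all-zero curve raises
`IllConditionedFitError`; a fully saturated curve (all responses within 2%
of the maximum) warns that K and n are unconstrained.

Inversion `I = K(V/(Vmax−V))^{1/n}` is valid on 0 < V < Vmax. Error
propagation is the dominant numerical hazard: dI/dV grows as (Vmax−V)⁻²,
so responses above 0.95·Vmax are excluded from inversion by default
(configurable), and the synthetic generator deliberately delivers spectral
flashes at ~0.8·Vmax (below the compressive shoulder) while the white
VlogI ladder tops out at 0.9·Vmax.

## Sensitivity derivation and λmax estimation

Per wavelength: equivalent intensity from the cell's fitted response
function, divided by the per-filter relative photon flux, max-normalized.
Responses of exactly zero map to zero sensitivity; a flat calibration is a
no-op. Replicate cells are averaged per wavelength; the standard error
(sample SD/√n) is computed before the mean is re-normalized to 1, matching
the convention that error bars are reported in raw relative units. Both
orders of template fitting — per cell then average the λmax estimates, or
fit the per-class average — are supported; the pipeline reports the
class-average fit, the acceptance protocol averages per-cell fits.

λmax is estimated by least-squares template regression with a **profiled
amplitude**: for each candidate λmax the optimal nonnegative scale has a
closed form, and the residual is minimized over a 1 nm grid search (ties
toward the lower λmax) followed by bounded 0.1 nm refinement. The profiled
amplitude matters because measured sensitivities are max-normalized on the
coarse 10 nm grid, which rarely contains the template's true peak; a
fixed-amplitude objective is then biased by up to ~1% in scale. A fit
whose optimum touches the search boundary is flagged. The default fit
window is the full 300–700 nm grid; a window restricted to ±120 nm around
the empirical peak is available for cells with secondary structure.

## Screening-pigment filter model

The lateral filtering geometry of the eye (pigment granules adjacent to
the rhabdom) is collapsed into one effective transmittance
`T(λ) = 10^(−d·Â(λ))` acting on the whole cell, with Â the max-normalized
pigment absorbance and d the effective peak optical density. The default
pigment shape is a **logistic long-pass edge** (midpoint 560 nm, softness
10 nm): red screening pigments absorb broadly below their transition and
transmit beyond it. A narrow α-band-shaped absorbance is selectable but
physically inadequate here — it transmits UV, so at useful densities the
filtered curve's global peak flips into the UV instead of shifting red; a
tabulated-CSV absorbance override is also provided. The edge softness was
fixed once so that the density *calibrated to the observed 590 nm peak*
also reproduces the observed 65–75 nm half-width class; density itself is
always a fitted, not measured, quantity, found by bisection for the
smallest d whose filtered peak lands within 1 nm of the target (peak
evaluated on a 1 nm grid; the peak is monotone in density for long-pass
pigments). For the 570 nm rhodopsin this gives d ≈ 0.74, peak 589 nm,
FWHM 67.9 nm — 47 nm narrower than the bare template.

## Co-expression and the broadband cell

Co-expression is a nonnegative weighted sum of member templates, filtered
if a filter is present, max-normalized. The packaged broadband-cell model
is blue+LW co-expression (weights 0.32/0.68) behind a broad
Gaussian-transmittance bandpass filter (center 503 nm, 1/e half-width
117 nm, density 0.62), chosen once to reproduce the observed cell
(peak ~530 nm, FWHM ~155 nm). A bare blue+green mixture cannot produce
this curve — it is bimodal with a saddle near 520 nm at any weights —
which is exactly the observation that motivates a short-wavelength filter
or self-screening in such cells; the bandpass filter is the minimal
generic mechanism of that kind. `mixture_fit` (NNLS over a template design
matrix, weights renormalized to sum 1) quantifies the mismatch: the
broadband fixture's mixture residual is orders of magnitude above a
unimodal cell's single-template residual.

## Classification and mosaic combinatorics

Cells are classified by peak wavelength and FWHM with an ordered,
config-exposed rule list; first match wins: broadband (FWHM ≥ 140 nm, any
peak) before the peak windows — UV ≤ 410, blue 410–500, yellow–orange
580–620 with FWHM ≤ 85, green 500–580 with FWHM ≥ 90 — so very wide
curves are never mistaken for green. Curves with no spectral contrast, or
matching no rule, are "unclassified"; diagnostics are always returned and
classification is deterministic and total. Ommatidial types are unordered
R1/R2 class pairs with repetition (k classes → k(k+1)/2), and the
multinomial retina sampler quantifies how rarely a blindly inserted
electrode hits a 5%-frequency UV cell.

## Character evolution

Binary characters on rooted trees (Newick via dendropy; polytomies are
resolved with zero-information edges for parsimony). Fitch parsimony
returns the minimum change count, one most-parsimonious assignment
(deterministic tie-breaks: state 0 at the root, parent state below), and
the change edges identified by the tip sets they subtend. Marginal ML uses
the symmetric two-state Mk model — transition probability
`0.5 ± 0.5·e^(−2μt)` — with a single rate and uniform root prior (the
standard default for binary likelihood character mapping); marginals are
computed by sum-product message passing, exact at every node for this
reversible model. Missing branch lengths are replaced by unit lengths and
flagged. The packaged fixture is the six-taxon Heliconiini topology with
the established blue-opsin site-116 states (Ala in *H. ismenius* and
*H. numata*, Ser elsewhere, *Eueides* outgroup); site numbering follows a
reference sequence through `map_reference_site` (1-based ungapped residue
→ alignment column, squid-rhodopsin convention for opsins).

## Synthetic data: what it emulates and what it does not

The generator produces per-cell VlogI series (OD 3.5→0, step 0.5) and
50 ms spectral flash series (300–700 nm, 10 nm) from the packaged species
models, with additive Gaussian response noise (default SD 1 mV) clipped at
zero, all driven by one seeded numpy Generator (bit-reproducible).
Defaults: Vmax = 60 mV, n = 1, K = 1/9 so the brightest white flash sits
at 0.9·Vmax; spectral flashes at 0.8·Vmax as above. Species model sets
encode the reported cell classes (UV1 365 nm in *H. melpomene* and
*H. ismenius*; blue 470 vs 445 nm; green 570 vs 555 nm in *H. erato*,
whose set also has UV1 355 and UV2 390) with class frequencies 5% UV,
20% blue and the 75% LW fraction split 55/15/5 among green, yellow–orange
and broadband (the split within LW is a plausible choice, not a measured
one).

Not emulated: heteroscedastic or correlated noise, electrode drift,
adaptation, rhabdom waveguide optics and self-screening, and the true
(unmeasured) filter-pigment spectrum. Passing recovery tests therefore
shows the analysis is correct and well-conditioned under the stated noise
model at the stated problem sizes (50 replicates per cell model), not
that real recordings meet those assumptions.

## Numerical conventions

Grids are strictly increasing within 250–800 nm (measurement grid
300–700/10 nm; internal evaluation 1 nm; argmax checks 0.1 nm). All
sensitivity products are max-normalized to exactly 1 on their own grid.
CSV readers validate rather than coerce (out-of-range wavelengths,
duplicates, non-numeric fields and locale decimal commas are errors naming
the offending row). Pipeline runs emit the resolved configuration, its
hash and the seed, and are byte-reproducible.
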