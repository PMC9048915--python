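# heliovis

Photoreceptor spectral physiology and opsin character evolution toolkit for
*Heliconius* butterflies.

Butterfly compound eyes build color vision from a handful of rhodopsins,
tuned by opsin sequence evolution, photostable screening pigments and opsin
co-expression. Measuring that tuning means intracellular recording: a cell's
voltage responses to neutral-density-attenuated white flashes and to
narrow-band spectral flashes (300–700 nm, 10 nm steps) are converted into a
relative spectral sensitivity and matched against visual-pigment absorbance
templates. `heliovis` implements that entire desk-side analysis, plus the
forward models and combinatorics needed to interpret it, for physiologists
and evolutionary biologists working on insect vision.

## The models at the core

**Intensity–response.** Response amplitude follows the Naka–Rushton
function

    V / Vmax = Iⁿ / (Iⁿ + Kⁿ)

with `Vmax` the maximal depolarization (mV), `K` the intensity of the
half-maximal response (relative photon flux) and `n` the slope. The fitted
function is inverted, `I = K (V/(Vmax−V))^{1/n}`, to convert each spectral
flash response to an equivalent intensity; dividing by the per-filter
photon-flux calibration and max-normalizing yields the relative spectral
sensitivity S(λ).

**Templates.** S(λ) of a single-pigment cell is described by a rhodopsin
nomogram parameterized only by the peak wavelength λmax (Govardovskii A1
α+β template by default; Stavenga 1993 as an alternative). λmax is
estimated by least-squares template regression with a profiled amplitude.

**Non-opsin tuning.** A screening pigment with effective optical density d
multiplies the rhodopsin absorbance by a transmittance `10^(−d·Â(λ))`,
red-shifting and narrowing the cell (the 590 nm yellow–orange cell built on
a 570 nm rhodopsin); opsin co-expression adds templates with nonnegative
weights (the broadband blue–green cell). `mixture_fit` solves the inverse
problem by NNLS.

**Mosaic and character evolution.** Ommatidial types are unordered pairs of
R1/R2 cell classes (k classes → k(k+1)/2 types). Binary opsin characters
(e.g. the blue-opsin Ser116Ala substitution, squid-rhodopsin numbering) are
reconstructed on species trees by Fitch parsimony and by marginal ML under
the symmetric two-state Mk model.

A seeded synthetic-recording generator runs the measurement process forward
from packaged per-species cell models (*H. melpomene*, *H. ismenius*,
*H. erato*), so every analysis step can be validated by parameter recovery.

## Worked example

```python
import numpy as np
import heliovis as hv

# recover the H. melpomene blue cell's lambda_max from 50 noisy synthetic
# recordings (1 mV response noise), running the full analysis per cell
model = hv.species_model_set("H_melpomene").models["blue"]
calib = hv.FluxCalibration.flat(hv.measurement_grid())
estimates = []
for seed in range(1, 51):
    rec = hv.generate_recording(model, noise=hv.NoiseModel(response_sd=1.0, seed=seed))
    params, _ = hv.fit_naka_rushton(rec.vlogi)
    sens = hv.derive_sensitivity(rec.flashes, params, calib)
    estimates.append(hv.fit_lambda_max(sens).lambda_max_hat)
print(f"blue cell lambda_max: {np.mean(estimates):.1f} +/- {np.std(estimates):.1f} nm (n=50)")

print(f"570 nm template half-width: {hv.half_width(hv.PigmentTemplate(570.0)):.1f} nm")

res = hv.fitch_parsimony(hv.HELICONIINI_TREE_NEWICK, hv.SER116ALA_STATES)
print(f"Ala116 origins: {res.n_changes}, on edge subtending {sorted(res.change_edges[0])}")

types = hv.enumerate_ommatidial_types({"UVRh1", "BRh", "BRh+LWRh"})
print(f"ommatidial types for 3 R1/R2 classes: {len(types)}")
```

prints

```
blue cell lambda_max: 470.1 +/- 1.1 nm (n=50)
570 nm template half-width: 115.1 nm
Ala116 origins: 1, on edge subtending ['Heliconius_ismenius', 'Heliconius_numata']
ommatidial types for 3 R1/R2 classes: 6
```

The blue-cell estimate recovers the generating 470 nm pigment to within the
noise; the template half-width is the shape diagnostic that separates
single-pigment cells (~115 nm at 570) from the filtered yellow–orange cell
(~68 nm) and the broadband cell (~155 nm); the Ser116Ala substitution maps
to a single origin in the common ancestor of *H. ismenius* and *H. numata*;
and three R1/R2 cell classes combine into six ommatidial types.

Estimators with a scikit-learn surface (`NakaRushtonRegressor`,
`LambdaMaxEstimator`, `OpsinMixture`, `CellClassifier`) wrap the same
functions for use in pipelines and model selection.

### Command line

```bash
heliovis simulate --species H_melpomene --n-cells 20 --noise-sd 1.0 --seed 42 --out-dir demo
heliovis average demo --out-dir demo/out         # full pipeline: fits, averages, lambda_max table
heliovis enumerate-mosaic UVRh1 BRh BRh+LWRh
heliovis ancestral tree.nwk states.csv --method fitch
heliovis map-site alignment.fasta --reference squid_rhodopsin --position 116
```

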