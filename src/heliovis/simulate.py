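"""Synthetic intracellular-recording generator and packaged species models.

The generator runs the measurement process forward: a cell model's relative
spectral sensitivity is combined with the stimulus photon flux, passed
through the Naka-Rushton response function and corrupted with additive
Gaussian noise, producing a VlogI series (white light over a 0-3.5 OD
neutral-density ladder) plus a 50 ms spectral flash series on the 300-700
nm / 10 nm interference-filter grid -- exactly the inputs the analysis
pipeline consumes.  Zero-noise recordings round-trip through the pipeline
to the generating sensitivity exactly.

Default generator parameters: Vmax = 60 mV (comfortably above the ~50 mV
amplitude screen applied to real recordings), slope n = 1, and K chosen so
the brightest unattenuated flash sits at 0.9 * Vmax; response noise SD is
1 mV.  All randomness flows through a single numpy Generator seeded from
the NoiseModel, so datasets are bit-reproducible.

The packaged species model sets encode the photoreceptor classes reported
for each species: UV1, blue and green cells as single rhodopsins; the
yellow-orange cell as the green rhodopsin behind the red screening-pigment
filter calibrated to a 590 nm peak; and the broadband cell as BRh+LWRh
co-expression behind a short-wavelength bandpass filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .photoresponse import NakaRushtonParams, VLogICurve, nr_response
from .sensitivity import FluxCalibration, SpectralFlashSeries
from .templates import measurement_grid
from .tuning import FilterSpec, PhotoreceptorModel, calibrate_filter, model_sensitivity
from .templates import PigmentTemplate, spectral_grid

__all__ = [
    "NoiseModel",
    "ResponseRecording",
    "SpeciesModelSet",
    "default_naka_rushton",
    "default_calibration",
    "xenon_calibration",
    "generate_recording",
    "generate_retina_dataset",
    "species_model_set",
    "SPECIES",
]

#: OD ladder of the intensity-response series (3.5 down to 0, step 0.5).
OD_STEPS = np.arange(3.5, -0.25, -0.5)

#: Brightest white flash sits at this fraction of Vmax with default params.
TOP_RESPONSE_FRACTION = 0.9

#: Spectral flashes drive the best wavelength to this fraction of Vmax; kept
#: below the compressive shoulder of the response function, where inversion
#: amplifies voltage noise into large intensity errors.
FLASH_RESPONSE_FRACTION = 0.8


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise (mV on responses)."""

    response_sd: float = 1.0
    sensitivity_sd: float = 0.0  # for direct-sensitivity mode
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response_sd < 0 or self.sensitivity_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class ResponseRecording:
    """One synthetic cell: VlogI series plus spectral flash series."""

    vlogi: VLogICurve
    flashes: SpectralFlashSeries
    label: str = ""


def default_naka_rushton(v_max: float = 60.0, n: float = 1.0) -> NakaRushtonParams:
    """Default generator parameters; K places the brightest white flash at
    0.9 * Vmax (reference flux 1.0)."""
    k = (TOP_RESPONSE_FRACTION / (1.0 - TOP_RESPONSE_FRACTION)) ** (-1.0 / n)
    return NakaRushtonParams(v_max=v_max, k=k, n=n)


def default_calibration(grid: np.ndarray | None = None) -> FluxCalibration:
    """Flat photon-flux calibration (perfectly corrected filters)."""
    grid = measurement_grid() if grid is None else grid
    return FluxCalibration.flat(grid)


def xenon_calibration(grid: np.ndarray | None = None) -> FluxCalibration:
    """Synthetic xenon-arc-shaped calibration for tests.

    A plausible smooth lamp-and-filter photon-flux profile (rising through
    the UV, broad maximum in the visible); not a measured spectrum.
    """
    grid = measurement_grid() if grid is None else np.asarray(grid, dtype=float)
    flux = 0.35 + 0.65 * np.exp(-(((grid - 520.0) / 210.0) ** 2))
    return FluxCalibration(wavelengths=grid, relative_flux=flux)


def generate_recording(
    model: PhotoreceptorModel,
    nr: NakaRushtonParams | None = None,
    calib: FluxCalibration | None = None,
    noise: NoiseModel | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> ResponseRecording:
    """Simulate one cell's VlogI and spectral-flash recording.

    Spectral responses are ``nr_response(flux0 * calib * S_model)`` with the
    flash intensity scale ``flux0`` set so the best-driven wavelength
    responds at 0.8 * Vmax (off the compressive shoulder); the VlogI series
    attenuates a reference white flash (flux 1.0) over the OD ladder.  Gaussian response noise is added
    to every response and clipped at zero (amplitudes are non-negative).
    """
    nr = default_naka_rushton() if nr is None else nr
    calib = default_calibration() if calib is None else calib
    noise = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(noise.seed) if rng is None else rng

    grid = calib.wavelengths
    s_model = model_sensitivity(model, grid).sensitivity

    v_white = nr_response(10.0 ** (-OD_STEPS), nr)
    drive = calib.relative_flux * s_model
    target_i = nr.k * (FLASH_RESPONSE_FRACTION / (1.0 - FLASH_RESPONSE_FRACTION)) ** (1.0 / nr.n)
    flux0 = target_i / drive.max()
    v_spec = nr_response(flux0 * drive, nr)

    if noise.response_sd > 0:
        v_white = v_white + rng.normal(0.0, noise.response_sd, v_white.shape)
        v_spec = v_spec + rng.normal(0.0, noise.response_sd, v_spec.shape)
    v_white = np.clip(v_white, 0.0, None)
    v_spec = np.clip(v_spec, 0.0, None)

    return ResponseRecording(
        vlogi=VLogICurve(od_steps=OD_STEPS.copy(), responses=v_white, reference_flux=1.0),
        flashes=SpectralFlashSeries(wavelengths=grid, responses=v_spec),
        label=model.label,
    )


@dataclass(frozen=True)
class SpeciesModelSet:
    """Named collection of cell models with retinal class frequencies."""

    species: str
    models: dict  # label -> PhotoreceptorModel
    frequencies: dict  # label -> frequency, summing to 1

    def __post_init__(self) -> None:
        if set(self.models) != set(self.frequencies):
            raise ValueError("models and frequencies must cover the same labels")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class frequencies must sum to 1, got {total:.9f}")


def _yellow_orange_model(lw_lambda_max: float) -> PhotoreceptorModel:
    # Red screening pigment: long-pass edge at 560 nm, density calibrated so
    # the filtered peak of the species' LW rhodopsin sits at 590 nm.
    filt = calibrate_filter(
        PigmentTemplate(lw_lambda_max),
        target_peak=590.0,
        grid=spectral_grid(300.0, 700.0, 1.0),
    )
    return PhotoreceptorModel(
        opsin_weights={lw_lambda_max: 1.0}, filter=filt, label="yellow-orange"
    )


def _broadband_model(blue_lambda_max: float, lw_lambda_max: float) -> PhotoreceptorModel:
    # BRh (weak) + LWRh co-expression behind a broad short-wavelength
    # bandpass filter; parameters calibrated once to the observed broadband
    # cell (peak ~530 nm, half-width ~155-160 nm).
    filt = FilterSpec(pigment_lambda_max=503.0, shape="bandpass_gaussian", width=117.0, density=0.62)
    return PhotoreceptorModel(
        opsin_weights={blue_lambda_max: 0.32, lw_lambda_max: 0.68},
        filter=filt,
        label="broadband",
    )


def _melpomene_like(species: str, blue: float) -> SpeciesModelSet:
    # 75% LW-sensitive cells (split 55/15/5 among green, yellow-orange and
    # broadband), 20% blue, 5% UV1.
    models = {
        "UV": PhotoreceptorModel({365.0: 1.0}, label="UV"),
        "blue": PhotoreceptorModel({blue: 1.0}, label="blue"),
        "green": PhotoreceptorModel({570.0: 1.0}, label="green"),
        "yellow-orange": _yellow_orange_model(570.0),
        "broadband": _broadband_model(blue, 570.0),
    }
    freqs = {"UV": 0.05, "blue": 0.20, "green": 0.55, "yellow-orange": 0.15, "broadband": 0.05}
    return SpeciesModelSet(species=species, models=models, frequencies=freqs)


def _erato_models() -> SpeciesModelSet:
    models = {
        "UV1": PhotoreceptorModel({355.0: 1.0}, label="UV1"),
        "UV2": PhotoreceptorModel({390.0: 1.0}, label="UV2"),
        "blue": PhotoreceptorModel({470.0: 1.0}, label="blue"),
        "green": PhotoreceptorModel({555.0: 1.0}, label="green"),
        "yellow-orange": _yellow_orange_model(555.0),
        "broadband": _broadband_model(470.0, 555.0),
    }
    freqs = {"UV1": 0.03, "UV2": 0.02, "blue": 0.20, "green": 0.55, "yellow-orange": 0.15, "broadband": 0.05}
    return SpeciesModelSet(species="H_erato", models=models, frequencies=freqs)


_SPECIES_BUILDERS = {
    "H_melpomene": lambda: _melpomene_like("H_melpomene", 470.0),
    "H_ismenius": lambda: _melpomene_like("H_ismenius", 445.0),
    "H_erato": _erato_models,
}

SPECIES = tuple(_SPECIES_BUILDERS)

_species_cache: dict = {}


def species_model_set(species: str) -> SpeciesModelSet:
    """Packaged cell-model set for a species (``H_melpomene``, ``H_ismenius``
    or ``H_erato``); built on first use and cached."""
    if species not in _SPECIES_BUILDERS:
        raise ValueError(f"unknown species {species!r}; available: {sorted(_SPECIES_BUILDERS)}")
    if species not in _species_cache:
        _species_cache[species] = _SPECIES_BUILDERS[species]()
    return _species_cache[species]


def generate_retina_dataset(
    models: SpeciesModelSet,
    n_cells: int,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    *,
    calib: FluxCalibration | None = None,
    nr: NakaRushtonParams | None = None,
) -> tuple[list[ResponseRecording], list[str]]:
    """Draw *n_cells* cells per the species class frequencies and simulate a
    recording for each; returns ``(recordings, true_labels)``."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    noise = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    from .mosaic import sample_retina  # local import to avoid a cycle

    labels = sample_retina(models.frequencies, n_cells, rng)
    recordings = [
        generate_recording(models.models[lbl], nr=nr, calib=calib, noise=noise, rng=rng)
        for lbl in labels
    ]
    return recordings, labels
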