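"""Visual-pigment absorbance templates (nomograms) and curve-shape statistics.

A rhodopsin's normalized absorbance spectrum is well described by a universal
parametric curve ("nomogram") that depends only on the wavelength of peak
absorbance, ``lambda_max``.  Two standard template families are provided:

* ``govardovskii_a1`` -- the Govardovskii et al. (2000) template for
  A1 (retinal) pigments: a log-inverse-wavelength alpha band plus a Gaussian
  beta (cis) band.  This is the default family.
* ``stavenga1993`` -- the modified-lognormal template of Stavenga, Smits &
  Hoeve (1993), alpha band plus a fixed 340 nm beta band.

Both are evaluated on wavelength grids in nanometres and max-normalized so
the returned curve attains exactly 1.0 at its peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRID_MIN_NM",
    "GRID_MAX_NM",
    "TEMPLATE_FAMILIES",
    "PigmentTemplate",
    "spectral_grid",
    "measurement_grid",
    "evaluate_template",
    "peak_wavelength",
    "half_width",
]

#: Wavelength range (nm) on which grids and templates are considered valid.
GRID_MIN_NM = 250.0
GRID_MAX_NM = 800.0

#: Valid lambda_max range (nm) for the supported template families.
LAMBDA_MAX_MIN_NM = 300.0
LAMBDA_MAX_MAX_NM = 700.0

TEMPLATE_FAMILIES = ("govardovskii_a1", "stavenga1993")


def spectral_grid(start: float = 300.0, stop: float = 700.0, step: float = 1.0) -> np.ndarray:
    """Strictly increasing wavelength grid in nm, validated to [250, 800]."""
    grid = np.arange(start, stop + step / 2, step, dtype=float)
    validate_grid(grid)
    return grid


def measurement_grid() -> np.ndarray:
    """The 300-700 nm, 10 nm interference-filter measurement grid."""
    return spectral_grid(300.0, 700.0, 10.0)


def validate_grid(wavelengths: np.ndarray) -> np.ndarray:
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.ndim != 1 or wavelengths.size < 2:
        raise ValueError("wavelength grid must be a 1-D array with at least 2 points")
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if wavelengths[0] < GRID_MIN_NM or wavelengths[-1] > GRID_MAX_NM:
        raise ValueError(
            f"wavelength grid must lie within [{GRID_MIN_NM:g}, {GRID_MAX_NM:g}] nm, "
            f"got [{wavelengths[0]:g}, {wavelengths[-1]:g}]"
        )
    return wavelengths


def _govardovskii_a1_alpha(lam: np.ndarray, lambda_max: float) -> np.ndarray:
    # Alpha band in x = lambda_max / lambda coordinates.
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )


def _govardovskii_a1_beta(lam: np.ndarray, lambda_max: float) -> np.ndarray:
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    return 0.26 * np.exp(-(((lam - lam_beta) / b_beta) ** 2))


def _stavenga_band(lam: np.ndarray, lam_peak: float, a0: float, a1: float) -> np.ndarray:
    # Modified lognormal; a2 is tied to a1 so the band is smooth at its peak.
    x = np.log10(lam / lam_peak)
    a2 = 3.0 * a1**2 / 8.0
    return np.exp(-a0 * x**2 * (1.0 + a1 * x + a2 * x**2))


#: Below this lambda_max the beta band is merged into the alpha band and the
#: published beta parameterizations are no longer valid; adding them would
#: double-count UV absorbance and shift the joint peak off lambda_max.
BETA_BAND_MIN_LAMBDA_MAX = 410.0


def _raw_template(lam: np.ndarray, lambda_max: float, family: str, include_beta_band: bool) -> np.ndarray:
    add_beta = include_beta_band and lambda_max >= BETA_BAND_MIN_LAMBDA_MAX
    if family == "govardovskii_a1":
        s = _govardovskii_a1_alpha(lam, lambda_max)
        if add_beta:
            s = s + _govardovskii_a1_beta(lam, lambda_max)
        return s
    if family == "stavenga1993":
        s = _stavenga_band(lam, lambda_max, 380.0, 6.09)
        if add_beta:
            s = s + 0.29 * _stavenga_band(lam, 340.0, 247.0, 3.59)
        return s
    raise ValueError(f"unknown template family {family!r}; expected one of {TEMPLATE_FAMILIES}")


@dataclass(frozen=True)
class PigmentTemplate:
    """Parametric rhodopsin absorbance template.

    Parameters
    ----------
    lambda_max : float
        Peak wavelength in nm; must lie in [300, 700].
    family : str
        ``"govardovskii_a1"`` (default) or ``"stavenga1993"``.
    include_beta_band : bool
        Whether the short-wavelength beta band is added to the alpha band
        before joint normalization (default True).  The beta band is only
        applied for lambda_max >= 410 nm: for UV/violet pigments it merges
        into the alpha band and the published beta parameterizations are
        invalid there.
    """

    lambda_max: float
    family: str = "govardovskii_a1"
    include_beta_band: bool = True
    #: normalization constant (max of raw alpha+beta on a dense grid); lazily cached
    _norm: float = field(default=0.0, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not (LAMBDA_MAX_MIN_NM <= self.lambda_max <= LAMBDA_MAX_MAX_NM):
            raise ValueError(
                f"lambda_max={self.lambda_max:g} nm outside the valid "
                f"[{LAMBDA_MAX_MIN_NM:g}, {LAMBDA_MAX_MAX_NM:g}] nm range"
            )
        if self.family not in TEMPLATE_FAMILIES:
            raise ValueError(f"unknown template family {self.family!r}")
        # Normalize jointly over alpha+beta on a 0.1 nm dense grid so the
        # evaluated curve peaks at exactly 1.0 wherever it is sampled.
        dense = np.arange(GRID_MIN_NM, GRID_MAX_NM + 0.05, 0.1)
        raw = _raw_template(dense, self.lambda_max, self.family, self.include_beta_band)
        object.__setattr__(self, "_norm", float(raw.max()))

    def __call__(self, wavelengths: np.ndarray | float) -> np.ndarray | float:
        lam = np.asarray(wavelengths, dtype=float)
        scalar = lam.ndim == 0
        lam = np.atleast_1d(lam)
        if np.any(lam < GRID_MIN_NM) or np.any(lam > GRID_MAX_NM):
            raise ValueError(f"wavelengths outside validity range [{GRID_MIN_NM:g}, {GRID_MAX_NM:g}] nm")
        s = _raw_template(lam, self.lambda_max, self.family, self.include_beta_band) / self._norm
        return float(s[0]) if scalar else s


def evaluate_template(template: PigmentTemplate, grid: np.ndarray) -> np.ndarray:
    """Relative absorbance of *template* on *grid*, in [0, 1], peak-normalized."""
    grid = validate_grid(np.asarray(grid, dtype=float))
    return template(grid)


def peak_wavelength(wavelengths: np.ndarray, values: np.ndarray) -> float:
    """Wavelength of the sampled curve's maximum (no interpolation)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.asarray(values, dtype=float)
    return float(wavelengths[int(np.argmax(values))])


def _resample(wavelengths: np.ndarray, values: np.ndarray, step: float = 1.0):
    """Linear-interpolation resample onto a <=1 nm internal grid."""
    fine = np.arange(wavelengths[0], wavelengths[-1] + step / 2, step)
    return fine, np.interp(fine, wavelengths, values)


def half_width(
    curve_or_template,
    wavelengths: np.ndarray | None = None,
    *,
    grid: np.ndarray | None = None,
) -> float:
    """Full width at half maximum (nm) of a sensitivity curve or template.

    Accepts either a :class:`PigmentTemplate` (evaluated on *grid*, default
    the full 1 nm 300-700 grid) or a sampled curve given as ``(values,
    wavelengths)``.  The curve is resampled onto a 1 nm internal grid and the
    two half-maximum crossings are located by linear interpolation; their
    separation is returned.

    Raises
    ------
    ValueError
        If the half-maximum level is not crossed on one side of the peak
        within the grid (the uncrossed side is named in the message).
    """
    if isinstance(curve_or_template, PigmentTemplate):
        lam = spectral_grid() if grid is None else validate_grid(np.asarray(grid, dtype=float))
        vals = curve_or_template(lam)
    else:
        vals = np.asarray(curve_or_template, dtype=float)
        if wavelengths is None:
            raise ValueError("wavelengths required when passing a sampled curve")
        lam = np.asarray(wavelengths, dtype=float)

    lam, vals = _resample(lam, vals)
    vals = vals / vals.max()
    ipk = int(np.argmax(vals))
    half = 0.5

    left = np.nonzero(vals[:ipk] < half)[0]
    if left.size == 0:
        raise ValueError("half maximum not crossed on the short-wavelength side of the peak")
    i = left[-1]
    lam_left = lam[i] + (half - vals[i]) / (vals[i + 1] - vals[i]) * (lam[i + 1] - lam[i])

    right = np.nonzero(vals[ipk:] < half)[0]
    if right.size == 0:
        raise ValueError("half maximum not crossed on the long-wavelength side of the peak")
    j = ipk + right[0]
    lam_right = lam[j - 1] + (vals[j - 1] - half) / (vals[j - 1] - vals[j]) * (lam[j] - lam[j - 1])

    return float(lam_right - lam_left)
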