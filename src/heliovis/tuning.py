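"""Forward spectral models for non-opsin photoreceptor tuning.

Two mechanisms, both widespread in butterfly compound eyes, are modeled:

* **Photostable screening-pigment filtering.**  A red filtering pigment
  adjacent to the rhabdom absorbs short wavelengths before they reach the
  visual pigment, red-shifting and narrowing the cell's sensitivity (the
  yellow-orange 590 nm cell built on a 570 nm rhodopsin).  The lateral
  filtering geometry is collapsed into a single effective transmittance
  ``T(lambda) = 10**(-density * A(lambda))`` acting on the whole cell, where
  ``A`` is the max-normalized pigment absorbance and ``density`` the
  effective peak optical density.
* **Opsin co-expression.**  Two opsins in one cell produce a sensitivity
  that is a nonnegative weighted sum of both templates (optionally filtered),
  e.g. the broadband blue-green cell modeled as BRh+LWRh co-expression
  behind a short-wavelength bandpass filter.

``mixture_fit`` solves the inverse problem -- the best nonnegative template
mixture for a measured sensitivity -- by NNLS, and is also exposed as the
sklearn-style :class:`OpsinMixture` transformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .sensitivity import SpectralSensitivity
from .templates import PigmentTemplate, half_width, peak_wavelength, validate_grid

__all__ = [
    "FilterSpec",
    "PhotoreceptorModel",
    "pigment_absorbance",
    "filter_transmittance",
    "filtered_sensitivity",
    "calibrate_filter",
    "coexpression_sensitivity",
    "model_sensitivity",
    "mixture_fit",
    "OpsinMixture",
]

PIGMENT_SHAPES = ("longpass_logistic", "alpha_band", "bandpass_gaussian", "tabulated")


@dataclass(frozen=True)
class FilterSpec:
    """Photostable screening-pigment filter.

    Parameters
    ----------
    pigment_lambda_max : float
        Spectral anchor of the pigment in nm (default 560, the ommochrome
        screening pigment reported for Heliconius eyes).  For the default
        long-pass shape this is the logistic edge midpoint; for the
        alpha-band shape the band peak; for the Gaussian bandpass the
        transmission-window center.
    shape : str
        ``"longpass_logistic"`` (default), ``"alpha_band"``,
        ``"bandpass_gaussian"``, or ``"tabulated"`` (absorbance supplied via
        ``tabulated``).
    density : float
        Effective peak optical density d >= 0; transmittance is
        ``10**(-d * A_hat)`` with ``A_hat`` max-normalized absorbance.
    width : float
        Shape parameter in nm: logistic edge softness (default 10) or
        Gaussian window half-width (1/e) for the bandpass shape.
    placement : str
        ``"proximal"`` or ``"distal"``; metadata only in the effective model.
    tabulated : tuple of arrays, optional
        ``(wavelengths, absorbance)`` for ``shape="tabulated"``; linearly
        interpolated and max-normalized.
    """

    pigment_lambda_max: float = 560.0
    shape: str = "longpass_logistic"
    density: float = 1.0
    width: float = 10.0
    placement: str = "proximal"
    tabulated: tuple | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("filter density must be >= 0")
        if self.shape not in PIGMENT_SHAPES:
            raise ValueError(f"unknown pigment shape {self.shape!r}; expected one of {PIGMENT_SHAPES}")
        if self.placement not in ("proximal", "distal"):
            raise ValueError("placement must be 'proximal' or 'distal'")
        if self.shape == "tabulated" and self.tabulated is None:
            raise ValueError("shape='tabulated' requires a (wavelengths, absorbance) table")


def pigment_absorbance(spec: FilterSpec, grid: np.ndarray) -> np.ndarray:
    """Max-normalized pigment absorbance A_hat(lambda) on *grid*."""
    lam = validate_grid(np.asarray(grid, dtype=float))
    if spec.shape == "longpass_logistic":
        # Broad absorber below the edge, transparent beyond it: the minimal
        # smooth model of a red screening pigment.
        a = 1.0 / (1.0 + np.exp((lam - spec.pigment_lambda_max) / spec.width))
    elif spec.shape == "alpha_band":
        a = PigmentTemplate(spec.pigment_lambda_max, "govardovskii_a1", include_beta_band=False)(lam)
    elif spec.shape == "bandpass_gaussian":
        # Absorbs everywhere except a Gaussian transmission window.
        a = 1.0 - np.exp(-(((lam - spec.pigment_lambda_max) / spec.width) ** 2))
    else:  # tabulated
        tab_lam, tab_a = (np.asarray(v, dtype=float) for v in spec.tabulated)
        a = np.interp(lam, tab_lam, tab_a)
    amax = a.max()
    if amax <= 0:
        raise ValueError("pigment absorbance is non-positive everywhere on the grid")
    return a / amax


def filter_transmittance(spec: FilterSpec, grid: np.ndarray) -> np.ndarray:
    """Transmittance T = 10**(-density * A_hat), in (0, 1]."""
    return 10.0 ** (-spec.density * pigment_absorbance(spec, grid))


def filtered_sensitivity(
    rh: PigmentTemplate,
    filt: FilterSpec,
    grid: np.ndarray,
) -> SpectralSensitivity:
    """Pointwise product of rhodopsin absorbance and filter transmittance,
    re-normalized to max 1."""
    lam = validate_grid(np.asarray(grid, dtype=float))
    s = rh(lam) * filter_transmittance(filt, lam)
    return SpectralSensitivity(wavelengths=lam, sensitivity=s)


def calibrate_filter(
    rh: PigmentTemplate,
    target_peak: float,
    grid: np.ndarray,
    *,
    base: FilterSpec | None = None,
    max_density: float = 10.0,
    tol_nm: float = 1.0,
) -> FilterSpec:
    """Smallest filter density whose filtered peak is within *tol_nm* of
    *target_peak*, by bisection on density (peak evaluated on a 1 nm grid).

    The pigment shape is fixed (taken from *base*, default the long-pass
    560 nm ommochrome spec); only the density is adjusted.  Raises if the
    target is unreachable at density <= *max_density*.
    """
    lam = validate_grid(np.asarray(grid, dtype=float))
    spec0 = base if base is not None else FilterSpec()
    rh_peak = peak_wavelength(lam, rh(lam))
    if target_peak < rh_peak:
        raise ValueError("target peak must not be below the unfiltered rhodopsin peak")

    def peak_at(d: float) -> float:
        s = filtered_sensitivity(rh, replace(spec0, density=d), lam)
        return peak_wavelength(lam, s.sensitivity)

    if abs(peak_at(0.0) - target_peak) <= tol_nm:
        return replace(spec0, density=0.0)
    if peak_at(max_density) < target_peak - tol_nm:
        raise ValueError(f"target peak {target_peak:g} nm unreachable at density <= {max_density:g}")

    lo, hi = 0.0, max_density
    # Bisect for the smallest density reaching the target (peak is a monotone
    # step function of density on the 1 nm grid for long-pass pigments).
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if peak_at(mid) >= target_peak - tol_nm:
            hi = mid
        else:
            lo = mid
    d = hi
    if abs(peak_at(d) - target_peak) > tol_nm:
        raise ValueError(f"no density yields a peak within {tol_nm:g} nm of {target_peak:g} nm")
    return replace(spec0, density=float(d))


@dataclass(frozen=True)
class PhotoreceptorModel:
    """Generative cell model: opsin mixture weights plus optional filter."""

    opsin_weights: dict  # lambda_max (nm) -> weight
    filter: FilterSpec | None = None
    label: str = ""
    family: str = "govardovskii_a1"

    def __post_init__(self) -> None:
        if not self.opsin_weights:
            raise ValueError("at least one opsin is required")
        w = np.array(list(self.opsin_weights.values()), dtype=float)
        if np.any(w < 0):
            raise ValueError("opsin weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("opsin weights must sum to 1 within 1e-9")


def coexpression_sensitivity(model: PhotoreceptorModel, grid: np.ndarray) -> SpectralSensitivity:
    """Weighted sum of member templates, filtered if a filter is present,
    max-normalized."""
    lam = validate_grid(np.asarray(grid, dtype=float))
    s = np.zeros_like(lam)
    for lmax, w in model.opsin_weights.items():
        s = s + w * PigmentTemplate(float(lmax), model.family)(lam)
    if model.filter is not None:
        s = s * filter_transmittance(model.filter, lam)
    return SpectralSensitivity(wavelengths=lam, sensitivity=s)


#: alias: a PhotoreceptorModel's forward sensitivity (single opsins included)
model_sensitivity = coexpression_sensitivity


def mixture_fit(
    sens: SpectralSensitivity,
    candidate_lambdas: list[float],
    *,
    family: str = "govardovskii_a1",
) -> tuple[np.ndarray, float]:
    """Best nonnegative mixture of candidate templates for a sensitivity.

    Solves ``min_w ||S - T w||^2, w >= 0`` by NNLS over the template design
    matrix, returns ``(weights, rss)`` with weights renormalized to sum 1
    (all-zero solutions keep zero weights).  Deterministic.
    """
    if not candidate_lambdas:
        raise ValueError("need at least one candidate lambda_max")
    lam = sens.wavelengths
    s = sens.sensitivity
    mask = np.isfinite(s)
    if not np.any(s[mask] > 0):
        raise ValueError("all-zero sensitivity cannot be decomposed")
    design = np.column_stack([PigmentTemplate(float(l), family)(lam[mask]) for l in candidate_lambdas])
    w, rnorm = nnls(design, s[mask])
    rss = float(rnorm**2)
    total = w.sum()
    if total > 0:
        w = w / total
    return w, rss


class OpsinMixture(BaseEstimator):
    """sklearn-style nonnegative spectral mixture decomposition.

    ``fit(X, y)`` takes wavelengths as a single column ``X`` and a relative
    sensitivity ``y``; ``weights_`` (renormalized to sum 1) and ``rss_`` are
    exposed and ``predict(X)`` reconstructs the fitted mixture.
    """

    def __init__(self, candidate_lambdas: tuple = (470.0, 570.0), family: str = "govardovskii_a1"):
        self.candidate_lambdas = candidate_lambdas
        self.family = family

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        sens = SpectralSensitivity(wavelengths=X, sensitivity=np.asarray(y, dtype=float))
        self.weights_, self.rss_ = mixture_fit(sens, list(self.candidate_lambdas), family=self.family)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        s = np.zeros_like(X)
        for lmax, w in zip(self.candidate_lambdas, self.weights_):
            s = s + w * PigmentTemplate(float(lmax), self.family)(X)
        m = s.max()
        return s / m if m > 0 else s


def narrowing_vs_unfiltered(rh: PigmentTemplate, filt: FilterSpec, grid: np.ndarray) -> float:
    """FWHM reduction (nm) of the filtered cell relative to the bare template."""
    lam = validate_grid(np.asarray(grid, dtype=float))
    fw_rh = half_width(rh, grid=lam)
    fw_f = half_width(filtered_sensitivity(rh, filt, lam).sensitivity, lam)
    return fw_rh - fw_f
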