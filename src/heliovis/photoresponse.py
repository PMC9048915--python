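"""The Naka-Rushton intensity-response model.

Photoreceptor depolarization amplitude V saturates with stimulus intensity I
according to

    V / Vmax = I**n / (I**n + K**n)

where ``Vmax`` is the maximal response amplitude (mV), ``K`` the intensity
eliciting the half-maximal response and ``n`` the dimensionless slope of the
function.  Intensities are handled throughout in *relative* photon-flux units
derived from neutral-density (OD) attenuation of a reference beam
(``I = reference_flux * 10**(-OD)``); K is therefore in the same relative
units and only intensity *ratios* are meaningful.

The module provides forward evaluation, algebraic inversion to effective
intensity, and a multi-start bounded nonlinear least-squares fit, exposed
both as functions and as the sklearn-style :class:`NakaRushtonRegressor`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NakaRushtonParams",
    "VLogICurve",
    "IllConditionedFitError",
    "FitWarning",
    "nr_response",
    "invert_response",
    "fit_naka_rushton",
    "NakaRushtonRegressor",
]


class IllConditionedFitError(RuntimeError):
    """Raised when a VlogI curve carries no usable intensity-response signal."""


class FitWarning(UserWarning):
    """Non-fatal fit diagnostics (saturated curve, non-convergence)."""


@dataclass(frozen=True)
class NakaRushtonParams:
    """Parameters of the intensity-response function (all strictly positive)."""

    v_max: float  # mV
    k: float      # relative photon flux at half-maximal response
    n: float      # dimensionless slope

    def __post_init__(self) -> None:
        if not (self.v_max > 0 and self.k > 0 and self.n > 0):
            raise ValueError(f"NakaRushtonParams must be strictly positive, got {self}")


@dataclass(frozen=True)
class VLogICurve:
    """One cell's response-log intensity series over a 0-3.5 OD attenuation range."""

    od_steps: np.ndarray      # neutral-density values, within [0, 3.5]
    responses: np.ndarray     # mV, non-negative
    reference_flux: float = 1.0  # relative photon flux at OD 0

    def __post_init__(self) -> None:
        od = np.asarray(self.od_steps, dtype=float)
        v = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "od_steps", od)
        object.__setattr__(self, "responses", v)
        if od.shape != v.shape:
            raise ValueError("od_steps and responses must have identical shapes")
        if np.any(od < 0) or np.any(od > 3.5):
            raise ValueError("OD steps must lie within [0, 3.5]")
        if np.any(v < 0):
            raise ValueError("responses must be non-negative")
        if not self.reference_flux > 0:
            raise ValueError("reference_flux must be positive")

    @property
    def intensities(self) -> np.ndarray:
        """Relative photon flux per step: reference_flux * 10**(-OD)."""
        return self.reference_flux * 10.0 ** (-self.od_steps)


def nr_response(intensity, params: NakaRushtonParams):
    """Response (mV) to *intensity* (relative flux >= 0); monotone, in [0, v_max)."""
    i = np.asarray(intensity, dtype=float)
    if np.any(i < 0):
        raise ValueError("intensity must be non-negative")
    with np.errstate(divide="ignore"):
        ip = i**params.n
        v = params.v_max * ip / (ip + params.k**params.n)
    v = np.where(i == 0, 0.0, v)
    return float(v) if np.isscalar(intensity) or np.ndim(intensity) == 0 else v


def invert_response(response, params: NakaRushtonParams):
    """Effective intensity eliciting *response*: I = K * (V / (Vmax - V))**(1/n).

    Valid for 0 < V < Vmax; the intensity is unbounded at Vmax.
    """
    v = np.asarray(response, dtype=float)
    if np.any(v <= 0):
        raise ValueError("response must be strictly positive to invert")
    if np.any(v >= params.v_max):
        raise ValueError("response at or above v_max cannot be inverted (intensity unbounded)")
    i = params.k * (v / (params.v_max - v)) ** (1.0 / params.n)
    return float(i) if np.isscalar(response) or np.ndim(response) == 0 else i


def _initial_k(intensities: np.ndarray, responses: np.ndarray, v_max0: float) -> float:
    """Intensity at the half-maximal response, by interpolation on log10 I."""
    order = np.argsort(intensities)
    i_sorted, v_sorted = intensities[order], responses[order]
    half = v_max0 / 2.0
    above = np.nonzero(v_sorted >= half)[0]
    if above.size == 0 or above[0] == 0:
        return float(np.median(i_sorted))
    j = above[0]
    x0, x1 = np.log10(i_sorted[j - 1]), np.log10(i_sorted[j])
    y0, y1 = v_sorted[j - 1], v_sorted[j]
    frac = (half - y0) / (y1 - y0) if y1 != y0 else 0.5
    return float(10.0 ** (x0 + frac * (x1 - x0)))


def fit_naka_rushton(
    curve: VLogICurve,
    initial_guess: NakaRushtonParams | None = None,
) -> tuple[NakaRushtonParams, float]:
    """Fit (Vmax, K, n) to a VlogI curve by bounded nonlinear least squares.

    The fit is multi-started over slope values n in {0.6, 1.0, 1.5} (plus the
    user's guess, if given), with K started at the intensity of the
    half-maximal response; the start with the lowest residual sum of squares
    wins, ties broken toward the lowest n.  Returns ``(params, rss)``.

    Raises :class:`IllConditionedFitError` for a flat (all-zero) curve and
    warns with :class:`FitWarning` when the curve is fully saturated.
    """
    if np.unique(curve.od_steps).size < 4 or np.ptp(curve.od_steps) < 2.0:
        raise ValueError("need >= 4 distinct OD steps spanning >= 2 OD units")
    return _fit_core(curve.intensities, np.asarray(curve.responses, dtype=float), initial_guess)


def _fit_core(
    intens: np.ndarray,
    resp: np.ndarray,
    initial_guess: NakaRushtonParams | None = None,
) -> tuple[NakaRushtonParams, float]:
    vmax_obs = resp.max()
    if vmax_obs <= 0:
        raise IllConditionedFitError("flat VlogI curve: all responses are zero")
    if np.all(resp >= 0.98 * vmax_obs):
        warnings.warn(
            "VlogI curve is saturated (all responses within 2% of max); "
            "K and n are ill-constrained",
            FitWarning,
            stacklevel=2,
        )

    def residuals(theta):
        v_max, log10_k, n = theta
        p = NakaRushtonParams(v_max=v_max, k=10.0**log10_k, n=n)
        return nr_response(intens, p) - resp

    log_i = np.log10(intens)
    bounds = (
        [0.5 * vmax_obs, log_i.min() - 3.0, 0.1],
        [3.0 * vmax_obs, log_i.max() + 3.0, 10.0],
    )
    starts = [0.6, 1.0, 1.5]
    if initial_guess is not None:
        starts.append(initial_guess.n)
    v_max0 = min(max(vmax_obs / 0.95, bounds[0][0] + 1e-9), bounds[1][0])
    if initial_guess is not None:
        v_max0 = float(np.clip(initial_guess.v_max, bounds[0][0] + 1e-12, bounds[1][0]))
        k0_guess = float(np.clip(np.log10(initial_guess.k), bounds[0][1], bounds[1][1]))
    k0_half = float(np.clip(np.log10(_initial_k(intens, resp, v_max0)), bounds[0][1], bounds[1][1]))

    best: tuple[float, float, NakaRushtonParams] | None = None  # (rss, n, params)
    converged = False
    for n0 in starts:
        n0 = float(np.clip(n0, bounds[0][2], bounds[1][2]))
        k0s = [k0_half] if initial_guess is None else [k0_half, k0_guess]
        for k0 in k0s:
            sol = least_squares(residuals, x0=[v_max0, k0, n0], bounds=bounds, method="trf")
            rss = float(2.0 * sol.cost)
            params = NakaRushtonParams(v_max=float(sol.x[0]), k=float(10.0 ** sol.x[1]), n=float(sol.x[2]))
            converged = converged or sol.success
            cand = (rss, params.n, params)
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
    assert best is not None
    rss, _, params = best

    if initial_guess is not None:
        rss_guess = float(np.sum(residuals([initial_guess.v_max, np.log10(initial_guess.k), initial_guess.n]) ** 2))
        if rss_guess < rss:  # never return a fit worse than the supplied guess
            params, rss = initial_guess, rss_guess
    if not converged:
        warnings.warn("Naka-Rushton fit did not converge; returning best-so-far parameters", FitWarning, stacklevel=2)
    return params, rss


class NakaRushtonRegressor(RegressorMixin, BaseEstimator):
    """sklearn-style estimator for the Naka-Rushton intensity-response fit.

    ``fit(X, y)`` takes intensities (relative flux) as a single-column ``X``
    and responses in mV as ``y``; fitted parameters are exposed as ``v_max_``,
    ``k_``, ``n_`` and the residual sum of squares as ``rss_``.

    Parameters
    ----------
    initial_guess : NakaRushtonParams, optional
        Extra multi-start point; the returned fit is never worse than it.
    """

    def __init__(self, initial_guess: NakaRushtonParams | None = None):
        self.initial_guess = initial_guess

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single intensity column")
            X = X[:, 0]
        if np.any(X <= 0):
            raise ValueError("intensities must be strictly positive")
        if np.unique(X).size < 4 or np.ptp(np.log10(X)) < 2.0:
            raise ValueError("need >= 4 distinct intensities spanning >= 2 decades")
        params, rss = _fit_core(X, y, self.initial_guess)
        self.v_max_, self.k_, self.n_, self.rss_ = params.v_max, params.k, params.n, rss
        self.n_features_in_ = 1
        return self

    @property
    def params_(self) -> NakaRushtonParams:
        check_is_fitted(self, "v_max_")
        return NakaRushtonParams(v_max=self.v_max_, k=self.k_, n=self.n_)

    def predict(self, X):
        check_is_fitted(self, "v_max_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return nr_response(X, self.params_)

    def inverse(self, y):
        """Effective intensities for responses *y* (0 < y < v_max_)."""
        check_is_fitted(self, "v_max_")
        return invert_response(np.asarray(y, dtype=float), self.params_)
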