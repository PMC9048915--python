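"""Photoreceptor classification and ommatidial-type combinatorics.

Cells are classified from the peak wavelength and half-width of their
relative spectral sensitivity: single-rhodopsin classes occupy
non-overlapping peak windows; the screening-pigment-filtered yellow-orange
cell is distinguished from the green cell by its narrow half-width; the
broadband cell by its very wide half-width regardless of peak.

Ommatidial types are the unordered pairs (with repetition) of the
short-wavelength opsin classes expressed in the R1/R2 cells, so a k-class
inventory yields k*(k+1)/2 types.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .sensitivity import SpectralSensitivity
from .templates import half_width, peak_wavelength

__all__ = [
    "CellClassRule",
    "DEFAULT_RULES",
    "default_rules",
    "classify_cell",
    "CellClassifier",
    "enumerate_ommatidial_types",
    "sample_retina",
]


@dataclass(frozen=True)
class CellClassRule:
    """One classification rule: peak window plus optional half-width bounds."""

    label: str
    peak_window: tuple[float, float] | None = None  # nm, inclusive
    min_halfwidth: float | None = None              # nm
    max_halfwidth: float | None = None              # nm
    preferred_model: str = "single"                 # single | filtered | mixture

    def matches(self, peak_nm: float, fwhm_nm: float | None) -> bool:
        if self.peak_window is not None:
            lo, hi = self.peak_window
            if not (lo <= peak_nm <= hi):
                return False
        if self.min_halfwidth is not None:
            if fwhm_nm is None or fwhm_nm < self.min_halfwidth:
                return False
        if self.max_halfwidth is not None:
            if fwhm_nm is None or fwhm_nm > self.max_halfwidth:
                return False
        return True


def default_rules() -> list[CellClassRule]:
    """Default class windows bracketing the reported Heliconius cell types.

    Evaluated in order, first match wins: the broadband rule (half-width >=
    140 nm at any peak) precedes the peak-window rules so that very wide
    curves are never mistaken for green cells; the yellow-orange rule
    requires the narrow half-width produced by screening-pigment filtering.
    All thresholds are configuration, not behavior baked into the classifier.
    """
    return [
        CellClassRule("broadband", None, min_halfwidth=140.0, preferred_model="mixture"),
        CellClassRule("UV", (300.0, 410.0)),
        CellClassRule("blue", (410.0, 500.0)),
        CellClassRule("yellow-orange", (580.0, 620.0), max_halfwidth=85.0, preferred_model="filtered"),
        CellClassRule("green", (500.0, 580.0), min_halfwidth=90.0),
    ]


DEFAULT_RULES = default_rules()


def classify_cell(
    sens: SpectralSensitivity,
    rules: list[CellClassRule] | None = None,
) -> tuple[str, dict]:
    """Classify one cell by peak sensitivity and curve shape.

    Returns ``(label, diagnostics)``; the label is ``"unclassified"`` when no
    rule matches or the curve is degenerate (e.g. the half maximum is never
    crossed).  Diagnostics (peak nm, FWHM nm when defined) are always
    returned.  Deterministic and total.
    """
    rules = DEFAULT_RULES if rules is None else rules
    lam = sens.wavelengths
    s = sens.sensitivity
    finite = np.isfinite(s)
    if np.ptp(s[finite]) < 1e-6:  # no spectral contrast at all
        return "unclassified", {"peak_nm": None, "fwhm_nm": None, "label": "unclassified"}
    peak = peak_wavelength(lam[finite], s[finite])
    try:
        fwhm = half_width(s[finite], lam[finite])
    except ValueError:
        fwhm = None
    label = "unclassified"
    for rule in rules:
        if rule.matches(peak, fwhm):
            label = rule.label
            break
    diagnostics = {"peak_nm": peak, "fwhm_nm": fwhm, "label": label}
    return label, diagnostics


class CellClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based spectral-class assignment with a sklearn predict surface.

    ``predict(X)`` takes a 2-D array of sensitivities (cells x wavelengths)
    on the grid given at construction and returns one label per cell.  The
    rule set is a parameter; ``fit`` records the label inventory and is
    otherwise a no-op (the rules are fixed, not learned).
    """

    def __init__(self, wavelengths=None, rules=None):
        self.wavelengths = wavelengths
        self.rules = rules

    def fit(self, X=None, y=None):
        rules = default_rules() if self.rules is None else self.rules
        self.classes_ = np.array([r.label for r in rules] + ["unclassified"])
        self.rules_ = rules
        return self

    def predict(self, X):
        if not hasattr(self, "rules_"):
            self.fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lam = np.asarray(self.wavelengths, dtype=float)
        labels = []
        for row in X:
            sens = SpectralSensitivity(wavelengths=lam, sensitivity=row)
            labels.append(classify_cell(sens, self.rules_)[0])
        return np.array(labels)


def enumerate_ommatidial_types(classes: set[str] | list[str]) -> list[frozenset]:
    """All unordered R1/R2 class pairs with repetition; k classes give
    k*(k+1)/2 ommatidial types."""
    classes = sorted(set(classes))
    if not classes:
        raise ValueError("class inventory must be non-empty")
    return [frozenset((a, b)) for a, b in combinations_with_replacement(classes, 2)]


def sample_retina(
    composition: dict[str, float],
    n_cells: int,
    seed: int | np.random.Generator,
) -> list[str]:
    """Multinomial draw of cell-class labels, reproducible under *seed*.

    Quantifies the sampling difficulty of rare classes (e.g. only ~5% of
    cells available to a randomly inserted electrode are UV cells).
    """
    labels = list(composition)
    freqs = np.array([composition[c] for c in labels], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError(f"class frequencies must sum to 1 +/- 1e-6, got {freqs.sum():.8f}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, freqs / freqs.sum())
    out: list[str] = []
    for lbl, c in zip(labels, counts):
        out.extend([lbl] * int(c))
    arr = np.array(out, dtype=object)
    rng.shuffle(arr)
    return arr.tolist()
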