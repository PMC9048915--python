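"""File I/O, run configuration and the end-to-end analysis pipeline.

Recordings travel as CSV pairs -- ``<cell>_vlogi.csv`` (columns: od,
response_mv) and ``<cell>_spectral.csv`` (columns: wavelength_nm,
response_mv) -- with a shared calibration CSV (wavelength_nm,
relative_flux).  Readers validate rather than coerce: malformed numbers,
out-of-range wavelengths and duplicates are rejected with errors naming the
offending row and column.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mosaic import classify_cell, default_rules
from .photoresponse import VLogICurve, fit_naka_rushton
from .sensitivity import (
    FluxCalibration,
    SpectralFlashSeries,
    average_cells,
    derive_sensitivity,
    fit_lambda_max,
)
from .simulate import ResponseRecording

logger = logging.getLogger("heliovis")

__all__ = [
    "RunConfig",
    "read_recording",
    "write_recording",
    "read_calibration",
    "write_calibration",
    "write_sensitivity",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; JSON round-trips losslessly."""

    family: str = "govardovskii_a1"
    fit_window: tuple[float, float] | None = None
    search_bounds: tuple[float, float] = (300.0, 700.0)
    calibration_path: str | None = None
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"
    fit_per_cell: bool = True  # also fit templates to per-class averages
    rules: list = field(default_factory=list)  # [] = package default rules

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for key in ("fit_window", "search_bounds"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _read_numeric_csv(path, columns: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Strict two-column numeric CSV reader; errors name row and column."""
    rows: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != list(columns):
            raise ValueError(f"{path}: expected header {','.join(columns)!r}, got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 2:
                raise ValueError(
                    f"{path}: row {lineno} has {len(row)} fields, expected 2 "
                    "(decimal commas or stray separators?)"
                )
            vals = []
            for col_name, cell in zip(columns, row[:2]):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: row {lineno}, column {col_name!r}: "
                        f"non-numeric value {cell!r} (decimal commas are not accepted)"
                    ) from None
            rows.append((vals[0], vals[1]))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


def read_recording(vlogi_path, spectral_path) -> ResponseRecording:
    """Read one cell's CSV pair into a validated ResponseRecording."""
    od, v_white = _read_numeric_csv(vlogi_path, ("od", "response_mv"))
    lam, v_spec = _read_numeric_csv(spectral_path, ("wavelength_nm", "response_mv"))
    if np.unique(lam).size != lam.size:
        dupes = sorted({w for w in lam if np.sum(lam == w) > 1})
        raise ValueError(f"{spectral_path}: duplicate wavelengths {dupes}")
    order = np.argsort(lam)
    lam, v_spec = lam[order], v_spec[order]
    bad = (lam < 300.0) | (lam > 700.0)
    if bad.any():
        rows = np.nonzero(bad)[0]
        raise ValueError(
            f"{spectral_path}: wavelengths outside the 300-700 nm measurement "
            f"range at data rows {', '.join(str(r + 2) for r in rows)}: "
            f"{', '.join(f'{w:g}' for w in lam[bad])}"
        )
    return ResponseRecording(
        vlogi=VLogICurve(od_steps=od, responses=v_white),
        flashes=SpectralFlashSeries(wavelengths=lam, responses=v_spec),
        label=Path(str(spectral_path)).stem.removesuffix("_spectral"),
    )


def write_recording(rec: ResponseRecording, out_dir, stem: str) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vpath = out_dir / f"{stem}_vlogi.csv"
    spath = out_dir / f"{stem}_spectral.csv"
    pd.DataFrame({"od": rec.vlogi.od_steps, "response_mv": rec.vlogi.responses}).to_csv(vpath, index=False)
    pd.DataFrame(
        {"wavelength_nm": rec.flashes.wavelengths, "response_mv": rec.flashes.responses}
    ).to_csv(spath, index=False)
    return vpath, spath


def read_calibration(path) -> FluxCalibration:
    lam, flux = _read_numeric_csv(path, ("wavelength_nm", "relative_flux"))
    order = np.argsort(lam)
    return FluxCalibration(wavelengths=lam[order], relative_flux=flux[order])


def write_calibration(calib: FluxCalibration, path) -> Path:
    path = Path(path)
    pd.DataFrame({"wavelength_nm": calib.wavelengths, "relative_flux": calib.relative_flux}).to_csv(
        path, index=False
    )
    return path


def write_sensitivity(sens, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "wavelength_nm": sens.wavelengths,
            "mean": sens.sensitivity,
            "se": sens.se,
            "n": sens.n_cells,
        }
    ).to_csv(path, index=False)
    return path


def analyze_recording(rec: ResponseRecording, calib: FluxCalibration, config: RunConfig) -> dict:
    """Fit one cell end to end: Naka-Rushton, sensitivity, template, class."""
    params, nr_rss = fit_naka_rushton(rec.vlogi)
    sens = derive_sensitivity(rec.flashes, params, calib)
    fit = fit_lambda_max(
        sens,
        family=config.family,
        search_bounds=tuple(config.search_bounds),
        fit_window=config.fit_window,
    )
    rules = config.rules or default_rules()
    label, diag = classify_cell(sens, rules)
    return {
        "cell": rec.label,
        "v_max": params.v_max,
        "k": params.k,
        "n": params.n,
        "nr_rss": nr_rss,
        "lambda_max_nm": fit.lambda_max_hat,
        "template_rss": fit.rss,
        "peak_nm": diag["peak_nm"],
        "fwhm_nm": diag["fwhm_nm"],
        "class": label,
        "sensitivity": sens,
    }


def run_pipeline(config: RunConfig, input_dir) -> dict:
    """Analyze every ``*_vlogi.csv`` / ``*_spectral.csv`` pair in *input_dir*.

    Per-cell failures are isolated: the pipeline logs the error, marks the
    cell failed and continues.  Outputs (per-cell fit table, per-class
    average sensitivities with SE, lambda-max table, run log with config
    hash and seed) are written under ``config.output_dir``.
    """
    input_dir = Path(input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    calib = (
        read_calibration(config.calibration_path)
        if config.calibration_path
        else None
    )

    pairs = sorted(input_dir.glob("*_vlogi.csv"))
    if not pairs:
        logger.warning("no recording pairs found in %s", input_dir)
    records, failures, by_class = [], [], {}
    for vpath in pairs:
        spath = vpath.with_name(vpath.name.replace("_vlogi.csv", "_spectral.csv"))
        try:
            if not spath.exists():
                raise FileNotFoundError(f"missing spectral file {spath}")
            rec = read_recording(vpath, spath)
            cell_calib = calib if calib is not None else FluxCalibration.flat(rec.flashes.wavelengths)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = analyze_recording(rec, cell_calib, config)
            by_class.setdefault(res["class"], []).append(res.pop("sensitivity"))
            records.append(res)
        except (ValueError, RuntimeError, FileNotFoundError) as exc:
            logger.error("cell %s failed: %s", vpath.stem, exc)
            failures.append({"cell": vpath.stem, "error": str(exc)})

    if records:
        pd.DataFrame.from_records(records).to_csv(out_dir / "percell_fits.csv", index=False)

    class_rows = []
    for label, cells in sorted(by_class.items()):
        avg = average_cells(cells)
        write_sensitivity(avg, out_dir / f"sensitivity_{label.replace('/', '-')}.csv")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lambda_max(avg, family=config.family, search_bounds=tuple(config.search_bounds))
        class_rows.append(
            {
                "class": label,
                "n_cells": len(cells),
                "lambda_max_nm": fit.lambda_max_hat,
                "template_rss": fit.rss,
            }
        )
    if class_rows:
        pd.DataFrame.from_records(class_rows).to_csv(out_dir / "lambda_max.csv", index=False)

    run_log = {
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_cells": len(records),
        "n_failed": len(failures),
        "failures": failures,
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return {"cells": records, "classes": class_rows, "failures": failures, "out_dir": str(out_dir)}
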