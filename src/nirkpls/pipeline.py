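"""End-to-end calibration pipeline and its result artifacts.

One run goes: load (or synthesise) spectra + reference chemistry ->
2:1:1 split -> per-analyte (sigma, s) grid search scored on the
validation set -> refit of the winner on the calibration set -> one-shot
evaluation on the held-out testing set.  Every artifact needed to
re-create a figure-style report is written as CSV/JSON:

* ``surface_<analyte>.csv``   — long-format validation RMSE/CC surface
* ``best_<analyte>.json``     — selected (sigma*, s*) with RMSE_V/CC_V
* ``trace_<analyte>.csv``     — 200-iteration refinement curve
* ``report_validation_<analyte>.json`` / ``report_testing_<analyte>.json``
* ``predictions_<analyte>.csv`` — reference vs predicted, testing set
* ``comparison.json``         — RBF-PLS vs linear PLS per analyte
* ``MANIFEST.json``           — config hash, seeds, versions, stage log

The testing indices are asserted disjoint from calibration and
validation at runtime; testing samples are never touched before the
final evaluation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .hypercube import RoiSpec, read_cube, roi_mean_spectrum
from .kernel_pls import KernelParams, refinement_trace
from .selection import (EvaluationReport, build_sigma_grid, cc,
                        evaluate_on_test, grid_search, rmse,
                        select_linear_pls, split_samples)
from .synthetic import SyntheticConfig, generate_dataset
from .tables import SpectraTable, read_reference_csv


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see the packaged example YAML)."""

    spectra_csv: str | None = None
    reference_csv: str | None = None
    synthetic: dict = field(default_factory=dict)   # SyntheticConfig overrides
    split_sizes: tuple = (120, 64, 64)
    sigma_lo: float = 0.01
    sigma_hi: float = 64.0
    sigma_step: float = 0.01
    sigma_log_num: int | None = None    # if set: log-spaced grid instead
    s_min: int = 1
    s_max: int = 20
    max_iter: int = 200
    tol: float = 1e-10
    literal_k: bool = False
    trace_iterations: int = 200
    trace_mode: str = "restart"
    analytes: tuple = ("SU", "VC", "OA")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.split_sizes, list):
            cfg.split_sizes = tuple(cfg.split_sizes)
        if isinstance(cfg.analytes, list):
            cfg.analytes = tuple(cfg.analytes)
        return cfg

    def sigma_grid(self) -> np.ndarray:
        if self.sigma_log_num:
            return np.geomspace(self.sigma_lo, self.sigma_hi, self.sigma_log_num)
        return build_sigma_grid(self.sigma_lo, self.sigma_hi, self.sigma_step)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_data(config: RunConfig):
    if config.spectra_csv and config.reference_csv:
        spectra = SpectraTable.from_csv(config.spectra_csv)
        reference = read_reference_csv(config.reference_csv)
        if list(reference.index) != spectra.ids:
            reference = reference.loc[spectra.ids]
        return spectra, reference
    syn = SyntheticConfig(**config.synthetic) if config.synthetic \
        else SyntheticConfig()
    ds = generate_dataset(syn, seed=config.seed)
    return ds.spectra, ds.reference


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> Path:
    """Execute the full calibration pipeline; returns the artifact dir.

    Raises on the first stage failure after writing a MANIFEST that names
    the failed stage (partial artifacts are preserved).
    """
    if seed is not None:
        config = replace(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }

    def _stage(name):
        manifest["stages"].append({"stage": name, "status": "ok"})

    def _write_manifest():
        (out / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, default=str, sort_keys=True) + "\n")

    try:
        # -- validation of the grid against the split, before any compute
        n_cal = config.split_sizes[0]
        if config.s_max > n_cal - 1:
            raise ValueError(
                f"s_max={config.s_max} exceeds n_cal-1={n_cal - 1}")
        sigma_grid = config.sigma_grid()
        s_grid = np.arange(config.s_min, config.s_max + 1)
        _stage("validate-config")

        spectra, reference = _load_data(config)
        _stage("load-data")

        split = split_samples(spectra.n_samples, config.split_sizes,
                              seed=config.seed)
        assert not (set(split.testing) & set(split.calibration)
                    | set(split.testing) & set(split.validation)), \
            "testing indices leaked into training"
        manifest["split_sizes"] = list(split.sizes)
        _stage("split")

        X = spectra.X
        fit_params = {"max_iter": config.max_iter, "tol": config.tol,
                      "seed": config.seed, "literal_k": config.literal_k}
        comparison = {}
        for analyte in config.analytes:
            y = reference[analyte].to_numpy(float)
            X_cal, y_cal = X[split.calibration], y[split.calibration]
            X_val, y_val = X[split.validation], y[split.validation]
            X_test, y_test = X[split.testing], y[split.testing]

            surface = grid_search(X_cal, y_cal, X_val, y_val,
                                  sigma_grid, s_grid, fit_params)
            surface.to_csv(out / f"surface_{analyte}.csv")
            best = surface.best
            (out / f"best_{analyte}.json").write_text(
                json.dumps({**best, "analyte": analyte,
                            "config_hash": manifest["config_hash"],
                            "seed": config.seed}, indent=2) + "\n")
            _stage(f"grid-search-{analyte}")

            val_report = EvaluationReport(analyte, best["rmse_v"],
                                          best["cc_v"], "validation",
                                          split.validation.size)
            (out / f"report_validation_{analyte}.json").write_text(
                json.dumps(val_report.to_dict(), indent=2) + "\n")

            params = KernelParams(sigma=best["sigma"], s=best["s"], **fit_params)
            per_iter, best_so_far = refinement_trace(
                X_cal, y_cal, X_val, y_val, params,
                n_iter=config.trace_iterations, mode=config.trace_mode)
            np.savetxt(out / f"trace_{analyte}.csv",
                       np.column_stack([np.arange(1, per_iter.size + 1),
                                        per_iter, best_so_far]),
                       delimiter=",", header="iteration,rmse_v,best_so_far",
                       comments="", fmt=("%d", "%.12e", "%.12e"))
            _stage(f"trace-{analyte}")

            test_report, pred, _ = evaluate_on_test(
                X_cal, y_cal, X_test, y_test, best["sigma"], best["s"],
                analyte=analyte, fit_params=fit_params)
            (out / f"report_testing_{analyte}.json").write_text(
                json.dumps(test_report.to_dict(), indent=2) + "\n")
            ids = [spectra.ids[i] for i in split.testing]
            with open(out / f"predictions_{analyte}.csv", "w") as fh:
                fh.write("id,reference,predicted\n")
                for i, r, p in zip(ids, y_test, pred):
                    fh.write(f"{i},{r:.10g},{p:.10g}\n")
            _stage(f"evaluate-{analyte}")

            pls_best = select_linear_pls(X_cal, y_cal, X_val, y_val, s_grid)
            comparison[analyte] = {"rbf_pls": {k: best[k] for k in
                                               ("sigma", "s", "rmse_v", "cc_v")},
                                   "pls": pls_best,
                                   "rmse_t": test_report.rmse,
                                   "cc_t": test_report.cc}
            _stage(f"compare-{analyte}")

        (out / "comparison.json").write_text(
            json.dumps(comparison, indent=2) + "\n")
        _stage("report")
    except Exception as exc:
        manifest["stages"].append({"stage": "FAILED", "status": "error",
                                   "error": f"{type(exc).__name__}: {exc}"})
        _write_manifest()
        raise
    _write_manifest()
    return out


def extract_roi_pipeline(cube_paths, rois, out_csv, dialect="auto") -> SpectraTable:
    """Read cubes, average the ROI pixels of each into one spectrum per
    sample, and write the spectra table CSV."""
    rois = [r if isinstance(r, RoiSpec) else RoiSpec(**r) for r in rois]
    rows, ids, wl = [], [], None
    for path in cube_paths:
        cube = read_cube(path, dialect=dialect)
        rows.append(roi_mean_spectrum(cube, rois))
        ids.append(cube.sample_id or Path(path).stem)
        wl = cube.wavelengths
    table = SpectraTable(np.vstack(rows), wl, ids)
    if out_csv:
        table.to_csv(out_csv)
    return table
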