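"""End-to-end orchestration: simulate/load → trim → split → preprocess →
select wavelengths → fit → evaluate, as one reproducible configured run.

All data-dependent statistics (MSC reference, wavelength selection, GA
fitness) are fitted on the training rows only; the test rows are touched
exactly once, by the final evaluation.  A single global seed fans out to
per-stage seeds through a fixed stage-name hash, so any stage can be rerun
independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import EvalReport, evaluate
from .exceptions import ConfigurationError
from .feature_selection import CARSConfig, run_cars, run_spa
from .modeling import GAConfig, SVRParams, fit_svr, ga_optimize
from .preprocessing import (
    DataSplit, SGParams, msc, sg_smooth, snv, split_train_test, trim_bands,
)
from .spectra import SpectraSet
from .synthetic import SynthConfig, generate_spectra

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_baselines",
           "derive_seed"]

PREPROCESSORS = ("none", "snv", "msc", "sg")
SELECTORS = ("none", "cars", "spa")
MODELS = ("svr", "gasvr", "lr", "rf")


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed XOR a CRC32 hash of the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    source_csv: str | None = None
    simulate: SynthConfig | None = None
    trim: tuple[float, float] = (400.0, 1000.0)
    split_ratio: float = 0.7
    preprocess: str = "none"
    sg: SGParams = field(default_factory=SGParams)
    selector: str = "none"
    cars: CARSConfig = field(default_factory=CARSConfig)
    spa_max_k: int = 20
    spa_cv_folds: int = 10
    model: str = "gasvr"
    ga: GAConfig = field(default_factory=GAConfig)
    svr_epsilon: float = 0.1
    rf_n_estimators: int = 100
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.source_csv is None) == (self.simulate is None):
            raise ConfigurationError(
                "exactly one data source required: source_csv or simulate")
        if self.source_csv is not None and not Path(self.source_csv).exists():
            raise ConfigurationError(f"source_csv {self.source_csv!r} does not exist")
        if self.preprocess not in PREPROCESSORS:
            raise ConfigurationError(f"preprocess must be one of {PREPROCESSORS}")
        if self.selector not in SELECTORS:
            raise ConfigurationError(f"selector must be one of {SELECTORS}")
        if self.model not in MODELS:
            raise ConfigurationError(f"model must be one of {MODELS}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulate" in d and isinstance(d["simulate"], dict):
            d["simulate"] = SynthConfig(**d["simulate"])
        if "sg" in d and isinstance(d["sg"], dict):
            d["sg"] = SGParams(**d["sg"])
        if "cars" in d and isinstance(d["cars"], dict):
            d["cars"] = CARSConfig(**d["cars"])
        if "ga" in d and isinstance(d["ga"], dict):
            d["ga"] = GAConfig(**{k: tuple(v) if k.endswith("_bounds") else v
                                  for k, v in d["ga"].items()})
        if "trim" in d:
            d["trim"] = tuple(d["trim"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sg is not None:
            d["sg"]["edge_mode"] = str(self.sg.edge_mode.value)
        return d


@dataclass
class PipelineResult:
    report: EvalReport
    split: DataSplit
    selected_indices: np.ndarray | None
    selected_wavelengths_nm: np.ndarray | None
    n_bands_used: int
    model_name: str
    fit_params: dict
    ga_history: np.ndarray | None
    model: object


def _load(cfg: RunConfig) -> SpectraSet:
    if cfg.source_csv is not None:
        return SpectraSet.from_csv(cfg.source_csv)
    sim = dataclasses.replace(cfg.simulate, seed=derive_seed(cfg.seed, "simulate"))
    spectra, _ = generate_spectra(sim)
    return spectra


def _preprocess(spectra: SpectraSet, split: DataSplit, cfg: RunConfig) -> SpectraSet:
    if cfg.preprocess == "none":
        return spectra
    if cfg.preprocess == "snv":
        return snv(spectra)
    if cfg.preprocess == "sg":
        return sg_smooth(spectra, cfg.sg)
    # MSC: reference from the calibration rows only (no test-set leakage)
    reference = spectra.reflectance[split.train_indices].mean(axis=0)
    corrected, _ = msc(spectra, reference=reference)
    return corrected


def _select(spectra: SpectraSet, split: DataSplit, cfg: RunConfig):
    if cfg.selector == "none":
        return None, None
    Xtr = spectra.reflectance[split.train_indices]
    ytr = spectra.brix[split.train_indices]
    seed = derive_seed(cfg.seed, "select")
    if cfg.selector == "cars":
        cars_cfg = dataclasses.replace(cfg.cars, seed=seed)
        result = run_cars(Xtr, ytr, cars_cfg)
        return np.sort(result.selected_indices), result
    result = run_spa(Xtr, ytr, max_k=min(cfg.spa_max_k, len(ytr) - 1,
                                         spectra.n_bands),
                     cv_folds=cfg.spa_cv_folds, seed=seed)
    return np.sort(result.selected_indices), result


class _SKWrapper:
    """Adapter giving sklearn regressors the model.predict contract used here."""

    def __init__(self, est):
        self.est = est

    def predict(self, X):
        return self.est.predict(np.asarray(X, float))


def _fit_model(X: np.ndarray, y: np.ndarray, cfg: RunConfig):
    seed = derive_seed(cfg.seed, "model")
    if cfg.model == "svr":
        params = SVRParams(C=1.0, g=1.0 / X.shape[1], epsilon=cfg.svr_epsilon)
        return fit_svr(X, y, params), dataclasses.asdict(params), None
    if cfg.model == "gasvr":
        ga_cfg = dataclasses.replace(cfg.ga, seed=seed, epsilon=cfg.svr_epsilon)
        fit = ga_optimize(X, y, ga_cfg)
        info = dataclasses.asdict(fit.params)
        info["cv_rmse"] = fit.cv_rmse
        return fit.model, info, fit.ga_history
    if cfg.model == "lr":
        from sklearn.linear_model import LinearRegression

        return _SKWrapper(LinearRegression().fit(X, y)), {}, None
    from sklearn.ensemble import RandomForestRegressor

    rf = RandomForestRegressor(n_estimators=cfg.rf_n_estimators, random_state=seed)
    return _SKWrapper(rf.fit(X, y)), {"n_estimators": cfg.rf_n_estimators}, None


class _BandSubsetModel:
    """Restrict a fitted model to the band subset it was trained on, so it can
    be evaluated against full-band spectra."""

    def __init__(self, model, band_indices: np.ndarray | None):
        self.model = model
        self.band_indices = band_indices

    def predict(self, X):
        X = np.asarray(X, float)
        if self.band_indices is not None:
            X = X[:, self.band_indices]
        return self.model.predict(X)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the configured pipeline and return its evaluation report.

    Stage order: load/simulate, trim to the working wavelength range, split,
    preprocess (training statistics only), select wavelengths on the training
    rows, fit the model, evaluate on both halves.  Byte-identical outputs for
    identical configs.
    """
    cfg.validate()
    spectra = _load(cfg)
    spectra = trim_bands(spectra, *cfg.trim)
    split = split_train_test(spectra, cfg.split_ratio,
                             seed=derive_seed(cfg.seed, "split"))
    pre = _preprocess(spectra, split, cfg)
    selected, sel_result = _select(pre, split, cfg)

    work = pre if selected is None else pre.take_bands(selected)
    Xtr = work.reflectance[split.train_indices]
    ytr = work.brix[split.train_indices]
    model, fit_params, ga_history = _fit_model(Xtr, ytr, cfg)

    wrapped = _BandSubsetModel(model, selected)
    report = evaluate(wrapped, split, pre)
    result = PipelineResult(
        report=report,
        split=split,
        selected_indices=selected,
        selected_wavelengths_nm=None if selected is None
        else pre.wavelengths_nm[selected],
        n_bands_used=work.n_bands,
        model_name=cfg.model,
        fit_params=fit_params,
        ga_history=ga_history,
        model=wrapped,
    )
    if cfg.out_dir is not None:
        _write_artifacts(cfg, result, sel_result)
    return result


def _write_artifacts(cfg: RunConfig, result: PipelineResult, sel_result) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_json(out / "report.json")
    if result.selected_indices is not None:
        (out / "selected_bands.json").write_text(json.dumps({
            "indices": [int(i) for i in result.selected_indices],
            "wavelengths_nm": [round(float(w), 1)
                               for w in result.selected_wavelengths_nm],
        }, indent=2) + "\n")
    if sel_result is not None and hasattr(sel_result, "rmsecv_trace"):
        trace = sel_result.rmsecv_trace
        lines = ["run,rmsecv"] + [f"{i + 1},{v}" for i, v in enumerate(trace)]
        (out / "rmsecv_trace.csv").write_text("\n".join(lines) + "\n")
    if sel_result is not None and hasattr(sel_result, "rmse_curve"):
        curve = sel_result.rmse_curve
        lines = ["k,rmse"] + [f"{i + 1},{v}" for i, v in enumerate(curve)]
        (out / "spa_rmse_curve.csv").write_text("\n".join(lines) + "\n")
    if result.ga_history is not None:
        lines = ["generation,best_cv_rmse"] + [
            f"{i + 1},{v}" for i, v in enumerate(result.ga_history)]
        (out / "ga_history.csv").write_text("\n".join(lines) + "\n")
    import joblib

    joblib.dump(result.model, out / "model.joblib")
    log = {"config": cfg.to_dict(), "seed": cfg.seed,
           "n_bands_used": result.n_bands_used,
           "fit_params": result.fit_params}
    (out / "log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")


def run_baselines(cfg: RunConfig) -> dict[str, EvalReport]:
    """Ordinary least squares and random-forest references on the identical
    trim/split/preprocess path (no wavelength selection)."""
    reports = {}
    for name, model in (("linear_regression", "lr"), ("random_forest", "rf")):
        sub = dataclasses.replace(cfg, model=model, selector="none", out_dir=None)
        reports[name] = run_pipeline(sub).report
    return reports
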