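"""Model evaluation: RMSEC/RMSEP and the calibration/prediction coefficients
of determination Rc²/Rp².

The R² used here is 1 − SS_res/SS_tot with the mean taken over the evaluated
set itself (calibration mean for Rc², prediction-set mean for Rp²).  Note this
is not the squared Pearson correlation: the two differ whenever predictions
are biased.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .exceptions import DegenerateDataError, DimensionError, LeakageError
from .preprocessing import DataSplit
from .spectra import SpectraSet

__all__ = ["EvalReport", "rmse", "r_squared", "evaluate", "render_table"]


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean square error, sqrt(mean((y_true − y_pred)²))."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise DimensionError("y_true and y_pred must share a nonzero length")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 − Σ(y−ŷ)² / Σ(y−ȳ)²."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise DimensionError("y_true and y_pred must share a nonzero length")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("y_true is constant; R² undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class EvalReport:
    """Calibration/prediction statistics, one table row per fitted model."""

    rc2: float
    rmsec: float
    rp2: float
    rmsep: float
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def evaluate(model, split: DataSplit, spectra: SpectraSet) -> EvalReport:
    """Score a fitted model on a split: Rc²/RMSEC on train, Rp²/RMSEP on test.

    ``model`` needs only a ``predict(X) -> y`` method trained on the split's
    training rows.  Overlapping train/test indices raise a leakage error.
    """
    if spectra.brix is None:
        raise DegenerateDataError("spectra have no brix labels to evaluate against")
    tr, te = split.train_indices, split.test_indices
    if np.intersect1d(tr, te).size:
        raise LeakageError("train and test indices overlap")
    y = spectra.brix
    pred_tr = np.ravel(model.predict(spectra.reflectance[tr]))
    pred_te = np.ravel(model.predict(spectra.reflectance[te]))
    return EvalReport(
        rc2=r_squared(y[tr], pred_tr),
        rmsec=rmse(y[tr], pred_tr),
        rp2=r_squared(y[te], pred_te),
        rmsep=rmse(y[te], pred_te),
        n_train=len(tr),
        n_test=len(te),
    )


def render_table(reports: dict[str, EvalReport]) -> str:
    """Text table with (Rc², RMSEC, Rp², RMSEP) columns at 4 decimals."""
    name_w = max([len(n) for n in reports] + [len("Model")])
    header = f"{'Model':<{name_w}}  {'Rc2':>8}  {'RMSEC':>8}  {'Rp2':>8}  {'RMSEP':>8}"
    lines = [header, "-" * len(header)]
    for name, r in reports.items():
        lines.append(
            f"{name:<{name_w}}  {r.rc2:8.4f}  {r.rmsec:8.4f}  "
            f"{r.rp2:8.4f}  {r.rmsep:8.4f}")
    return "\n".join(lines)
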