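"""Wavelength selection: competitive adaptive reweighted sampling (CARS) and
the successive projections algorithm (SPA).

CARS shrinks the band set over N Monte-Carlo runs.  Each run fits a PLS model
on a random calibration subsample, turns the regression vector b into weights
ω_i = |b_i| / Σ|b_j|, keeps the top ⌈p·r_i⌉ bands under the exponential decay
schedule r_i = a·e^{−k·i} (with a = (p/2)^{1/(N−1)}, k = ln(p/2)/(N−1), so
r_1 = 1 and r_N = 2/p), then resamples that many bands with replacement in
proportion to ω (adaptive reweighted sampling) and deduplicates.  The subset
with the smallest cross-validated RMSE wins.

SPA grows a chain from every candidate start band, each step picking the band
with maximal residual norm after orthogonal projection onto the complement of
the bands chosen so far; chain prefixes are scored by cross-validated OLS RMSE
and the best (start, k) prefix wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .exceptions import ConfigurationError, DegenerateDataError

__all__ = [
    "CARSConfig",
    "CARSResult",
    "SPAResult",
    "pls_regression_vector",
    "edf_constants",
    "edf_ratio",
    "ars_weights",
    "run_cars",
    "run_spa",
    "successive_projection_chain",
]


# ----------------------------------------------------------------------- PLS
def pls_regression_vector(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """PLS1 regression coefficient vector b (on centered data).

    Decomposes X into scores T = XW and regresses y on T, so that
    ``y ≈ X_centered · b + intercept``.  With ``n_components`` equal to the
    rank of X this reduces to the ordinary least-squares direction.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ConfigurationError("X and y row counts differ")
    if np.std(y) == 0:
        raise DegenerateDataError("y has zero variance; PLS undefined")
    n_components = int(n_components)
    if not 1 <= n_components <= min(X.shape[0] - 1, X.shape[1]):
        raise ConfigurationError(
            f"n_components={n_components} must lie in [1, min(rows-1, cols)]")
    model = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        # exact fits (noiseless synthetic data) legitimately exhaust the y
        # residual before all components are extracted
        warnings.filterwarnings("ignore", message="y residual is constant")
        model.fit(X, y)
    return np.ravel(model.coef_)


def _pls_rmsecv(X: np.ndarray, y: np.ndarray, n_components: int,
                folds: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Root mean square error of PLS predictions under the given CV folds."""
    sq_sum, n_tot = 0.0, 0
    for tr, te in folds:
        ncomp = max(1, min(n_components, len(tr) - 1, X.shape[1]))
        model = PLSRegression(n_components=ncomp, scale=False)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="y residual is constant")
            model.fit(X[tr], y[tr])
        pred = np.ravel(model.predict(X[te]))
        sq_sum += float(np.sum((y[te] - pred) ** 2))
        n_tot += len(te)
    return math.sqrt(sq_sum / n_tot)


# ------------------------------------------------------------- EDF schedule
def edf_constants(p: int, N: int) -> tuple[float, float]:
    """Constants (a, k) of the exponential decay schedule.

    ``a = (p/2)^{1/(N−1)}`` and ``k = ln(p/2)/(N−1)``; together they pin the
    schedule to r_1 = 1 (all p bands) and r_N = 2/p (two bands).
    """
    if p <= 2:
        raise ConfigurationError("p must exceed 2 for the decay schedule")
    if N < 2:
        raise ConfigurationError("N must be >= 2")
    a = (p / 2.0) ** (1.0 / (N - 1))
    k = math.log(p / 2.0) / (N - 1)
    return a, k


def edf_ratio(i: int, p: int, N: int) -> float:
    """Retention fraction r_i = a·e^{−k·i} at Monte-Carlo run i (1-based)."""
    if not 1 <= i <= N:
        raise ConfigurationError(f"run index i={i} outside [1, N={N}]")
    a, k = edf_constants(p, N)
    return a * math.exp(-k * i)


def ars_weights(b: np.ndarray) -> np.ndarray:
    """Normalised absolute-coefficient weights ω_i = |b_i| / Σ|b_j|."""
    b = np.asarray(b, float)
    denom = np.abs(b).sum()
    if denom == 0:
        raise DegenerateDataError("all regression coefficients are zero")
    return np.abs(b) / denom


# ------------------------------------------------------------------- CARS
@dataclass
class CARSConfig:
    """CARS settings; defaults follow common practice for ~250-band spectra:
    50 Monte-Carlo runs, 10-fold cross-validation, at most 10 latent
    components, and an 80% calibration subsample per run."""

    n_runs: int = 50
    cv_folds: int = 10
    max_latent_components: int = 10
    mc_calibration_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_runs < 2:
            raise ConfigurationError("n_runs must be >= 2")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.max_latent_components < 1:
            raise ConfigurationError("max_latent_components must be >= 1")
        if not 0 < self.mc_calibration_fraction < 1:
            raise ConfigurationError(
                "mc_calibration_fraction must lie strictly between 0 and 1")


@dataclass
class CARSResult:
    retained_sets: list[np.ndarray]
    weights_history: list[np.ndarray]
    rmsecv_trace: np.ndarray
    best_run: int
    selected_indices: np.ndarray
    full_rmsecv: float  # RMSECV of the all-band PLS model under the same folds


def run_cars(X: np.ndarray, y: np.ndarray, cfg: CARSConfig) -> CARSResult:
    """Run CARS and return the band subset with minimum cross-validated RMSE.

    The CV folds are drawn once from the seed and shared by every run (and by
    the full-band reference model), so RMSECV values are comparable across the
    trace.  Fully reproducible for a fixed seed.
    """
    cfg.validate()
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if n != y.shape[0]:
        raise ConfigurationError("X and y row counts differ")
    rng = np.random.default_rng(cfg.seed)
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True,
               random_state=int(rng.integers(2**31)))
    folds = [(tr, te) for tr, te in kf.split(X)]

    a, k = edf_constants(p, cfg.n_runs)
    n_cal = max(2, round(cfg.mc_calibration_fraction * n))
    retained = np.arange(p)
    retained_sets: list[np.ndarray] = []
    weights_history: list[np.ndarray] = []
    rmsecv = np.empty(cfg.n_runs)

    for i in range(1, cfg.n_runs + 1):
        cal = rng.choice(n, size=n_cal, replace=False)
        ncomp = min(cfg.max_latent_components, len(retained), n_cal - 1)
        b = pls_regression_vector(X[np.ix_(cal, retained)], y[cal], ncomp)
        w = ars_weights(b)
        full_w = np.zeros(p)
        full_w[retained] = w
        weights_history.append(full_w)

        n_keep = max(2, math.ceil(p * edf_ratio(i, p, cfg.n_runs)))
        if n_keep < len(retained):
            # EDF: keep the top-weight bands; ties broken toward lower index
            order = np.argsort(-w, kind="stable")[:n_keep]
            retained = np.sort(retained[order])
            w = full_w[retained] / full_w[retained].sum()
        # ARS: weighted resampling with replacement, deduplicated
        picks = rng.choice(len(retained), size=n_keep, replace=True, p=w / w.sum())
        uniq = np.unique(picks)
        if uniq.size < 2:  # clamp: never drop below two bands
            uniq = np.unique(np.concatenate([uniq, np.argsort(-w, kind="stable")[:2]]))[:2]
        retained = np.sort(retained[uniq])

        rmsecv[i - 1] = _pls_rmsecv(
            X[:, retained], y,
            min(cfg.max_latent_components, len(retained)), folds)
        if not np.isfinite(rmsecv[i - 1]):
            raise DegenerateDataError(f"non-finite RMSECV at run {i}")
        retained_sets.append(retained.copy())

    best = int(np.argmin(rmsecv))
    full_rmsecv = _pls_rmsecv(X, y, cfg.max_latent_components, folds)
    return CARSResult(
        retained_sets=retained_sets,
        weights_history=weights_history,
        rmsecv_trace=rmsecv,
        best_run=best,
        selected_indices=retained_sets[best],
        full_rmsecv=full_rmsecv,
    )


# -------------------------------------------------------------------- SPA
@dataclass
class SPAResult:
    selected_indices: np.ndarray  # ordered as picked
    rmse_curve: np.ndarray        # CV RMSE vs subset size k (winning chain)
    chosen_k: int
    start_index: int


def successive_projection_chain(X: np.ndarray, start: int, max_k: int,
                                tol: float = 1e-10) -> list[int]:
    """Projection chain from ``start``: each step picks the column with the
    largest norm after orthogonal projection onto the complement of the span
    of the columns already picked.  Stops early if every residual vanishes
    (rank deficiency)."""
    R = np.array(X, float, copy=True)
    n, p = R.shape
    chain = [int(start)]
    scale = float(np.linalg.norm(R)) or 1.0
    for _ in range(min(max_k, p) - 1):
        v = R[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv <= tol * scale:
            break
        R = R - np.outer(v, v @ R) / (nv * nv)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] <= tol * scale:
            break
        chain.append(j)
    return chain


def _ols_cv_rmse_curve(X: np.ndarray, y: np.ndarray, chain: list[int],
                       folds: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """CV RMSE of an OLS fit (with intercept) on each chain prefix."""
    curve = np.full(len(chain), np.nan)
    for k in range(1, len(chain) + 1):
        cols = chain[:k]
        sq, n_tot = 0.0, 0
        for tr, te in folds:
            A = np.column_stack([np.ones(len(tr)), X[np.ix_(tr, cols)]])
            coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
            At = np.column_stack([np.ones(len(te)), X[np.ix_(te, cols)]])
            sq += float(np.sum((y[te] - At @ coef) ** 2))
            n_tot += len(te)
        curve[k - 1] = math.sqrt(sq / n_tot)
    return curve


def run_spa(X: np.ndarray, y: np.ndarray, max_k: int,
            cv_folds: int = 10, seed: int = 0) -> SPAResult:
    """Successive projections algorithm over all candidate start bands.

    Columns are autoscaled before building chains (projection norms are then
    comparable across bands); prefix scoring regresses y on the original
    columns.  Returns the chain prefix with the smallest cross-validated RMSE.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if n != y.shape[0]:
        raise ConfigurationError("X and y row counts differ")
    max_k = int(max_k)
    if not 1 <= max_k <= min(n - 1, p):
        raise ConfigurationError("max_k must lie in [1, min(n_samples-1, n_bands)]")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in kf.split(X)]

    best: tuple[float, int, int] | None = None  # (rmse, start, k)
    best_chain: list[int] = []
    best_curve: np.ndarray | None = None
    for start in range(p):
        chain = successive_projection_chain(Z, start, max_k)
        curve = _ols_cv_rmse_curve(X, y, chain, folds)
        k = int(np.argmin(curve)) + 1
        cand = (float(curve[k - 1]), start, k)
        if best is None or cand[0] < best[0]:
            best, best_chain, best_curve = cand, chain, curve
    assert best is not None
    return SPAResult(
        selected_indices=np.array(best_chain[:best[2]]),
        rmse_curve=best_curve,
        chosen_k=best[2],
        start_index=best[1],
    )
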