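"""ε-support-vector regression with an RBF kernel and the genetic algorithm
that tunes its penalty C and kernel width g.

The SVR dual itself is solved by scikit-learn (libsvm); what is bespoke here
is the parameterisation: features standardised by training-set statistics, a
real-valued GA over (log10 C, log10 g) with roulette selection on inverse-RMSE
rank, arithmetic-blend crossover, Gaussian mutation clamped to the bounds, and
elitism.  Fitness of a chromosome is its cross-validated RMSE on the training
set (lower is fitter) — the quantity the evaluation tables report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .exceptions import ConfigurationError, DegenerateDataError, DimensionError

__all__ = ["SVRParams", "GAConfig", "FitResult", "SVRModel",
           "fit_svr", "predict", "ga_optimize", "cv_rmse"]


@dataclass
class SVRParams:
    """Hyperparameters of the ε-SVR: penalty C, RBF width g (the kernel is
    exp(−g‖x−x'‖²)), and the ε-insensitive tube half-width in °Brix."""

    C: float = 1.0
    g: float = 0.1
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigurationError("C must be > 0")
        if self.g <= 0:
            raise ConfigurationError("g must be > 0")
        if self.epsilon < 0:
            raise ConfigurationError("epsilon must be >= 0")


@dataclass
class SVRModel:
    """A fitted SVR bundled with the training-set standardisation it expects."""

    params: SVRParams
    mean_: np.ndarray
    scale_: np.ndarray
    svr_: SVR

    @property
    def n_features(self) -> int:
        return self.mean_.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise DimensionError(
                f"expected {self.n_features} bands, got shape {X.shape}")
        return self.svr_.predict((X - self.mean_) / self.scale_)


def fit_svr(X_train: np.ndarray, y_train: np.ndarray, p: SVRParams) -> SVRModel:
    """Standardise features by training mean/SD and fit the ε-SVR."""
    X = np.asarray(X_train, float)
    y = np.asarray(y_train, float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DimensionError("X_train rows must match y_train length")
    if X.shape[0] < 2:
        raise ConfigurationError("need at least 2 training samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DegenerateDataError("non-finite values in training data")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    svr = SVR(kernel="rbf", C=p.C, gamma=p.g, epsilon=p.epsilon)
    svr.fit((X - mean) / scale, y)
    return SVRModel(params=p, mean_=mean, scale_=scale, svr_=svr)


def predict(model: SVRModel, X: np.ndarray) -> np.ndarray:
    """Predict °Brix for spectra with the model's band count."""
    return model.predict(X)


def cv_rmse(X: np.ndarray, y: np.ndarray, params: SVRParams,
            folds: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Cross-validated RMSE of an SVR at fixed hyperparameters."""
    sq, n_tot = 0.0, 0
    for tr, te in folds:
        model = fit_svr(X[tr], y[tr], params)
        sq += float(np.sum((y[te] - model.predict(X[te])) ** 2))
        n_tot += len(te)
    return math.sqrt(sq / n_tot)


@dataclass
class GAConfig:
    """Genetic-algorithm settings for the (C, g) search.

    Chromosomes are real-valued pairs (log10 C, log10 g); the default bounds
    span C ∈ [0.01, 100] and g ∈ [0.001, 10], four to five decades that cover
    the optima typically reported for NIR sugar-content models.
    """

    pop_size: int = 20
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    max_generations: int = 30
    C_bounds: tuple[float, float] = (0.01, 100.0)
    g_bounds: tuple[float, float] = (0.001, 10.0)
    elitism: int = 1
    cv_folds: int = 5
    epsilon: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.pop_size < 2:
            raise ConfigurationError("pop_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.max_generations < 0:
            raise ConfigurationError("max_generations must be >= 0")
        for name in ("C_bounds", "g_bounds"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ConfigurationError(f"{name} must be a positive interval lo < hi")
        if not 0 <= self.elitism < self.pop_size:
            raise ConfigurationError("elitism must be < pop_size")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")


@dataclass
class FitResult:
    params: SVRParams
    model: SVRModel
    ga_history: np.ndarray  # best-so-far CV RMSE after each generation
    cv_rmse: float


def _roulette_pick(rng: np.random.Generator, rank_weights: np.ndarray) -> int:
    return int(rng.choice(len(rank_weights), p=rank_weights))


def ga_optimize(X_train: np.ndarray, y_train: np.ndarray,
                cfg: GAConfig) -> FitResult:
    """Tune (C, g) by a seeded genetic algorithm and refit on all of X_train.

    Selection is roulette over inverse-RMSE ranks, crossover an arithmetic
    blend, mutation a Gaussian step of 10% of each gene's log-range, clamped
    to the bounds; the top ``elitism`` chromosomes survive unchanged.  The CV
    folds are fixed once per call, so fitness is deterministic and the
    best-so-far history is non-increasing whenever ``elitism >= 1``.
    """
    cfg.validate()
    X = np.asarray(X_train, float)
    y = np.asarray(y_train, float).ravel()
    if X.shape[0] < cfg.cv_folds:
        raise ConfigurationError("training set smaller than cv_folds")
    rng = np.random.default_rng(cfg.seed)
    lo = np.log10([cfg.C_bounds[0], cfg.g_bounds[0]])
    hi = np.log10([cfg.C_bounds[1], cfg.g_bounds[1]])
    sigma = 0.1 * (hi - lo)

    kf = KFold(n_splits=cfg.cv_folds, shuffle=True,
               random_state=int(rng.integers(2**31)))
    folds = [(tr, te) for tr, te in kf.split(X)]

    def fitness(chrom: np.ndarray) -> float:
        p = SVRParams(C=10.0 ** chrom[0], g=10.0 ** chrom[1], epsilon=cfg.epsilon)
        return cv_rmse(X, y, p, folds)

    pop = rng.uniform(lo, hi, size=(cfg.pop_size, 2))
    fits = np.array([fitness(c) for c in pop])
    best_idx = int(np.argmin(fits))
    best_chrom, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    history = []

    for _ in range(cfg.max_generations):
        order = np.argsort(fits)  # best (lowest RMSE) first
        ranks = np.empty(cfg.pop_size)
        ranks[order] = np.arange(cfg.pop_size, 0, -1)  # best gets highest weight
        weights = ranks / ranks.sum()
        new = [pop[i].copy() for i in order[:cfg.elitism]]
        while len(new) < cfg.pop_size:
            p1 = pop[_roulette_pick(rng, weights)]
            p2 = pop[_roulette_pick(rng, weights)]
            if rng.random() < cfg.crossover_rate:
                u = rng.random()
                c1 = u * p1 + (1 - u) * p2
                c2 = (1 - u) * p1 + u * p2
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                for gene in range(2):
                    if rng.random() < cfg.mutation_rate:
                        child[gene] += rng.normal(0.0, sigma[gene])
                np.clip(child, lo, hi, out=child)
                if len(new) < cfg.pop_size:
                    new.append(child)
        pop = np.array(new)
        fits = np.array([fitness(c) for c in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_chrom = pop[gen_best].copy()
        history.append(best_fit)

    params = SVRParams(C=10.0 ** best_chrom[0], g=10.0 ** best_chrom[1],
                       epsilon=cfg.epsilon)
    model = fit_svr(X, y, params)
    return FitResult(params=params, model=model,
                     ga_history=np.array(history), cv_rmse=best_fit)
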