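"""Radiometric calibration, band trimming, train/test splitting, and the three
spectral preprocessors: Savitzky–Golay convolution smoothing (SG), standard
normal variate (SNV) and multiplicative scatter correction (MSC).

SG is realised from first principles: the smoothing weights are the center row
of the least-squares polynomial projection ``X (XᵀX)⁻¹ Xᵀ`` on the window
design ``x = −m … m``, applied as a convolution; edge samples are either fitted
on the truncated window (default) or handled by reflect padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import (
    ConfigurationError,
    DegenerateDataError,
    DimensionError,
    EmptySelectionError,
)
from .spectra import SpectraSet

__all__ = [
    "SGParams",
    "DataSplit",
    "black_white_correct",
    "mean_roi_spectrum",
    "trim_bands",
    "split_train_test",
    "sg_coefficients",
    "sg_smooth",
    "snv",
    "msc",
]


# --------------------------------------------------------------- calibration
def black_white_correct(raw: np.ndarray, black: np.ndarray,
                        white: np.ndarray) -> np.ndarray:
    """Black/white reference correction ``I = (I0 − B) / (W − B)``, elementwise.

    ``raw``, ``black`` and ``white`` must share a shape and ``white`` must
    exceed-or-differ-from ``black`` everywhere, otherwise the calibration is
    degenerate at that element.
    """
    raw = np.asarray(raw, float)
    black = np.asarray(black, float)
    white = np.asarray(white, float)
    if not (raw.shape == black.shape == white.shape):
        raise DimensionError(
            f"raw {raw.shape}, black {black.shape}, white {white.shape} "
            "must share a shape")
    denom = white - black
    bad = np.nonzero(denom == 0)
    if bad[0].size:
        first = tuple(int(b[0]) for b in bad)
        raise DegenerateDataError(
            f"white equals black at index {first}: calibration undefined")
    return (raw - black) / denom


def mean_roi_spectrum(cube: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-band mean reflectance over the masked pixels of a (h, w, bands) cube."""
    cube = np.asarray(cube, float)
    mask = np.asarray(mask, bool)
    if mask.shape != cube.shape[:2]:
        raise DimensionError(
            f"mask shape {mask.shape} does not match cube spatial dims {cube.shape[:2]}")
    if not mask.any():
        raise EmptySelectionError("ROI mask selects no pixels")
    return cube[mask].mean(axis=0)


# ------------------------------------------------------------ trim and split
def trim_bands(s: SpectraSet, lo_nm: float, hi_nm: float) -> SpectraSet:
    """Keep bands whose wavelength lies in the closed interval [lo_nm, hi_nm]."""
    if not lo_nm < hi_nm:
        raise ConfigurationError("lo_nm must be < hi_nm")
    keep = np.flatnonzero((s.wavelengths_nm >= lo_nm) & (s.wavelengths_nm <= hi_nm))
    if keep.size == 0:
        raise EmptySelectionError(
            f"no band survives trimming to [{lo_nm}, {hi_nm}] nm")
    return s.take_bands(keep)


@dataclass
class DataSplit:
    """Disjoint train/test row partition of a SpectraSet."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, int)
        self.test_indices = np.asarray(self.test_indices, int)
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ConfigurationError("train and test indices overlap")


def split_train_test(s: SpectraSet, ratio: float = 0.7, seed: int = 0) -> DataSplit:
    """Seeded uniform random partition with ``|train| = round-half-up(n·ratio)``.

    Rounding half up makes a 7:3 split of 168 samples 118:50, the customary
    calibration/prediction division for this sample size.
    """
    if s.brix is None:
        raise ConfigurationError("split requires brix labels")
    if not 0 < ratio < 1:
        raise ConfigurationError("ratio must lie strictly between 0 and 1")
    n = s.n_samples
    if n < 2:
        raise ConfigurationError("need at least 2 samples to split")
    n_train = int(math.floor(n * ratio + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return DataSplit(np.sort(perm[:n_train]), np.sort(perm[n_train:]), ratio, seed)


# ------------------------------------------------------------ Savitzky–Golay
class EdgeMode(str, Enum):
    REFLECT = "reflect"
    TRUNCATE_FIT = "truncate_fit"


@dataclass
class SGParams:
    """Savitzky–Golay smoothing parameters.

    ``window`` is the odd full window length (2m+1 points), ``polyorder`` the
    degree of the fitted polynomial. Defaults (11, 2) are a common chemometrics
    choice at ~2.5 nm band spacing.
    """

    window: int = 11
    polyorder: int = 2
    edge_mode: EdgeMode = EdgeMode.TRUNCATE_FIT

    def __post_init__(self) -> None:
        self.edge_mode = EdgeMode(self.edge_mode)
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigurationError("window must be an odd count >= 3")
        if not 0 <= self.polyorder < self.window:
            raise ConfigurationError("polyorder must satisfy 0 <= polyorder < window")


def _ls_projection_row(positions: np.ndarray, polyorder: int,
                       eval_at: float) -> np.ndarray:
    """Row of the least-squares polynomial smoother: weights w such that
    w·y is the degree-``polyorder`` fit over ``positions`` evaluated at
    ``eval_at``.  This is the ``eval_at`` row of X(XᵀX)⁻¹Xᵀ."""
    order = min(polyorder, len(positions) - 1)
    X = np.vander(positions, order + 1, increasing=True)
    x0 = np.vander(np.array([eval_at]), order + 1, increasing=True)[0]
    # row = x0ᵀ (XᵀX)⁻¹ Xᵀ, via a solve for numerical sanity
    return x0 @ np.linalg.solve(X.T @ X, X.T)


def sg_coefficients(p: SGParams) -> np.ndarray:
    """Center-point convolution weights of the SG smoother.

    The weights are symmetric and sum to one (a polynomial fit reproduces
    constants exactly).
    """
    m = p.window // 2
    x = np.arange(-m, m + 1, dtype=float)
    return _ls_projection_row(x, p.polyorder, 0.0)


def sg_smooth(s: SpectraSet, p: SGParams) -> SpectraSet:
    """Smooth every spectrum by SG convolution; shape is preserved.

    Interior bands are convolved with :func:`sg_coefficients`; the first and
    last m bands are handled per ``p.edge_mode``.
    """
    nb = s.n_bands
    if p.window > nb:
        raise DimensionError(f"window {p.window} exceeds band count {nb}")
    S = _smoothing_matrix(nb, p)
    return s.with_reflectance(s.reflectance @ S.T)


def _smoothing_matrix(n_bands: int, p: SGParams) -> np.ndarray:
    """Dense n_bands x n_bands operator applying SG smoothing to a spectrum."""
    m = p.window // 2
    w = sg_coefficients(p)
    S = np.zeros((n_bands, n_bands))
    for i in range(m, n_bands - m):
        S[i, i - m:i + m + 1] = w
    for i in list(range(m)) + list(range(n_bands - m, n_bands)):
        if p.edge_mode is EdgeMode.TRUNCATE_FIT:
            lo, hi = max(0, i - m), min(n_bands - 1, i + m)
            pos = np.arange(lo, hi + 1, dtype=float) - i
            S[i, lo:hi + 1] = _ls_projection_row(pos, p.polyorder, 0.0)
        else:  # reflect about the edge point (edge value not repeated)
            for t, wt in enumerate(w):
                j = i - m + t
                if j < 0:
                    j = -j
                elif j > n_bands - 1:
                    j = 2 * (n_bands - 1) - j
                S[i, j] += wt
    return S


# ------------------------------------------------------------------ SNV, MSC
def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: center each spectrum and scale it to unit
    sample standard deviation (n−1 denominator)."""
    x = s.reflectance
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise DegenerateDataError(
            f"sample {s.sample_ids[zero[0]]!r} has zero spectral variance; "
            "SNV undefined")
    return s.with_reflectance((x - mu) / sd)


def msc(
    s: SpectraSet,
    reference: np.ndarray | None = None,
    b1_tol: float = 1e-8,
) -> tuple[SpectraSet, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x`` is regressed on the reference, ``x ≈ b0 + b1·r``, and
    returned as ``(x − b0)/b1``, undoing the per-sample affine scatter.  The
    default reference is the mean spectrum of ``s``; pass the calibration-set
    mean explicitly to avoid test-set leakage.  Returns the corrected set and
    the reference actually used.
    """
    if reference is None:
        reference = s.reflectance.mean(axis=0)
    reference = np.asarray(reference, float)
    if reference.shape != (s.n_bands,):
        raise DimensionError("reference length must equal the band count")
    if np.std(reference) == 0:
        raise DegenerateDataError("reference spectrum has zero variance")
    r = reference - reference.mean()
    x = s.reflectance
    b1 = (x - x.mean(axis=1, keepdims=True)) @ r / (r @ r)
    bad = np.flatnonzero(np.abs(b1) < b1_tol)
    if bad.size:
        raise DegenerateDataError(
            f"sample {s.sample_ids[bad[0]]!r}: fitted slope {b1[bad[0]]:.2e} "
            "below tolerance; MSC degenerate")
    b0 = x.mean(axis=1) - b1 * reference.mean()
    corrected = (x - b0[:, None]) / b1[:, None]
    return s.with_reflectance(corrected), reference
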