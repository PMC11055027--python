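"""Synthetic visible/NIR reflectance spectra with a planted sugar-content signal.

The generator emulates a pushbroom hyperspectral acquisition of fruit: a
smooth reflectance envelope, Gaussian absorption valleys whose depth grows
linearly with the sample's °Brix, per-sample multiplicative/additive scatter
(the affine model that MSC assumes), and i.i.d. Gaussian detector noise.
Ground truth (labels, scatter terms, informative band indices) is returned
alongside so selection and regression stages can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DimensionError
from .spectra import SpectraSet

__all__ = ["SynthConfig", "SynthTruth", "generate_spectra", "generate_image_stack"]

# Reflectance envelope: low-order polynomial in normalised wavelength u in [0,1],
# rising from ~0.30 at the blue end, peaking ~0.75 near 800 nm, easing to 0.60.
_BASELINE_COEFFS = (0.30, 1.40, -1.10)  # b0 + b1*u + b2*u^2


@dataclass
class SynthConfig:
    """Study conditions for the simulator.

    Defaults mirror a 168-fruit acquisition on a 256-band 387–1034 nm
    instrument with sugar content spanning 7.4–12.5 °Brix, three absorption
    valleys (chlorophyll ~680 nm, O–H third overtone ~760 nm, water second
    overtone ~960 nm), mild per-sample scatter and 1% reflectance noise.
    """

    n_samples: int = 168
    n_bands: int = 256
    axis_start_nm: float = 387.0
    axis_end_nm: float = 1034.0
    brix_min: float = 7.4
    brix_max: float = 12.5
    absorption_centers_nm: tuple[float, ...] = (680.0, 760.0, 960.0)
    absorption_widths_nm: tuple[float, ...] = (20.0, 15.0, 30.0)
    signal_gain: float = 0.02  # absorption depth (reflectance) per °Brix above brix_min
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.n_bands < 2:
            raise ConfigurationError("n_bands must be >= 2")
        if not self.axis_start_nm < self.axis_end_nm:
            raise ConfigurationError("axis_start_nm must be < axis_end_nm")
        if not self.brix_min < self.brix_max:
            raise ConfigurationError("brix_min must be < brix_max")
        if len(self.absorption_centers_nm) != len(self.absorption_widths_nm):
            raise ConfigurationError(
                "absorption_centers_nm and absorption_widths_nm lengths differ")
        for c in self.absorption_centers_nm:
            if not (self.axis_start_nm <= c <= self.axis_end_nm):
                raise ConfigurationError(
                    f"absorption_centers_nm: center {c} outside wavelength axis")
        for w in self.absorption_widths_nm:
            if w <= 0:
                raise ConfigurationError("absorption_widths_nm must be positive")
        for name in ("signal_gain", "scatter_slope_sd", "scatter_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class SynthTruth:
    """Ground truth emitted with each synthetic set."""

    brix: np.ndarray
    informative_band_indices: np.ndarray  # bands within +/- one width of a center
    scatter_slopes: np.ndarray
    scatter_offsets: np.ndarray
    clean_reflectance: np.ndarray = field(repr=False, default=None)  # pre-scatter, pre-noise


def _baseline(wavelengths_nm: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    u = (wavelengths_nm - cfg.axis_start_nm) / (cfg.axis_end_nm - cfg.axis_start_nm)
    b0, b1, b2 = _BASELINE_COEFFS
    return b0 + b1 * u + b2 * u**2


def generate_spectra(cfg: SynthConfig) -> tuple[SpectraSet, SynthTruth]:
    """Simulate a labelled spectra set.

    Each clean spectrum is ``baseline − Σ_j gain·(brix − brix_min)·G_j(λ)``
    with unit-height Gaussians ``G_j`` at the configured centers/widths; a
    per-sample affine distortion ``(1+slope)·x + offset`` and additive
    Gaussian noise are then applied.  Bit-identical for identical seeds.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    wl = np.linspace(cfg.axis_start_nm, cfg.axis_end_nm, cfg.n_bands)
    base = _baseline(wl, cfg)

    brix = rng.uniform(cfg.brix_min, cfg.brix_max, size=cfg.n_samples)
    slopes = rng.normal(0.0, cfg.scatter_slope_sd, size=cfg.n_samples)
    offsets = rng.normal(0.0, cfg.scatter_offset_sd, size=cfg.n_samples)

    shapes = np.zeros_like(wl)
    informative = np.zeros(cfg.n_bands, dtype=bool)
    for c, w in zip(cfg.absorption_centers_nm, cfg.absorption_widths_nm):
        shapes = shapes + np.exp(-0.5 * ((wl - c) / w) ** 2)
        informative |= np.abs(wl - c) <= w

    depth = cfg.signal_gain * (brix - cfg.brix_min)  # (n,)
    clean = base[None, :] - depth[:, None] * shapes[None, :]
    distorted = (1.0 + slopes)[:, None] * clean + offsets[:, None]
    noisy = distorted + rng.normal(0.0, cfg.noise_sd, size=distorted.shape)

    spectra = SpectraSet(noisy, wl, brix=brix)
    truth = SynthTruth(
        brix=brix,
        informative_band_indices=np.flatnonzero(informative),
        scatter_slopes=slopes,
        scatter_offsets=offsets,
        clean_reflectance=clean,
    )
    return spectra, truth


def generate_image_stack(
    cfg: SynthConfig,
    height: int,
    width: int,
    truth: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Emit (raw, white, black, truth) image cubes of shape (height, width, bands).

    Constructed so that radiometric calibration is an exact inverse:
    ``raw = black + truth · (white − black)`` elementwise, with
    ``white > black`` at every pixel/band.  When ``truth`` is omitted, one
    synthetic spectrum per pixel is generated from ``cfg``.
    """
    cfg.validate()
    if height < 1 or width < 1:
        raise ConfigurationError("height and width must be >= 1")
    if truth is None:
        import dataclasses

        pix_cfg = dataclasses.replace(cfg, n_samples=height * width)
        spectra, _ = generate_spectra(pix_cfg)
        truth = spectra.reflectance.reshape(height, width, cfg.n_bands)
    else:
        truth = np.asarray(truth, dtype=float)
        if truth.shape[:2] != (height, width):
            raise DimensionError("truth cube spatial dims must match height/width")

    rng = np.random.default_rng(cfg.seed + 1)
    bands = truth.shape[2]
    # dark current: small, band-dependent, spatially flat-ish
    black = 0.04 + 0.02 * rng.random(bands)[None, None, :] \
        + 0.005 * rng.random((height, width, 1))
    white = 0.85 + 0.1 * rng.random(bands)[None, None, :] \
        + 0.02 * rng.random((height, width, 1))
    raw = black + truth * (white - black)
    return raw, white, black, truth
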