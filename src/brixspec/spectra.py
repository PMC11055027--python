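"""The ``SpectraSet`` container: a samples x bands reflectance matrix with a
wavelength axis, sample identifiers and optional °Brix labels.

Every pipeline stage consumes and produces this object. On disk it is a wide
CSV: first column ``sample_id``, an optional ``brix`` column, and one column
per band named by its wavelength in nm at 0.1 nm precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DimensionError, EmptySelectionError

__all__ = ["SpectraSet"]


@dataclass
class SpectraSet:
    """Reflectance spectra for a set of samples.

    Parameters
    ----------
    reflectance : ndarray of shape (n_samples, n_bands)
        Dimensionless reflectance values.
    wavelengths_nm : ndarray of shape (n_bands,)
        Strictly increasing wavelength axis in nanometres.
    sample_ids : sequence of str
        Unique identifier per sample.
    brix : ndarray of shape (n_samples,), optional
        Sugar content labels in °Brix; all values must be finite.
    """

    reflectance: np.ndarray
    wavelengths_nm: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    brix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.reflectance.ndim != 2:
            raise DimensionError("reflectance must be a 2-D samples x bands matrix")
        n, p = self.reflectance.shape
        if self.wavelengths_nm.shape != (p,):
            raise DimensionError(
                f"wavelength axis length {self.wavelengths_nm.shape} does not match "
                f"{p} reflectance columns"
            )
        if p >= 2 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise DimensionError("wavelengths_nm must be strictly increasing")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise DimensionError(f"{len(self.sample_ids)} sample_ids for {n} samples")
        if len(set(self.sample_ids)) != n:
            raise DimensionError("sample_ids must be unique")
        if self.brix is not None:
            self.brix = np.asarray(self.brix, dtype=float)
            if self.brix.shape != (n,):
                raise DimensionError(f"brix length {self.brix.shape} != {n} samples")
            if not np.all(np.isfinite(self.brix)):
                raise DimensionError("brix labels must all be finite")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def with_reflectance(self, reflectance: np.ndarray) -> "SpectraSet":
        """Copy of this set with the reflectance matrix replaced (same shape)."""
        reflectance = np.asarray(reflectance, dtype=float)
        if reflectance.shape != self.reflectance.shape:
            raise DimensionError("replacement reflectance must keep the same shape")
        return SpectraSet(reflectance, self.wavelengths_nm.copy(),
                          list(self.sample_ids),
                          None if self.brix is None else self.brix.copy())

    def take_samples(self, indices: Sequence[int]) -> "SpectraSet":
        """Row subset (e.g. the training half of a split)."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            self.reflectance[idx],
            self.wavelengths_nm.copy(),
            [self.sample_ids[i] for i in idx],
            None if self.brix is None else self.brix[idx],
        )

    def take_bands(self, indices: Sequence[int]) -> "SpectraSet":
        """Column subset (e.g. a selected-wavelength view)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise EmptySelectionError("band subset is empty")
        order = np.argsort(self.wavelengths_nm[idx])
        idx = idx[order]
        return SpectraSet(
            self.reflectance[:, idx],
            self.wavelengths_nm[idx],
            list(self.sample_ids),
            None if self.brix is None else self.brix.copy(),
        )

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path) -> None:
        """Write the wide-format CSV described in the module docstring."""
        cols: dict[str, np.ndarray | list[str]] = {"sample_id": list(self.sample_ids)}
        if self.brix is not None:
            cols["brix"] = self.brix
        for j, wl in enumerate(self.wavelengths_nm):
            cols[f"{wl:.1f}"] = self.reflectance[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraSet":
        df = pd.read_csv(path)
        if "sample_id" not in df.columns:
            raise DimensionError("spectra CSV must have a sample_id column")
        ids = df["sample_id"].astype(str).tolist()
        brix = df["brix"].to_numpy(float) if "brix" in df.columns else None
        band_cols = [c for c in df.columns if c not in ("sample_id", "brix")]
        wl = np.array([float(c) for c in band_cols])
        order = np.argsort(wl)
        refl = df[band_cols].to_numpy(float)[:, order]
        return cls(refl, wl[order], ids, brix)
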