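"""Core containers: a single Raman spectrum and a map (collection) of spectra.

A :class:`Spectrum` is one wavenumber axis (cm^-1, strictly increasing) plus
an intensity series of the same length.  A :class:`SpectralMap` is an ordered
stack of spectra sharing one axis, with per-spectrum metadata (sample id,
class label, optional X/Y stage position) held in a pandas DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


@dataclass
class Spectrum:
    axis: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("axis and intensity must be one-dimensional")
        if self.axis.size != self.intensity.size:
            raise ValueError(
                f"axis length {self.axis.size} != intensity length {self.intensity.size}"
            )
        if self.axis.size < 2:
            raise ValueError("a spectrum needs at least two channels")
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.axis.size

    def with_intensity(self, intensity: np.ndarray, **extra_meta) -> "Spectrum":
        """New spectrum on the same axis with replaced intensities."""
        meta = dict(self.metadata)
        meta.update(extra_meta)
        return Spectrum(self.axis, np.asarray(intensity, dtype=float), meta)


@dataclass
class SpectralMap:
    axis: np.ndarray
    intensities: np.ndarray  # (n_spectra, n_channels)
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D (n_spectra, n_channels) array")
        if self.intensities.shape[0] == 0:
            raise ValueError("a spectral map must contain at least one spectrum")
        if self.intensities.shape[1] != self.axis.size:
            raise ValueError("intensity row length must match the axis")
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if self.meta is None:
            self.meta = pd.DataFrame(index=range(self.intensities.shape[0]))
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("metadata table must have one row per spectrum")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[i], dict(self.meta.iloc[i].dropna()))

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self[i]

    @property
    def positions(self) -> np.ndarray | None:
        """(n, 2) X/Y stage positions if present in metadata, else None."""
        if {"x", "y"}.issubset(self.meta.columns):
            pos = self.meta[["x", "y"]].to_numpy(dtype=float)
            if not np.any(np.isnan(pos)):
                return pos
        return None

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectralMap":
        if len(spectra) == 0:
            raise ValueError("empty spectrum list")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if s.axis.size != axis.size or not np.array_equal(s.axis, axis):
                raise ValueError("all spectra in a map must share one axis")
        inten = np.stack([s.intensity for s in spectra])
        meta = pd.DataFrame([s.metadata for s in spectra])
        return cls(axis, inten, meta)

    def subset(self, mask_or_idx) -> "SpectralMap":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectralMap(self.axis, self.intensities[idx], self.meta.iloc[idx])

    def mean_spectrum(self, metadata: dict | None = None) -> Spectrum:
        return Spectrum(self.axis, self.intensities.mean(axis=0), metadata or {})
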