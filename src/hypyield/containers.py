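"""Sample-level data container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hypyield.errors import DataError, DimensionError, FormatError


@dataclass
class SampleTable:
    """Samples x bands reflectance matrix with its wavelength grid and yields.

    Parameters
    ----------
    spectra : ndarray, shape (n_samples, n_bands)
        Reflectance (or pretreated) spectra, one row per sample.
    wavelengths : ndarray, shape (n_bands,)
        Strictly increasing band centres in nm.
    y : ndarray, shape (n_samples,)
        Per-sample yield (arbitrary mass units).
    sample_ids : ndarray of str, optional
        Defaults to ``S0001, S0002, ...``.
    split : ndarray of str, optional
        Per-sample partition label in {"train", "val", "test"}; empty string
        until :func:`hypyield.models.split_dataset` assigns one.
    """

    spectra: np.ndarray
    wavelengths: np.ndarray
    y: np.ndarray
    sample_ids: np.ndarray | None = None
    split: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.spectra.ndim != 2:
            raise DimensionError("spectra must be 2-D (samples x bands)")
        if self.spectra.shape[1] != self.wavelengths.size:
            raise DimensionError(
                f"{self.spectra.shape[1]} spectral columns but "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.spectra.shape[0] != self.y.size:
            raise DimensionError("yield vector length must match sample count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise FormatError("wavelengths must be strictly increasing")
        if self.sample_ids is None:
            self.sample_ids = np.array(
                [f"S{i + 1:04d}" for i in range(self.n_samples)], dtype=object
            )
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def mask(self, label: str) -> np.ndarray:
        """Boolean mask of samples carrying the given split label."""
        if self.split is None:
            raise DataError("table has no split labels; run split_dataset first")
        return self.split == label

    def subset(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) restricted to one split label."""
        m = self.mask(label)
        return self.spectra[m], self.y[m]

    def with_spectra(self, spectra: np.ndarray, wavelengths: np.ndarray | None = None) -> "SampleTable":
        """Copy of the table with the spectral block replaced (e.g. pretreated)."""
        return SampleTable(
            spectra=np.asarray(spectra, dtype=float),
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            y=self.y.copy(),
            sample_ids=self.sample_ids.copy(),
            split=None if self.split is None else self.split.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"sample_id": self.sample_ids, "yield": self.y}
        if self.split is not None:
            cols["split"] = self.split
        df = pd.DataFrame(cols)
        band_cols = pd.DataFrame(
            self.spectra, columns=[f"{wl:.2f}" for wl in self.wavelengths]
        )
        return pd.concat([df, band_cols], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleTable":
        df = pd.read_csv(path)
        meta = [c for c in ("sample_id", "yield", "split") if c in df.columns]
        if "yield" not in meta:
            raise FormatError("sample table CSV must contain a 'yield' column")
        band_cols = [c for c in df.columns if c not in meta]
        try:
            wavelengths = np.array([float(c) for c in band_cols])
        except ValueError as exc:
            raise FormatError(f"non-numeric band column name: {exc}") from exc
        return cls(
            spectra=df[band_cols].to_numpy(dtype=float),
            wavelengths=wavelengths,
            y=df["yield"].to_numpy(dtype=float),
            sample_ids=df["sample_id"].to_numpy() if "sample_id" in df else None,
            split=df["split"].to_numpy() if "split" in df.columns else None,
        )
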