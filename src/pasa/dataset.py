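"""Columnar container for per-sample APSD spectra.

The central record of the pipeline: one row per sample, one column per laser
wavelength, plus sample id and class label. Serialized as plain CSV with
header ``id,label,apsd_1200,...,apsd_1700``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import validate_grid
from .synth import LABELS


@dataclass(frozen=True)
class APSDSpectrum:
    """APSD value per wavelength for one sample."""

    sample_id: str
    label: str
    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.wavelengths.shape:
            raise ValueError("values must align with the wavelength grid")
        if np.any(self.values < 0):
            raise ValueError("APSD values must be non-negative")


@dataclass(frozen=True)
class SpectraSet:
    """APSD spectra of a whole study: (n_samples, n_wavelengths) matrix."""

    ids: list[str]
    labels: np.ndarray
    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if len(self.ids) != n or len(self.labels) != n:
            raise ValueError("ids/labels must match the number of rows")
        if len(self.wavelengths) != p:
            raise ValueError("value columns must match the wavelength grid")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def binary_response(self) -> np.ndarray:
        """Response coding used throughout: cancer = 1, normal = 0."""
        return (self.labels == "cancer").astype(float)

    def subset_labels(self, label: str) -> "SpectraSet":
        mask = self.labels == label
        return SpectraSet(
            [i for i, m in zip(self.ids, mask) if m],
            self.labels[mask],
            self.wavelengths,
            self.values[mask],
        )

    def select_wavelengths(self, wavelengths: np.ndarray) -> "SpectraSet":
        idx = [int(np.flatnonzero(np.isclose(self.wavelengths, w))[0]) for w in wavelengths]
        return SpectraSet(
            self.ids, self.labels, self.wavelengths[idx], self.values[:, idx]
        )

    @classmethod
    def from_spectra(cls, spectra: list[APSDSpectrum]) -> "SpectraSet":
        wl = spectra[0].wavelengths
        for s in spectra:
            if not np.array_equal(s.wavelengths, wl):
                raise ValueError("all spectra must share one wavelength grid")
        return cls(
            [s.sample_id for s in spectra],
            np.array([s.label for s in spectra]),
            wl,
            np.stack([s.values for s in spectra]),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.values, columns=[f"apsd_{int(w)}" for w in self.wavelengths]
        )
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraSet":
        return import_spectra(path)


def import_spectra(path: str | Path) -> SpectraSet:
    """Read and validate an APSD spectra CSV.

    Raises with a row/column diagnostic on NaNs, unknown labels, or a
    non-increasing wavelength grid.
    """
    df = pd.read_csv(path)
    if "id" not in df.columns or "label" not in df.columns:
        raise ValueError("spectra CSV must have 'id' and 'label' columns")
    apsd_cols = [c for c in df.columns if c.startswith("apsd_")]
    if not apsd_cols:
        raise ValueError("spectra CSV has no 'apsd_<nm>' columns")
    try:
        wavelengths = np.array([float(c.split("_", 1)[1]) for c in apsd_cols])
    except ValueError as exc:
        raise ValueError(f"unparseable wavelength column: {exc}") from exc
    validate_grid(wavelengths)
    values = df[apsd_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"NaN APSD value at row id={df['id'].iloc[r]!r}, column {apsd_cols[c]}"
        )
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown class labels {sorted(bad)}; expected {LABELS}")
    return SpectraSet(
        [str(i) for i in df["id"]], df["label"].to_numpy(), wavelengths, values
    )
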