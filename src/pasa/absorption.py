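"""Normalized chromophore absorption models for the NIR-II window.

Each biomacromolecule (collagen, water, lipid) is represented by a smooth
parametric absorption curve evaluated on the laser wavelength grid and
normalized to unit maximum, mirroring how normalized absorption coefficients
are used to assign dominated absorption wavebands.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .grid import validate_grid, wavelength_grid

CHROMOPHORES = ("collagen", "water", "lipid")


@dataclass(frozen=True)
class AbsorptionModel:
    """Normalized absorption curve of one chromophore on a wavelength grid.

    ``values`` is dimensionless, non-negative, with max exactly 1 on the grid.
    """

    chromophore: str
    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.wavelengths.shape:
            raise ValueError("values and wavelengths must have matching shape")
        if np.any(self.values < 0):
            raise ValueError("absorption values must be non-negative")
        if not np.isclose(self.values.max(), 1.0):
            raise ValueError("absorption values must be normalized to max 1")

    def at(self, wavelength_nm: float) -> float:
        """Linearly interpolated normalized absorption at ``wavelength_nm``."""
        return float(np.interp(wavelength_nm, self.wavelengths, self.values))


@lru_cache(maxsize=1)
def _load_params() -> dict:
    text = resources.files("pasa.data").joinpath("absorption.yaml").read_text()
    return yaml.safe_load(text)


def _evaluate(params: dict, wavelengths: np.ndarray) -> np.ndarray:
    values = np.full_like(wavelengths, float(params.get("offset", 0.0)))
    for comp in params["components"]:
        c, w, a = float(comp["center"]), float(comp["width"]), float(comp["amplitude"])
        values = values + a * np.exp(-((wavelengths - c) ** 2) / (2.0 * w**2))
    return values


def builtin_absorption(
    chromophore: str, wavelengths: np.ndarray | None = None
) -> AbsorptionModel:
    """Return the packaged normalized absorption model for one chromophore.

    Parameters
    ----------
    chromophore
        One of ``"collagen"``, ``"water"``, ``"lipid"``.
    wavelengths
        Grid on which to evaluate; defaults to the 51-point 1200-1700 nm grid.
    """
    if chromophore not in CHROMOPHORES:
        raise ValueError(
            f"unknown chromophore {chromophore!r}; expected one of {CHROMOPHORES}"
        )
    wl = wavelength_grid() if wavelengths is None else validate_grid(wavelengths)
    raw = _evaluate(_load_params()[chromophore], wl)
    return AbsorptionModel(chromophore, wl, raw / raw.max())


@lru_cache(maxsize=8)
def _cached_table(wl_key: tuple[float, ...]) -> dict[str, AbsorptionModel]:
    wl = np.array(wl_key)
    return {name: builtin_absorption(name, wl) for name in CHROMOPHORES}


def absorption_table(wavelengths: np.ndarray | None = None) -> dict[str, AbsorptionModel]:
    """All three chromophore models keyed by name, on a shared grid."""
    wl = wavelength_grid() if wavelengths is None else validate_grid(wavelengths)
    return _cached_table(tuple(float(w) for w in wl))
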