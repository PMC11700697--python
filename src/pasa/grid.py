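"""Optical wavelength grid for NIR-II photoacoustic scanning.

The scanning protocol steps a tunable laser from 1200 to 1700 nm in 10 nm
increments, giving 51 detection wavelengths. Collagen, water and lipid are
the dominant absorbers in this window; hemoglobin absorption is negligible,
which is what makes the band attractive for probing extracellular-matrix
composition.
"""

from __future__ import annotations

import numpy as np

GRID_START_NM = 1200.0
GRID_STOP_NM = 1700.0
GRID_STEP_NM = 10.0


def wavelength_grid(
    start: float = GRID_START_NM,
    stop: float = GRID_STOP_NM,
    step: float = GRID_STEP_NM,
) -> np.ndarray:
    """Return the inclusive, strictly increasing laser wavelength grid in nm.

    Defaults give the 51-point 1200-1700 nm grid used throughout the package.
    """
    if step <= 0:
        raise ValueError("wavelength step must be positive")
    if stop <= start:
        raise ValueError("stop wavelength must exceed start")
    n = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(n)
    if not np.isclose(grid[-1], stop):
        raise ValueError("grid step does not evenly divide the span")
    return grid


def validate_grid(wavelengths: np.ndarray) -> np.ndarray:
    """Check that ``wavelengths`` is a strictly increasing arithmetic sequence."""
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength grid must be a 1-D array with >= 2 points")
    diffs = np.diff(wl)
    if np.any(diffs <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if not np.allclose(diffs, diffs[0]):
        raise ValueError("wavelength grid must be an arithmetic sequence")
    return wl
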