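"""Spectral preprocessing: de-duplication/resampling, Savitzky-Golay
smoothing, and first-derivative reflectance (FDR).

The canonical grid is integer nanometres 350..1350 inclusive (1001
bands).  The canonical FDR is the central difference
``(R(l+h) - R(l-h)) / 2h`` on interior bands with one-sided differences
at the two ends; a Savitzky-Golay derivative is available behind the
``method`` flag since either convention is defensible for 1-nm
vegetation spectra.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .errors import GridRangeError, ValidationError
from .spectra_io import Spectrum

CANONICAL_GRID = np.arange(350.0, 1351.0, 1.0)

DEFAULT_WINDOW = 11
DEFAULT_POLYORDER = 2


def _dedupe(wavelengths: np.ndarray, values: np.ndarray):
    """Collapse duplicated wavelengths to their mean, sort ascending."""
    order = np.argsort(wavelengths, kind="stable")
    wl, vals = wavelengths[order], values[order]
    uniq, inverse, counts = np.unique(wl, return_inverse=True, return_counts=True)
    if uniq.size == wl.size:
        return wl, vals
    sums = np.zeros(uniq.size)
    np.add.at(sums, inverse, vals)
    return uniq, sums / counts


def resample_to_grid(spectrum: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation).

    Duplicated input wavelengths are collapsed to their mean first;
    grid points coinciding with input wavelengths pass through exactly.
    """
    grid = np.asarray(grid, dtype=float)
    wl, vals = _dedupe(spectrum.wavelengths, spectrum.values)
    if wl.size < 2:
        raise ValidationError("need at least 2 distinct wavelengths to resample")
    if grid.min() < wl[0] or grid.max() > wl[-1]:
        raise GridRangeError(
            f"grid [{grid.min():g}, {grid.max():g}] outside spectrum span "
            f"[{wl[0]:g}, {wl[-1]:g}]; extrapolation is not supported"
        )
    out = np.interp(grid, wl, vals)
    return Spectrum(grid, out, kind=spectrum.kind, metadata=dict(spectrum.metadata))


def _require_uniform(wavelengths: np.ndarray) -> float:
    d = np.diff(wavelengths)
    if d.size == 0:
        raise ValidationError("spectrum too short")
    if not np.allclose(d, d[0], rtol=1e-8, atol=1e-10):
        raise ValidationError("non-uniform grid; resample_to_grid first")
    return float(d[0])


def savgol_smooth(
    spectrum: Spectrum,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> Spectrum:
    """Savitzky-Golay least-squares convolution smoothing.

    Requires a uniform grid.  Ends are handled by fitting the edge
    polynomial on the truncated window (``mode="interp"``).  Defaults
    (window 11, order 2) are the standard choice for 1-nm canopy
    spectra; both are config-overridable.
    """
    if window % 2 != 1 or window < 3:
        raise ValidationError("window must be an odd count >= 3")
    if polyorder >= window:
        raise ValidationError("polyorder must be < window")
    _require_uniform(spectrum.wavelengths)
    if len(spectrum) < window:
        raise ValidationError("spectrum shorter than smoothing window")
    sm = savgol_filter(spectrum.values, window, polyorder, mode="interp")
    return Spectrum(spectrum.wavelengths, sm, kind=spectrum.kind,
                    metadata=dict(spectrum.metadata))


def first_derivative(
    spectrum: Spectrum,
    method: str = "central",
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> Spectrum:
    """First-derivative reflectance, per nm.

    ``method="central"`` (canonical) uses central differences on
    interior bands and one-sided differences at the ends; exact for
    linear spectra.  ``method="savgol"`` differentiates the local
    least-squares polynomial instead.
    """
    if spectrum.kind != "reflectance":
        raise ValidationError("first_derivative expects a reflectance spectrum")
    if len(spectrum) < 3:
        raise ValidationError("need at least 3 bands to differentiate")
    h = _require_uniform(spectrum.wavelengths)
    if method == "central":
        d = np.gradient(spectrum.values, h)
    elif method == "savgol":
        d = savgol_filter(spectrum.values, window, polyorder, deriv=1,
                          delta=h, mode="interp")
    else:
        raise ValidationError(f"unknown derivative method {method!r}")
    return Spectrum(spectrum.wavelengths, d, kind="first_derivative",
                    metadata=dict(spectrum.metadata))


def smooth_matrix(X: np.ndarray, window: int = DEFAULT_WINDOW,
                  polyorder: int = DEFAULT_POLYORDER) -> np.ndarray:
    """Row-wise SG smoothing of a samples x bands matrix (uniform grid)."""
    return savgol_filter(np.asarray(X, dtype=float), window, polyorder,
                         axis=-1, mode="interp")


def derivative_matrix(X: np.ndarray, step: float = 1.0,
                      method: str = "central",
                      window: int = DEFAULT_WINDOW,
                      polyorder: int = DEFAULT_POLYORDER) -> np.ndarray:
    """Row-wise FDR of a samples x bands matrix on a uniform grid."""
    X = np.asarray(X, dtype=float)
    if method == "central":
        return np.gradient(X, step, axis=-1)
    if method == "savgol":
        return savgol_filter(X, window, polyorder, deriv=1, delta=step,
                             axis=-1, mode="interp")
    raise ValidationError(f"unknown derivative method {method!r}")
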