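"""Trilateral (three-edge) spectral parameters.

Twenty descriptors of the blue, yellow and red edges plus the green
peak and red valley of a reflectance/first-derivative spectrum pair:
edge amplitudes (extreme FDR) and positions, peak/valley reflectance
and positions, edge areas (trapezoidal FDR integrals) and seven
ratio/normalised-difference combinations of those quantities.

Conventions (the red edge window [680, 780] nm is standard; the others
follow the prevailing literature):

* ``Dy`` is the signed FDR value of the largest ``|FDR|`` in the
  yellow-edge window (the derivative is typically negative there, and
  the sign carries information).
* ``SDr`` and ``SDb`` integrate signed FDR; ``SDy`` integrates
  ``|FDR|`` so that all three areas are positive and the printed ratios
  (SDr/SDy etc.) are well defined.
* argmax/argmin ties break toward the shorter wavelength.
* Ratio and normalised-difference fields are NaN when their denominator
  is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError, WindowError
from .spectra_io import Spectrum

Interval = tuple[float, float]


@dataclass
class EdgeWindows:
    """Wavelength intervals (nm) bounding each spectral feature region."""

    red_edge: Interval = (680.0, 780.0)
    blue_edge: Interval = (490.0, 530.0)
    yellow_edge: Interval = (560.0, 640.0)
    green_peak: Interval = (510.0, 560.0)
    red_valley: Interval = (640.0, 700.0)

    def __post_init__(self):
        for f in fields(self):
            lo, hi = getattr(self, f.name)
            if not lo < hi:
                raise ValidationError(f"window {f.name} has lo >= hi")


PARAM_NAMES = (
    "Dr", "lambda_r", "Db", "lambda_b", "Dy", "lambda_y",
    "Rg", "lambda_g", "Rr", "lambda_v",
    "SDr", "SDb", "SDy",
    "Rg_minus_Rr_norm", "Rg_over_Rr",
    "SDr_over_SDb", "SDr_over_SDy",
    "SDr_minus_SDb", "SDr_minus_SDb_norm", "SDr_minus_SDy_norm",
)


@dataclass
class TrilateralParameters:
    """The 20 trilateral parameters of one spectrum.

    Amplitudes ``D*`` are FDR values (per nm); positions ``lambda_*``
    are nm; ``Rg``/``Rr`` are reflectances; ``SD*`` are derivative
    areas (dimensionless, since FDR integrates back to reflectance).
    """

    Dr: float
    lambda_r: float
    Db: float
    lambda_b: float
    Dy: float
    lambda_y: float
    Rg: float
    lambda_g: float
    Rr: float
    lambda_v: float
    SDr: float
    SDb: float
    SDy: float
    Rg_minus_Rr_norm: float
    Rg_over_Rr: float
    SDr_over_SDb: float
    SDr_over_SDy: float
    SDr_minus_SDb: float
    SDr_minus_SDb_norm: float
    SDr_minus_SDy_norm: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


def _window_slice(wavelengths: np.ndarray, interval: Interval, name: str):
    lo, hi = interval
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise WindowError(f"window {name} [{lo:g}, {hi:g}] covers "
                          f"{idx.size} grid point(s); need >= 2")
    return idx


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0.0 else float("nan")


def extract_trilateral(
    reflectance: Spectrum,
    derivative: Spectrum,
    windows: EdgeWindows | None = None,
) -> TrilateralParameters:
    """Extract the 20 trilateral parameters from a spectrum pair.

    ``reflectance`` and ``derivative`` must share one grid; the
    derivative is the FDR of the reflectance (the caller computes it,
    so smoothing/derivative conventions stay in one place).
    """
    windows = windows or EdgeWindows()
    wl = reflectance.wavelengths
    if wl.size != derivative.wavelengths.size or not np.allclose(
        wl, derivative.wavelengths
    ):
        raise AlignmentError("reflectance and derivative grids differ")
    r = reflectance.values
    d = derivative.values

    i_red = _window_slice(wl, windows.red_edge, "red_edge")
    i_blue = _window_slice(wl, windows.blue_edge, "blue_edge")
    i_yel = _window_slice(wl, windows.yellow_edge, "yellow_edge")
    i_grn = _window_slice(wl, windows.green_peak, "green_peak")
    i_val = _window_slice(wl, windows.red_valley, "red_valley")

    # np.argmax/argmin return the first extreme index, i.e. ties break
    # toward the shorter wavelength on an ascending grid
    jr = i_red[np.argmax(d[i_red])]
    jb = i_blue[np.argmax(d[i_blue])]
    jy = i_yel[np.argmax(np.abs(d[i_yel]))]
    jg = i_grn[np.argmax(r[i_grn])]
    jv = i_val[np.argmin(r[i_val])]

    Dr, Db, Dy = float(d[jr]), float(d[jb]), float(d[jy])
    Rg, Rr = float(r[jg]), float(r[jv])
    SDr = float(np.trapezoid(d[i_red], wl[i_red]))
    SDb = float(np.trapezoid(d[i_blue], wl[i_blue]))
    SDy = float(np.trapezoid(np.abs(d[i_yel]), wl[i_yel]))

    return TrilateralParameters(
        Dr=Dr, lambda_r=float(wl[jr]),
        Db=Db, lambda_b=float(wl[jb]),
        Dy=Dy, lambda_y=float(wl[jy]),
        Rg=Rg, lambda_g=float(wl[jg]),
        Rr=Rr, lambda_v=float(wl[jv]),
        SDr=SDr, SDb=SDb, SDy=SDy,
        Rg_minus_Rr_norm=_safe_div(Rg - Rr, Rg + Rr),
        Rg_over_Rr=_safe_div(Rg, Rr),
        SDr_over_SDb=_safe_div(SDr, SDb),
        SDr_over_SDy=_safe_div(SDr, SDy),
        SDr_minus_SDb=SDr - SDb,
        SDr_minus_SDb_norm=_safe_div(SDr - SDb, SDr + SDb),
        SDr_minus_SDy_norm=_safe_div(SDr - SDy, SDr + SDy),
    )


def red_edge_summary(
    derivative: Spectrum, window: Interval = (680.0, 780.0)
) -> tuple[float, float, float]:
    """(position, amplitude, area) of the red edge from an FDR spectrum."""
    wl = derivative.wavelengths
    idx = _window_slice(wl, window, "red_edge")
    d = derivative.values
    j = idx[np.argmax(d[idx])]
    sdr = float(np.trapezoid(d[idx], wl[idx]))
    return float(wl[j]), float(d[j]), sdr


def extract_table(
    wavelengths: np.ndarray,
    reflectance_matrix: np.ndarray,
    derivative_matrix: np.ndarray,
    sample_ids: Sequence,
    windows: EdgeWindows | None = None,
) -> pd.DataFrame:
    """Per-sample trilateral parameter table (20 columns)."""
    rows = []
    for i in range(len(sample_ids)):
        params = extract_trilateral(
            Spectrum(wavelengths, reflectance_matrix[i]),
            Spectrum(wavelengths, derivative_matrix[i], kind="first_derivative"),
            windows,
        )
        rows.append(params.as_dict())
    return pd.DataFrame(rows, index=list(sample_ids), columns=list(PARAM_NAMES))
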