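"""Per-band correlation spectra, top-k band picks, and SPA selection.

The successive projections algorithm (SPA) is a forward search that
starts from one band and, at every iteration, residualises all
unselected bands against the most recently selected one, then picks the
candidate with the largest residual norm.  Because the candidates are
themselves residualised in place, the net effect is successive
orthogonalisation against the whole selected set, which keeps the
selection minimally collinear.  The start band k0 and subset size N are
chosen by the cross-validated RMSE (RMSECV) of an ordinary
least-squares model on the selection.

Columns are mean-centred and unit-scaled before projection (standard
chemometrics practice; switchable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from .errors import DegenerateMatrixError, ValidationError

logger = logging.getLogger(__name__)

_ZERO_TOL = 1e-12


@dataclass
class CorrelationSpectrum:
    """Per-band Pearson correlation of spectra with one indicator."""

    wavelengths: np.ndarray
    r: np.ndarray
    n: int
    indicator: str = ""
    zero_variance: np.ndarray | None = None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.wavelengths.size != self.r.size:
            raise ValidationError("wavelengths and r must have equal length")
        if np.any(np.abs(self.r) > 1 + 1e-9):
            raise ValidationError("|r| > 1 in correlation spectrum")
        if self.zero_variance is None:
            self.zero_variance = np.zeros(self.r.size, dtype=bool)


@dataclass
class SPAResult:
    """Outcome of the RMSECV-driven SPA sweep."""

    selected: tuple
    k0: int
    n_selected: int
    rmsecv: float
    path: tuple = ()

    def __post_init__(self):
        if len(set(self.selected)) != len(self.selected):
            raise ValidationError("SPA selection contains duplicates")
        if self.rmsecv < 0:
            raise ValidationError("rmsecv must be >= 0")


def correlation_spectrum(
    X: np.ndarray, wavelengths, y, indicator: str = ""
) -> CorrelationSpectrum:
    """Pearson r between every band and an indicator.

    Bands with zero variance get r = 0 and are flagged in
    ``zero_variance``; a constant indicator is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValidationError("X rows must match y length")
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 samples")
    if np.ptp(y) == 0.0:
        raise ValidationError("constant indicator: correlation undefined")
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc**2))
    Xc = X - X.mean(axis=0)
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    zero = sx <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ Xc) / (sy * np.where(zero, 1.0, sx))
    r = np.where(zero, 0.0, r)
    return CorrelationSpectrum(np.asarray(wavelengths, dtype=float), r,
                               n=int(X.shape[0]), indicator=indicator,
                               zero_variance=zero)


def top_k_bands(corr: CorrelationSpectrum, k: int = 10) -> np.ndarray:
    """The k wavelengths of largest |r|, sorted by |r| descending.

    Ties break toward the shorter wavelength (lexsort is stable on the
    secondary wavelength key).
    """
    if k > corr.r.size:
        raise ValidationError(f"k={k} exceeds {corr.r.size} bands")
    order = np.lexsort((corr.wavelengths, -np.abs(corr.r)))
    return corr.wavelengths[order[:k]]


def _standardize(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    return Xc / np.where(sd > 0, sd, 1.0)


def spa_select(
    X: np.ndarray,
    k0: int,
    n_select: int,
    standardize: bool = True,
    return_norms: bool = False,
):
    """Successive projections from start band ``k0``; ``n_select`` picks.

    Returns the ordered list of selected column indices (k0 first); with
    ``return_norms`` also the residual norm of each pick.  A selected
    column of zero norm (degenerate X) raises
    :class:`DegenerateMatrixError` naming the iteration.
    """
    X = np.asarray(X, dtype=float)
    n, B = X.shape
    if not 0 <= k0 < B:
        raise ValidationError(f"k0={k0} outside [0, {B})")
    if not 1 <= n_select <= min(n, B):
        raise ValidationError(f"n_select={n_select} outside [1, min(n, B)]")
    R = _standardize(X) if standardize else X.astype(float, copy=True)
    selected = [k0]
    norms_path = [float(np.linalg.norm(R[:, k0]))]
    unselected = np.ones(B, dtype=bool)
    unselected[k0] = False
    for it in range(1, n_select):
        v = R[:, selected[-1]]
        nv = float(v @ v)
        if nv <= _ZERO_TOL:
            raise DegenerateMatrixError(
                f"selected column {selected[-1]} has zero norm at iteration {it}",
                iteration=it,
            )
        # residualise every candidate against the latest pick
        R = R - np.outer(v, (v @ R) / nv)
        cand_norms = np.linalg.norm(R, axis=0)
        cand_norms[~unselected] = -1.0
        nxt = int(np.argmax(cand_norms))  # first max -> smallest index on ties
        if cand_norms[nxt] <= max(np.sqrt(nv), 1.0) * 1e-9:
            # every remaining candidate lies in the span of the selection
            raise DegenerateMatrixError(
                f"no candidate with nonzero residual at iteration {it}",
                iteration=it,
            )
        selected.append(nxt)
        norms_path.append(float(cand_norms[nxt]))
        unselected[nxt] = False
    if return_norms:
        return selected, norms_path
    return selected


def _cv_rmse(
    X_sel: np.ndarray, y: np.ndarray, cv_folds: int, seed: int
) -> float:
    """Pooled K-fold RMSECV of OLS (with intercept) on selected bands."""
    n = y.size
    kf = KFold(n_splits=min(cv_folds, n), shuffle=True, random_state=seed)
    sq_errs = np.empty(n)
    for train, test in kf.split(X_sel):
        A = np.column_stack([np.ones(train.size), X_sel[train]])
        At = np.column_stack([np.ones(test.size), X_sel[test]])
        coef, _, rank, _ = np.linalg.lstsq(A, y[train], rcond=None)
        if rank < A.shape[1]:
            # rank-deficient fold: tiny ridge stabiliser
            logger.debug("rank-deficient CV fold; ridge fallback (1e-8)")
            G = A.T @ A + 1e-8 * np.eye(A.shape[1])
            coef = np.linalg.solve(G, A.T @ y[train])
        sq_errs[test] = (y[test] - At @ coef) ** 2
    return float(np.sqrt(sq_errs.mean()))


def spa_optimize(
    X: np.ndarray,
    y: np.ndarray,
    n_max: int,
    cv_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
    k0_candidates=None,
) -> SPAResult:
    """Sweep start band and subset size, minimising RMSECV.

    For every k0 (all bands by default) and every N in 2..n_max (N = 1
    when ``n_max == 1``), runs :func:`spa_select` and scores the
    selection by seeded K-fold OLS RMSECV; returns the minimiser.  Ties
    break toward smaller N, then smaller k0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, B = X.shape
    if np.ptp(y) == 0.0:
        raise ValidationError("constant indicator")
    if n_max > min(n - 1, B):
        raise ValidationError(f"n_max={n_max} exceeds min(samples - 1, bands)")
    n_values = [1] if n_max == 1 else list(range(2, n_max + 1))
    k0s = range(B) if k0_candidates is None else k0_candidates
    best = None  # (rmsecv, N, k0, selected, norms)
    for k0 in k0s:
        try:
            path, norms = spa_select(X, k0, n_max, standardize=standardize,
                                     return_norms=True)
        except DegenerateMatrixError:
            continue
        for N in n_values:
            sel = path[:N]
            # score on sorted columns: OLS is order-invariant, and a
            # fixed order makes equal selection sets tie bit-exactly
            rmsecv = _cv_rmse(X[:, sorted(sel)], y, cv_folds, seed)
            key = (rmsecv, N, k0)
            if best is None or key < (best[0], best[1], best[2]):
                best = (rmsecv, N, k0, tuple(sel), tuple(norms[:N]))
    if best is None:
        raise DegenerateMatrixError("no feasible SPA start band")
    rmsecv, N, k0, sel, norms = best
    return SPAResult(selected=sel, k0=k0, n_selected=N, rmsecv=rmsecv,
                     path=norms)
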