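"""Two-band optimized spectral indices and the exhaustive pair search.

Three index families over band reflectances R(lambda_m), R(lambda_n):

    NDSI = (Rm - Rn) / (Rm + Rn)      normalized difference
    DSI  =  Rm - Rn                   difference
    RSI  =  Rm / Rn                   ratio

The "optimized" index of a family is the ordered band pair maximizing the
squared Pearson correlation r^2 between the per-sample index values and
LPC, found by scanning every ordered pair on the grid.  On derivative
spectra the "reflectance" can be negative or cross zero, so near-zero
denominators (|.| < 1e-12) yield missing values rather than infinities;
pairs with more than 10 % missing samples, fewer than 3 complete samples,
or zero index variance are excluded from the argmax.

NDSI and DSI have swap-antisymmetric values, so their r^2 grids are
symmetric and computed on one triangle; RSI is nonlinear under swap and is
scanned in both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SpectraError
from .fod import FODResult

KINDS = ("NDSI", "DSI", "RSI")
DENOM_EPS = 1e-12
MAX_MISSING_FRAC = 0.10
MIN_COMPLETE = 3


@dataclass(frozen=True)
class IndexDefinition:
    """A concrete two-band index: family, band pair (nm), source FOD order."""

    kind: str
    lambda_m: float
    lambda_n: float
    source_order: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SpectraError(f"unknown index kind {self.kind!r}")
        if self.lambda_m == self.lambda_n:
            raise SpectraError("index bands must differ")


@dataclass
class PairScanResult:
    """r^2 over all ordered band pairs of one (kind, order) combination.

    ``r2_grid[i, j]`` is the squared correlation of index(lambda_i,
    lambda_j) with LPC; the diagonal and excluded pairs are NaN.  ``best``
    is the argmax pair with deterministic tie-breaking (smallest lambda_m,
    then smallest lambda_n); ``best_r`` keeps the signed correlation.
    """

    kind: str
    source_order: float
    wavelengths: np.ndarray
    r2_grid: np.ndarray
    best: IndexDefinition
    best_r2: float
    best_r: float
    n_samples: int


def compute_index(values_m: np.ndarray, values_n: np.ndarray,
                  kind: str) -> np.ndarray:
    """Per-sample index values; undefined entries (zero denominator) are NaN."""
    vm = np.asarray(values_m, dtype=float)
    vn = np.asarray(values_n, dtype=float)
    try:
        np.broadcast_shapes(vm.shape, vn.shape)
    except ValueError:
        raise SpectraError("band value vectors must have equal length") from None
    if kind == "DSI":
        return vm - vn
    if kind == "NDSI":
        denom = vm + vn
    elif kind == "RSI":
        denom = vn
    else:
        raise SpectraError(f"unknown index kind {kind!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (vm - vn) / denom if kind == "NDSI" else vm / denom
    out = np.where(np.abs(denom) < DENOM_EPS, np.nan, out)
    return out


def _corr_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``x`` against ``y``, NaN-aware.

    Columns with fewer than MIN_COMPLETE finite entries, more than
    MAX_MISSING_FRAC missing entries, or zero variance on either side of
    the pairwise-complete subset come back NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    finite = np.isfinite(x)
    if finite.all():
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        num = yc @ xc
        den = np.sqrt((xc * xc).sum(axis=0) * (yc @ yc))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / den, np.nan)
        return np.clip(r, -1.0, 1.0)
    xz = np.where(finite, x, 0.0)
    counts = finite.sum(axis=0)
    ok = (counts >= MIN_COMPLETE) & (n - counts <= MAX_MISSING_FRAC * n)
    with np.errstate(invalid="ignore", divide="ignore"):
        xmean = xz.sum(axis=0) / counts
        xc = np.where(finite, xz - xmean, 0.0)
        ymean = (finite * y[:, None]).sum(axis=0) / counts
        ssy = (finite * (y[:, None] - ymean) ** 2).sum(axis=0)
        num = ((y[:, None] - ymean) * xc * finite).sum(axis=0)
        den = np.sqrt((xc * xc).sum(axis=0) * ssy)
        r = np.where(ok & (den > 0), num / den, np.nan)
    return np.clip(r, -1.0, 1.0)


def scan_pairs(matrix: np.ndarray, lpc: np.ndarray, kind: str,
               wavelengths: np.ndarray,
               source_order: float = 0.0) -> PairScanResult:
    """Exhaustive ordered-pair scan of one index family against LPC."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    lpc = np.asarray(lpc, dtype=float)
    n, b = matrix.shape
    if n < 3:
        raise SpectraError("need at least 3 samples to scan")
    if b < 2:
        raise SpectraError("need at least 2 bands to scan")
    if lpc.shape != (n,):
        raise SpectraError("lpc length must match sample count")
    if np.std(lpc) == 0:
        raise SpectraError("lpc is constant; correlations are undefined")
    wavelengths = np.asarray(wavelengths, dtype=float)

    grid = np.full((b, b), np.nan)
    symmetric = kind in ("NDSI", "DSI")
    for m in range(b):
        cols = slice(m + 1, b) if symmetric else slice(0, b)
        idx = compute_index(matrix[:, m : m + 1], matrix[:, cols], kind)
        row = _corr_columns(idx, lpc) ** 2
        grid[m, cols] = row
        if symmetric:
            grid[cols, m] = row
    np.fill_diagonal(grid, np.nan)

    flat = np.where(np.isnan(grid), -np.inf, grid).ravel()
    best_flat = int(np.argmax(flat))  # row-major => smallest lambda_m, then lambda_n ties
    if not np.isfinite(flat[best_flat]):
        raise SpectraError("no band pair admits a defined correlation")
    mi, ni = divmod(best_flat, b)
    best = IndexDefinition(kind=kind, lambda_m=float(wavelengths[mi]),
                           lambda_n=float(wavelengths[ni]),
                           source_order=float(source_order))
    best_vals = compute_index(matrix[:, mi], matrix[:, ni], kind)
    best_r = float(_corr_columns(best_vals[:, None], lpc)[0])
    return PairScanResult(kind=kind, source_order=float(source_order),
                          wavelengths=wavelengths, r2_grid=grid, best=best,
                          best_r2=float(grid[mi, ni]), best_r=best_r,
                          n_samples=n)


def scan_all(fod_results: list[FODResult], lpc: np.ndarray,
             kinds: tuple[str, ...] = KINDS) -> list[PairScanResult]:
    """One scan per (kind, FOD order); errors carry the offending context."""
    results = []
    for fr in fod_results:
        for kind in kinds:
            try:
                results.append(
                    scan_pairs(fr.matrix, lpc, kind, fr.wavelengths,
                               source_order=fr.order)
                )
            except SpectraError as err:
                raise SpectraError(
                    f"scan failed for kind={kind}, order={fr.order}: {err}"
                ) from err
    return results


def best_pairs_table(results: list[PairScanResult]) -> pd.DataFrame:
    """Tidy report of the optimum pair per (kind, order)."""
    rows = [
        {
            "kind": r.kind,
            "order": r.source_order,
            "lambda_m_nm": r.best.lambda_m,
            "lambda_n_nm": r.best.lambda_n,
            "best_r2": r.best_r2,
            "best_r": r.best_r,
            "n_samples": r.n_samples,
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values(["kind", "order"]).reset_index(drop=True)
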