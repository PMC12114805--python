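"""Single-band Pearson screening of derivative spectra against LPC.

For each fractional order the screen reports the maximum absolute
correlation |r| over bands, the wavelength attaining it (smallest nm on
ties), and how many bands pass a two-tailed significance test at
alpha = 0.01.  Significance uses the exact t transform
t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom — no multiple-testing
correction, matching the raw per-band counting convention of nutrient
band-screening studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SpectraError
from .fod import FODResult
from .indices import _corr_columns


@dataclass(frozen=True)
class ScreenRow:
    """Per-order screening summary: max |r|, its band, significant count."""

    order: float
    max_abs_r: float
    argmax_band: float
    n_significant: int
    n_bands: int


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN when either side has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SpectraError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise SpectraError("need at least 3 samples")
    return float(_corr_columns(x[:, None], y)[0])


def critical_r(n: int, alpha: float = 0.01) -> float:
    """Two-tailed |r| significance threshold for sample size n.

    Inverts t = r sqrt((n-2)/(1-r^2)): with t_c the upper alpha/2 quantile
    of Student's t on n-2 df, the threshold is t_c / sqrt(n - 2 + t_c^2).
    """
    if n < 4:
        raise SpectraError("need n >= 4 for a correlation test")
    if not (0.0 < alpha < 1.0):
        raise SpectraError("alpha must be in (0, 1)")
    t_c = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t_c / np.sqrt(n - 2 + t_c**2))


def screen_order(fr: FODResult, lpc: np.ndarray,
                 alpha: float = 0.01) -> ScreenRow:
    """Screen one order's matrix band-by-band against LPC."""
    lpc = np.asarray(lpc, dtype=float)
    n = fr.matrix.shape[0]
    if lpc.shape != (n,):
        raise SpectraError("lpc length must match sample count")
    if n < 4:
        raise SpectraError("need at least 4 samples to screen")
    r = _corr_columns(fr.matrix, lpc)
    abs_r = np.abs(r)
    if np.all(np.isnan(abs_r)):
        raise SpectraError(f"all bands undefined at order {fr.order}")
    masked = np.where(np.isnan(abs_r), -np.inf, abs_r)
    best = int(np.argmax(masked))  # first occurrence => smallest wavelength
    threshold = critical_r(n, alpha)
    n_sig = int(np.sum(masked >= threshold))
    return ScreenRow(order=fr.order, max_abs_r=float(abs_r[best]),
                     argmax_band=float(fr.wavelengths[best]),
                     n_significant=n_sig, n_bands=fr.matrix.shape[1])


def screen_sweep(fod_results: list[FODResult], lpc: np.ndarray,
                 alpha: float = 0.01) -> list[ScreenRow]:
    """One :class:`ScreenRow` per order, ascending by order."""
    if not fod_results:
        raise SpectraError("no FOD results to screen")
    ordered = sorted(fod_results, key=lambda fr: fr.order)
    return [screen_order(fr, lpc, alpha) for fr in ordered]


def screen_table(rows: list[ScreenRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "order": [r.order for r in rows],
            "max_abs_r": [r.max_abs_r for r in rows],
            "band_nm": [r.argmax_band for r in rows],
            "n_significant": [r.n_significant for r in rows],
        }
    )


def select_fractional_order(rows: list[ScreenRow],
                            exclude: tuple[float, ...] = (0.0, 1.0, 2.0)) -> float:
    """Order with the highest max |r| among non-integer (by default) orders.

    Used to pick the data-driven best fractional order that joins
    {0, 1, 2} in the model feature set.
    """
    candidates = [r for r in rows if r.order not in exclude]
    if not candidates:
        raise SpectraError("no candidate orders after exclusion")
    best = max(candidates, key=lambda r: (r.max_abs_r, -r.order))
    return best.order
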