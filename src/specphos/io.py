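"""Reading, writing and preprocessing of spectra and LPC tables.

Two CSV dialects are supported:

* wide — first column ``wavelength_nm``, one column per sample (the native
  layout of field campaigns exporting one spectrum per measurement point);
* long — columns ``sample_id``, ``wavelength``, ``reflectance``.

Leaf phosphorus content travels in a separate two-column CSV
(``sample_id``, ``lpc_mg_per_g``).  Reflectance is held internally as a
fraction in [0, 1]; percent-scaled files are converted at the I/O boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .dataset import LpcSummary, SpectraError, SpectraSet

WAVELENGTH_COL = "wavelength_nm"
LPC_COL = "lpc_mg_per_g"


def read_lpc(path: str | Path) -> pd.Series:
    """Read a two-column LPC CSV into a Series indexed by sample id."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "sample_id" not in df.columns or LPC_COL not in df.columns:
        raise SpectraError(f"LPC file {path} needs columns 'sample_id', '{LPC_COL}'")
    return pd.Series(df[LPC_COL].to_numpy(float), index=df["sample_id"].astype(str))


def read_spectra(
    path: str | Path,
    layout: str = "wide",
    reflectance_scale: str = "fraction",
    lpc_path: str | Path | None = None,
) -> SpectraSet:
    """Read a spectra CSV into a :class:`SpectraSet`.

    Parameters
    ----------
    layout
        ``"wide"`` (wavelength rows, sample columns) or ``"long"``
        (sample_id / wavelength / reflectance rows).
    reflectance_scale
        ``"fraction"`` for values already in [0, 1], ``"percent"`` for
        0-100 scaled files (divided by 100 on read).
    lpc_path
        Optional LPC CSV; its sample ids must cover the spectra's.
    """
    if layout == "wide":
        header = pd.read_csv(path, header=None, nrows=1).iloc[0].tolist()
        raw_ids = [str(c) for c in header[1:]]
        if len(set(raw_ids)) != len(raw_ids):
            raise SpectraError("duplicate sample ids in spectra file")
        df = pd.read_csv(path, float_precision="round_trip")
        wl_col = df.columns[0]
        wavelengths = df[wl_col].to_numpy(float)
        sample_ids = raw_ids
        matrix = df.iloc[:, 1:].to_numpy(float).T
    elif layout == "long":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("sample_id", "wavelength", "reflectance"):
            if col not in df.columns:
                raise SpectraError(f"long layout requires column '{col}'")
        wide = df.pivot(index="wavelength", columns="sample_id", values="reflectance")
        wide = wide.sort_index()
        wavelengths = wide.index.to_numpy(float)
        sample_ids = [str(c) for c in wide.columns]
        matrix = wide.to_numpy(float).T
    else:
        raise SpectraError(f"unknown layout {layout!r}")

    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    matrix = matrix[:, order]
    if reflectance_scale == "percent":
        matrix = matrix / 100.0
    elif reflectance_scale != "fraction":
        raise SpectraError(f"unknown reflectance_scale {reflectance_scale!r}")
    if len(set(sample_ids)) != len(sample_ids):
        raise SpectraError("duplicate sample ids in spectra file")

    lpc = None
    if lpc_path is not None:
        series = read_lpc(lpc_path)
        missing = [s for s in sample_ids if s not in series.index]
        if missing:
            raise SpectraError(f"LPC file lacks samples: {missing[:5]}")
        lpc = series.loc[sample_ids].to_numpy(float)
    return SpectraSet(wavelengths=wavelengths, reflectance=matrix,
                      lpc=lpc, sample_ids=sample_ids)


def write_spectra(s: SpectraSet, path: str | Path,
                  lpc_path: str | Path | None = None) -> None:
    """Write the wide CSV dialect (and optionally the LPC CSV).

    Values are written with full repr precision so that
    ``read_spectra(write_spectra(s))`` round-trips bit-identically.
    """
    df = pd.DataFrame(s.reflectance.T, columns=s.sample_ids)
    df.insert(0, WAVELENGTH_COL, s.wavelengths)
    df.to_csv(path, index=False)
    if lpc_path is not None:
        if s.lpc is None:
            raise SpectraError("SpectraSet has no lpc to write")
        pd.DataFrame({"sample_id": s.sample_ids, LPC_COL: s.lpc}).to_csv(
            lpc_path, index=False
        )


def smooth_sg(s: SpectraSet, window: int = 11, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay smoothing along the wavelength axis, per sample."""
    if window % 2 == 0:
        raise SpectraError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise SpectraError(f"polyorder {polyorder} must be < window {window}")
    if window > s.n_bands:
        raise SpectraError(f"window {window} exceeds band count {s.n_bands}")
    smoothed = savgol_filter(s.reflectance, window, polyorder, axis=1)
    # local polynomial fits can push slightly below zero at sharp valleys
    return s.with_reflectance(np.clip(smoothed, 0.0, None))


def trim_range(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Drop bands outside [lo, hi] nm."""
    if lo >= hi:
        raise SpectraError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise SpectraError(f"[{lo}, {hi}] nm does not intersect the grid")
    out = SpectraSet(
        wavelengths=s.wavelengths[mask],
        reflectance=s.reflectance[:, mask],
        lpc=None if s.lpc is None else s.lpc.copy(),
        sample_ids=list(s.sample_ids),
        metadata=dict(s.metadata),
    )
    return out


def summarize_lpc(s: SpectraSet) -> LpcSummary:
    """Descriptive statistics of the LPC vector (Table-style summary).

    The standard deviation uses the n-1 denominator; the coefficient of
    variation is 100*sd/mean.
    """
    if s.lpc is None:
        raise SpectraError("SpectraSet has no lpc vector")
    x = s.lpc
    if x.size < 2:
        raise SpectraError("need at least 2 samples to summarize")
    mean = float(np.mean(x))
    # a constant vector has sd exactly 0, not a floating-point residue
    sd = 0.0 if np.all(x == x[0]) else float(np.std(x, ddof=1))
    return LpcSummary(
        n=int(x.size),
        min=float(np.min(x)),
        max=float(np.max(x)),
        mean=mean,
        sd=sd,
        cv_percent=100.0 * sd / mean,
    )
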