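"""Core containers for hyperspectral leaf data.

The central object is :class:`SpectraSet`: a samples x bands reflectance
matrix on a strictly uniform 1 nm wavelength grid, optionally carrying a
per-sample leaf phosphorus content (LPC, mg per g dry mass) and free-form
per-sample metadata.  The 1 nm spacing is a hard invariant because the
fractional differencing downstream assumes a unit step between bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np


class SpectraError(ValueError):
    """Raised when a spectra container or operation violates its contract."""


@dataclass(frozen=True)
class LpcSummary:
    """Descriptive statistics of a leaf-phosphorus vector (mg/g).

    ``sd`` is the sample standard deviation (n-1 denominator) and
    ``cv_percent`` is the coefficient of variation, 100*sd/mean.
    """

    n: int
    min: float
    max: float
    mean: float
    sd: float
    cv_percent: float


@dataclass
class SpectraSet:
    """Reflectance spectra for a set of samples on a uniform 1 nm grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths in nm, spaced exactly 1 nm apart.
    reflectance
        ``(n_samples, n_bands)`` matrix of reflectance fractions in [0, 1].
    lpc
        Optional per-sample leaf phosphorus content, mg/g, all > 0.
    sample_ids
        Unique per-sample labels; defaults to ``s001, s002, ...``.
    metadata
        Free key -> per-sample sequence mapping (treatment, cultivar, ...).
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    lpc: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise SpectraError("need a 1-D wavelength axis with at least 2 bands")
        steps = np.diff(self.wavelengths)
        bad = np.nonzero(steps != 1.0)[0]
        if bad.size:
            i = int(bad[0])
            raise SpectraError(
                "wavelength grid must be uniform at 1 nm; first irregular step "
                f"{self.wavelengths[i]:g} -> {self.wavelengths[i + 1]:g} nm"
            )
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise SpectraError(
                f"reflectance has {self.reflectance.shape[1]} bands but the "
                f"wavelength axis has {self.wavelengths.size}"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise SpectraError("reflectance contains non-finite values")
        if np.any(self.reflectance < 0):
            raise SpectraError("reflectance contains negative values")
        n = self.reflectance.shape[0]
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1:03d}" for i in range(n)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise SpectraError("sample_ids length does not match sample count")
        if len(set(self.sample_ids)) != n:
            raise SpectraError("sample_ids must be unique")
        if self.lpc is not None:
            self.lpc = np.asarray(self.lpc, dtype=float)
            if self.lpc.shape != (n,):
                raise SpectraError("lpc must have one value per sample")
            if not np.all(np.isfinite(self.lpc)) or np.any(self.lpc <= 0):
                raise SpectraError("lpc values must be finite and > 0")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of an exact wavelength on the grid; raises if off-grid."""
        idx = np.searchsorted(self.wavelengths, wavelength_nm)
        if idx >= self.wavelengths.size or self.wavelengths[idx] != wavelength_nm:
            raise SpectraError(f"wavelength {wavelength_nm} nm is not on the grid")
        return int(idx)

    def with_reflectance(self, reflectance: np.ndarray) -> "SpectraSet":
        """Copy of this set with a replaced reflectance matrix."""
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            reflectance=np.asarray(reflectance, dtype=float),
            lpc=None if self.lpc is None else self.lpc.copy(),
            sample_ids=list(self.sample_ids),
            metadata=dict(self.metadata),
        )

    def copy(self) -> "SpectraSet":
        return self.with_reflectance(self.reflectance.copy())
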