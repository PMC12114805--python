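"""Synthetic green-leaf reflectance spectra with a phosphorus-linked signal.

Two generation modes:

``leaf_model``
    A phenomenological cotton-leaf spectrum on 325-1075 nm: a low visible
    baseline with blue (460 nm) and red (680 nm) absorption valleys and a
    green chlorophyll peak (540 nm), a logistic red edge near 715 nm, and a
    NIR plateau at 40-60 % reflectance with a water-absorption valley at
    960 nm.  The plateau amplitude rises linearly with leaf phosphorus
    content (LPC), emulating the observed monotone NIR response to
    phosphorus supply.

``planted``
    The leaf model with the NIR-LPC link switched off, plus a controlled
    perturbation at one wavelength so that the difference spectral index
    DSI(lambda_m, lambda_n) is an exact linear function of LPC before noise.
    Because the true optimal band pair is known by construction, this mode
    supports parameter-recovery tests of the exhaustive pair search.

Both modes are bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectraError, SpectraSet

GRID_LO = 325.0
GRID_HI = 1075.0

#: Fixed shape constants of the leaf model (reflectance fractions / nm).
LEAF_SHAPE = {
    "visible_baseline": 0.18,
    "blue_dip_center": 460.0, "blue_dip_depth": 0.06, "blue_dip_width": 25.0,
    "red_dip_center": 680.0, "red_dip_depth": 0.08, "red_dip_width": 18.0,
    "green_peak_center": 540.0, "green_peak_height": 0.07, "green_peak_width": 30.0,
    "red_edge_center": 715.0, "red_edge_width": 9.0,
    "nir_amplitude": 0.50, "nir_amplitude_bounds": (0.40, 0.60),
    "water_dip_center": 960.0, "water_dip_depth": 0.05, "water_dip_width": 22.0,
    "brightness_jitter": 0.02,
}


@dataclass
class SynthConfig:
    """Configuration of the synthetic spectra generator.

    Defaults mirror the study conditions: 60 samples, LPC uniform on
    [0.06, 0.12] mg/g, per-band Gaussian noise of 0.01 reflectance units.
    ``planted_slope`` of 4.0 index units per mg/g puts the planted DSI
    signal at a signal-to-noise ratio of about 5 at the default noise
    (signal sd 4.0 * 0.0173 vs DSI noise sd sqrt(2) * 0.01).
    """

    n_samples: int = 60
    lpc_range: tuple[float, float] = (0.06, 0.12)
    seed: int = 0
    mode: str = "leaf_model"
    noise_sd: float = 0.01
    nir_lpc_slope: float = 2.0
    planted_bands: tuple[float, float] = (850.0, 950.0)
    planted_slope: float = 4.0
    lpc_distribution: str = "uniform"
    lpc_mean: float = 0.090
    lpc_sd: float = 0.0146
    shape: dict = field(default_factory=lambda: dict(LEAF_SHAPE))

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise SpectraError("n_samples must be >= 2")
        lo, hi = self.lpc_range
        if not (0.0 < lo < hi < 1.0):
            raise SpectraError(f"lpc_range must satisfy 0 < lo < hi < 1, got {self.lpc_range}")
        if self.noise_sd < 0:
            raise SpectraError("noise_sd must be >= 0")
        if self.mode not in ("leaf_model", "planted"):
            raise SpectraError(f"unknown mode {self.mode!r}")
        if self.mode == "planted":
            m, n = self.planted_bands
            if m == n:
                raise SpectraError("planted bands must be distinct")
            for b in (m, n):
                if not (GRID_LO <= b <= GRID_HI and float(b).is_integer()):
                    raise SpectraError(f"planted band {b} nm is off the 1 nm grid")


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _draw_lpc(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.lpc_range
    if cfg.lpc_distribution == "uniform":
        return rng.uniform(lo, hi, size=cfg.n_samples)
    if cfg.lpc_distribution == "normal":
        # truncated normal via rejection; range is ~2 sd wide so this is cheap
        out = np.empty(cfg.n_samples)
        filled = 0
        while filled < cfg.n_samples:
            draw = rng.normal(cfg.lpc_mean, cfg.lpc_sd, size=cfg.n_samples)
            keep = draw[(draw >= lo) & (draw <= hi)][: cfg.n_samples - filled]
            out[filled:filled + keep.size] = keep
            filled += keep.size
        return out
    raise SpectraError(f"unknown lpc_distribution {cfg.lpc_distribution!r}")


def _base_spectra(cfg: SynthConfig, lpc: np.ndarray,
                  nir_lpc_slope: float) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free leaf spectra; returns (wavelengths, samples x bands)."""
    p = cfg.shape
    wl = np.arange(GRID_LO, GRID_HI + 1.0)
    visible = (
        p["visible_baseline"]
        - p["blue_dip_depth"] * _gauss(wl, p["blue_dip_center"], p["blue_dip_width"])
        - p["red_dip_depth"] * _gauss(wl, p["red_dip_center"], p["red_dip_width"])
        + p["green_peak_height"] * _gauss(wl, p["green_peak_center"], p["green_peak_width"])
    )
    edge = 1.0 / (1.0 + np.exp(-(wl - p["red_edge_center"]) / p["red_edge_width"]))
    lo_a, hi_a = p["nir_amplitude_bounds"]
    amplitude = np.clip(
        p["nir_amplitude"] + nir_lpc_slope * (lpc - lpc.mean()), lo_a, hi_a
    )
    plateau_shape = 1.0 - p["water_dip_depth"] / p["nir_amplitude"] * _gauss(
        wl, p["water_dip_center"], p["water_dip_width"]
    )
    spectra = (
        visible[None, :] * (1.0 - edge[None, :])
        + amplitude[:, None] * plateau_shape[None, :] * edge[None, :]
    )
    return wl, spectra


def _finalize(cfg: SynthConfig, wl: np.ndarray, spectra: np.ndarray,
              lpc: np.ndarray, rng: np.random.Generator) -> SpectraSet:
    # Brightness jitter mimics canopy-level illumination variation; it is a
    # leaf_model-only noise source and, like the additive noise, is off when
    # noise_sd = 0 so that noise-free runs are exactly deterministic.
    jitter = cfg.shape["brightness_jitter"]
    if jitter > 0 and cfg.noise_sd > 0 and cfg.mode == "leaf_model":
        spectra = spectra * rng.uniform(1 - jitter, 1 + jitter,
                                        size=(cfg.n_samples, 1))
    if cfg.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, cfg.noise_sd, size=spectra.shape)
    spectra = np.clip(spectra, 0.0, 1.0)
    return SpectraSet(wavelengths=wl, reflectance=spectra, lpc=lpc,
                      metadata={"mode": cfg.mode, "seed": cfg.seed})


def generate_leaf_model(cfg: SynthConfig) -> SpectraSet:
    """Generate leaf-model spectra with a phosphorus-linked NIR plateau."""
    if cfg.mode != "leaf_model":
        raise SpectraError("config mode must be 'leaf_model'")
    rng = np.random.default_rng(cfg.seed)
    lpc = _draw_lpc(cfg, rng)
    wl, spectra = _base_spectra(cfg, lpc, cfg.nir_lpc_slope)
    return _finalize(cfg, wl, spectra, lpc, rng)


def generate_planted(cfg: SynthConfig) -> SpectraSet:
    """Generate spectra whose optimal DSI band pair is known by construction.

    Starting from the leaf model with the NIR-LPC link off, the LPC signal
    ``delta_i = planted_slope * (lpc_i - mean lpc)`` is split across the two
    planted bands (+delta/2 at lambda_m, -delta/2 at lambda_n) so that,
    before noise, DSI(lambda_m, lambda_n) = delta_i + baseline exactly.
    Splitting the signal makes the pair identifiable: a pair sharing only
    one planted band carries half the signal.

    A smooth LPC-independent nuisance component — a per-sample random
    scalar times a parabola whose only zeros are the two planted bands — is
    added so that every other pair also carries variance uncorrelated with
    LPC.  The nuisance cancels exactly on the planted pair, which is
    therefore the strict r^2 optimum even in noise-free runs.
    """
    if cfg.mode != "planted":
        raise SpectraError("config mode must be 'planted'")
    rng = np.random.default_rng(cfg.seed)
    lpc = _draw_lpc(cfg, rng)
    wl, spectra = _base_spectra(cfg, lpc, nir_lpc_slope=0.0)
    bm, bn = cfg.planted_bands
    m_idx = int(np.searchsorted(wl, bm))
    n_idx = int(np.searchsorted(wl, bn))
    delta = cfg.planted_slope * (lpc - lpc.mean())
    spectra[:, m_idx] += 0.5 * delta
    spectra[:, n_idx] -= 0.5 * delta
    nuisance_shape = (wl - bm) * (wl - bn)
    nuisance_shape = nuisance_shape / np.max(np.abs(nuisance_shape))
    u = rng.normal(0.0, 0.005, size=cfg.n_samples)
    spectra = spectra + u[:, None] * nuisance_shape[None, :]
    return _finalize(cfg, wl, spectra, lpc, rng)


def generate(cfg: SynthConfig) -> SpectraSet:
    """Dispatch on ``cfg.mode``."""
    if cfg.mode == "leaf_model":
        return generate_leaf_model(cfg)
    return generate_planted(cfg)
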