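"""Random-forest estimation of leaf phosphorus from optimized indices.

Samples are split once (60 % calibration / 40 % validation by default,
seeded).  For each index family the feature vector of a sample is the
index value at the best band pair of each configured fractional order —
four features for the default order set {0, 1, best fractional, 2} — and a
random forest maps features to LPC.

Two R^2 conventions are reported.  The headline ``r2`` is the squared
Pearson correlation between predicted and observed per split, the common
convention in spectral chemometrics (it can make validation R^2 exceed
calibration R^2).  The residual-based coefficient of determination is kept
alongside as ``r2_residual``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .dataset import SpectraError
from .fod import FODResult
from .indices import IndexDefinition, PairScanResult, compute_index


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings: 500 trees, all features, unlimited depth."""

    n_trees: int = 500
    max_features: float | int | None = 1.0
    max_depth: int | None = None
    seed: int = 42


@dataclass
class SplitSpec:
    """A seeded calibration/validation partition by sample id."""

    n_total: int
    calibration_fraction: float
    seed: int
    calibration_ids: list[str]
    validation_ids: list[str]


@dataclass
class ModelReport:
    """Fit/validation summary for one index family (one table row)."""

    index_kind: str
    feature_defs: list[IndexDefinition]
    r2_cal: float
    r2_val: float
    rmse_cal: float
    rmse_val: float
    r2_residual_cal: float
    r2_residual_val: float
    predictions: pd.DataFrame
    rf_config: RFConfig = field(default_factory=RFConfig)


def make_split(n_total: int, fraction: float = 0.6, seed: int = 0,
               sample_ids: list[str] | None = None) -> SplitSpec:
    """Uniform random split with |calibration| = round(fraction * n)."""
    if not (0.0 < fraction < 1.0):
        raise SpectraError("fraction must be in (0, 1)")
    if n_total < 5:
        raise SpectraError("need at least 5 samples to split")
    n_cal = int(round(fraction * n_total))
    if n_cal == 0 or n_cal == n_total:
        raise SpectraError("split leaves one side empty")
    if sample_ids is None:
        sample_ids = [f"s{i + 1:03d}" for i in range(n_total)]
    if len(sample_ids) != n_total:
        raise SpectraError("sample_ids length must equal n_total")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_total)
    cal = sorted(perm[:n_cal])
    val = sorted(perm[n_cal:])
    return SplitSpec(n_total=n_total, calibration_fraction=fraction, seed=seed,
                     calibration_ids=[sample_ids[i] for i in cal],
                     validation_ids=[sample_ids[i] for i in val])


def build_features(fod_results: list[FODResult],
                   best_pairs: list[IndexDefinition] | list[PairScanResult],
                   kind: str) -> pd.DataFrame:
    """Samples x orders feature table for one index family.

    Column j holds the ``kind`` index at order j's optimal pair, evaluated
    on that order's differentiated matrix.  Columns follow the order of
    ``best_pairs`` (the configured order grid).
    """
    defs: list[IndexDefinition] = []
    for bp in best_pairs:
        d = bp.best if isinstance(bp, PairScanResult) else bp
        if d.kind != kind:
            raise SpectraError(f"pair for order {d.source_order} is {d.kind}, not {kind}")
        defs.append(d)
    by_order = {fr.order: fr for fr in fod_results}
    cols = {}
    for d in defs:
        fr = by_order.get(d.source_order)
        if fr is None:
            raise SpectraError(f"no FOD result for order {d.source_order}")
        wl = fr.wavelengths
        mi = int(np.searchsorted(wl, d.lambda_m))
        ni = int(np.searchsorted(wl, d.lambda_n))
        if wl[mi] != d.lambda_m or wl[ni] != d.lambda_n:
            raise SpectraError(f"pair ({d.lambda_m}, {d.lambda_n}) off the grid")
        cols[f"{kind}_v{d.source_order:g}"] = compute_index(
            fr.matrix[:, mi], fr.matrix[:, ni], kind
        )
    return pd.DataFrame(cols)


def _metrics(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float, float]:
    """(corr^2, residual R^2, RMSE)."""
    resid = observed - predicted
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r2_resid = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    if np.std(predicted) == 0 or np.std(observed) == 0:
        # a constant prediction equal to the observations is a perfect fit
        r2_corr = 1.0 if rmse == 0.0 else 0.0
    else:
        r2_corr = float(np.corrcoef(observed, predicted)[0, 1]) ** 2
    return r2_corr, r2_resid, rmse


def fit_and_evaluate(features: pd.DataFrame, lpc: np.ndarray, split: SplitSpec,
                     rf_config: RFConfig | None = None,
                     sample_ids: list[str] | None = None,
                     index_kind: str = "",
                     feature_defs: list[IndexDefinition] | None = None) -> ModelReport:
    """Train on calibration rows only; report both splits."""
    rf_config = rf_config or RFConfig()
    lpc = np.asarray(lpc, dtype=float)
    x = features.to_numpy(float)
    if np.isnan(x).any():
        raise SpectraError("feature table contains missing values")
    if np.std(lpc) == 0:
        raise SpectraError("constant LPC target")
    if sample_ids is None:
        sample_ids = [f"s{i + 1:03d}" for i in range(len(lpc))]
    id_to_row = {sid: i for i, sid in enumerate(sample_ids)}
    cal = np.array([id_to_row[s] for s in split.calibration_ids])
    val = np.array([id_to_row[s] for s in split.validation_ids])

    rf = RandomForestRegressor(
        n_estimators=rf_config.n_trees,
        max_features=rf_config.max_features,
        max_depth=rf_config.max_depth,
        random_state=rf_config.seed,
    )
    rf.fit(x[cal], lpc[cal])
    pred = np.empty(len(lpc))
    pred[cal] = rf.predict(x[cal])
    pred[val] = rf.predict(x[val])

    r2c, r2rc, rmsec = _metrics(lpc[cal], pred[cal])
    r2v, r2rv, rmsev = _metrics(lpc[val], pred[val])
    labels = np.array(["calibration"] * len(lpc), dtype=object)
    labels[val] = "validation"
    predictions = pd.DataFrame(
        {"sample_id": sample_ids, "split": labels,
         "observed_lpc": lpc, "predicted_lpc": pred}
    )
    return ModelReport(index_kind=index_kind, feature_defs=feature_defs or [],
                       r2_cal=r2c, r2_val=r2v, rmse_cal=rmsec, rmse_val=rmsev,
                       r2_residual_cal=r2rc, r2_residual_val=r2rv,
                       predictions=predictions, rf_config=rf_config)


def evaluate_predictions(observed: np.ndarray,
                         predicted: np.ndarray) -> tuple[float, float]:
    """(corr^2 R^2, RMSE) of an external prediction vector."""
    r2, _, rmse = _metrics(np.asarray(observed, float), np.asarray(predicted, float))
    return r2, rmse


def compare_models(reports: list[ModelReport]) -> pd.DataFrame:
    """Rank models by validation R^2 (desc), then validation RMSE (asc)."""
    if len(reports) < 2:
        raise SpectraError("need at least 2 reports to compare")
    df = pd.DataFrame(
        {
            "index_kind": [r.index_kind for r in reports],
            "r2_cal": [r.r2_cal for r in reports],
            "rmse_cal": [r.rmse_cal for r in reports],
            "r2_val": [r.r2_val for r in reports],
            "rmse_val": [r.rmse_val for r in reports],
        }
    )
    return df.sort_values(["r2_val", "rmse_val"],
                          ascending=[False, True]).reset_index(drop=True)
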