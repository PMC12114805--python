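"""End-to-end pipeline: ingest/simulate -> smooth -> FOD sweep -> screen ->
pair scan -> random-forest model -> report tables.

A single global seed fans out to per-stage derived seeds (simulation, split,
forest) so each stage is independently reproducible; reruns with the same
config produce byte-identical outputs for deterministic stages, verified by
the sha256 checksums recorded in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fod, indices, io, model, screening, synth
from .dataset import SpectraError, SpectraSet

log = logging.getLogger("specphos")

MODEL_INTEGER_ORDERS = (0.0, 1.0, 2.0)


def derive_seed(seed: int, stage: int) -> int:
    """Per-stage seed below 2^31, deterministic in (seed, stage)."""
    return (seed * 9973 + stage * 7919 + 1) % (2**31)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML via :meth:`from_yaml`."""

    spectra_path: str | None = None
    lpc_path: str | None = None
    reflectance_scale: str = "fraction"
    synth: synth.SynthConfig | None = None
    sg_window: int = 11
    sg_polyorder: int = 2
    trim: tuple[float, float] | None = None
    fod_orders: tuple[float, ...] = fod.DEFAULT_ORDERS
    index_kinds: tuple[str, ...] = indices.KINDS
    alpha: float = 0.01
    model_fractional_order: float | None = None  # None => derived from screening
    split_fraction: float = 0.6
    seed: int = 0
    rf_config: model.RFConfig = field(default_factory=model.RFConfig)
    write_fod_csv: bool = False
    write_grids: bool = False
    outdir: str = "specphos_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = synth.SynthConfig(**raw["synth"])
        if "rf_config" in raw and raw["rf_config"] is not None:
            raw["rf_config"] = model.RFConfig(**raw["rf_config"])
        for key in ("trim", "fod_orders", "index_kinds", "lpc_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _ingest(cfg: PipelineConfig) -> SpectraSet:
    if cfg.synth is not None:
        scfg = cfg.synth
        scfg.seed = derive_seed(cfg.seed, 0)
        return synth.generate(scfg)
    if cfg.spectra_path is None:
        raise SpectraError("config needs either a synth block or spectra_path")
    if cfg.lpc_path is None:
        raise SpectraError(f"no LPC file configured for {cfg.spectra_path}")
    return io.read_spectra(cfg.spectra_path, reflectance_scale=cfg.reflectance_scale,
                           lpc_path=cfg.lpc_path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage, write stage CSVs, return the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {"seed": cfg.seed, "outdir": str(outdir)},
                      "stages": {}, "files": {}, "status": "running"}
    t_all = time.time()
    log_handler = logging.FileHandler(outdir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(log_handler)

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"t_start": time.time()}

    def done(name, **info):
        st = manifest["stages"][name]
        st["seconds"] = round(time.time() - st.pop("t_start"), 3)
        st.update(info)

    def record(path: Path):
        manifest["files"][path.name] = _sha256(path)

    try:
        stage("ingest")
        s = _ingest(cfg)
        io.write_spectra(s, outdir / "spectra.csv", outdir / "lpc.csv")
        record(outdir / "spectra.csv")
        record(outdir / "lpc.csv")
        done("ingest", n_samples=s.n_samples, n_bands=s.n_bands)

        stage("preprocess")
        s = io.smooth_sg(s, cfg.sg_window, cfg.sg_polyorder)
        if cfg.trim is not None:
            s = io.trim_range(s, *cfg.trim)
        summary = io.summarize_lpc(s)
        pd.DataFrame([vars(summary)]).to_csv(outdir / "lpc_summary.csv", index=False)
        record(outdir / "lpc_summary.csv")
        done("preprocess", cv_percent=summary.cv_percent)

        stage("fod")
        fcfg = fod.FODConfig(orders=tuple(cfg.fod_orders))
        fod_results = fod.fod_sweep(s, fcfg)
        fod_entries = []
        for fr in fod_results:
            entry = {"order": fr.order}
            if cfg.write_fod_csv:
                path = outdir / f"fod_v{fr.order:g}.csv"
                df = pd.DataFrame(fr.matrix.T, columns=s.sample_ids)
                df.insert(0, io.WAVELENGTH_COL, fr.wavelengths)
                df.to_csv(path, index=False)
                record(path)
                entry["file"] = path.name
            fod_entries.append(entry)
        done("fod", outputs=fod_entries)

        stage("screen")
        rows = screening.screen_sweep(fod_results, s.lpc, cfg.alpha)
        screening.screen_table(rows).to_csv(outdir / "screen.csv", index=False)
        record(outdir / "screen.csv")
        if cfg.model_fractional_order is None:
            frac_order = screening.select_fractional_order(rows)
        else:
            frac_order = cfg.model_fractional_order
        model_orders = tuple(sorted({*MODEL_INTEGER_ORDERS, frac_order}))
        done("screen", n_rows=len(rows), fractional_order=frac_order)

        stage("scan")
        by_order = {fr.order: fr for fr in fod_results}
        missing = [v for v in model_orders if v not in by_order]
        if missing:
            raise SpectraError(f"model orders {missing} absent from the FOD sweep")
        scan_inputs = [by_order[v] for v in model_orders]
        scans = indices.scan_all(scan_inputs, s.lpc, tuple(cfg.index_kinds))
        best = indices.best_pairs_table(scans)
        best.to_csv(outdir / "best_pairs.csv", index=False)
        record(outdir / "best_pairs.csv")
        if cfg.write_grids:
            for r in scans:
                path = outdir / f"r2_grid_{r.kind}_v{r.source_order:g}.csv"
                pd.DataFrame(r.r2_grid, index=r.wavelengths,
                             columns=r.wavelengths).to_csv(path)
                record(path)
        done("scan", n_results=len(scans))

        stage("model")
        split = model.make_split(s.n_samples, cfg.split_fraction,
                                 derive_seed(cfg.seed, 1), s.sample_ids)
        rf_cfg = model.RFConfig(n_trees=cfg.rf_config.n_trees,
                                max_features=cfg.rf_config.max_features,
                                max_depth=cfg.rf_config.max_depth,
                                seed=derive_seed(cfg.seed, 2))
        reports = []
        all_pred = []
        for kind in cfg.index_kinds:
            kind_scans = [r for r in scans if r.kind == kind]
            feats = model.build_features(scan_inputs, kind_scans, kind)
            rep = model.fit_and_evaluate(feats, s.lpc, split, rf_cfg,
                                         s.sample_ids, index_kind=kind,
                                         feature_defs=[r.best for r in kind_scans])
            reports.append(rep)
            pred = rep.predictions.copy()
            pred.insert(0, "index_kind", kind)
            all_pred.append(pred)
        ranking = model.compare_models(reports) if len(reports) >= 2 else None
        report_df = pd.DataFrame(
            {
                "index_kind": [r.index_kind for r in reports],
                "variables": [
                    "; ".join(f"v{d.source_order:g}:({d.lambda_m:g},{d.lambda_n:g})"
                              for d in r.feature_defs)
                    for r in reports
                ],
                "r2_cal": [r.r2_cal for r in reports],
                "rmse_cal": [r.rmse_cal for r in reports],
                "r2_val": [r.r2_val for r in reports],
                "rmse_val": [r.rmse_val for r in reports],
            }
        )
        report_df.to_csv(outdir / "model_report.csv", index=False)
        record(outdir / "model_report.csv")
        pd.concat(all_pred, ignore_index=True).to_csv(
            outdir / "predictions.csv", index=False
        )
        record(outdir / "predictions.csv")
        if ranking is not None:
            ranking.to_csv(outdir / "model_ranking.csv", index=False)
            record(outdir / "model_ranking.csv")
        done("model", n_reports=len(reports))

        manifest["status"] = "completed"
    except Exception as err:
        manifest["status"] = "FAILED"
        manifest["error"] = f"{type(err).__name__}: {err}"
        failed_stage = next(
            (n for n, st in manifest["stages"].items() if "t_start" in st), "?"
        )
        for st in manifest["stages"].values():
            st.pop("t_start", None)
        manifest["failed_stage"] = failed_stage
        (outdir / "FAILED").write_text(f"{failed_stage}: {manifest['error']}\n")
        _write_manifest(manifest, outdir)
        raise SpectraError(
            f"pipeline failed at stage '{failed_stage}': {err}"
        ) from err
    finally:
        log.removeHandler(log_handler)
        log_handler.close()

    manifest["seconds_total"] = round(time.time() - t_all, 3)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def report_tables(manifest: dict) -> str:
    """Render the summary, screening and model CSVs as aligned text."""
    outdir = Path(manifest["config"]["outdir"])
    blocks = []
    warn = []
    for title, name in (
        ("LPC summary", "lpc_summary.csv"),
        ("Band screening (per order)", "screen.csv"),
        ("Model comparison", "model_report.csv"),
    ):
        path = outdir / name
        if path.exists():
            df = pd.read_csv(path)
            blocks.append(f"== {title} ==\n{df.to_string(index=False)}")
        else:
            warn.append(f"[warning] {name} missing — stage incomplete")
    if not blocks:
        raise SpectraError("no stage outputs found to report")
    return "\n\n".join(blocks + warn)
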