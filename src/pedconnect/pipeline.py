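"""Full-pipeline orchestration: quality → gating → F/Ne trends → connectedness.

Writes every stage's output as CSV into one output directory together with a
JSON run manifest echoing the configuration, so a run is reproducible from
its own outputs.  Floats are printed with 4 decimals (a ``full_precision``
switch keeps full precision in a sidecar).  All stages log to a module
logger; any stage failure leaves a FAILED marker in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import completeness_metrics as cm
from .connectedness import RecordsDesign, classify_connectedness, connectedness, read_records
from .effective_size import ne_trend
from .pedigree_core import Pedigree, PedigreeDialect, read_pedigree, validate, write_pedigree
from .relatedness import generation_interval, inbreeding_table

logger = logging.getLogger("pedconnect")

#: Bin layouts used by the printed distribution tables.
PCI_BIN_EDGES = np.arange(0.0, 1.2, 0.2)
F_BIN_EDGES = np.arange(0.0, 1.1, 0.1)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs; echoed into the manifest."""

    pedigree_path: str
    records_path: str | None = None
    out_dir: str = "pedconnect_out"
    pci_depth: int = cm.DEFAULT_PCI_DEPTH
    window_start: int | None = None
    window_end: int | None = None
    window_len: int = 4
    window_step: int = 1
    min_pci: float | None = None
    min_neg: float | None = None
    min_nfg: int | None = None
    h2: float = 0.3
    sigma_e2: float = 1.0
    full_precision: bool = False
    seed: int | None = None


def _write_csv(df: pd.DataFrame, path: Path, full_precision: bool) -> None:
    df.to_csv(path, index=False, float_format=None if full_precision else "%.4f")


def run_full_pipeline(cfg: RunConfig) -> Path:
    """Run every analysis stage, returning the output directory.

    Emits: normalised pedigree, validation summary, per-animal quality table
    with summary, PCI and F distribution tables, the sliding-window Ne table
    with its trend block, and (when records are given) the four
    connectedness matrices with summaries and cross-statistic correlations.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": {}, "status": "RUNNING"}
    try:
        _run_stages(cfg, out, manifest)
        manifest["status"] = "OK"
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _run_stages(cfg: RunConfig, out: Path, manifest: dict) -> None:
    fp = cfg.full_precision

    logger.info("reading pedigree from %s", cfg.pedigree_path)
    ped = read_pedigree(cfg.pedigree_path, PedigreeDialect())
    report = validate(ped)
    manifest["stages"]["validate"] = {
        "counts": report.counts,
        "n_errors": len(report.errors),
        "n_warnings": len(report.warnings),
    }
    if not report.ok:
        raise ValueError(f"pedigree failed validation with {len(report.errors)} errors")
    write_pedigree(ped, out / "pedigree_normalized.csv")

    logger.info("quality metrics for %d animals (PCI depth %d)", len(ped), cfg.pci_depth)
    quality = cm.quality_table(ped, cfg.pci_depth)
    _write_csv(quality, out / "quality.csv", fp)
    cm.summarize(ped, cfg.pci_depth).to_csv(out / "quality_summary.csv")
    _write_csv(
        cm.distribution_table(quality["PCI"], PCI_BIN_EDGES),
        out / "pci_distribution.csv", fp,
    )
    manifest["stages"]["quality"] = {"n_animals": len(ped)}

    logger.info("inbreeding and generation interval")
    ftab = inbreeding_table(ped)
    _write_csv(ftab, out / "inbreeding.csv", fp)
    _write_csv(
        cm.distribution_table(ftab["F"], F_BIN_EDGES), out / "f_distribution.csv", fp
    )
    try:
        gi = generation_interval(ped)
        manifest["stages"]["generation_interval"] = {"GI": gi.gi, "n": len(gi.mid_parent_ages)}
    except ValueError:
        manifest["stages"]["generation_interval"] = {"GI": None, "n": 0}

    years = ped.birth_year[ped.birth_year >= 0]
    if years.size and (cfg.window_start is not None or years.size > 0):
        start = cfg.window_start if cfg.window_start is not None else int(years.min())
        end = cfg.window_end if cfg.window_end is not None else int(years.max())
        logger.info("sliding-window Ne over %d-%d (len %d)", start, end, cfg.window_len)
        result = ne_trend(
            ped, start, end, cfg.window_len, cfg.window_step,
            min_pci=cfg.min_pci, min_neg=cfg.min_neg, min_nfg=cfg.min_nfg,
            pci_depth=cfg.pci_depth,
        )
        _write_csv(result.table, out / "ne_windows.csv", fp)
        trend_rows = []
        for name, t in (("delta_Ne", result.delta_ne), ("delta_F", result.delta_f)):
            if t is not None:
                trend_rows.append((name, t.slope, t.se, t.p_value, t.n))
        if trend_rows:
            _write_csv(
                pd.DataFrame(trend_rows, columns=["trend", "slope", "se", "p_value", "n_windows"]),
                out / "ne_trend.csv", fp,
            )
        manifest["stages"]["ne"] = {
            "n_windows": len(result.table),
            "window": [start, end, cfg.window_len, cfg.window_step],
            "gates": {"min_pci": cfg.min_pci, "min_neg": cfg.min_neg, "min_nfg": cfg.min_nfg},
        }

    if cfg.records_path is not None:
        logger.info("connectedness from records %s (h2=%.2f)", cfg.records_path, cfg.h2)
        design = read_records(cfg.records_path)
        result = connectedness(ped, design, h2=cfg.h2, sigma_e2=cfg.sigma_e2)
        for name, mat in result.matrices.items():
            mat.round(None if fp else 4).to_csv(out / f"connectedness_{name}.csv")
        summary = result.unit_means.copy()
        summary.insert(0, "n_recorded", result.n_per_unit)
        summary.to_csv(out / "connectedness_units.csv")
        result.cross_statistic_correlation().to_csv(out / "connectedness_correlations.csv")
        r_bar = float(result.overall_means["r"])
        overall = result.overall_means.to_frame("overall_mean")
        overall.to_csv(out / "connectedness_overall.csv")
        manifest["stages"]["connectedness"] = {
            "n_units": len(result.unit_labels),
            "n_records": len(design.animals),
            "overall": {k: float(v) for k, v in result.overall_means.items()},
            "r_benchmark": classify_connectedness(r_bar),
        }


def simulate_to_files(
    out_dir, preset: str = "flocks", seed: int = 0, **kwargs
) -> tuple[Path, Path | None]:
    """Generate a synthetic pedigree (and records, for the flock preset).

    Thin file-writing wrapper over the simulators so the CLI and pipeline
    can consume their output like any other data set.
    """
    from .synthetic_data import IdealizedConfig, SimConfig, simulate_flock_population, simulate_idealized

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped_path = out / "pedigree.csv"
    if preset == "flocks":
        ped, design = simulate_flock_population(SimConfig(seed=seed, **kwargs))
        write_pedigree(ped, ped_path)
        rec_path = out / "records.csv"
        pd.DataFrame({"animal_id": design.animals, "unit": design.units}).to_csv(
            rec_path, index=False
        )
        return ped_path, rec_path
    if preset == "idealized":
        ped = simulate_idealized(IdealizedConfig(seed=seed, **kwargs))
        write_pedigree(ped, ped_path)
        return ped_path, None
    raise ValueError(f"unknown preset {preset!r}")
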