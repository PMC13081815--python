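"""End-to-end orchestration from a single structured config.

A run executes preprocess -> svd -> scales on single-cell input (either read
from disk or simulated in-stage), plus optional epistasis and physiology
stages when their inputs are configured.  Every stage writes plain-text
outputs (TSV/JSON) with fixed numeric formatting, so reruns with the same
config and seed are byte-identical; a manifest records parameters, seeds,
stage outputs and versions.  Unknown config keys are rejected before any
computation.
"""

from __future__ import annotations

import json
import time
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import epistasis as ep
from . import io as aio
from . import physiology as phys
from . import scales as sc
from . import spectral as spec
from . import synthetic as syn

_SCHEMA = {
    "run": {"out_dir", "seed"},
    "input": {"counts", "format", "meta"},
    "simulate": {"n_genes", "cells_per_condition", "seed"},
    "preprocess": {"min_genes", "max_genes", "min_counts", "min_cells",
                   "target_sum"},
    "svd": {"components", "center"},
    "scales": {"variables", "width", "stride", "max_pc", "bins", "pairs",
               "null", "nperm"},
    "epistasis": {"counts", "design", "sets", "reference"},
    "physiology": {"trace", "growth", "competition"},
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    for section, keys in cfg.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(keys, dict):
            raise ConfigError(f"section {section!r} must be a table")
        unknown = set(keys) - _SCHEMA[section]
        if unknown:
            raise ConfigError(
                f"unknown key(s) in [{section}]: {sorted(unknown)}"
            )
    if "input" not in cfg and "simulate" not in cfg and "epistasis" not in cfg \
            and "physiology" not in cfg:
        raise ConfigError("config drives no stage: add [input], [simulate], "
                          "[epistasis] or [physiology]")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns the run manifest."""
    t0 = time.time()
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    run = config.get("run", {})
    out = Path(out_dir or run.get("out_dir", "adaptscales_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(run.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": [],
        "outputs": {},
    }

    norm = None
    if "simulate" in config or "input" in config:
        if "simulate" in config:
            s = config["simulate"]
            spec_obj = syn.SyntheticSpec(
                n_genes=int(s.get("n_genes", 1000)),
                cells_per_condition=int(s.get("cells_per_condition", 100)),
                seed=int(s.get("seed", seed)),
            )
            m, gt = syn.simulate_scrna(spec_obj)
            _write_json(out / "ground_truth.json", {
                "planted_depths": gt.planted_depths,
                "planted_ordering": gt.planted_ordering,
                "seed": spec_obj.seed,
            })
            manifest["stages"].append("simulate")
        else:
            i = config["input"]
            meta = aio.read_cell_meta(i["meta"]) if "meta" in i else None
            m = aio.read_counts(i["counts"], i.get("format", "mtx_dir"), meta)
            manifest["stages"].append("input")
        p = config.get("preprocess", {})
        thresholds = aio.QCThresholds(
            min_genes=int(p.get("min_genes", 200)),
            max_genes=int(p.get("max_genes", 4000)),
            min_counts=int(p.get("min_counts", 300)),
            min_cells_per_gene=int(p.get("min_cells", 10)),
        )
        norm, report = aio.preprocess(
            m, thresholds, float(p.get("target_sum", 10_000))
        )
        _write_json(out / "qc_report.json", report.to_dict())
        manifest["stages"].append("preprocess")
        manifest["outputs"]["qc_report"] = "qc_report.json"

    if norm is not None:
        v = config.get("svd", {})
        K = int(v.get("components", 30))
        K = min(K, min(norm.n_cells, norm.n_genes))
        d = spec.decompose(norm, K=K, center=bool(v.get("center", True)),
                           seed=seed)
        vs = spec.variance_spectrum(d)
        _write_tsv(out / "variance_fractions.tsv", pd.DataFrame({
            "component": np.arange(1, d.K + 1),
            "variance_fraction": vs.fractions,
            "cumulative": vs.cumulative,
        }).set_index("component"))
        top = []
        for k in range(1, d.K + 1):
            for rank, (g, w) in enumerate(spec.top_loadings(d, k, 25), 1):
                top.append({"component": k, "rank": rank, "gene": g,
                            "loading": w})
        _write_tsv(out / "top_loadings.tsv",
                   pd.DataFrame(top).set_index("component"))
        manifest["stages"].append("svd")
        manifest["outputs"]["variance_fractions"] = "variance_fractions.tsv"

        s = config.get("scales", {})
        variables = s.get("variables")
        if variables is None:
            variables = [c for c in norm.cell_meta.columns if c != "sample_id"]
        if variables:
            res = sc.run_scales(
                d, norm.cell_meta, list(variables),
                width=int(s.get("width", 3)),
                stride=int(s.get("stride", 1)),
                max_pc=int(s.get("max_pc", 30)),
                n_bins=int(s.get("bins", 16)),
                pair_budget=int(s.get("pairs", sc.DEFAULT_PAIR_BUDGET)),
                null_mode=s.get("null", "per_condition"),
                n_perm=int(s.get("nperm", 100)),
                seed=seed,
            )
            for var, prof in res.profiles.items():
                df = pd.DataFrame({
                    "window_start": [w.start for w in prof.windows],
                    "mi_bits": prof.mi,
                    "cumulative": prof.cumulative,
                    "cumulative_normalized": (
                        prof.cumulative_normalized
                        if prof.cumulative_normalized is not None
                        else np.full(len(prof.mi), np.nan)
                    ),
                    "null_mean": prof.null_mean,
                    "null_q95": prof.null_q95,
                }).set_index("window_start")
                _write_tsv(out / f"scales_{var}.tsv", df)
            _write_json(out / "hierarchy.json", {
                "depths": res.ranking.depths,
                "ordering": res.ranking.ordering,
                "ties": res.ranking.ties,
                "undefined": res.ranking.undefined,
            })
            manifest["stages"].append("scales")
            manifest["outputs"]["hierarchy"] = "hierarchy.json"

    if "epistasis" in config:
        e = config["epistasis"]
        bulk = aio.read_bulk(e["counts"], e["design"])
        table = ep.epistasis_table(
            ep.normalize_bulk(bulk),
            reference=e.get("reference", ep.REFERENCE),
        )
        sets = [aio.read_gene_set(p) for p in e.get("sets", [])]
        _write_tsv(out / "epistasis_table.tsv", table)
        _write_tsv(out / "epistasis_summary.tsv",
                   ep.epistasis_summary(table, sets))
        manifest["stages"].append("epistasis")
        manifest["outputs"]["epistasis_summary"] = "epistasis_summary.tsv"

    if "physiology" in config:
        p = config["physiology"]
        results = {}
        if "trace" in p:
            df = pd.read_csv(p["trace"], sep="\t")
            trace = phys.AbsorbanceTrace(df.iloc[:, 0], df.iloc[:, 1])
            regions = phys.detect_regions(trace)
            q = phys.pm_ratio(trace, regions)
            results["polysome"] = {
                "area_mono": q.area_mono, "area_poly": q.area_poly,
                "pm_ratio": q.pm_ratio,
            }
        if "growth" in p:
            df = pd.read_csv(p["growth"], sep="\t")
            curve = phys.GrowthCurve(df.iloc[:, 0], df.iloc[:, 1])
            gr = phys.max_growth_rate(curve)
            dia = phys.detect_diauxie(curve)
            results["growth"] = {
                "max_rate_per_h": gr.rate, "r_squared": gr.r_squared,
                "diauxic": dia.diauxic,
                "diauxie_criterion": "operational (see docs)",
            }
        if "competition" in p:
            df = pd.read_csv(p["competition"], sep="\t")
            series = phys.CompetitionSeries(
                df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]
            )
            fit = phys.competitive_fitness(series)
            results["fitness"] = {
                "selection_coefficient_per_day": fit.s,
                "r_squared": fit.r_squared,
            }
        _write_json(out / "physiology.json", results)
        manifest["stages"].append("physiology")
        manifest["outputs"]["physiology"] = "physiology.json"

    manifest["wall_clock_s"] = round(time.time() - t0, 3)
    _write_json(out / "manifest.json", manifest)
    return manifest
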