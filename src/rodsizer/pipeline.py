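"""End-to-end runs: simulate -> (render/quantify) -> analyze, from one config.

A run is described by a :class:`RunConfig` (usually loaded from YAML),
executes deterministically under its seed, writes every intermediate table
as CSV into the output directory, and finishes with a ``summary.json``
holding the headline numbers: per-strain homeostasis slopes, the
three-measure normalized-RMSD table, division-size CVs, the optimal
gamma, the alpha/beta exponents for model-generated nodal data, and the
division-geometry fits.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .divfit import DivisionGeometryModel
from .model import ModelParams, steady_state_nodal
from .scans import AlphaBetaScan, GammaScan
from .simulate import (
    DivisionRule,
    StrainConfig,
    records_frame,
    simulate_strains,
    strain_presets,
)
from .stats import binned_line, division_cv, homeostasis_points, normalized_rmsd

log = logging.getLogger("rodsizer")

__all__ = ["RunConfig", "run", "export_tables", "load_config"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int
    output_dir: Path
    strains: list[StrainConfig]
    n_cells: int = 500
    n_bins: int = 10
    min_per_bin: int = 5
    n_mc: int = 10_000
    model_params: ModelParams = field(default_factory=ModelParams)
    nodal_noise: float = 0.10
    stages: tuple[str, ...] = (
        "simulate",
        "homeostasis",
        "gamma-scan",
        "scaling-scan",
        "division-fit",
    )

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValueError("run config must list at least one strain")
        self.output_dir = Path(self.output_dir)


def _rule_from_dict(d: Mapping) -> DivisionRule:
    if d.get("kind") == "competing":
        members = tuple(_rule_from_dict(m) for m in d["members"])
        return DivisionRule(kind="competing", members=members)
    return DivisionRule(
        kind=d["kind"],
        threshold=float(d["threshold"]),
        gamma=d.get("gamma"),
        measure=d.get("measure", "length"),
    )


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    ``strains`` may be the literal string ``presets`` (thin/normal/fat
    family) or a list of explicit strain mappings; a shared
    ``division_rule`` mapping applies to all strains that do not override
    it.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    rule = _rule_from_dict(raw.get("division_rule", {"kind": "area", "threshold": 165.0}))
    strains_raw = raw.get("strains", "presets")
    shared = {
        k: raw[k]
        for k in ("threshold_cv", "division_asymmetry_cv", "radius_cv")
        if k in raw
    }
    if strains_raw == "presets":
        strains = list(strain_presets(rule, **shared).values())
    else:
        strains = []
        for s in strains_raw:
            s = dict(s)
            srule = _rule_from_dict(s.pop("division_rule")) if "division_rule" in s else rule
            strains.append(
                StrainConfig(division_rule=srule, **{**shared, **s})
            )
    mp = ModelParams(**raw.get("model", {}))
    return RunConfig(
        seed=int(raw["seed"]),
        output_dir=Path(raw.get("output_dir", "rodsizer-run")),
        strains=strains,
        n_cells=int(raw.get("n_cells", 500)),
        n_bins=int(raw.get("n_bins", 10)),
        min_per_bin=int(raw.get("min_per_bin", 5)),
        n_mc=int(raw.get("n_mc", 10_000)),
        model_params=mp,
        nodal_noise=float(raw.get("nodal_noise", 0.10)),
        stages=tuple(
            raw.get(
                "stages",
                ("simulate", "homeostasis", "gamma-scan", "scaling-scan", "division-fit"),
            )
        ),
    )


# ---------------------------------------------------------------------------
# stages


def _homeostasis_stage(records_by_strain, cfg: RunConfig) -> dict:
    out: dict = {"slopes": {}, "rmsd": {}, "division_cv": {}}
    for measure in ("length", "area", "volume"):
        lines, ranges = [], []
        for name, recs in records_by_strain.items():
            birth, delta = homeostasis_points(recs, measure)
            binned, line = binned_line(
                birth, delta, n_bins=cfg.n_bins, min_per_bin=cfg.min_per_bin
            )
            out["slopes"].setdefault(name, {})[measure] = round(line.slope, 6)
            lines.append(line)
            ranges.append(binned.x_range)
        if len(lines) == 3:
            try:
                out["rmsd"][measure] = round(
                    normalized_rmsd(lines, ranges).normalized_rmsd, 6
                )
            except ValueError:
                # strains may not share a birth-size range in every measure
                # (e.g. no length overlap under an area rule); record that
                out["rmsd"][measure] = None
    for name, recs in records_by_strain.items():
        out["division_cv"][name] = round(
            division_cv([r.A_div for r in recs]), 6
        )
    return out


def _scaling_stage(records_by_strain, cfg: RunConfig, rng: np.random.Generator) -> dict:
    """Alpha/beta scans on nodal quantities generated by both model limits."""
    R, L = [], []
    for recs in records_by_strain.values():
        for r in recs:
            R.append(r.R)
            # interphase length: uniform stage within the cycle
            L.append(r.L_birth + rng.uniform(0.0, 1.0) * (r.L_div - r.L_birth))
    R, L = np.array(R), np.array(L)
    sigma = math.sqrt(math.log(1.0 + cfg.nodal_noise**2))
    out = {}
    for mode in ("wt", "t166a"):
        # the model's own volume convention: cylinder approximation
        geoms = [(2.0 * math.pi * r * l, math.pi * r * r * l) for r, l in zip(R, L)]
        N = np.array(
            [steady_state_nodal(cfg.model_params, g, mode=mode) for g in geoms]
        )
        N = N * rng.lognormal(-0.5 * sigma * sigma, sigma, N.size)
        rho = N / (2.0 * math.pi * R * cfg.model_params.W)
        out[mode] = {
            "alpha_beta_total": AlphaBetaScan(R, L, N).fit().ratio,
            "alpha_beta_density": AlphaBetaScan(R, L, rho).fit().ratio,
        }
    return out


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    t_start = time.time()
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_cells": config.n_cells,
        "strains": [s.name for s in config.strains],
    }
    manifest: dict = {"output_dir": str(outdir), "tables": {}}

    log.info("simulating %d strains x %d cells", len(config.strains), config.n_cells)
    records_by_strain = simulate_strains(config.strains, config.n_cells, config.seed)
    all_records = [r for recs in records_by_strain.values() for r in recs]
    df = records_frame(all_records)
    path = outdir / "records.csv"
    df.to_csv(path, index=False)
    manifest["tables"]["records"] = str(path)

    if "homeostasis" in config.stages:
        t0 = time.time()
        summary["homeostasis"] = _homeostasis_stage(records_by_strain, config)
        log.info("homeostasis stage done in %.2fs", time.time() - t0)

    if "gamma-scan" in config.stages and len(records_by_strain) == 3:
        t0 = time.time()
        res = GammaScan(
            records_by_strain, n_bins=config.n_bins, min_per_bin=config.min_per_bin
        ).fit()
        summary["gamma_opt"] = res.gamma_opt
        np.savetxt(
            outdir / "gamma_scan.csv",
            np.column_stack([res.grid, res.objective]),
            delimiter=",",
            header="gamma,normalized_rmsd",
            comments="",
        )
        manifest["tables"]["gamma_scan"] = str(outdir / "gamma_scan.csv")
        log.info("gamma scan done in %.2fs (gamma_opt=%.2f)", time.time() - t0, res.gamma_opt)

    if "scaling-scan" in config.stages:
        t0 = time.time()
        summary["scaling"] = _scaling_stage(records_by_strain, config, rng)
        log.info("scaling scans done in %.2fs", time.time() - t0)

    if "division-fit" in config.stages:
        t0 = time.time()
        model = DivisionGeometryModel(
            all_records, n_bins=config.n_bins, min_per_bin=config.min_per_bin
        )
        fits = {}
        for kind in ("length", "area", "volume", "free", "crossover"):
            res = model.fit(kind)
            fits[kind] = {
                "params": {k: round(v, 6) for k, v in res.params.items()},
                "chi2": round(res.chi2, 4),
                "dof": res.dof,
                "p_value": res.p_value,
            }
        summary["division_geometry"] = fits
        log.info("division-geometry fits done in %.2fs", time.time() - t0)

    summary["runtime_s"] = round(time.time() - t_start, 3)
    # determinism: runtime excluded from the stable summary file
    stable = {k: v for k, v in summary.items() if k != "runtime_s"}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(stable, fh, indent=1, sort_keys=True, default=float)
    manifest["summary"] = str(outdir / "summary.json")
    manifest["runtime_s"] = summary["runtime_s"]
    return manifest


def export_tables(manifest: Mapping, fmt: str = "csv") -> list[Path]:
    """Re-export the run's tables as csv or json; returns written paths."""
    import pandas as pd

    if "tables" not in manifest:
        raise ValueError("manifest has no tables to export")
    written = []
    for name, path in manifest["tables"].items():
        src = Path(path)
        if not src.exists():
            log.warning("table %s missing (%s); skipping", name, src)
            continue
        df = pd.read_csv(src)
        if fmt == "csv":
            written.append(src)
        elif fmt == "json":
            dst = src.with_suffix(".json")
            df.to_json(dst, orient="records", indent=1)
            written.append(dst)
        else:
            raise ValueError(f"unknown export format: {fmt!r}")
    return written
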