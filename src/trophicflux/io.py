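"""Model readers/writers, analysis configuration, and the full pipeline.

A model lives in a directory of plain CSVs:

* ``groups.csv`` — id, name, type, biomass, pb, qb, ae
* ``diet.csv`` — square matrix, id header row and id index column;
  cell [i, j] is the diet fraction of prey i in predator j's diet
* ``landings.csv`` — group_id, fleet_id, rate (optional)
* ``pedigree.csv`` — target, cv (optional; targets address either a
  diet cell, ``diet:<prey_id>:<pred_id>``, or a group parameter,
  ``param:<group_id>:<biomass|pb|qb|ae>``)

Writers round-trip exactly: reading back a written model reproduces
every value bitwise.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import difference_network, harmonize_models
from .metrics import DEFAULT_EXCLUDE, adjacency, bootstrap_metrics, compute_network_metrics
from .model import (
    FoodWebError,
    FoodWebModel,
    FunctionalGroup,
    PARAM_NAMES,
    PedigreeCV,
    consumption_flux_matrix,
    validate_model,
)
from .temperature import TemperatureScenario, apply_temperature_scenario
from .tracing import footprint_reach
from .uncertainty import compare_ensembles, ensemble_metrics

logger = logging.getLogger("trophicflux")

__all__ = [
    "read_model",
    "write_model",
    "AnalysisConfig",
    "stage_seed",
    "run_pipeline",
]


def write_model(model: FoodWebModel, path: str | Path) -> None:
    """Write a model directory (groups/diet/landings/pedigree CSVs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in model.groups:
        rows.append(
            {
                "id": g.id,
                "name": g.name,
                "type": g.group_type,
                "biomass": g.biomass,
                "pb": g.pb,
                "qb": g.qb,
                "ae": g.ae,
            }
        )
    pd.DataFrame(rows).to_csv(path / "groups.csv", index=False, float_format="%.17g")

    ids = model.ids
    diet = pd.DataFrame(model.diet, index=ids, columns=ids)
    diet.index.name = "id"
    diet.to_csv(path / "diet.csv", float_format="%.17g")

    land_rows = []
    fleet_pos = np.flatnonzero(model.mask("fleet"))
    for f in fleet_pos:
        for i in range(model.n):
            if model.landings[i, f] > 0:
                land_rows.append(
                    {
                        "group_id": int(ids[i]),
                        "fleet_id": int(ids[f]),
                        "rate": model.landings[i, f],
                    }
                )
    pd.DataFrame(land_rows, columns=["group_id", "fleet_id", "rate"]).to_csv(
        path / "landings.csv", index=False, float_format="%.17g"
    )

    ped_rows = []
    ped = model.pedigree
    for i in range(model.n):
        for j in range(model.n):
            if ped.diet[i, j] > 0:
                ped_rows.append(
                    {"target": f"diet:{ids[i]}:{ids[j]}", "cv": ped.diet[i, j]}
                )
    for i in range(model.n):
        for k, pname in enumerate(PARAM_NAMES):
            if ped.params[i, k] > 0:
                ped_rows.append({"target": f"param:{ids[i]}:{pname}", "cv": ped.params[i, k]})
    pd.DataFrame(ped_rows, columns=["target", "cv"]).to_csv(
        path / "pedigree.csv", index=False, float_format="%.17g"
    )

    meta = {
        "currency": model.currency,
        "time_unit": model.time_unit,
        "provenance": model.provenance,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_model(path: str | Path, validate: bool = True) -> FoodWebModel:
    """Read a model directory written by :func:`write_model`.

    A missing ``pedigree.csv`` defaults every CV to zero (logged as a
    warning); a missing ``landings.csv`` defaults to no catches.
    """
    path = Path(path)
    gfile = path / "groups.csv"
    dfile = path / "diet.csv"
    if not gfile.exists():
        raise FoodWebError(f"missing groups.csv under {path}")
    if not dfile.exists():
        raise FoodWebError(f"missing diet.csv under {path}")

    gdf = pd.read_csv(gfile, float_precision="round_trip")
    required = {"id", "name", "type", "biomass", "pb", "qb", "ae"}
    if not required.issubset(gdf.columns):
        raise FoodWebError(
            f"groups.csv missing columns {sorted(required - set(gdf.columns))}"
        )
    if gdf["id"].duplicated().any():
        dupes = gdf.loc[gdf["id"].duplicated(), "id"].tolist()
        raise FoodWebError(f"duplicated group ids in groups.csv: {dupes}")
    groups = [
        FunctionalGroup(
            id=int(r.id),
            name=str(r.name),
            group_type=str(r.type),
            biomass=float(r.biomass),
            pb=float(r.pb),
            qb=float(r.qb),
            ae=float(r.ae),
        )
        for r in gdf.itertuples()
    ]
    ids = [g.id for g in groups]

    ddf = pd.read_csv(dfile, index_col=0, float_precision="round_trip")
    ddf.columns = [int(c) for c in ddf.columns]
    ddf.index = [int(i) for i in ddf.index]
    if list(ddf.index) != ids or list(ddf.columns) != ids:
        missing = (set(ids) ^ set(ddf.index)) | (set(ids) ^ set(ddf.columns))
        raise FoodWebError(
            f"diet.csv index/columns do not match group ids (mismatch: {sorted(missing)})"
        )
    diet = ddf.to_numpy(dtype=float)

    n = len(ids)
    pos = {gid: k for k, gid in enumerate(ids)}
    landings = np.zeros((n, n))
    lfile = path / "landings.csv"
    if lfile.exists():
        ldf = pd.read_csv(lfile, float_precision="round_trip")
        for r in ldf.itertuples():
            if int(r.group_id) not in pos or int(r.fleet_id) not in pos:
                raise FoodWebError(
                    f"landings.csv refers to unknown ids ({r.group_id}, {r.fleet_id})"
                )
            landings[pos[int(r.group_id)], pos[int(r.fleet_id)]] = float(r.rate)

    ped = PedigreeCV.zeros(n)
    pfile = path / "pedigree.csv"
    if pfile.exists():
        pdf = pd.read_csv(pfile, float_precision="round_trip")
        for r in pdf.itertuples():
            parts = str(r.target).split(":")
            if parts[0] == "diet" and len(parts) == 3:
                ped.diet[pos[int(parts[1])], pos[int(parts[2])]] = float(r.cv)
            elif parts[0] == "param" and len(parts) == 3:
                ped.params[pos[int(parts[1])], PARAM_NAMES.index(parts[2])] = float(r.cv)
            else:
                raise FoodWebError(f"unparseable pedigree target {r.target!r}")
    else:
        logger.warning("no pedigree.csv under %s; all CVs default to 0", path)

    currency, time_unit, provenance = "mt km^-2", "yr^-1", ""
    mfile = path / "meta.json"
    if mfile.exists():
        meta = json.loads(mfile.read_text())
        currency = meta.get("currency", currency)
        time_unit = meta.get("time_unit", time_unit)
        provenance = meta.get("provenance", provenance)

    model = FoodWebModel(
        groups=groups,
        diet=diet,
        landings=landings,
        pedigree=ped,
        currency=currency,
        time_unit=time_unit,
        provenance=provenance,
    )
    if validate:
        problems = validate_model(model)
        if problems:
            raise FoodWebError(
                f"model at {path} fails validation:\n  " + "\n  ".join(problems)
            )
    return model


# ---------------------------------------------------------------------------
# configuration and pipeline


@dataclass
class AnalysisConfig:
    """Configuration of the two-state comparison pipeline."""

    model_a: str
    model_b: str
    output_dir: str = "trophicflux_out"
    exclude_from_network: tuple[str, ...] = DEFAULT_EXCLUDE
    #: named focal sets: {label: [group name or id, ...]}
    focal_sets: dict = field(default_factory=dict)
    monte_carlo_n: int = 1000
    bootstrap_n: int = 100
    seed: int = 0
    mapping_csv: str | None = None
    temperature: dict | None = None  # {t_pre, t_post, q10, k}

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        cfg = cls(**data)
        if cfg.monte_carlo_n < 1 or cfg.bootstrap_n < 1:
            raise FoodWebError("monte_carlo_n and bootstrap_n must be >= 1")
        if cfg.seed < 0:
            raise FoodWebError("seed must be a non-negative integer")
        cfg.exclude_from_network = tuple(cfg.exclude_from_network)
        return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the top-level seed.

    Documented rule: SeedSequence(entropy=seed, spawn_key=(crc32(stage),))
    hashed down to one 31-bit integer, so every stage is independently
    reproducible from the run seed alone.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(stage.encode()),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _footprint_reach_metrics(model: FoodWebModel, focal_sets: dict) -> dict:
    out = {}
    for label, focal in focal_sets.items():
        r = footprint_reach(model, focal, validate=False)
        out[f"{label}:footprint"] = r.footprint
        out[f"{label}:reach"] = r.reach
    return out


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full comparison: metrics, footprint/reach Monte Carlo,
    bootstrap network comparison, difference network, temperature report.

    Deterministic given the config seed.  Writes CSV/JSON outputs under
    the configured output directory and returns them in memory.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise FoodWebError(f"pipeline stage {name!r} failed: {exc}") from exc

    model_a = _stage("read_model_a", lambda: read_model(config.model_a))
    model_b = _stage("read_model_b", lambda: read_model(config.model_b))

    mapping = None
    if config.mapping_csv:
        mapping = pd.read_csv(config.mapping_csv)
    model_a, model_b = _stage(
        "harmonize", lambda: harmonize_models(model_a, model_b, mapping)
    )

    # network metrics + bootstrap comparison
    def _metrics():
        rows = []
        for tag, m in (("a", model_a), ("b", model_b)):
            s = compute_network_metrics(m, config.exclude_from_network)
            row = s.to_frame()
            row.insert(0, "model", tag)
            rows.append(row)
        return pd.concat(rows, ignore_index=True)

    metrics_table = _stage("network_metrics", _metrics)
    results["metrics"] = metrics_table
    metrics_table.to_csv(out_dir / "metrics.csv", index=False)

    def _boot():
        frames = []
        for tag, m in (("a", model_a), ("b", model_b)):
            adj = adjacency(m, config.exclude_from_network)
            f = bootstrap_metrics(adj, config.bootstrap_n, stage_seed(config.seed, f"bootstrap_{tag}"))
            f.insert(0, "model", tag)
            frames.append(f)
        long = pd.concat(frames, ignore_index=True)
        wide_a = long[long["model"] == "a"].pivot(index="replicate", columns="metric", values="value")
        wide_b = long[long["model"] == "b"].pivot(index="replicate", columns="metric", values="value")
        tests = compare_ensembles(wide_a, wide_b)
        return long, tests

    boot_long, boot_tests = _stage("bootstrap", _boot)
    results["bootstrap"] = boot_long
    results["bootstrap_tests"] = boot_tests
    boot_long.to_csv(out_dir / "bootstrap.csv", index=False)
    boot_tests.to_csv(out_dir / "bootstrap_tests.csv", index=False)

    # footprint/reach Monte Carlo
    focal_sets = config.focal_sets or {
        g.name: [g.name] for g in model_a.groups if g.group_type == "living"
    }

    def _mc():
        fn = lambda m: _footprint_reach_metrics(m, focal_sets)  # noqa: E731
        ma = ensemble_metrics(
            model_a, config.monte_carlo_n, stage_seed(config.seed, "mc_a"), fn
        )
        mb = ensemble_metrics(
            model_b, config.monte_carlo_n, stage_seed(config.seed, "mc_b"), fn
        )
        tests = compare_ensembles(ma, mb)
        return ma, mb, tests

    mc_a, mc_b, mc_tests = _stage("monte_carlo", _mc)
    results["mc_a"], results["mc_b"] = mc_a, mc_b
    results["mc_tests"] = mc_tests
    mc_a.describe().T.to_csv(out_dir / "footprint_reach_a_summary.csv")
    mc_b.describe().T.to_csv(out_dir / "footprint_reach_b_summary.csv")
    mc_tests.to_csv(out_dir / "footprint_reach_tests.csv", index=False)

    base_fr = pd.DataFrame(
        {
            "model_a": _footprint_reach_metrics(model_a, focal_sets),
            "model_b": _footprint_reach_metrics(model_b, focal_sets),
        }
    )
    base_fr.index.name = "metric"
    results["footprint_reach"] = base_fr
    base_fr.to_csv(out_dir / "footprint_reach.csv")

    # difference network
    def _diff():
        fa = consumption_flux_matrix(model_a, validate=False)
        fb = consumption_flux_matrix(model_b, validate=False)
        return difference_network(fa, fb)

    diff = _stage("difference_network", _diff)
    results["difference"] = diff
    diff.node_frame().to_csv(out_dir / "difference_nodes.csv", index=False)
    diff.edge_frame().to_csv(out_dir / "difference_edges.csv", index=False)

    if config.temperature:
        t = config.temperature
        scen = TemperatureScenario(
            t_pre=t["t_pre"], t_post=t["t_post"],
            q10=t.get("q10", 2.0), k=t.get("k", 1.0),
        )
        _, temp_report = _stage(
            "temperature", lambda: apply_temperature_scenario(model_a, scen)
        )
        results["temperature"] = temp_report
        temp_report.to_csv(out_dir / "temperature_report.csv", index=False)

    log = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("bootstrap_a", "bootstrap_b", "mc_a", "mc_b")
        },
        "monte_carlo_n": config.monte_carlo_n,
        "bootstrap_n": config.bootstrap_n,
        "n_groups": int(model_a.n),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    results["log"] = log
    return results
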