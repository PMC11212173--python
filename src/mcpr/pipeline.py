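"""Config-driven orchestration of the full analysis.

Stages: simulate (records + geography) -> screen & code variables ->
descriptive tables and screening -> four-model random-intercept sequence
-> road-network accessibility -> Jenks district classification.  All
randomness flows from one master seed; outputs are deterministic CSV /
JSON / GeoJSON files plus a run log that keeps the sample-screening
accounting (interviewed - non-users - pregnant users = analytic n).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import access as acc
from . import coding, descriptives, geography, jenks, mlm, simulate
from .errors import ConfigurationError

log = logging.getLogger("mcpr")

__all__ = ["PipelineConfig", "run_pipeline", "INDIVIDUAL_TERMS", "COMMUNITY_TERMS"]

INDIVIDUAL_TERMS = [
    "age_group", "marital", "head_sex", "parity", "ever_terminated",
    "education", "media_exposure", "wanted_last", "wealth", "religion",
    "employed",
]
COMMUNITY_TERMS = [
    "residence_majority", "community_age", "community_ses",
    "community_media_fp", "community_education", "community_facility_access",
]


@dataclass
class PipelineConfig:
    """What to run and where to put it."""

    outdir: str = "mcpr_output"
    seed: int = 0
    records_path: str | None = None       # CSV of raw records; else simulate
    geography_path: str | None = None     # directory of GeoJSON layers; else simulate
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    run_spatial: bool = True
    run_model: bool = True
    screen_alpha: float = 0.05
    vif_max: float = 10.0
    n_quad: int = 7
    speeds: dict = field(default_factory=lambda: dict(acc.DEFAULT_SPEEDS))
    tolerance_km: float = 15.0
    breaks: tuple = acc.DEFAULT_BREAKS
    barriers: bool = True
    jenks_classes: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in _FIELD_NAMES})
        unknown = set(raw) - _FIELD_NAMES
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if sim_raw is not None:
            if cfg.records_path is not None:
                raise ConfigurationError(
                    "give either records_path or a simulation block, not both"
                )
            geo_raw = sim_raw.pop("geography", None)
            sim = simulate.SimulationConfig(**sim_raw)
            if geo_raw:
                sim = dataclasses.replace(sim, geography=simulate.GeographyConfig(**geo_raw))
            cfg.simulation = sim
        cfg.simulation = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        return cfg


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig)}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", na_rep="NA")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns a report bundle dict.

    Raises with the failing stage's name in the message; partial outputs
    written before the failure stay on disk for inspection.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": config.seed}
    logpath = out / "run_log.txt"
    handler = logging.FileHandler(logpath, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        stage = "simulate"
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        if config.records_path:
            records = pd.read_csv(config.records_path, na_values=["NA"])
        else:
            records = simulate.generate_population(sim)
            _write_csv(records, out / "records.csv")
        log.info("seed=%d n_interviewed=%d", config.seed, len(records))

        stage = "code"
        n_input = len(records)
        users = records[records["used_any_method"] == "yes"]
        analytic = coding.apply_sample_filter(records)
        accounting = {
            "n_input": int(n_input),
            "n_excluded_nonusers": int(n_input - len(users)),
            "n_excluded_pregnant": int(len(users) - len(analytic)),
            "n_analytic": int(len(analytic)),
        }
        assert (
            accounting["n_input"]
            - accounting["n_excluded_nonusers"]
            - accounting["n_excluded_pregnant"]
            == accounting["n_analytic"]
        )
        bundle["sample_accounting"] = accounting
        log.info("sample accounting: %s", accounting)
        coded = coding.code_records(analytic)
        summary = coding.aggregate_community(coded)
        coded = coding.attach_community(coded, summary)
        _write_csv(coded, out / "coded_records.csv")
        _write_csv(summary, out / "district_summary.csv")
        prevalence = 100.0 * coded["outcome_modern"].mean()
        bundle["prevalence_modern_pct"] = float(prevalence)
        log.info("modern prevalence %.2f%%", prevalence)

        stage = "describe"
        variables = [t for t in INDIVIDUAL_TERMS + COMMUNITY_TERMS]
        tabs = {v: descriptives.crosstab(coded, v) for v in variables}
        table1 = pd.concat(
            [t.to_frame().assign(variable=v) for v, t in tabs.items()]
        )
        _write_csv(table1, out / "table1.csv")
        kept, screen_log = descriptives.select_variables(
            tabs, coded, alpha=config.screen_alpha, vif_max=config.vif_max
        )
        bundle["screened_variables"] = kept
        for line in screen_log:
            log.info("screen: %s", line)
        with open(out / "table1.md", "w") as fh:
            fh.write(_table1_markdown(tabs, coded))

        if config.run_model:
            stage = "model"
            ind = [v for v in kept if v in INDIVIDUAL_TERMS]
            com = [v for v in kept if v in COMMUNITY_TERMS]
            fits, best = mlm.run_model_sequence(
                coded, ind, com, n_quad=config.n_quad
            )
            models = {}
            for m, fit in fits.items():
                if isinstance(fit, mlm.ModelFit):
                    d = fit.to_dict()
                    if fit.terms:
                        ame = mlm.average_marginal_effects(fit, coded)
                        _write_csv(ame, out / f"ame_model{m}.csv")
                        d["ame"] = ame.to_dict(orient="records")
                    models[m] = d
                    log.info(
                        "model %d: loglik=%.2f aic=%.2f icc=%.4f converged=%s",
                        m, fit.loglik, fit.aic, fit.icc, fit.converged,
                    )
                else:
                    models[m] = {"error": str(fit)}
                    log.warning("model %d failed: %s", m, fit)
            bundle["models"] = models
            bundle["best_model"] = best
            with open(out / "model_sequence.json", "w") as fh:
                json.dump(_jsonify(models), fh, indent=2, sort_keys=True)

        if config.run_spatial:
            stage = "access"
            if config.geography_path:
                layers = {
                    name: json.load(open(Path(config.geography_path) / f"{name}.geojson"))
                    for name in ("roads", "facilities", "lakes", "districts")
                }
                geo = geography.geography_from_geojson(layers)
            else:
                geo = geography.generate_geography(sim)
                for name, col in geography.geography_to_geojson(geo).items():
                    geography.write_geojson(col, out / f"{name}.geojson")
            graph = acc.build_graph(geo.roads, speeds=config.speeds)
            if config.barriers:
                graph = acc.apply_barriers(graph, geo.lakes)
            graph = acc.snap_facilities(graph, geo.facilities, config.tolerance_km)
            log.info(
                "facilities located=%d unlocated=%d edges_removed=%d",
                len(graph.graph["facilities"]),
                len(graph.graph["unlocated_facilities"]),
                len(graph.graph["removed_edges"]),
            )
            surface = acc.travel_time_surface(graph, config.breaks)
            centroids = pd.DataFrame(
                {
                    "district_id": [did for did, _ in geo.districts],
                    "x": [poly.centroid.x for _, poly in geo.districts],
                    "y": [poly.centroid.y for _, poly in geo.districts],
                }
            )
            weights = coded.groupby("district_id").size().rename("n_women").reset_index()
            demand = centroids.merge(weights, on="district_id", how="left").fillna(
                {"n_women": 0.0}
            )
            demand = demand[demand["n_women"] > 0]
            report = acc.district_access_report(surface, graph, demand)
            _write_csv(report, out / "district_access.csv")
            bundle["access"] = {
                "n_located": len(graph.graph["facilities"]),
                "n_unlocated": len(graph.graph["unlocated_facilities"]),
                "median_minutes_overall": float(report["median_minutes"].median()),
                "n_flagged_over_240": int(report["flag_over_240"].sum()),
            }

            stage = "classify"
            values = summary.set_index("district_id")["share_national_modern"]
            jres = jenks.classify_districts(values, k=config.jenks_classes)
            cls_df = pd.DataFrame(
                {
                    "district_id": list(jres.assignments),
                    "value": [values.get(d, np.nan) for d in jres.assignments],
                    "class": list(jres.assignments.values()),
                }
            ).sort_values("district_id")
            _write_csv(cls_df, out / "district_classes.csv")
            bundle["jenks"] = {
                "breaks": jres.breaks,
                "gvf": jres.gvf,
                "n_no_data": jres.n_no_data,
                "top_class_upper_bound": jres.breaks[-1] if jres.breaks else None,
            }
        bundle["status"] = "ok"
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonify(bundle), fh, indent=2, sort_keys=True)
    return bundle


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    return obj


def _table1_markdown(tabs, coded) -> str:
    lines = [
        "# Background characteristics and contraceptive use",
        "",
        "| Variable | Category | n (%) | Traditional (%) | Modern (%) | chi-square p |",
        "|---|---|---|---|---|---|",
    ]
    for var, t in tabs.items():
        for i, cat in enumerate(t.categories):
            p = f"{t.p_value:.3f}" if i == 0 and np.isfinite(t.p_value) else ""
            lines.append(
                f"| {var if i == 0 else ''} | {cat} | {t.counts[i]} "
                f"({t.pct_total[i]:.1f}) | {t.traditional_pct[i]:.1f} | "
                f"{t.modern_pct[i]:.1f} | {p} |"
            )
    n = int(coded["outcome_modern"].notna().sum())
    modern = 100.0 * coded["outcome_modern"].mean()
    lines += ["", f"Total n = {n}; modern {modern:.1f}%, traditional {100 - modern:.1f}%."]
    return "\n".join(lines) + "\n"
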