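"""End-to-end orchestration: simulate -> index -> features -> fit -> networks -> report.

A single YAML run configuration drives all stages; every stage writes its
outputs under the run directory and the manifest records parameters and
content digests so a re-run with the same configuration and seeds is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import codemap as cm
from . import features as ft
from . import index as ix
from . import models as md
from . import networks as nw
from . import report as rp
from . import simulate as sim

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

DEFAULT_STAGES = ("simulate", "index", "features", "fit", "networks", "report")


class PipelineError(RuntimeError):
    pass


class RunConfig:
    """Validated run configuration with per-stage sections."""

    def __init__(self, raw: dict, out_dir):
        self.raw = dict(raw)
        self.out_dir = Path(out_dir)
        self.stages = list(raw.get("stages", DEFAULT_STAGES))
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        self.seed = int(raw.get("seed", 0))
        self.n_patients = int(raw.get("n_patients", 2000))
        self.start_date = pd.Timestamp(raw.get("start_date", "2013-01-01")).date()
        self.end_date = pd.Timestamp(raw.get("end_date", "2022-12-31")).date()
        self.fit = dict(raw.get("fit", {}))
        self.networks = dict(raw.get("networks", {}))

    @property
    def grid_dates(self):
        years = range(self.start_date.year, self.end_date.year + 1)
        return [pd.Timestamp(y, 1, 1) for y in years]


def load_run_config(path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    out_dir = raw.get("out_dir", path.parent / "run")
    return RunConfig(raw, out_dir)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": config.raw, "stages": {}, "digests": {}}

    def _require(path: Path, needed_by: str, producer: str):
        if not path.exists():
            raise PipelineError(
                f"stage {needed_by!r} needs {path.name}; run stage {producer!r} first"
            )

    scfg = sim.default_config(n_patients=config.n_patients, seed=config.seed)
    codemap = sim.codemap_from_config(scfg)
    weights = sim.weights_from_config(scfg)

    if "simulate" in config.stages:
        patients, events = sim.generate_cohort(scfg)
        sim.write_cohort(patients, events, out)
        cm.write_codemap(codemap, out / "codemap.csv")
        cm.write_weights(weights, out / "weights.csv")
        manifest["stages"]["simulate"] = {
            "n_patients": len(patients),
            "n_events": len(events),
        }

    if "index" in config.stages:
        _require(out / "events.csv", "index", "simulate")
        patients, events = sim.read_cohort(out)
        codemap = cm.load_codemap(out / "codemap.csv")
        weights = cm.load_weights(out / "weights.csv")
        mapped, n_dropped = cm.map_events(events, codemap)
        kept, rejections = ix.validate_diagnoses(
            mapped, patients, _default_rules(), period=None
        )
        table = ix.cohort_index_table(patients, kept, weights, config.grid_dates)
        end_grid = config.grid_dates[-1]
        ref = table.loc[table["date"] == end_grid, "index"]
        thresholds = ix.compute_thresholds(ref)
        table["stratum"] = ix.stratify_values(table["index"].values, thresholds)
        table.assign(date=table["date"].dt.strftime("%Y-%m-%d")).to_csv(
            out / "index_series.csv", index=False
        )
        (out / "thresholds.json").write_text(
            json.dumps({"p50": thresholds.p50, "p80": thresholds.p80, "p95": thresholds.p95})
        )
        summary = ft.descriptive_summary(
            patients, kept, weights, thresholds, config.grid_dates[0], end_grid
        )
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        manifest["stages"]["index"] = {
            "n_rows": len(table),
            "n_unmapped_dropped": n_dropped,
            "n_rejected": len(rejections),
        }

    if "features" in config.stages:
        _require(out / "index_series.csv", "features", "index")
        patients, events = sim.read_cohort(out)
        codemap = cm.load_codemap(out / "codemap.csv")
        weights = cm.load_weights(out / "weights.csv")
        mapped, _ = cm.map_events(events, codemap)
        table = pd.read_csv(out / "index_series.csv", parse_dates=["date"])
        th = json.loads((out / "thresholds.json").read_text())
        thresholds = ix.StratumThresholds(th["p50"], th["p80"], th["p95"])
        outcomes = ft.transition_outcomes(table, thresholds, patients, config.grid_dates[-1])
        outcomes.to_csv(out / "outcomes.csv", index=False)
        feats = ft.build_feature_table(
            patients, mapped, weights, config.grid_dates[0], spec="full_disease"
        )
        feats.to_csv(out / "features.csv", index=False)
        ms = ft.multistate_tabulation(table, thresholds, patients, config.grid_dates)
        ms.assign(date=ms["date"].dt.strftime("%Y-%m-%d")).to_csv(
            out / "multistate.csv", index=False
        )
        manifest["stages"]["features"] = {
            "n_eligible": int(outcomes["eligible"].sum()),
            "n_events_among_eligible": int(
                outcomes.loc[outcomes["eligible"], "event"].sum()
            ),
        }

    if "fit" in config.stages:
        _require(out / "features.csv", "fit", "features")
        feats = pd.read_csv(out / "features.csv")
        outcomes = pd.read_csv(out / "outcomes.csv")
        rows = feats.merge(
            outcomes.loc[outcomes["eligible"], ["patient_id", "event"]],
            on="patient_id",
        )
        rows["event"] = rows["event"].astype(int)
        specs = config.fit.get("specs", ["base", "complexity"])
        learners = config.fit.get("learners", ["glm", "xgboost"])
        cv_repeats = int(config.fit.get("cv_repeats", 3))
        results = {}
        for spec_name in specs:
            cols = _spec_columns(rows, spec_name)
            spec_rows = rows[cols + ["patient_id", "event"]]
            train, test = md.split_cohort(spec_rows, seed=config.seed)
            for learner in learners:
                mspec = md.ModelSpec(spec_name, learner, seed=config.seed, cv_repeats=cv_repeats)
                fitted = md.fit_and_tune(mspec, train)
                results[(spec_name, learner)] = md.evaluate(
                    fitted, test, compute_importance=False
                )
        metrics = md.compare_specs(results)
        metrics.to_csv(out / "metrics.csv", index=False)
        manifest["stages"]["fit"] = {"n_models": len(results)}

    if "networks" in config.stages:
        _require(out / "events.csv", "networks", "simulate")
        patients, events = sim.read_cohort(out)
        codemap = cm.load_codemap(out / "codemap.csv")
        mapped, _ = cm.map_events(events, codemap)
        onsets = nw.chronic_onsets(mapped)
        n_total = len(patients)
        stats = nw.compute_pair_stats(onsets, n_total)
        fcfg = nw.FilterConfig(
            alpha=float(config.networks.get("alpha", 0.05)),
            min_n=int(config.networks.get("min_n", 50)),
        )
        retained, meta = nw.apply_filters(stats, fcfg)
        transitions = None
        if (out / "outcomes.csv").exists():
            transitions = pd.read_csv(out / "outcomes.csv", parse_dates=["transition_date"])
        stats.to_csv(out / "pairs.csv", index=False)
        nw.pair_frequency_table(stats, n_total).to_csv(out / "pairs_top.csv", index=False)
        nw.triad_frequency_table(onsets, n_total).to_csv(out / "triads_top.csv", index=False)
        net = nw.build_general_network(retained, onsets, n_total, transitions)
        net.write_graphml(out / "general_network.graphml")
        (out / "general_network.json").write_text(json.dumps(net.to_json_dict(), indent=1))
        centrals = config.networks.get("centrals", [])
        for central in centrals:
            sub = nw.build_disease_centred(central, retained, onsets, n_total, transitions)
            sub.write_graphml(out / f"network_{central}.graphml")
        manifest["stages"]["networks"] = {
            "m_pairs": meta["m"],
            "n_retained": len(retained),
            "bonferroni_threshold": meta["threshold"],
        }

    if "report" in config.stages:
        _require(out / "summary.json", "report", "index")
        text = rp.render_report(out)
        (out / "report.txt").write_text(text)
        manifest["stages"]["report"] = {"n_chars": len(text)}

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["digests"][path.name] = _digest(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _default_rules() -> "ix.ValidationRules":
    """Plausibility rules for the default synthetic roster: pregnancy-related
    diagnoses are valid only for women aged 14-55."""
    return ix.ValidationRules(
        {"PREG": ix.GroupRule(min_age=14, max_age=55, allowed_sex="F")}
    )


def _spec_columns(rows: pd.DataFrame, spec_name: str) -> list[str]:
    base = ["age", "is_female"]
    if spec_name == "base":
        return base
    complexity = base + list(ft.COMPLEXITY_FEATURES)
    if spec_name == "complexity":
        return complexity
    return complexity + [c for c in rows.columns if c.startswith("has_")]
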