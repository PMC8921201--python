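"""End-to-end orchestration of the analysis stages with a run manifest.

Stages communicate through files in a single output directory:

    responses.csv, participants.csv, simulation_config.yaml   (simulate / input)
    clean_phases.csv                                          (preprocess)
    trial_stats.csv, participant_stats.csv, group_stats.csv,
    group_ttests.csv                                          (describe)
    distribution_fits.csv, fit_curves.csv                     (phasefit)
    transitions_<group>_<paradigm>.csv, weights_...,
    counts_..., chain_<group>_<paradigm>.graphml/.dot,
    chi_square.csv, kl_divergence.csv                         (markov)
    weighted_<group>_<paradigm>.csv, ratio_<paradigm>.csv,
    ratio_<paradigm>_long.csv, table_comparison.json          (compare)
    trait_correlations.csv                                    (correlate)
    report.json                                               (report)

Every stage appends an entry (record counts, warnings) to manifest.json so
each numeric output is traceable to a config snapshot and seed.
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

from . import __version__, compare, markov, phasedist, records, simulate, stats

log = logging.getLogger(__name__)


class MissingPrerequisite(RuntimeError):
    """A stage input file is absent; the message names the stage to run first."""


@dataclass
class PipelineConfig:
    """Run-wide settings; defaults reproduce the standard analysis choices
    (180 ms cutoff, participant-weighted aggregation, subject x condition
    normalization, 12-value / 10,000-replicate bootstrap null)."""

    out_dir: Path = Path("rivaldyn_out")
    seed: int = 0
    responses: Path | None = None  # external input; otherwise run `simulate`
    metadata: Path | None = None
    short_response_cutoff_s: float = records.SHORT_RESPONSE_CUTOFF_S
    strict: bool = False
    per_condition: bool = False
    normalize_by: str = "participant_condition"
    n_boot: int = 10_000
    n_null_values: int = 12
    group_a: str = "autism"
    group_b: str = "control"
    simulation: simulate.SimulationConfig | None = None

    def to_dict(self) -> dict:
        d = {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "responses": str(self.responses) if self.responses else None,
            "metadata": str(self.metadata) if self.metadata else None,
            "short_response_cutoff_s": self.short_response_cutoff_s,
            "strict": self.strict,
            "per_condition": self.per_condition,
            "normalize_by": self.normalize_by,
            "n_boot": self.n_boot,
            "n_null_values": self.n_null_values,
            "group_a": self.group_a,
            "group_b": self.group_b,
        }
        if self.simulation is not None:
            d["simulation"] = simulate.config_to_dict(self.simulation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = d.get("simulation")
        return cls(
            out_dir=Path(d.get("out_dir", "rivaldyn_out")),
            seed=int(d.get("seed", 0)),
            responses=Path(d["responses"]) if d.get("responses") else None,
            metadata=Path(d["metadata"]) if d.get("metadata") else None,
            short_response_cutoff_s=float(
                d.get("short_response_cutoff_s", records.SHORT_RESPONSE_CUTOFF_S)
            ),
            strict=bool(d.get("strict", False)),
            per_condition=bool(d.get("per_condition", False)),
            normalize_by=str(d.get("normalize_by", "participant_condition")),
            n_boot=int(d.get("n_boot", 10_000)),
            n_null_values=int(d.get("n_null_values", 12)),
            group_a=str(d.get("group_a", "autism")),
            group_b=str(d.get("group_b", "control")),
            simulation=simulate.config_from_dict(sim) if sim else None,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _manifest_path(cfg: PipelineConfig) -> Path:
    return Path(cfg.out_dir) / "manifest.json"


def _record_stage(cfg: PipelineConfig, stage: str, entry: dict) -> None:
    path = _manifest_path(cfg)
    manifest = {"version": __version__, "config": cfg.to_dict(), "stages": {}}
    if path.exists():
        manifest = json.loads(path.read_text())
        manifest["version"] = __version__
        manifest["config"] = cfg.to_dict()
    manifest["stages"][stage] = entry
    path.write_text(json.dumps(manifest, indent=2) + "\n")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingPrerequisite(
            f"{path} not found: run the `{producer}` stage first (or point the "
            f"config at existing input files)"
        )
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.simulation or simulate.study_config(cfg.seed)
    sim_cfg = dataclasses.replace(sim_cfg, seed=cfg.seed)
    resp, meta, sidecar = simulate.write_cohort(sim_cfg, out)
    n_rows = sum(1 for _ in open(resp)) - 1
    entry = {"responses": resp.name, "metadata": meta.name, "config": sidecar.name,
             "n_response_rows": n_rows, "seed": cfg.seed}
    _record_stage(cfg, "simulate", entry)
    return entry


def _responses_path(cfg: PipelineConfig) -> Path:
    if cfg.responses is not None:
        return _require(Path(cfg.responses), "simulate")
    return _require(Path(cfg.out_dir) / "responses.csv", "simulate")


def _metadata_path(cfg: PipelineConfig) -> Path:
    if cfg.metadata is not None:
        return _require(Path(cfg.metadata), "simulate")
    return _require(Path(cfg.out_dir) / "participants.csv", "simulate")


def stage_preprocess(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = records.read_responses(_responses_path(cfg), strict=cfg.strict)
    cleans = records.preprocess_trials(trials, cutoff_s=cfg.short_response_cutoff_s)
    n_empty = sum(c.is_empty for c in cleans)
    records.write_clean_trials([c for c in cleans if not c.is_empty],
                               out / "clean_phases.csv")
    entry = {
        "n_trials": len(trials),
        "n_clean_trials": len(cleans) - n_empty,
        "n_empty_trials": n_empty,
        "n_raw_responses": sum(len(t.responses) for t in trials),
        "n_clean_phases": sum(c.n_phases for c in cleans),
        "cutoff_s": cfg.short_response_cutoff_s,
    }
    _record_stage(cfg, "preprocess", entry)
    return entry


def _load_cleans(cfg: PipelineConfig):
    path = _require(Path(cfg.out_dir) / "clean_phases.csv", "preprocess")
    return records.read_clean_trials(path)


def stage_describe(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    cleans = _load_cleans(cfg)
    trial_df = stats.trial_summary_table(cleans)
    part_df = stats.participant_summary(trial_df, per_condition=cfg.per_condition)
    group_df = stats.group_summary(part_df, per_condition=cfg.per_condition)
    tt = stats.group_comparison_table(part_df, cfg.group_a, cfg.group_b)
    trial_df.to_csv(out / "trial_stats.csv", index=False)
    part_df.to_csv(out / "participant_stats.csv", index=False)
    group_df.to_csv(out / "group_stats.csv", index=False)
    tt.to_csv(out / "group_ttests.csv", index=False)
    entry = {"n_trials": len(trial_df), "n_participants": part_df["participant_id"].nunique(),
             "n_tests": len(tt)}
    _record_stage(cfg, "describe", entry)
    return entry


def stage_phasefit(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    cleans = _load_cleans(cfg)
    fits = phasedist.fit_summary_table(cleans, by=cfg.normalize_by)
    fits.to_csv(out / "distribution_fits.csv", index=False)
    if not fits.empty:
        phasedist.curve_points_table(fits).to_csv(out / "fit_curves.csv", index=False)
    entry = {"n_fits": len(fits)}
    _record_stage(cfg, "phasefit", entry)
    return entry


def stage_markov(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    cleans = _load_cleans(cfg)
    aggregates = markov.group_paradigm_aggregates(cleans)
    chi_rows = []
    for (group, paradigm), agg in sorted(aggregates.items()):
        tag = f"{group}_{paradigm}"
        markov.write_matrix(agg["probabilities"], out / f"transitions_{tag}.csv")
        markov.write_matrix(agg["weights"], out / f"weights_{tag}.csv")
        markov.write_matrix(agg["counts"], out / f"counts_{tag}.csv")
        g = markov.build_chain_graph(
            group, paradigm, agg["probabilities"], agg["weights"],
            agg["state_means"], agg["chi_square"],
        )
        markov.write_graphml(g, out / f"chain_{tag}.graphml")
        markov.write_dot(g, out / f"chain_{tag}.dot")
        for s, stat, p in agg["chi_square"]:
            chi_rows.append({"group": group, "paradigm": paradigm, "state": s,
                             "chi_square": stat, "p": p, "df": 2})
    pd.DataFrame(chi_rows).to_csv(out / "chi_square.csv", index=False)
    kl = markov.kl_table(aggregates, cfg.group_a, cfg.group_b)
    kl.to_csv(out / "kl_divergence.csv", index=False)
    entry = {"n_group_paradigm_cells": len(aggregates), "n_kl_rows": len(kl)}
    _record_stage(cfg, "markov", entry)
    return entry


def stage_compare(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    paradigms = sorted(
        {p.name.split("_")[-1].split(".")[0] for p in out.glob("transitions_*.csv")}
    )
    if not paradigms:
        raise MissingPrerequisite(
            f"no transitions_*.csv in {out}: run the `markov` stage first"
        )
    tables = {}
    for par in paradigms:
        mats = {}
        for grp in (cfg.group_a, cfg.group_b):
            p_path = _require(out / f"transitions_{grp}_{par}.csv", "markov")
            w_path = _require(out / f"weights_{grp}_{par}.csv", "markov")
            wm = compare.weighted_matrix(markov.read_matrix(p_path),
                                         markov.read_matrix(w_path))
            markov.write_matrix(wm, out / f"weighted_{grp}_{par}.csv")
            mats[grp] = wm
        table = compare.ratio_table(mats[cfg.group_a], mats[cfg.group_b])
        markov.write_matrix(table, out / f"ratio_{par}.csv")
        compare.ratio_table_long(table).to_csv(out / f"ratio_{par}_long.csv", index=False)
        tables[par] = table
    entry: dict = {"paradigms": paradigms}
    if "IOG" in tables and "CBR" in tables:
        null = compare.bootstrap_null(cfg.n_null_values, cfg.n_boot, rng=cfg.seed)
        result = compare.compare_tables(tables["IOG"], tables["CBR"], null)
        compare.write_comparison_json(result, null, out / "table_comparison.json")
        entry["table_comparison"] = result.to_dict()
    _record_stage(cfg, "compare", entry)
    return entry


def stage_correlate(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    part_path = _require(out / "participant_stats.csv", "describe")
    part_df = pd.read_csv(part_path, dtype={"participant_id": str})
    meta = records.read_metadata(_metadata_path(cfg))
    corr = stats.trait_correlation_table(part_df, meta)
    corr.to_csv(out / "trait_correlations.csv", index=False)
    entry = {"n_fits": len(corr)}
    _record_stage(cfg, "correlate", entry)
    return entry


def stage_report(cfg: PipelineConfig) -> dict:
    """Collate the per-stage outputs into one JSON bundle."""
    out = Path(cfg.out_dir)
    bundle: dict = {"version": __version__, "seed": cfg.seed}
    for name, fname in [
        ("group_stats", "group_stats.csv"),
        ("group_ttests", "group_ttests.csv"),
        ("distribution_fits", "distribution_fits.csv"),
        ("chi_square", "chi_square.csv"),
        ("kl_divergence", "kl_divergence.csv"),
        ("trait_correlations", "trait_correlations.csv"),
    ]:
        path = out / fname
        if path.exists():
            df = pd.read_csv(path)
            bundle[name] = json.loads(df.to_json(orient="records"))
    cmp_path = out / "table_comparison.json"
    if cmp_path.exists():
        bundle["table_comparison"] = json.loads(cmp_path.read_text())
    (out / "report.json").write_text(json.dumps(bundle, indent=2) + "\n")
    entry = {"sections": [k for k in bundle if k not in ("version", "seed")]}
    _record_stage(cfg, "report", entry)
    return entry


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "describe": stage_describe,
    "phasefit": stage_phasefit,
    "markov": stage_markov,
    "compare": stage_compare,
    "correlate": stage_correlate,
    "report": stage_report,
}


def run_all(cfg: PipelineConfig, include_simulate: bool | None = None) -> dict:
    """Run every stage in order; `simulate` only when no external input is
    configured (or when forced)."""
    results = {}
    if include_simulate is None:
        include_simulate = cfg.responses is None
    for name, fn in STAGES.items():
        if name == "simulate" and not include_simulate:
            continue
        results[name] = fn(cfg)
    return results
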