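"""Semi-Markov generator of synthetic rivalry/grouping response streams.

Real participant data for this kind of experiment are rarely shareable, so the
package ships a generator that produces response streams with the statistical
structure the downstream analysis assumes:

* a 4-state semi-Markov process — the percept sequence follows a zero-diagonal
  row-stochastic transition matrix, and each state's dwell time is drawn from a
  gamma distribution (the canonical dominance-duration family for rivalry);
* between-participant heterogeneity as a lognormal multiplier on dwell means;
* motor noise: occasional spurious sub-180 ms reports inserted at a homogeneous
  Poisson rate, splitting the host phase (total trial time is conserved), which
  exercises the short-response filter and same-state merging of preprocessing;
* a truncated final response: generation continues until the cumulative report
  time crosses the minimum trial duration, and the crossing phase is emitted at
  its full sampled length — trials end when the button is released, not at the
  minimum duration, so the last report must be discarded by preprocessing;
* questionnaire scores (AQ, EQ) and demographics drawn per participant from
  truncated normal distributions with group-specific means.

A single integer seed controls all randomness; per-participant substreams are
derived from it with :class:`numpy.random.SeedSequence`, so cohorts are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import (
    STATE_INDEX,
    STATE_ORDER,
    PerceptResponse,
    PerceptState,
    Trial,
    trials_to_frame,
    write_metadata,
    write_responses,
)

NOISE_MAX_DURATION_S = 0.18

CONDITIONS = ("0.78v0.78", "0.08v0.08", "0.50v0.08")
PARADIGMS = ("IOG", "CBR")


class ConfigurationError(ValueError):
    """A generator configuration violates its invariants."""


@dataclass(frozen=True)
class StateParams:
    """Gamma dwell-time parameters for one perceptual state.

    The implied mean dwell is ``dwell_shape * dwell_scale`` seconds; the shape
    parameter controls the skewness of the dwell distribution.
    """

    state: PerceptState
    dwell_shape: float
    dwell_scale: float

    def __post_init__(self) -> None:
        if self.dwell_shape <= 0 or self.dwell_scale <= 0:
            raise ConfigurationError(
                f"gamma dwell parameters must be > 0, got shape={self.dwell_shape}, "
                f"scale={self.dwell_scale}"
            )

    @property
    def mean_dwell(self) -> float:
        return self.dwell_shape * self.dwell_scale


def _check_matrix(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape != (4, 4):
        raise ConfigurationError(f"transition matrix must be 4x4, got {P.shape}")
    if np.any(np.diag(P) != 0):
        raise ConfigurationError("transition matrix diagonal must be exactly 0")
    if np.any(P < 0):
        raise ConfigurationError("transition probabilities must be >= 0")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigurationError(f"transition matrix rows must sum to 1, got {P.sum(axis=1)}")
    return P


@dataclass
class ParadigmOverride:
    """Optional per-paradigm dwell parameters / transition matrix for a group."""

    state_params: dict[PerceptState, StateParams] | None = None
    transition_matrix: np.ndarray | None = None


@dataclass
class GroupGeneratorConfig:
    """Generative settings for one participant group."""

    group_label: str
    n_participants: int
    transition_matrix: np.ndarray
    state_params: dict[PerceptState, StateParams]
    participant_dwell_multiplier_sd: float = 0.0
    aq_mean: float = 20.0
    aq_sd: float = 6.0
    eq_mean: float = 40.0
    eq_sd: float = 10.0
    age_mean: float = 30.0
    age_sd: float = 8.0
    prop_male: float = 0.5
    noise_rate: float = 0.0  # expected sub-180 ms spurious reports per minute
    paradigm_overrides: dict[str, ParadigmOverride] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.transition_matrix = _check_matrix(self.transition_matrix)
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.participant_dwell_multiplier_sd < 0:
            raise ConfigurationError("participant_dwell_multiplier_sd must be >= 0")
        if self.noise_rate < 0:
            raise ConfigurationError("noise_rate must be >= 0")
        if set(self.state_params) != set(STATE_ORDER):
            raise ConfigurationError("state_params must cover all 4 states")

    def params_for(self, paradigm: str) -> tuple[dict[PerceptState, StateParams], np.ndarray]:
        ov = self.paradigm_overrides.get(paradigm)
        sp = self.state_params
        P = self.transition_matrix
        if ov is not None:
            if ov.state_params is not None:
                sp = ov.state_params
            if ov.transition_matrix is not None:
                P = _check_matrix(ov.transition_matrix)
        return sp, P


@dataclass
class SimulationConfig:
    """Full cohort-simulation settings; the study layout is 8 trials per contrast
    condition per paradigm, each lasting at least 60 s."""

    seed: int
    groups: list[GroupGeneratorConfig]
    paradigms: tuple[str, ...] = PARADIGMS
    conditions: tuple[str, ...] = CONDITIONS
    trials_per_condition: int = 8
    min_trial_duration: float = 60.0

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise ConfigurationError("trials_per_condition must be >= 1")
        if self.min_trial_duration <= 0:
            raise ConfigurationError("min_trial_duration must be > 0")


# ---------------------------------------------------------------------------
# Trial-level simulation
# ---------------------------------------------------------------------------


def sample_state_sequence(
    P: np.ndarray,
    state_params: Mapping[PerceptState, StateParams],
    min_duration: float,
    rng: np.random.Generator,
    dwell_multiplier: float = 1.0,
) -> list[tuple[PerceptState, float]]:
    """Sample the noise-free semi-Markov phase sequence of one trial.

    The initial state is uniform over the four states.  Phases are appended
    until their cumulative time reaches ``min_duration``; the phase that
    crosses the threshold is kept at its full sampled length (the overrun
    final response that preprocessing later removes).
    """
    P = _check_matrix(P)
    if min_duration <= 0:
        raise ConfigurationError("min_duration must be > 0")
    seq: list[tuple[PerceptState, float]] = []
    state = STATE_ORDER[rng.integers(4)]
    t = 0.0
    while True:
        sp = state_params[state]
        d = float(rng.gamma(sp.dwell_shape, sp.dwell_scale * dwell_multiplier))
        d = max(d, 1e-9)
        seq.append((state, d))
        t += d
        if t >= min_duration:
            return seq
        state = STATE_ORDER[rng.choice(4, p=P[STATE_INDEX[state]])]


def insert_noise(
    seq: list[tuple[PerceptState, float]],
    noise_rate: float,
    rng: np.random.Generator,
) -> list[tuple[PerceptState, float]]:
    """Insert spurious sub-180 ms reports at ``noise_rate`` per minute.

    Each insertion draws a duration uniform on (0, 0.18], picks a host phase
    with probability proportional to its duration, and splits it in place, so
    total trial time is conserved.  The split point is chosen so that both
    host fragments stay above the short-response cutoff — an insertion never
    manufactures additional sub-cutoff reports, keeping the count of short
    responses exactly Poisson at the configured rate.  Insertions that fit in
    no phase are skipped.
    """
    if noise_rate <= 0:
        return list(seq)
    out = list(seq)
    total = sum(d for _, d in out)
    n_noise = rng.poisson(noise_rate * total / 60.0)
    margin = NOISE_MAX_DURATION_S + 1e-6  # keep host fragments above the cutoff
    for _ in range(n_noise):
        e = float(rng.uniform(0.0, NOISE_MAX_DURATION_S))
        e = max(e, 1e-6)
        durs = np.array([d for _, d in out])
        eligible = durs > e + 2 * margin
        if not eligible.any():
            continue
        w = np.where(eligible, durs, 0.0)
        host = int(rng.choice(len(out), p=w / w.sum()))
        s, d = out[host]
        offset = float(rng.uniform(margin, d - e - margin))
        noise_state = STATE_ORDER[rng.integers(4)]
        out[host : host + 1] = [(s, offset), (noise_state, e), (s, d - offset - e)]
    return out


def simulate_trial(
    group_cfg: GroupGeneratorConfig,
    min_duration: float,
    rng: np.random.Generator,
    *,
    paradigm: str = "CBR",
    dwell_multiplier: float = 1.0,
) -> list[PerceptResponse]:
    """Simulate one trial's ordered response stream for a group configuration."""
    state_params, P = group_cfg.params_for(paradigm)
    seq = sample_state_sequence(P, state_params, min_duration, rng, dwell_multiplier)
    seq = insert_noise(seq, group_cfg.noise_rate, rng)
    responses = []
    t = 0.0
    for s, d in seq:
        responses.append(PerceptResponse(state=s, onset=t, duration=d))
        t += d
    return responses


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi):
    # rejection sampling; ranges are wide relative to sd, so this terminates fast
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def simulate_cohort(config: SimulationConfig) -> tuple[list[Trial], pd.DataFrame]:
    """Simulate every participant x paradigm x condition x trial of a cohort.

    Returns the full list of trials plus a metadata table (one row per
    participant: group, age, sex, AQ, EQ).  Identical seeds give bit-identical
    output.
    """
    root = np.random.SeedSequence(config.seed)
    group_seeds = root.spawn(len(config.groups))
    trials: list[Trial] = []
    meta_rows = []
    seen_ids: set[str] = set()
    for g_cfg, g_seed in zip(config.groups, group_seeds):
        part_seeds = g_seed.spawn(g_cfg.n_participants)
        for p_idx, p_seed in enumerate(part_seeds):
            rng = np.random.Generator(np.random.PCG64(p_seed))
            pid = f"{g_cfg.group_label[:3]}{p_idx + 1:02d}"
            if pid in seen_ids:
                raise ConfigurationError(f"duplicate participant id {pid}")
            seen_ids.add(pid)
            mult = 1.0
            sd = g_cfg.participant_dwell_multiplier_sd
            if sd > 0:
                # lognormal with unit mean: mu = -sd^2/2
                mult = float(rng.lognormal(-0.5 * sd * sd, sd))
            meta_rows.append(
                {
                    "participant_id": pid,
                    "group": g_cfg.group_label,
                    "age": round(_truncated_normal(rng, g_cfg.age_mean, g_cfg.age_sd, 18, 80), 1),
                    "sex": "M" if rng.random() < g_cfg.prop_male else "F",
                    "aq": round(_truncated_normal(rng, g_cfg.aq_mean, g_cfg.aq_sd, 0, 50), 1),
                    "eq": round(_truncated_normal(rng, g_cfg.eq_mean, g_cfg.eq_sd, 0, 80), 1),
                }
            )
            for paradigm in config.paradigms:
                for condition in config.conditions:
                    for t_idx in range(config.trials_per_condition):
                        orientation = ("A", "B")[t_idx % 2]  # counterbalanced arrangement
                        responses = simulate_trial(
                            g_cfg,
                            config.min_trial_duration,
                            rng,
                            paradigm=paradigm,
                            dwell_multiplier=mult,
                        )
                        trials.append(
                            Trial(
                                participant_id=pid,
                                group=g_cfg.group_label,
                                paradigm=paradigm,
                                condition=condition,
                                orientation=orientation,
                                trial_index=t_idx + 1,
                                responses=responses,
                            )
                        )
    meta = pd.DataFrame(meta_rows, columns=["participant_id", "group", "age", "sex", "aq", "eq"])
    return trials, meta


# ---------------------------------------------------------------------------
# Config (de)serialisation and study defaults
# ---------------------------------------------------------------------------


def _state_params_to_dict(sp: Mapping[PerceptState, StateParams]) -> dict:
    return {
        s.value: {"dwell_shape": sp[s].dwell_shape, "dwell_scale": sp[s].dwell_scale}
        for s in STATE_ORDER
    }


def _state_params_from_dict(d: Mapping) -> dict[PerceptState, StateParams]:
    return {
        s: StateParams(s, float(d[s.value]["dwell_shape"]), float(d[s.value]["dwell_scale"]))
        for s in STATE_ORDER
    }


def config_to_dict(config: SimulationConfig) -> dict:
    groups = []
    for g in config.groups:
        gd = {
            "group_label": g.group_label,
            "n_participants": g.n_participants,
            "transition_matrix": np.asarray(g.transition_matrix).tolist(),
            "state_params": _state_params_to_dict(g.state_params),
            "participant_dwell_multiplier_sd": g.participant_dwell_multiplier_sd,
            "aq_mean": g.aq_mean, "aq_sd": g.aq_sd,
            "eq_mean": g.eq_mean, "eq_sd": g.eq_sd,
            "age_mean": g.age_mean, "age_sd": g.age_sd,
            "prop_male": g.prop_male,
            "noise_rate": g.noise_rate,
        }
        if g.paradigm_overrides:
            gd["paradigm_overrides"] = {
                par: {
                    "state_params": _state_params_to_dict(ov.state_params)
                    if ov.state_params is not None else None,
                    "transition_matrix": np.asarray(ov.transition_matrix).tolist()
                    if ov.transition_matrix is not None else None,
                }
                for par, ov in g.paradigm_overrides.items()
            }
        groups.append(gd)
    return {
        "seed": config.seed,
        "groups": groups,
        "paradigms": list(config.paradigms),
        "conditions": list(config.conditions),
        "trials_per_condition": config.trials_per_condition,
        "min_trial_duration": config.min_trial_duration,
    }


def config_from_dict(d: Mapping) -> SimulationConfig:
    groups = []
    for gd in d["groups"]:
        overrides = {}
        for par, ov in (gd.get("paradigm_overrides") or {}).items():
            overrides[par] = ParadigmOverride(
                state_params=_state_params_from_dict(ov["state_params"])
                if ov.get("state_params") else None,
                transition_matrix=np.asarray(ov["transition_matrix"])
                if ov.get("transition_matrix") is not None else None,
            )
        groups.append(
            GroupGeneratorConfig(
                group_label=gd["group_label"],
                n_participants=int(gd["n_participants"]),
                transition_matrix=np.asarray(gd["transition_matrix"]),
                state_params=_state_params_from_dict(gd["state_params"]),
                participant_dwell_multiplier_sd=float(gd.get("participant_dwell_multiplier_sd", 0.0)),
                aq_mean=float(gd.get("aq_mean", 20.0)), aq_sd=float(gd.get("aq_sd", 6.0)),
                eq_mean=float(gd.get("eq_mean", 40.0)), eq_sd=float(gd.get("eq_sd", 10.0)),
                age_mean=float(gd.get("age_mean", 30.0)), age_sd=float(gd.get("age_sd", 8.0)),
                prop_male=float(gd.get("prop_male", 0.5)),
                noise_rate=float(gd.get("noise_rate", 0.0)),
                paradigm_overrides=overrides,
            )
        )
    return SimulationConfig(
        seed=int(d["seed"]),
        groups=groups,
        paradigms=tuple(d.get("paradigms", PARADIGMS)),
        conditions=tuple(d.get("conditions", CONDITIONS)),
        trials_per_condition=int(d.get("trials_per_condition", 8)),
        min_trial_duration=float(d.get("min_trial_duration", 60.0)),
    )


def write_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def read_config(path: str | Path) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def _sp(means: Sequence[float], shape: float = 2.5) -> dict[PerceptState, StateParams]:
    return {
        s: StateParams(s, shape, m / shape) for s, m in zip(STATE_ORDER, means)
    }


# Default transition structure: exclusive percepts usually dissolve via piecemeal;
# piecemeal resolves to either exclusive percept; superimposition is transient.
_P_CONTROL = np.array(
    [
        [0.00, 0.15, 0.65, 0.20],
        [0.15, 0.00, 0.65, 0.20],
        [0.40, 0.40, 0.00, 0.20],
        [0.35, 0.35, 0.30, 0.00],
    ]
)
_P_AUTISM = np.array(
    [
        [0.00, 0.10, 0.70, 0.20],
        [0.10, 0.00, 0.70, 0.20],
        [0.35, 0.35, 0.00, 0.30],
        [0.30, 0.30, 0.40, 0.00],
    ]
)


def study_config(
    seed: int,
    n_autism: int = 17,
    n_control: int = 18,
    trials_per_condition: int = 8,
    noise_rate: float = 2.0,
    participant_dwell_multiplier_sd: float = 0.3,
) -> SimulationConfig:
    """Cohort configuration emulating the study conditions.

    Two groups (17 autistic, 18 neurotypical participants), both paradigms,
    three contrast conditions, 8 trials per condition of at least 60 s.  Group
    dwell means per state and paradigm are set to the groups' reported mean
    durations (seconds): autism CBR exclusive 6.7, piecemeal 2.8, superimposed
    1.4 (control 4.2 / 1.7 / 1.0); autism IOG exclusive 4.3, piecemeal 10.7,
    superimposed 1.6 (control 2.9 / 6.4 / 1.1).  AQ/EQ distributions use the
    demographic table means and SDs.
    """
    autism = GroupGeneratorConfig(
        group_label="autism",
        n_participants=n_autism,
        transition_matrix=_P_AUTISM,
        state_params=_sp([6.7, 6.7, 2.8, 1.4]),  # CBR defaults
        participant_dwell_multiplier_sd=participant_dwell_multiplier_sd,
        aq_mean=39.1, aq_sd=5.9, eq_mean=19.5, eq_sd=12.2,
        age_mean=39.2, age_sd=12.4, prop_male=6 / 17,
        noise_rate=noise_rate,
        paradigm_overrides={
            "IOG": ParadigmOverride(state_params=_sp([4.3, 4.3, 10.7, 1.6]))
        },
    )
    control = GroupGeneratorConfig(
        group_label="control",
        n_participants=n_control,
        transition_matrix=_P_CONTROL,
        state_params=_sp([4.2, 4.2, 1.7, 1.0]),
        participant_dwell_multiplier_sd=participant_dwell_multiplier_sd,
        aq_mean=17.7, aq_sd=6.5, eq_mean=47.4, eq_sd=9.8,
        age_mean=28.9, age_sd=6.5, prop_male=13 / 18,
        noise_rate=noise_rate,
        paradigm_overrides={
            "IOG": ParadigmOverride(state_params=_sp([2.9, 2.9, 6.4, 1.1]))
        },
    )
    return SimulationConfig(
        seed=seed,
        groups=[autism, control],
        trials_per_condition=trials_per_condition,
    )


def write_cohort(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Simulate a cohort and write responses.csv, participants.csv and the
    simulation config sidecar into ``out_dir``; returns the three paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials, meta = simulate_cohort(config)
    resp_path = out / "responses.csv"
    meta_path = out / "participants.csv"
    cfg_path = out / "simulation_config.yaml"
    write_responses(trials, resp_path)
    write_metadata(meta, meta_path)
    write_config(config, cfg_path)
    return resp_path, meta_path, cfg_path
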