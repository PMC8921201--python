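"""Markov transition modelling of clean percept sequences.

With fully observed state sequences the maximum-likelihood estimate of a
Markov transition matrix is simply the row-normalised matrix of adjacent-pair
counts, so no latent-state machinery is needed.  Alongside the probabilities,
every ordered transition (i -> j) carries an "actual-to-posterior" weight: the
mean duration the actual state i was held immediately before changing to the
posterior state j (the final phase of a trial has no posterior and contributes
nothing).

Matrices are 4x4 in the canonical state order (H, V, PM, SI) with a
structurally zero diagonal (merging makes self-transitions impossible).  Rows
or cells that were never observed are *undefined* and carried as NaN — never
imputed as zero — and averaging across trials and participants is hierarchical
over defined entries only, with averaged probability rows re-normalised.

The module also provides the non-randomness test (Pearson chi-square of a
row's three destination counts against the uniform null of 1/3 each), the
Kullback-Leibler divergence between two transition rows for group comparison,
and a serialisable chain-graph export (nodes sized by state mean duration,
edges attributed with probability and weight).
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import STATE_INDEX, STATE_ORDER, CleanTrial

log = logging.getLogger(__name__)

N_STATES = len(STATE_ORDER)
KL_EPS = 1e-12


def uniform_null_probability(n_states: int = N_STATES) -> float:
    """Per-destination transition probability under the random null for a
    process with no self-transitions: 1 / (n_states - 1)."""
    return 1.0 / (n_states - 1)


# ---------------------------------------------------------------------------
# Per-trial estimation
# ---------------------------------------------------------------------------


def transition_counts(clean: CleanTrial) -> np.ndarray:
    """4x4 adjacent-pair counts of the clean sequence (diagonal always 0)."""
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    states = clean.states()
    if len(states) >= 2:
        idx = np.array([STATE_INDEX[s] for s in states])
        np.add.at(counts, (idx[:-1], idx[1:]), 1)
    return counts


def counts_to_probabilities(counts: np.ndarray) -> np.ndarray:
    """Row-normalise counts; rows with zero departures become NaN (undefined)."""
    counts = np.asarray(counts, dtype=float)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / row_sums
    probs[row_sums.ravel() == 0, :] = np.nan
    # structural zero diagonal stays 0 on defined rows
    for i in range(N_STATES):
        if row_sums[i, 0] > 0:
            probs[i, i] = 0.0
    return probs


def estimate_transitions(clean: CleanTrial) -> tuple[np.ndarray, np.ndarray]:
    """(counts, MLE probabilities) for one trial; < 2 phases gives a fully
    undefined matrix (flagged in the log)."""
    counts = transition_counts(clean)
    if counts.sum() == 0:
        log.info("trial %s has < 2 phases: transition matrix undefined",
                 (clean.participant_id, clean.paradigm, clean.condition, clean.trial_index))
    return counts, counts_to_probabilities(counts)


def actual_to_posterior_weights(clean: CleanTrial) -> np.ndarray:
    """Mean duration of state i phases immediately followed by state j.

    The final phase has no posterior and contributes nothing; cells whose
    transition never occurred are NaN.
    """
    sums = np.zeros((N_STATES, N_STATES))
    counts = np.zeros((N_STATES, N_STATES))
    phases = clean.phases
    for (s_a, d_a), (s_b, _) in zip(phases, phases[1:]):
        i, j = STATE_INDEX[s_a], STATE_INDEX[s_b]
        sums[i, j] += d_a
        counts[i, j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        w = sums / counts
    w[counts == 0] = np.nan
    return w


def state_mean_durations(clean: CleanTrial) -> np.ndarray:
    """Per-state mean dwell of one trial (NaN for absent states)."""
    sums = np.zeros(N_STATES)
    counts = np.zeros(N_STATES)
    for s, d in clean.phases:
        sums[STATE_INDEX[s]] += d
        counts[STATE_INDEX[s]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        m = sums / counts
    m[counts == 0] = np.nan
    return m


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------


def average_matrices(
    matrices: Sequence[np.ndarray], renormalize_rows: bool = False
) -> np.ndarray:
    """Cell-wise unweighted mean over defined (non-NaN) entries.

    Cells undefined everywhere stay NaN.  With ``renormalize_rows`` the
    averaged probability rows are re-scaled to sum to 1 over their defined
    cells (averaging masked rows does not preserve stochasticity).
    """
    arr = np.stack([np.asarray(m, dtype=float) for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN cells
        mean = np.nanmean(arr, axis=0)
    if renormalize_rows:
        for i in range(mean.shape[0]):
            row = mean[i]
            s = np.nansum(row)
            if s > 0:
                mean[i] = row / s
    return mean


def hierarchical_average(
    matrices_by_participant: Mapping[str, Sequence[np.ndarray]],
    renormalize_rows: bool = False,
) -> np.ndarray:
    """Trial -> participant -> group averaging over defined entries only."""
    participant_means = [
        average_matrices(mats) for mats in matrices_by_participant.values() if len(mats)
    ]
    if not participant_means:
        return np.full((N_STATES, N_STATES), np.nan)
    return average_matrices(participant_means, renormalize_rows=renormalize_rows)


# ---------------------------------------------------------------------------
# Tests and divergences
# ---------------------------------------------------------------------------


def offdiagonal_row(matrix: np.ndarray, i: int) -> np.ndarray:
    """The 3 destination cells of row i (diagonal removed)."""
    row = np.asarray(matrix, dtype=float)[i]
    return np.delete(row, i)


def chi_square_uniform(destination_counts: Sequence[float]) -> tuple[float, float]:
    """Pearson goodness-of-fit of 3 destination counts against equal thirds.

    df = 2.  Zero departures give (nan, nan), flagged in the log.
    """
    c = np.asarray(destination_counts, dtype=float)
    if c.ndim != 1 or len(c) != N_STATES - 1:
        raise ValueError(f"expected {N_STATES - 1} destination counts, got {c.shape}")
    if c.sum() == 0:
        log.warning("chi-square undefined: zero departures")
        return math.nan, math.nan
    stat, p = sps.chisquare(c)
    return float(stat), float(p)


def kl_divergence(p_row: Sequence[float], q_row: Sequence[float],
                  eps: float = KL_EPS) -> float:
    """KL(p || q) in nats over jointly defined cells, with an eps floor on q.

    Zero p-cells contribute 0 (0 log 0 = 0).  Fully undefined rows give NaN.
    """
    p = np.asarray(p_row, dtype=float)
    q = np.asarray(q_row, dtype=float)
    mask = np.isfinite(p) & np.isfinite(q)
    if not mask.any():
        log.warning("KL divergence undefined: no jointly defined cells")
        return math.nan
    p = p[mask]
    q = q[mask]
    if np.any(q < eps):
        log.info("KL divergence: eps floor (%.0e) applied to %d q cell(s)",
                 eps, int(np.sum(q < eps)))
    q = np.maximum(q, eps)
    pos = p > 0
    return float(np.sum(p[pos] * np.log(p[pos] / q[pos])))


def js_divergence(p_row: Sequence[float], q_row: Sequence[float]) -> float:
    """Symmetrised Jensen-Shannon divergence (nats)."""
    p = np.asarray(p_row, dtype=float)
    q = np.asarray(q_row, dtype=float)
    m = 0.5 * (p + q)
    return 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)


# ---------------------------------------------------------------------------
# Dataset-level aggregation
# ---------------------------------------------------------------------------


def group_paradigm_aggregates(
    cleans: Iterable[CleanTrial],
) -> dict[tuple[str, str], dict]:
    """Aggregate per group x paradigm: hierarchically averaged probabilities and
    weights, summed transition counts, state mean durations, chi-square rows.

    Returns {(group, paradigm): {"probabilities", "weights", "counts",
    "state_means", "chi_square"}}; chi_square is a list of (state, stat, p)
    computed on the pooled counts of each source state's 3 destinations.
    """
    by_gp: dict[tuple[str, str], dict[str, dict[str, list]]] = {}
    counts_by_gp: dict[tuple[str, str], np.ndarray] = {}
    for c in cleans:
        if c.n_phases < 2:
            continue
        key = (c.group, c.paradigm)
        slot = by_gp.setdefault(key, {"probs": {}, "weights": {}, "means": {}})
        counts, probs = estimate_transitions(c)
        slot["probs"].setdefault(c.participant_id, []).append(probs)
        slot["weights"].setdefault(c.participant_id, []).append(
            actual_to_posterior_weights(c)
        )
        slot["means"].setdefault(c.participant_id, []).append(state_mean_durations(c))
        counts_by_gp[key] = counts_by_gp.get(key, np.zeros((N_STATES, N_STATES), int)) + counts

    out = {}
    for key, slot in by_gp.items():
        probs = hierarchical_average(slot["probs"], renormalize_rows=True)
        weights = hierarchical_average(slot["weights"])
        mean_stack = {
            pid: [m.reshape(1, -1) for m in mats] for pid, mats in slot["means"].items()
        }
        state_means = hierarchical_average(mean_stack).ravel()
        counts = counts_by_gp[key]
        chi = []
        for i, s in enumerate(STATE_ORDER):
            dest = np.delete(counts[i], i)
            stat, p = (math.nan, math.nan) if dest.sum() == 0 else chi_square_uniform(dest)
            chi.append((s.value, stat, p))
        out[key] = {
            "probabilities": probs,
            "weights": weights,
            "counts": counts,
            "state_means": state_means,
            "chi_square": chi,
        }
    return out


def kl_table(
    aggregates: Mapping[tuple[str, str], dict],
    group_a: str = "autism",
    group_b: str = "control",
) -> pd.DataFrame:
    """Per-state KL(group_a || group_b) and Jensen-Shannon divergence of the
    group-averaged transition rows, per paradigm."""
    rows = []
    paradigms = sorted({par for (_, par) in aggregates})
    for par in paradigms:
        a = aggregates.get((group_a, par))
        b = aggregates.get((group_b, par))
        if a is None or b is None:
            continue
        for i, s in enumerate(STATE_ORDER):
            p_row = offdiagonal_row(a["probabilities"], i)
            q_row = offdiagonal_row(b["probabilities"], i)
            rows.append(
                {
                    "paradigm": par, "state": s.value,
                    "kl_nats": kl_divergence(p_row, q_row),
                    "js_nats": js_divergence(p_row, q_row),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Chain graph export
# ---------------------------------------------------------------------------


def build_chain_graph(
    group: str,
    paradigm: str,
    probabilities: np.ndarray,
    weights: np.ndarray,
    state_means: np.ndarray,
    chi_square: Sequence[tuple[str, float, float]] | None = None,
) -> nx.DiGraph:
    """Directed chain graph: one node per state (mean dwell as size attribute),
    one edge per observed transition with probability and weight attributes."""
    g = nx.DiGraph(group=group, paradigm=paradigm)
    for i, s in enumerate(STATE_ORDER):
        g.add_node(s.value, mean_duration_s=float(state_means[i])
                   if np.isfinite(state_means[i]) else -1.0)
    if chi_square:
        for s, stat, p in chi_square:
            if math.isfinite(stat):
                g.nodes[s]["chi_square"] = float(stat)
                g.nodes[s]["chi_square_p"] = float(p)
    P = np.asarray(probabilities, dtype=float)
    W = np.asarray(weights, dtype=float)
    for i, si in enumerate(STATE_ORDER):
        for j, sj in enumerate(STATE_ORDER):
            if i == j or not np.isfinite(P[i, j]) or P[i, j] <= 0:
                continue
            attrs = {"probability": float(P[i, j])}
            if np.isfinite(W[i, j]):
                attrs["weight_s"] = float(W[i, j])
            g.add_edge(si.value, sj.value, **attrs)
    return g


def write_graphml(g: nx.DiGraph, path) -> None:
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.DiGraph:
    return nx.read_graphml(path)


def write_dot(g: nx.DiGraph, path) -> None:
    """Minimal Graphviz DOT serialisation with node/edge attributes."""
    lines = [f'digraph "{g.graph.get("group", "")}_{g.graph.get("paradigm", "")}" {{']
    for n, attrs in g.nodes(data=True):
        kv = " ".join(f'{k}="{v}"' for k, v in attrs.items())
        lines.append(f'  "{n}" [{kv}];')
    for a, b, attrs in g.edges(data=True):
        kv = " ".join(f'{k}="{v}"' for k, v in attrs.items())
        lines.append(f'  "{a}" -> "{b}" [{kv}];')
    lines.append("}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Matrix CSV round-trip (labelled 4x4, undefined cells empty)
# ---------------------------------------------------------------------------

_LABELS = [s.value for s in STATE_ORDER]


def matrix_to_frame(matrix: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(matrix, dtype=float), index=_LABELS, columns=_LABELS)


def write_matrix(matrix: np.ndarray, path) -> None:
    matrix_to_frame(matrix).to_csv(path)


def read_matrix(path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    return df.loc[_LABELS, _LABELS].to_numpy(dtype=float)
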