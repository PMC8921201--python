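"""Weighted transition matrices, group ratio tables, and the bootstrap z-test.

Dividing each transition probability by its actual-to-posterior mean duration
gives a *weighted* transition matrix (units 1/s): transitions that are both
likely and quickly executed score high.  Per paradigm, the autism group's
weighted matrix is divided cell-wise by the control group's, giving a 12-cell
ratio table (4x4 minus the structural diagonal) whose cells sit near 1 when
the groups behave alike.

Whether the IOG and CBR ratio tables differ more than chance is tested
non-parametrically: the null is built from 12 evenly spaced base values on
[0, 1] (mean exactly 0.5), resampled with replacement 10,000 times; each
replicate records the mean of its 12 draws.  The observed table-difference
statistic is compared to that bootstrap distribution with a two-tailed z-test.
The difference statistic is not uniquely pinned down by convention, so three
variants are computed (mean |IOG - CBR| over jointly defined cells — the
primary one — plus mean signed difference and max |difference|).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import STATE_ORDER

log = logging.getLogger(__name__)

N_RATIO_CELLS = 12  # 4x4 minus diagonal


@dataclass
class BootstrapNull:
    """A realised bootstrap null distribution of means of 12 base values."""

    base_values: np.ndarray
    means: np.ndarray
    mean: float
    sd: float
    n_boot: int
    seed: int | None = None


@dataclass
class TableComparison:
    statistic: float  # primary: mean |IOG - CBR| over jointly defined cells
    z: float
    p: float  # two-tailed
    within_95: bool
    n_cells: int
    variants: dict[str, float] = field(default_factory=dict)
    null_mean: float = math.nan
    null_sd: float = math.nan

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "z": self.z, "p": self.p,
            "within_95": self.within_95, "n_cells": self.n_cells,
            "variants": self.variants,
            "null_mean": self.null_mean, "null_sd": self.null_sd,
        }


def weighted_matrix(probabilities: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Element-wise probability / actual-to-posterior weight (1/s).

    Undefined cells in either factor propagate; non-positive weights are
    flagged invalid (NaN).
    """
    P = np.asarray(probabilities, dtype=float)
    W = np.asarray(weights, dtype=float)
    if P.shape != W.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {W.shape}")
    bad = np.isfinite(W) & (W <= 0)
    if bad.any():
        log.warning("weighted_matrix: %d non-positive weight cell(s) flagged invalid",
                    int(bad.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = P / W
    out[bad] = np.nan
    return out


def ratio_table(autism: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Cell-wise autism / control quotient over jointly defined off-diagonal
    cells; the diagonal and undefined cells are NaN."""
    a = np.asarray(autism, dtype=float)
    c = np.asarray(control, dtype=float)
    if a.shape != c.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {c.shape}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = a / c
    out[~np.isfinite(out)] = np.nan
    np.fill_diagonal(out, np.nan)
    n_missing = int(np.isnan(out).sum()) - out.shape[0]
    if n_missing:
        log.info("ratio_table: %d off-diagonal cell(s) undefined", n_missing)
    return out


def bootstrap_null(
    n_values: int = N_RATIO_CELLS,
    n_boot: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> BootstrapNull:
    """Resample means of ``n_values`` evenly spaced base values on [0, 1].

    The base values include both endpoints, the only reading with 12 values,
    both endpoints and mean exactly 0.5.
    """
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    elif rng is None:
        rng = np.random.default_rng()
    base = np.linspace(0.0, 1.0, n_values)
    draws = rng.integers(0, n_values, size=(n_boot, n_values))
    means = base[draws].mean(axis=1)
    return BootstrapNull(
        base_values=base,
        means=means,
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)),
        n_boot=n_boot,
        seed=seed,
    )


def _difference_variants(t_a: np.ndarray, t_b: np.ndarray) -> tuple[dict, int]:
    a = np.asarray(t_a, dtype=float)
    b = np.asarray(t_b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no jointly defined cells to compare")
    diff = a[mask] - b[mask]
    return (
        {
            "mean_abs_difference": float(np.mean(np.abs(diff))),
            "mean_signed_difference": float(np.mean(diff)),
            "max_abs_difference": float(np.max(np.abs(diff))),
        },
        n,
    )


def compare_tables(
    t_iog: np.ndarray, t_cbr: np.ndarray, null: BootstrapNull
) -> TableComparison:
    """Two-tailed z-test of the table difference against the bootstrap null.

    Primary statistic: mean |IOG - CBR| over jointly defined cells.  The
    ``within_95`` flag says whether the observed statistic falls inside the
    central 95% of the null (difference compatible with chance).
    """
    variants, n = _difference_variants(t_iog, t_cbr)
    stat = variants["mean_abs_difference"]
    z = (stat - null.mean) / null.sd
    p = 2.0 * float(sps.norm.sf(abs(z)))
    lo, hi = np.quantile(null.means, [0.025, 0.975])
    return TableComparison(
        statistic=stat, z=float(z), p=p,
        within_95=bool(lo <= stat <= hi), n_cells=n,
        variants=variants, null_mean=null.mean, null_sd=null.sd,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_LABELS = [s.value for s in STATE_ORDER]


def ratio_table_long(table: np.ndarray) -> pd.DataFrame:
    rows = []
    t = np.asarray(table, dtype=float)
    for i, a in enumerate(_LABELS):
        for j, b in enumerate(_LABELS):
            if i == j:
                continue
            rows.append({"from_state": a, "to_state": b,
                         "ratio": t[i, j] if np.isfinite(t[i, j]) else np.nan})
    return pd.DataFrame(rows)


def write_comparison_json(
    result: TableComparison, null: BootstrapNull, path
) -> None:
    payload = result.to_dict()
    payload.update(
        {
            "n_boot": null.n_boot,
            "seed": null.seed,
            "n_base_values": len(null.base_values),
            "statistic_definition": "mean absolute cell-wise difference |IOG - CBR| "
                                    "over jointly defined off-diagonal cells",
        }
    )
    from pathlib import Path

    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
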