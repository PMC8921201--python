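"""Gamma (and comparison lognormal) fits to normalized exclusive phase durations.

Dominance durations in rivalry are classically summarised by a gamma
distribution

    f(x | alpha, beta) = x**(alpha-1) * exp(-x/beta) / (beta**alpha * Gamma(alpha)),
    x > 0, alpha > 0, beta > 0,

fitted to phase durations that were first normalized within each subject x
condition cell (duration divided by the cell mean, so every cell has unit mean)
and then pooled across subjects within a group x paradigm.  The summaries
derived from a fit are:

* R^2 against a density-normalized histogram of the pooled sample (fixed bin
  width 0.2 over [0, 4], so the goodness-of-fit number is reproducible);
* the density peak: for alpha > 1 the mode is at x = (alpha - 1) * beta; for
  alpha <= 1 the density is monotone and the peak is flagged at the left
  evaluation bound;
* the area under the curve by trapezoidal integration on 100 evenly spaced
  points over [0.18, 4], both for the unit-area density and for the
  event-scaled curve n_events * pdf(x) whose amplitude reflects how many
  exclusive percepts a group actually produced.

A lognormal fit with the same machinery is provided for model comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import EXCLUSIVE_STATES, CleanTrial, PerceptState

log = logging.getLogger(__name__)

AUC_GRID = (0.18, 4.0, 100)  # lo, hi, number of evaluation points
HIST_BIN_WIDTH = 0.2
HIST_RANGE = (0.0, 4.0)


@dataclass
class DistributionFit:
    """A fitted dwell-time distribution and its derived curve summaries."""

    family: str  # "gamma" or "lognormal"
    shape: float  # gamma alpha / lognormal sigma
    scale: float  # gamma beta / lognormal exp(mu)
    n_events: int
    r_squared: float
    peak_x: float
    peak_y: float  # on the event-scaled curve, matching plotted amplitude
    auc_scaled: float  # trapezoid AUC of n_events * pdf over the grid
    auc_density: float  # trapezoid AUC of the unit-area density
    boundary_peak: bool = False  # alpha <= 1: monotone density, no interior mode


GammaFit = DistributionFit  # the primary family


def gamma_pdf(x, alpha: float, beta: float):
    """Gamma density with shape ``alpha`` and scale ``beta``."""
    return sps.gamma.pdf(x, a=alpha, scale=beta)


def lognormal_pdf(x, sigma: float, scale: float):
    return sps.lognorm.pdf(x, s=sigma, scale=scale)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_phases(
    cleans: Iterable[CleanTrial],
    percept_class: str | PerceptState = "exclusive",
    by: str = "participant_condition",
) -> pd.DataFrame:
    """Normalize qualifying phase durations by their cell mean and pool them.

    ``percept_class='exclusive'`` pools horizontal and vertical phases
    together before normalization (the exclusive class is analysed jointly).
    The normalization cell is subject x condition within each group x paradigm
    (``by='participant'`` instead normalizes per subject pooled over
    conditions).  Returns a tidy frame with column ``x`` (dimensionless,
    unit mean per cell).  Single-phase cells yield x = 1 and are flagged in
    the log.
    """
    if isinstance(percept_class, PerceptState):
        members = {percept_class}
    elif percept_class == "exclusive":
        members = set(EXCLUSIVE_STATES)
    else:
        members = {PerceptState(percept_class)}

    rows = []
    for c in cleans:
        for s, d in c.phases:
            if s in members:
                rows.append(
                    {
                        "group": c.group, "paradigm": c.paradigm,
                        "participant_id": c.participant_id,
                        "condition": c.condition,
                        "state": s.value, "duration_s": d,
                    }
                )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(x=pd.Series(dtype=float))
    cell_keys = ["group", "paradigm", "participant_id"]
    if by == "participant_condition":
        cell_keys.append("condition")
    elif by != "participant":
        raise ValueError(f"unknown normalization mode {by!r}")
    cell_means = df.groupby(cell_keys)["duration_s"].transform("mean")
    cell_sizes = df.groupby(cell_keys)["duration_s"].transform("size")
    n_single = int((cell_sizes == 1).sum())
    if n_single:
        log.warning("%d normalization cell(s) contain a single phase (x = 1)", n_single)
    df["x"] = df["duration_s"] / cell_means
    return df


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _r_squared(samples: np.ndarray, pdf_at) -> float:
    """R^2 between a density-normalized histogram and the fitted density."""
    nbins = int(round((HIST_RANGE[1] - HIST_RANGE[0]) / HIST_BIN_WIDTH))
    hist, edges = np.histogram(samples, bins=nbins, range=HIST_RANGE, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pred = pdf_at(centers)
    ss_res = float(np.sum((hist - pred) ** 2))
    ss_tot = float(np.sum((hist - hist.mean()) ** 2))
    if ss_tot == 0:
        return math.nan
    return 1.0 - ss_res / ss_tot


def _curve_summaries(family, shape, scale, n_events):
    lo, hi, npts = AUC_GRID
    grid = np.linspace(lo, hi, npts)
    if family == "gamma":
        dens = gamma_pdf(grid, shape, scale)
        if shape > 1:
            peak_x = (shape - 1) * scale
            boundary = False
        else:
            peak_x = lo
            boundary = True
        peak_dens = gamma_pdf(peak_x, shape, scale)
    else:
        dens = lognormal_pdf(grid, shape, scale)
        peak_x = scale * math.exp(-shape**2)  # lognormal mode
        boundary = False
        peak_dens = lognormal_pdf(peak_x, shape, scale)
    auc_density = float(np.trapezoid(dens, grid))
    return peak_x, float(n_events * peak_dens), float(n_events * auc_density), auc_density, boundary


def _validate_samples(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if len(x) < 10:
        raise ValueError(f"need at least 10 samples to fit, got {len(x)}")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("samples must be finite and strictly positive")
    return x


def fit_gamma(samples: Sequence[float]) -> DistributionFit:
    """Maximum-likelihood gamma fit (location fixed at 0) with curve summaries."""
    x = _validate_samples(samples)
    alpha, _, beta = sps.gamma.fit(x, floc=0)
    r2 = _r_squared(x, lambda c: gamma_pdf(c, alpha, beta))
    peak_x, peak_y, auc_scaled, auc_density, boundary = _curve_summaries(
        "gamma", alpha, beta, len(x)
    )
    if boundary:
        log.warning("fitted shape %.3f <= 1: monotone density, peak flagged at bound", alpha)
    return DistributionFit(
        family="gamma", shape=float(alpha), scale=float(beta), n_events=len(x),
        r_squared=r2, peak_x=peak_x, peak_y=peak_y,
        auc_scaled=auc_scaled, auc_density=auc_density, boundary_peak=boundary,
    )


def fit_lognormal(samples: Sequence[float]) -> DistributionFit:
    """Maximum-likelihood lognormal fit, same summaries as the gamma fit."""
    x = _validate_samples(samples)
    sigma, _, scale = sps.lognorm.fit(x, floc=0)
    r2 = _r_squared(x, lambda c: lognormal_pdf(c, sigma, scale))
    peak_x, peak_y, auc_scaled, auc_density, boundary = _curve_summaries(
        "lognormal", sigma, scale, len(x)
    )
    return DistributionFit(
        family="lognormal", shape=float(sigma), scale=float(scale), n_events=len(x),
        r_squared=r2, peak_x=peak_x, peak_y=peak_y,
        auc_scaled=auc_scaled, auc_density=auc_density, boundary_peak=boundary,
    )


def gamma_peak(fit: DistributionFit) -> tuple[float, float]:
    """(peak_x, peak_y) of a fit; peak_y is on the event-scaled curve."""
    return fit.peak_x, fit.peak_y


def auc_curve(fit: DistributionFit) -> tuple[float, float]:
    """(event-scaled AUC, unit-density AUC) over the standard grid."""
    return fit.auc_scaled, fit.auc_density


def fit_summary_table(
    cleans: Iterable[CleanTrial],
    percept_class: str | PerceptState = "exclusive",
    by: str = "participant_condition",
) -> pd.DataFrame:
    """Gamma + lognormal fit summaries per group x paradigm pooled sample."""
    norm = normalize_phases(cleans, percept_class=percept_class, by=by)
    rows = []
    if norm.empty:
        return pd.DataFrame(rows)
    for (group, paradigm), sub in norm.groupby(["group", "paradigm"]):
        x = sub["x"].to_numpy()
        if len(x) < 10:
            log.warning("skipping %s/%s: only %d phases", group, paradigm, len(x))
            continue
        for fitter in (fit_gamma, fit_lognormal):
            f = fitter(x)
            rows.append(
                {
                    "group": group, "paradigm": paradigm, "family": f.family,
                    "shape": f.shape, "scale": f.scale, "n_events": f.n_events,
                    "r_squared": f.r_squared, "peak_x": f.peak_x, "peak_y": f.peak_y,
                    "auc_scaled": f.auc_scaled, "auc_density": f.auc_density,
                    "boundary_peak": f.boundary_peak,
                }
            )
    return pd.DataFrame(rows)


def curve_points_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Evaluation-grid points of every fitted curve, for external plotting."""
    lo, hi, npts = AUC_GRID
    grid = np.linspace(lo, hi, npts)
    rows = []
    for _, f in fits.iterrows():
        if f["family"] == "gamma":
            dens = gamma_pdf(grid, f["shape"], f["scale"])
        else:
            dens = lognormal_pdf(grid, f["shape"], f["scale"])
        for xv, dv in zip(grid, dens):
            rows.append(
                {
                    "group": f["group"], "paradigm": f["paradigm"],
                    "family": f["family"], "x": xv,
                    "density": dv, "scaled": f["n_events"] * dv,
                }
            )
    return pd.DataFrame(rows)
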