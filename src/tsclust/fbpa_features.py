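"""Curve-summary features for feature-based PAM clustering of time courses.

Each gene's sparse curve is reduced to a fixed-length vector:

* median slopes over the baseline-augmented time grid (one per gap),
* maximum and minimum of the median profile (log2 units),
* times (hours) at which those extrema occur,
* steepest positive and steepest negative median slope.

Because paired treated/control samples are identical before treatment, a
baseline point (t = 0, ratio = 0) is prepended to every replicate series so
that the initial response slope is captured; for n observed time points this
yields n slopes and hence n + 6 features (12 for the canonical 6-point
design).  Set ``include_baseline_slope=False`` to drop the baseline gap and
obtain the n − 1 inter-observation slopes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timecourse_io import MedianProfile, TimeCourseExperiment, ValidationError

__all__ = [
    "FeatureVector",
    "slope_vector",
    "extremum_features",
    "extract_features",
    "feature_names",
]


@dataclass
class FeatureVector:
    """Feature summary of one gene's curve.

    ``slopes`` are in log2 units per hour; ``max_expr``/``min_expr`` in log2
    units; ``t_max``/``t_min`` in hours on the observed grid.
    """

    gene_id: str
    slopes: np.ndarray
    max_expr: float
    min_expr: float
    t_max: float
    t_min: float
    steepest_up: float
    steepest_down: float

    def to_array(self) -> np.ndarray:
        return np.concatenate(
            [
                self.slopes,
                [
                    self.max_expr,
                    self.min_expr,
                    self.t_max,
                    self.t_min,
                    self.steepest_up,
                    self.steepest_down,
                ],
            ]
        )


def _augmented_grid(
    times: np.ndarray, include_baseline_slope: bool
) -> tuple[np.ndarray, bool]:
    if np.any(np.diff(times) <= 0):
        raise ValidationError("duplicate or decreasing time stamps")
    if include_baseline_slope:
        return np.concatenate([[0.0], times]), True
    return np.asarray(times, dtype=float), False


def slope_vector(
    exp: TimeCourseExperiment, gene: str, include_baseline_slope: bool = True
) -> np.ndarray:
    """Median-over-replicates slope for each adjacent pair of time points.

    Per replicate, slope over gap i is (x_{i+1} - x_i) / (t_{i+1} - t_i) on
    the baseline-augmented grid; the median is then taken over replicates
    with both endpoints observed.  A gap where no replicate has both
    endpoints falls back to the slope of the median profile (the container
    invariant guarantees at least one replicate per time point).
    """
    g = exp.gene_index(gene)
    x = exp.ratios[g]  # (times, reps)
    grid, augmented = _augmented_grid(exp.times, include_baseline_slope)
    if augmented:
        x = np.vstack([np.zeros((1, x.shape[1])), x])
    dt = np.diff(grid)[:, None]
    per_rep = np.diff(x, axis=0) / dt  # (gaps, reps); NaN where an endpoint missing
    with np.errstate(invalid="ignore"):
        slopes = np.nanmedian(per_rep, axis=1)
    if np.any(np.isnan(slopes)):
        u = np.nanmedian(x, axis=1)
        fallback = np.diff(u) / np.diff(grid)
        slopes = np.where(np.isnan(slopes), fallback, slopes)
    return slopes


def extremum_features(
    profile: MedianProfile, times: np.ndarray
) -> tuple[float, float, float, float]:
    """(max_expr, min_expr, t_max, t_min) of a median profile.

    Extrema are taken over the observed time points only (the implicit
    baseline is excluded); ties are broken by the earliest time so the result
    is deterministic.
    """
    u = np.asarray(profile.u, dtype=float)
    times = np.asarray(times, dtype=float)
    if u.size != times.size:
        raise ValidationError("profile and time grid lengths differ")
    i_max = int(np.argmax(u))  # argmax/argmin return the first (earliest) index
    i_min = int(np.argmin(u))
    return float(u[i_max]), float(u[i_min]), float(times[i_max]), float(times[i_min])


def feature_names(
    times: np.ndarray, include_baseline_slope: bool = True
) -> list[str]:
    """Column names in the fixed feature order (slopes by time, then scalars)."""
    grid, _ = _augmented_grid(np.asarray(times, dtype=float), include_baseline_slope)
    names = [f"slope_{a:g}_{b:g}" for a, b in zip(grid[:-1], grid[1:])]
    return names + ["max_expr", "min_expr", "t_max", "t_min", "steepest_up", "steepest_down"]


def extract_features(
    exp: TimeCourseExperiment,
    include_baseline_slope: bool = True,
    standardize: bool = False,
) -> pd.DataFrame:
    """Feature matrix for all genes, one row per gene in experiment order.

    Features enter clustering with equal weight (no scaling) by default;
    ``standardize=True`` z-scores each column (constant columns are left at
    zero) for sensitivity analyses, since hour-valued extremum times and
    log2-unit amplitudes live on different scales.
    """
    rows = []
    medians = np.nanmedian(exp.ratios, axis=2)
    for g, gene in enumerate(exp.gene_ids):
        slopes = slope_vector(exp, gene, include_baseline_slope)
        mx, mn, t_mx, t_mn = extremum_features(
            MedianProfile(gene, medians[g]), exp.times
        )
        fv = FeatureVector(
            gene_id=gene,
            slopes=slopes,
            max_expr=mx,
            min_expr=mn,
            t_max=t_mx,
            t_min=t_mn,
            steepest_up=float(np.max(slopes)),
            steepest_down=float(np.max(-slopes)),
        )
        rows.append(fv.to_array())
    cols = feature_names(exp.times, include_baseline_slope)
    df = pd.DataFrame(rows, index=pd.Index(exp.gene_ids, name="gene_id"), columns=cols)
    if standardize:
        sd = df.std(ddof=0)
        sd[sd == 0] = 1.0
        df = (df - df.mean()) / sd
    return df
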