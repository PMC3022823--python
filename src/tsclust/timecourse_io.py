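"""Reading, writing and basic transforms for short expression time courses.

The central container is :class:`TimeCourseExperiment`, a dense
``genes x times x replicates`` tensor of log2 treated/control ratios with
``NaN`` marking missing measurements.  The baseline (t = 0, ratio = 0) is a
property of the experimental design — paired treated/control samples are
identical before treatment — and is therefore *not* stored; feature
extraction prepends it where needed.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourseExperiment",
    "MedianProfile",
    "ColumnSchema",
    "read_ratio_table",
    "write_ratio_table",
    "compute_log_ratios",
    "median_profile",
    "median_profiles",
    "flag_filter",
    "read_assignments",
    "write_assignments",
]


class FormatError(ValueError):
    """A file does not follow the expected tabular layout."""


class ValidationError(ValueError):
    """Data violate a container invariant."""


@dataclass
class TimeCourseExperiment:
    """Log2 treated/control ratios for a set of genes over a shared time grid.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row of ``ratios``.
    times
        Strictly increasing measurement times in hours; all > 0.  The
        pre-treatment baseline is implicit and not included here.
    ratios
        Array of shape ``(n_genes, n_times, n_replicates)`` holding
        ``log2(treated / control)`` values; ``NaN`` marks missing cells.
    condition_label
        Free-text condition tag (e.g. ``"irradiated"``, ``"bystander"``).
    truth_labels
        Optional integer cluster labels per gene (synthetic data only).
    """

    gene_ids: list[str]
    times: np.ndarray
    ratios: np.ndarray
    condition_label: str = ""
    truth_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if self.ratios.ndim != 3:
            raise ValidationError("ratios must be a genes x times x replicates tensor")
        if self.ratios.shape[0] != len(self.gene_ids):
            raise ValidationError("gene_ids length does not match ratios")
        if self.ratios.shape[1] != self.times.size:
            raise ValidationError("times length does not match ratios")
        if self.times.size and (np.any(np.diff(self.times) <= 0) or self.times[0] <= 0):
            raise ValidationError("times must be strictly increasing and > 0")
        if self.n_genes and np.any(self.missing_mask.all(axis=2)):
            bad = [
                self.gene_ids[g]
                for g in np.nonzero(self.missing_mask.all(axis=2).any(axis=1))[0]
            ]
            raise ValidationError(
                f"genes with no replicate at some time point: {bad}"
            )
        if self.truth_labels is not None and len(self.truth_labels) != self.n_genes:
            raise ValidationError("truth_labels length does not match gene count")

    # -- convenience --------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.ratios.shape[0]

    @property
    def n_times(self) -> int:
        return self.ratios.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.ratios.shape[2]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean tensor, True where a measurement is missing."""
        return np.isnan(self.ratios)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None

    def subset(self, genes: Sequence[str] | np.ndarray) -> "TimeCourseExperiment":
        """Return a new experiment restricted to ``genes`` (ids or bool mask)."""
        if isinstance(genes, np.ndarray) and genes.dtype == bool:
            idx = np.nonzero(genes)[0]
        else:
            idx = np.array([self.gene_index(g) for g in genes])
        return TimeCourseExperiment(
            gene_ids=[self.gene_ids[i] for i in idx],
            times=self.times.copy(),
            ratios=self.ratios[idx].copy(),
            condition_label=self.condition_label,
            truth_labels=None if self.truth_labels is None else self.truth_labels[idx],
        )


@dataclass
class MedianProfile:
    """Per-time median log2 ratio u_i of one gene over its replicates."""

    gene_id: str
    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)


@dataclass
class ColumnSchema:
    """Naming convention for data columns: ``<condition>_<timeHours>_<rep>``.

    ``pattern`` must expose named groups ``condition``, ``time`` and ``rep``.
    """

    gene_column: str = "gene_id"
    pattern: str = r"^(?P<condition>[^_]+)_(?P<time>[0-9.]+)_(?P<rep>\w+)$"
    separator: str = "\t"

    def parse(self, column: str) -> tuple[str, float, str]:
        m = re.match(self.pattern, column)
        if m is None:
            raise FormatError(
                f"column {column!r} does not match schema {self.pattern!r}"
            )
        return m.group("condition"), float(m.group("time")), m.group("rep")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def read_ratio_table(
    path: str | Path, schema: ColumnSchema | None = None
) -> TimeCourseExperiment:
    """Read a tab-delimited ratio table into a :class:`TimeCourseExperiment`.

    One gene per row; data columns named per ``schema``.  Unparseable cells
    become missing.  Genes left without any replicate at some time point are
    dropped with a warning.
    """
    schema = schema or ColumnSchema()
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=schema.separator, dtype={0: str})
    if schema.gene_column not in df.columns:
        raise FormatError(
            f"missing gene column {schema.gene_column!r}; found {list(df.columns)[:5]}"
        )
    data_cols = [c for c in df.columns if c != schema.gene_column]
    parsed = [schema.parse(c) for c in data_cols]  # raises FormatError w/ column name
    conditions = {p[0] for p in parsed}
    if len(conditions) != 1:
        raise FormatError(f"mixed conditions in one table: {sorted(conditions)}")
    condition = parsed[0][0]
    times = sorted({p[1] for p in parsed})
    reps = sorted({p[2] for p in parsed})
    t_index = {t: i for i, t in enumerate(times)}
    r_index = {r: i for i, r in enumerate(reps)}

    gene_ids = df[schema.gene_column].tolist()
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValidationError(f"duplicate gene ids in {path}: {dupes}")

    ratios = np.full((len(gene_ids), len(times), len(reps)), np.nan)
    for col, (_, t, r) in zip(data_cols, parsed):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        ratios[:, t_index[t], r_index[r]] = vals

    keep = ~np.isnan(ratios).all(axis=2).any(axis=1)
    if not keep.all():
        dropped = [g for g, k in zip(gene_ids, keep) if not k]
        logger.warning(
            "dropping %d gene(s) with an all-missing time point: %s",
            len(dropped),
            dropped,
        )
    return TimeCourseExperiment(
        gene_ids=[g for g, k in zip(gene_ids, keep) if k],
        times=np.array(times),
        ratios=ratios[keep],
        condition_label=condition,
    )


def write_ratio_table(
    exp: TimeCourseExperiment, path: str | Path, schema: ColumnSchema | None = None
) -> None:
    """Write an experiment back to the tab-delimited layout of the schema."""
    schema = schema or ColumnSchema()
    condition = exp.condition_label or "COND"
    cols: dict[str, np.ndarray] = {schema.gene_column: np.array(exp.gene_ids)}
    for i, t in enumerate(exp.times):
        for r in range(exp.n_replicates):
            t_str = f"{t:g}"
            cols[f"{condition}_{t_str}_{r + 1}"] = exp.ratios[:, i, r]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def compute_log_ratios(
    treated: np.ndarray,
    control: np.ndarray,
    gene_ids: Sequence[str],
    times: Sequence[float],
    pairing: Sequence[int] | None = None,
    condition_label: str = "",
) -> TimeCourseExperiment:
    """Form x_igr = log2(treated / control) from paired raw intensities.

    ``pairing[r]`` gives the control replicate paired with treated replicate
    ``r`` (identity by default).  Missing values (NaN) propagate.  Nonpositive
    raw intensities are rejected: a log-ratio is undefined there.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape:
        raise ValidationError("treated and control tensors must share shape")
    if pairing is not None:
        control = control[:, :, list(pairing)]
    for name, tensor in (("treated", treated), ("control", control)):
        bad = np.nonzero(~np.isnan(tensor) & (tensor <= 0))
        if bad[0].size:
            g, t, r = bad[0][0], bad[1][0], bad[2][0]
            raise ValueError(
                f"nonpositive {name} intensity at gene={gene_ids[g]!r}, "
                f"time={times[t]}, replicate={r}"
            )
    ratios = np.log2(treated / control)
    return TimeCourseExperiment(
        gene_ids=list(gene_ids),
        times=np.asarray(times, dtype=float),
        ratios=ratios,
        condition_label=condition_label,
    )


def median_profile(exp: TimeCourseExperiment, gene: str) -> MedianProfile:
    """u_i = median over non-missing replicates of x_igr at each time point.

    The median (rather than the mean) is used throughout because it is robust
    to single-replicate outliers; an even replicate count gives the midpoint
    of the two central values.
    """
    g = exp.gene_index(gene)
    u = np.nanmedian(exp.ratios[g], axis=1)
    return MedianProfile(gene_id=gene, u=u)


def median_profiles(exp: TimeCourseExperiment) -> np.ndarray:
    """All median profiles as a ``(n_genes, n_times)`` array."""
    return np.nanmedian(exp.ratios, axis=2)


def flag_filter(
    detect_flags: np.ndarray,
    outlier_flags: np.ndarray,
    max_bad_fraction: float = 0.10,
) -> np.ndarray:
    """Quality filter on per-measurement flags; returns a boolean keep-mask.

    A measurement is *bad* if it was not detected above background
    (``detect_flags`` False) or was flagged as a non-uniformity outlier
    (``outlier_flags`` True).  A gene is retained iff the fraction of bad
    measurements over all its (time, replicate) cells is at most
    ``max_bad_fraction`` (default 10%).
    """
    detect = np.asarray(detect_flags, dtype=bool)
    outlier = np.asarray(outlier_flags, dtype=bool)
    if detect.shape != outlier.shape:
        raise ValidationError("flag tensors must share shape")
    if not 0.0 <= max_bad_fraction <= 1.0:
        raise ValueError("max_bad_fraction must lie in [0, 1]")
    bad = ~detect | outlier
    frac = bad.reshape(bad.shape[0], -1).mean(axis=1)
    return frac <= max_bad_fraction


def write_assignments(
    path: str | Path,
    gene_ids: Sequence[str],
    clusters: Sequence[int] | np.ndarray,
    distances: Sequence[float] | np.ndarray | None = None,
) -> None:
    """Write a partition as TSV: gene_id, cluster, distance_to_medoid."""
    df = pd.DataFrame({"gene_id": list(gene_ids), "cluster": np.asarray(clusters)})
    if distances is not None:
        df["distance_to_medoid"] = np.asarray(distances, dtype=float)
    df.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Read a partition TSV written by :func:`write_assignments`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or "cluster" not in df.columns:
        raise FormatError(f"{path} lacks gene_id/cluster columns")
    return df
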