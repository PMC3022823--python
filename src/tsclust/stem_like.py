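"""Profile-grammar clustering for short time series, with permutation tests.

This module follows the approach of the Short Time-series Expression Miner
(STEM): enumerate every discrete expression profile that starts at 0 and
moves at most c units between adjacent time points, pick m mutually distant
candidate profiles, assign each gene's median profile to the nearest
candidate under a Pearson-correlation distance, and judge each candidate
cluster against the count of genes it would attract if every gene's time
order were random.

Because the Pearson distance is location- and scale-free, genes are compared
to candidates without any per-gene unit calibration; this keeps the method
applicable to log2-ratio data directly.  Constant (zero-variance) profiles
are uncorrelated with everything by convention: their distance to any other
profile is 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .timecourse_io import TimeCourseExperiment, median_profiles

__all__ = [
    "StemResult",
    "enumerate_profiles",
    "select_candidates",
    "assign_genes",
    "pearson_distance",
    "permutation_significance",
]

_MAX_PROFILES = 10**7


@dataclass
class StemResult:
    """Outcome of a profile-based clustering run.

    Significance is per candidate profile: every gene is assigned somewhere,
    but only candidates attracting more genes than expected at random are
    flagged, so not every gene lies in a significant cluster.
    """

    c: int
    m: int
    candidates: np.ndarray
    assignment: np.ndarray
    observed_counts: np.ndarray
    expected_counts: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float
    n_permutations: int


def enumerate_profiles(c: int, n: int) -> np.ndarray:
    """All discrete profiles of length n anchored at 0 with steps in [-c, c].

    There are (2c+1)^(n-1) such profiles; enumeration is lexicographic in the
    step sequence.  Guarded against combinatorial blow-up.
    """
    if c < 1:
        raise ValueError("units of change c must be >= 1")
    if n < 2:
        raise ValueError("need at least 2 time points")
    count = (2 * c + 1) ** (n - 1)
    if count > _MAX_PROFILES:
        raise ValueError(
            f"(2c+1)^(n-1) = {count} profiles exceeds the {_MAX_PROFILES} guard"
        )
    steps = np.array(list(product(range(-c, c + 1), repeat=n - 1)), dtype=int)
    profiles = np.concatenate(
        [np.zeros((count, 1), dtype=int), np.cumsum(steps, axis=1)], axis=1
    )
    return profiles


def pearson_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson(r) distance between rows of A and rows of B.

    Zero-variance rows are treated as uncorrelated with everything
    (distance 1), which sends constant genes to the lowest-index candidate.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n = A.shape[1]
    if B.shape[1] != n:
        raise ValueError("profiles must share length")

    def _z(M: np.ndarray) -> np.ndarray:
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (M - mu) / sd
        Z[np.repeat(sd == 0, M.shape[1], axis=1)] = 0.0
        return Z

    corr = _z(A) @ _z(B).T / n
    return 1.0 - corr


def select_candidates(
    profiles: np.ndarray, m: int, metric: str = "euclidean"
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy max-min (farthest-point) selection of m candidate profiles.

    Seeds with the flat profile, then repeatedly adds the profile whose
    minimum distance to the already-selected set is largest, so the minimum
    pairwise distance within the candidate set is (greedily) maximised.
    Ties go to the lowest enumeration index.  Returns (indices, profiles).
    """
    profiles = np.asarray(profiles)
    total = profiles.shape[0]
    if m <= 0:
        raise ValueError("m must be positive")
    if m > total:
        raise ValueError(f"m={m} exceeds {total} available profiles")
    if m == total:
        return np.arange(total), profiles

    flat_idx = int(np.nonzero((profiles == 0).all(axis=1))[0][0])
    selected = [flat_idx]
    P = profiles.astype(float)
    if metric == "euclidean":
        dist_to_sel = np.linalg.norm(P - P[flat_idx], axis=1)
    elif metric == "pearson":
        dist_to_sel = pearson_distance(P, P[flat_idx : flat_idx + 1])[:, 0]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    for _ in range(m - 1):
        dist_to_sel[selected] = -np.inf
        nxt = int(np.argmax(dist_to_sel))
        selected.append(nxt)
        if metric == "euclidean":
            d_new = np.linalg.norm(P - P[nxt], axis=1)
        else:
            d_new = pearson_distance(P, P[nxt : nxt + 1])[:, 0]
        dist_to_sel = np.minimum(dist_to_sel, d_new)
    idx = np.array(selected)
    return idx, profiles[idx]


def assign_genes(U: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Assign each median profile (row of U) to its nearest candidate.

    Distance is 1 - Pearson correlation; ties are broken by the lowest
    candidate index.
    """
    D = pearson_distance(np.atleast_2d(U), candidates)
    return np.argmin(D, axis=1)


def permutation_significance(
    data: TimeCourseExperiment | np.ndarray,
    candidates: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    c: int | None = None,
) -> StemResult:
    """Permutation test for how many genes each candidate attracts at random.

    The null hypothesis is the absence of temporal structure: each
    permutation shuffles the time order of every gene's median profile
    independently and re-runs the assignment.  The candidate-level p-value is
    the fraction of orderings (the observed one included, so p >= 1/(n_perm+1)
    and the test is exactly valid) in which the candidate attracts at least
    as many genes as observed; significance applies a Bonferroni correction
    over the m candidates at level ``alpha``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    U = median_profiles(data) if isinstance(data, TimeCourseExperiment) else np.asarray(data, dtype=float)
    m = candidates.shape[0]
    n = U.shape[1]
    rng = np.random.default_rng(seed)

    assignment = assign_genes(U, candidates)
    observed = np.bincount(assignment, minlength=m)

    # Pearson z-scores are permutation-equivariant: permuting a row permutes
    # its z-scores, so standardise once and shuffle the z rows.
    mu = U.mean(axis=1, keepdims=True)
    sd = U.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (U - mu) / sd
    Z[np.repeat(sd == 0, n, axis=1)] = 0.0
    mu_c = candidates.mean(axis=1, keepdims=True)
    sd_c = candidates.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Zc = (candidates - mu_c) / sd_c
    Zc[np.repeat(sd_c == 0, n, axis=1)] = 0.0

    counts = np.empty((n_perm, m), dtype=int)
    for p in range(n_perm):
        order = np.argsort(rng.random(U.shape), axis=1)
        Zp = np.take_along_axis(Z, order, axis=1)
        corr = Zp @ Zc.T / n
        perm_assign = np.argmax(corr, axis=1)
        counts[p] = np.bincount(perm_assign, minlength=m)

    expected = counts.mean(axis=0)
    p_values = (1.0 + (counts >= observed).sum(axis=0)) / (1.0 + n_perm)
    significant = p_values <= alpha / m
    return StemResult(
        c=c if c is not None else int(np.abs(np.diff(candidates, axis=1)).max()),
        m=m,
        candidates=candidates,
        assignment=assignment,
        observed_counts=observed,
        expected_counts=expected,
        p_values=p_values,
        significant=significant,
        alpha=alpha,
        n_permutations=n_perm,
    )
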