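"""Partitioning Around Medoids with gap-statistic model selection.

PAM is implemented as the classic BUILD + SWAP local search of Kaufman &
Rousseeuw: BUILD greedily seeds k medoids to minimise total point-to-medoid
distance, SWAP then repeatedly applies the best strictly improving
(medoid, non-medoid) exchange.  Because single-exchange local search can
stall in non-global optima, the search is additionally restarted from a few
seeded random medoid subsets by default.  Everything is deterministic for a
fixed input row order (ties resolved by lowest index), so results are
exactly reproducible.

The number of clusters is chosen with the gap statistic: the log
within-cluster dispersion of the PAM solution is compared against its
expectation under B reference data sets drawn uniformly over each feature's
observed range.  Dispersion W_k is the PAM objective itself (total distance
to medoid), keeping the selection criterion aligned with what the clusterer
optimises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = ["ClusterResult", "GapCurve", "pam", "gap_statistic", "select_k"]


@dataclass
class ClusterResult:
    """A k-medoid partition.

    ``assignment[i]`` is the cluster index of point i; cluster j's medoid is
    row ``medoids[j]`` of the feature matrix.  ``objective`` is the summed
    distance of every point to its medoid.
    """

    k: int
    assignment: np.ndarray
    medoids: np.ndarray
    objective: float
    per_gene_distance: np.ndarray
    gene_ids: list[str] | None = None

    def cluster_members(self, j: int) -> np.ndarray:
        return np.nonzero(self.assignment == j)[0]


@dataclass
class GapCurve:
    """Gap statistic over a range of k, with its Monte-Carlo error term."""

    k_values: np.ndarray
    gap: np.ndarray
    s: np.ndarray
    log_w: np.ndarray
    log_w_ref: np.ndarray
    elbow_candidates: list[int] = field(default_factory=list)


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-medoid assignment; ties go to the lowest cluster index."""
    dm = D[:, medoids]  # (n, k)
    assignment = np.argmin(dm, axis=1)  # argmin picks first minimum
    return assignment, dm[np.arange(D.shape[0]), assignment]


def _build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    first = int(np.argmin(D.sum(axis=0)))
    medoids = [first]
    dmin = D[:, first].copy()
    for _ in range(k - 1):
        # gain of adding candidate j: sum of positive reductions in dmin
        gains = np.maximum(dmin[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        nxt = int(np.argmax(gains))
        medoids.append(nxt)
        dmin = np.minimum(dmin, D[:, nxt])
    return sorted(medoids)


def _swap(D: np.ndarray, medoids: list[int]) -> list[int]:
    n = D.shape[0]
    medoids = sorted(medoids)
    current = _assign(D, np.array(medoids))[1].sum()
    while True:
        best = (current, None, None)
        med_arr = np.array(medoids)
        for mi, m in enumerate(medoids):
            others = np.delete(med_arr, mi)
            if others.size:
                dmin_excl = D[:, others].min(axis=1)
            else:
                dmin_excl = np.full(n, np.inf)
            # objective after swapping m for every candidate h, vectorised
            obj_h = np.minimum(dmin_excl[:, None], D).sum(axis=0)
            obj_h[med_arr] = np.inf
            h = int(np.argmin(obj_h))
            if obj_h[h] < best[0] - 1e-12:
                best = (obj_h[h], mi, h)
        if best[1] is None:
            return medoids
        current = best[0]
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)


def pam(
    X: np.ndarray,
    k: int,
    metric: str = "euclidean",
    gene_ids: list[str] | None = None,
    n_restarts: int = 10,
    restart_seed: int = 0,
) -> ClusterResult:
    """Cluster rows of ``X`` around k medoids (BUILD then SWAP).

    SWAP is a single-exchange local search and can stall in a non-global
    local optimum, so in addition to the BUILD seeding the search is restarted
    from ``n_restarts`` random medoid subsets (drawn from a fixed
    ``restart_seed``) and the lowest-objective solution is kept; set
    ``n_restarts=0`` for the plain BUILD+SWAP algorithm.  Everything is
    deterministic for a fixed input row order: ties in seeding, swapping and
    assignment are broken by the lowest row index, and the BUILD solution
    wins ties against restarts.  Duplicate rows are allowed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} points")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    D = cdist(X, X, metric=metric)
    medoids = _swap(D, _build(D, k))
    best_obj = _assign(D, np.array(medoids))[1].sum()
    rng = np.random.default_rng(restart_seed)
    for _ in range(n_restarts):
        start = sorted(rng.choice(n, size=k, replace=False).tolist())
        cand = _swap(D, start)
        obj = _assign(D, np.array(cand))[1].sum()
        if obj < best_obj - 1e-12:
            best_obj, medoids = obj, cand
    med_arr = np.array(medoids)
    assignment, dist = _assign(D, med_arr)
    return ClusterResult(
        k=k,
        assignment=assignment,
        medoids=med_arr,
        objective=float(dist.sum()),
        per_gene_distance=dist,
        gene_ids=gene_ids,
    )


def _within_dispersion(X: np.ndarray, k: int, metric: str) -> float:
    return pam(X, k, metric=metric).objective


def gap_statistic(
    X: np.ndarray,
    k_range: range | list[int],
    B: int = 100,
    seed: int | None = None,
    metric: str = "euclidean",
    rule: str = "one_se",
) -> GapCurve:
    """Gap statistic gap(k) = E*[log W*_k] - log W_k over ``k_range``.

    References are drawn uniformly over each feature's observed range
    (constant columns carry no spread and are held fixed, with a warning).
    ``s`` is the reference-set standard deviation of log W* inflated by
    sqrt(1 + 1/B) to account for Monte-Carlo error.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    k_values = np.array(sorted(k_range))
    n = X.shape[0]
    if k_values[0] < 1 or k_values[-1] > n - 1:
        raise ValueError("k_range must lie within [1, n_points - 1]")
    if B < 10:
        raise ValueError("need at least 10 reference sets")
    lo, hi = X.min(axis=0), X.max(axis=0)
    constant = hi == lo
    if constant.any():
        logger.warning(
            "%d constant feature column(s) excluded from reference ranges",
            int(constant.sum()),
        )
    rng = np.random.default_rng(seed)

    log_w = np.array(
        [np.log(max(_within_dispersion(X, k, metric), 1e-300)) for k in k_values]
    )
    log_w_star = np.empty((B, k_values.size))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref[:, constant] = lo[constant]
        for j, k in enumerate(k_values):
            log_w_star[b, j] = np.log(max(_within_dispersion(ref, k, metric), 1e-300))
    gap = log_w_star.mean(axis=0) - log_w
    s = log_w_star.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    curve = GapCurve(
        k_values=k_values, gap=gap, s=s, log_w=log_w, log_w_ref=log_w_star.mean(axis=0)
    )
    curve.elbow_candidates = _elbow_candidates(curve, rule)
    return curve


def _elbow_candidates(curve: GapCurve, rule: str = "one_se") -> list[int]:
    """All k satisfying the one-standard-error stopping inequality.

    ``rule="one_se"`` uses gap(k) > gap(k+1) - s_k; ``rule="tibshirani"`` uses
    the canonical gap(k) >= gap(k+1) - s_{k+1}.  The last k in the range has
    no successor and cannot be evaluated.
    """
    out = []
    for j in range(curve.k_values.size - 1):
        if rule == "one_se":
            ok = curve.gap[j] > curve.gap[j + 1] - curve.s[j]
        elif rule == "tibshirani":
            ok = curve.gap[j] >= curve.gap[j + 1] - curve.s[j + 1]
        else:
            raise ValueError(f"unknown rule {rule!r}")
        if ok:
            out.append(int(curve.k_values[j]))
    return out


def select_k(curve: GapCurve, rule: str = "one_se") -> tuple[int | None, list[int]]:
    """Smallest k satisfying the stopping rule, plus all satisfying k.

    Several elbow candidates are typically inspected side by side (with
    homogeneity and silhouette) before settling on one; the full candidate
    list supports that workflow.  Returns ``(None, [])`` with a log message
    when no k satisfies the rule.
    """
    candidates = _elbow_candidates(curve, rule)
    if not candidates:
        logger.info("no k in %s satisfies the gap stopping rule", list(curve.k_values))
        return None, []
    return candidates[0], candidates
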