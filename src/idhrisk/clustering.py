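"""DTW distance and k-medoids clustering of session RBV trajectories.

Sessions are clustered on their raw per-minute RBV series (%) — the level
carries the signal, so no z-normalisation — using classic dynamic time
warping (absolute-difference local cost, diagonal/horizontal/vertical unit
steps, optionally a Sakoe–Chiba band).  k-medoids (PAM-style greedy swap on
the precomputed distance matrix) is used because DTW admits no well-defined
mean; average-linkage hierarchical clustering is available as an alternative.
The cluster with the lowest session-level IDH incidence becomes the low-risk
reference; all others are merged into the high-risk group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

try:  # numba accelerates the O(n*m) DP; a pure-python fallback keeps tiny runs working
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _dtw_cost(a, b, band):  # pragma: no cover - exercised via dtw_distance
    n = a.shape[0]
    m = b.shape[0]
    inf = np.inf
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(m + 1):
        prev[j] = inf
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[0] = inf
        jlo = 1
        jhi = m
        if band >= 0:
            jlo = max(1, i - band)
            jhi = min(m, i + band)
        for j in range(1, m + 1):
            cur[j] = inf
        for j in range(jlo, jhi + 1):
            c = abs(a[i - 1] - b[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        for j in range(m + 1):
            prev[j] = cur[j]
    return prev[m]


def dtw_distance(a: Sequence[float], b: Sequence[float], band: Optional[int] = None) -> float:
    """Accumulated cost of the optimal DTW alignment of two series.

    ``band`` is an optional Sakoe–Chiba radius (in samples); ``None`` means
    unconstrained alignment.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw_distance requires non-empty series")
    eff_band = -1 if band is None else max(int(band), abs(a.size - b.size))
    return float(_dtw_cost(a, b, eff_band))


def dtw_matrix(series: Sequence[np.ndarray], band: Optional[int] = None) -> np.ndarray:
    """Symmetric pairwise DTW distance matrix."""
    n = len(series)
    arrs = [np.ascontiguousarray(s, dtype=np.float64) for s in series]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(arrs[i], arrs[j], band)
    return D


@dataclass
class ClusterResult:
    """k-medoids partition of sessions with IDH incidence and risk groups."""

    session_ids: List[str]
    labels: np.ndarray  # cluster id 1..k per session
    medoid_ids: List[str]
    counts: Dict[int, int]
    incidence: Dict[int, float]  # session-level IDH incidence per cluster
    risk_group: Dict[int, str]  # cluster -> "high" | "low"
    total_cost: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session_id": self.session_ids,
                "cluster": self.labels,
                "risk_group": [self.risk_group[c] for c in self.labels],
            }
        )

    def risk_by_session(self) -> Dict[str, str]:
        return dict(zip(self.session_ids, (self.risk_group[c] for c in self.labels)))


def _pam(D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int) -> tuple[np.ndarray, float]:
    """One PAM run: random init then greedy best-swap until no improvement."""
    n = D.shape[0]
    medoids = np.sort(rng.choice(n, size=k, replace=False))

    def cost(meds):
        return D[:, meds].min(axis=1).sum()

    current = cost(medoids)
    for _ in range(max_iter):
        best_delta = 0.0
        best_swap = None
        med_set = set(medoids.tolist())
        for mi, m in enumerate(medoids):
            trial = medoids.copy()
            for o in range(n):
                if o in med_set:
                    continue
                trial[mi] = o
                c = cost(trial)
                if c < current + best_delta - 1e-12:
                    best_delta = c - current
                    best_swap = (mi, o)
            trial[mi] = m
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        medoids = np.sort(medoids)
        current = cost(medoids)
    return medoids, float(current)


def cluster_trajectories(
    sessions: Sequence,
    k: int = 3,
    n_init: int = 5,
    max_iter: int = 100,
    seed: int = 0,
    band: Optional[int] = None,
    method: str = "kmedoids",
    precomputed: Optional[np.ndarray] = None,
) -> ClusterResult:
    """Cluster sessions by the DTW distance between their RBV trajectories.

    ``sessions`` are :class:`idhrisk.core.SessionRecord` objects (their
    ``rbv_pct`` series may differ in length; DTW handles that natively).
    ``method`` is ``"kmedoids"`` (default) or ``"average"`` (hierarchical,
    average linkage, cut at k clusters).  Deterministic given ``seed``.
    """
    n = len(sessions)
    if n < k:
        raise ValueError(f"need at least k={k} sessions, got {n}")
    for s in sessions:
        if s.rbv_pct.size < 30:
            raise ValueError(f"{s.session_id}: RBV series shorter than 30 min")
    ids = [s.session_id for s in sessions]
    D = precomputed if precomputed is not None else dtw_matrix([s.rbv_pct for s in sessions], band)

    if method == "kmedoids":
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_init):
            medoids, c = _pam(D, k, rng, max_iter)
            if best is None or c < best[1] - 1e-12 or (
                abs(c - best[1]) <= 1e-12 and tuple(medoids) < tuple(best[0])
            ):
                best = (medoids, c)
        medoids, total_cost = best
        assign = np.argmin(D[:, medoids], axis=1)
        labels = assign + 1  # clusters ordered by medoid index: deterministic
        medoid_ids = [ids[m] for m in medoids]
    elif method == "average":
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        Z = linkage(squareform(D, checks=False), method="average")
        labels = fcluster(Z, k, criterion="maxclust")
        medoid_ids = []
        total_cost = float("nan")
        for c in np.unique(labels):
            idx = np.where(labels == c)[0]
            medoid_ids.append(ids[idx[np.argmin(D[np.ix_(idx, idx)].sum(axis=1))]])
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    any_idh = {s.session_id: s.labels().any_idh for s in sessions}
    counts = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    incidence = {
        int(c): float(np.mean([any_idh[ids[i]] for i in np.where(labels == c)[0]]))
        for c in np.unique(labels)
    }
    risk = assign_risk_groups(incidence, counts)
    return ClusterResult(
        session_ids=ids,
        labels=np.asarray(labels, dtype=int),
        medoid_ids=medoid_ids,
        counts=counts,
        incidence=incidence,
        risk_group=risk,
        total_cost=float(total_cost),
    )


def assign_risk_groups(
    incidence: Dict[int, float], counts: Optional[Dict[int, int]] = None
) -> Dict[int, str]:
    """Map clusters to risk groups: the lowest-IDH-incidence cluster is low-risk.

    Generalises the published 2-vs-1 merge to any k.  Ties on incidence are
    broken toward the larger cluster (then the smaller cluster id).
    """
    if not incidence:
        raise ValueError("no clusters to assign")
    counts = counts or {c: 0 for c in incidence}

    def key(c):
        return (incidence[c], -counts.get(c, 0), c)

    low = min(incidence, key=key)
    return {c: ("low" if c == low else "high") for c in incidence}
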