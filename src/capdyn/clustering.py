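"""Co-activation-pattern extraction: PAM k-medoids in correlation distance.

Individual fMRI frames are points in an N-dimensional regional
activation space; recurring co-activation patterns are found by
partitioning the frames around medoids under the correlation distance
d = 1 - Pearson r. Because the Pearson correlation of two frames is the
dot product of their centered, unit-norm versions, all pairwise
distances reduce to matrix products of an N x T "frame factor" with
itself: the PAM build and swap phases below exploit that to run on
cohort-scale point clouds (tens of thousands of frames) without ever
holding more than a chunk of the T x T distance matrix when T is large.

The module also carries the full K-selection battery (explained
variance, variance gain, medoid silhouette, per-subject state absence,
centroid overlap), split-half stability, Hungarian state matching, and
the cosine mapping of states onto resting-state networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datatypes import ConcatenatedDataset, ParcellationTable, ValidationError

logger = logging.getLogger(__name__)

_TOL = 1e-10


def correlation_distance(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Correlation distance d = 1 - Pearson r between two frames.

    Ranges over [0, 2]: identical patterns give 0, sign-flipped patterns
    give 2. Constant frames have undefined correlation and are rejected.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValidationError("frames must be equal-length 1-D vectors of size >= 3")
    for name, v in (("first", a), ("second", b)):
        if np.std(v) == 0:
            raise ValidationError(f"{name} frame is constant; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - r


def _as_matrix(dataset: ConcatenatedDataset | np.ndarray) -> np.ndarray:
    if isinstance(dataset, ConcatenatedDataset):
        return dataset.matrix
    return np.asarray(dataset, dtype=float)


class _CorrDistance:
    """Chunked correlation-distance provider over the frames of a dataset.

    Stores centered unit-norm frames (N x T); d(i, j) = 1 - f_i . f_j.
    For small T the full distance matrix is cached.
    """

    def __init__(self, dataset: ConcatenatedDataset | np.ndarray,
                 precompute_limit: int = 10000):
        x = _as_matrix(dataset)
        if x.shape[0] < 3:
            raise ValidationError("need at least 3 ROIs for correlation distance")
        centered = x - x.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(centered, axis=0)
        bad = norms == 0
        if bad.any():
            raise ValidationError(
                f"constant frame(s) at columns {np.flatnonzero(bad)[:5].tolist()}: "
                "correlation distance undefined"
            )
        self.frames = centered / norms
        self.n_frames = x.shape[1]
        self._full: np.ndarray | None = None
        if self.n_frames <= precompute_limit:
            # float32 cache above ~3000 frames: the swap sweeps are memory
            # bound and distances are O(1), so single precision costs ~1e-7
            # absolute while halving traffic; small instances stay exact
            dtype = np.float32 if self.n_frames > 3000 else np.float64
            f = self.frames.astype(dtype)
            d = dtype(1.0) - f.T @ f
            np.fill_diagonal(d, 0.0)
            self._full = np.clip(d, 0.0, 2.0)
        # chunk rows so a block stays around ~64 MB
        self.chunk = max(256, int(8e6 / max(self.n_frames, 1)))

    def rows(self, idx: np.ndarray | list[int]) -> np.ndarray:
        """Distance rows d(idx, :) as a dense (len(idx), T) block."""
        idx = np.asarray(idx, dtype=int)
        if self._full is not None:
            return self._full[idx]
        d = 1.0 - self.frames[:, idx].T @ self.frames
        d[np.arange(idx.size), idx] = 0.0
        return np.clip(d, 0.0, 2.0)

    def block(self, lo: int, hi: int) -> np.ndarray:
        """Contiguous candidate block d(lo:hi, :); a view when cached."""
        if self._full is not None:
            return self._full[lo:hi]
        return self.rows(np.arange(lo, hi))

    def total_distances(self) -> np.ndarray:
        """Sum_j d(c, j) for every candidate c, via the rank-N identity."""
        s = self.frames.sum(axis=1)
        return self.n_frames - self.frames.T @ s

    def sum_squared_distances(self) -> np.ndarray:
        """Sum_j d(c, j)^2 for every candidate c (chunked full pass)."""
        out = np.empty(self.n_frames)
        for lo in range(0, self.n_frames, self.chunk):
            hi = min(lo + self.chunk, self.n_frames)
            d = self.rows(np.arange(lo, hi))
            out[lo:hi] = np.einsum("ij,ij->i", d, d)
        return out


@dataclass
class ClusterSolution:
    """One k-medoids partition of the concatenated point cloud.

    ``labels`` are 1-based; ``mean_centroids`` are cluster means of the
    original frames (the non-binary state patterns used downstream),
    while ``medoid_frame_indices`` point at the representative frames.
    """

    k: int
    medoid_frame_indices: np.ndarray
    labels: np.ndarray
    mean_centroids: np.ndarray
    total_within_distance: float
    restart_seed: int
    n_iterations: int = 0
    objective_history: list[float] = field(default_factory=list)


def _assign(dm: np.ndarray, medoids: np.ndarray):
    """Nearest/second-nearest medoid per frame from the k x T distance rows."""
    k = dm.shape[0]
    if k == 1:
        n1 = np.zeros(dm.shape[1], dtype=int)
        return n1, dm[0].copy(), np.full(dm.shape[1], np.inf)
    order = np.argpartition(dm, 1, axis=0)
    n1 = order[0]
    d1 = dm[n1, np.arange(dm.shape[1])]
    d2 = dm[order[1], np.arange(dm.shape[1])]
    # medoids always belong to their own cluster
    n1[medoids] = np.arange(k)
    d1[medoids] = 0.0
    return n1, d1, d2


def _build_init(dist: _CorrDistance, k: int) -> np.ndarray:
    """Greedy PAM BUILD: add the medoid with the largest marginal gain."""
    medoids = [int(np.argmin(dist.total_distances()))]
    d1 = dist.rows([medoids[0]])[0].copy()
    for _ in range(1, k):
        best_gain, best_c = -np.inf, -1
        for lo in range(0, dist.n_frames, dist.chunk):
            hi = min(lo + dist.chunk, dist.n_frames)
            dc = dist.block(lo, hi)
            gain = np.maximum(d1[None, :] - dc, 0.0).sum(axis=1)
            gain[np.isin(np.arange(lo, hi), medoids)] = -np.inf
            j = int(np.argmax(gain))
            if gain[j] > best_gain:
                best_gain, best_c = float(gain[j]), lo + j
        medoids.append(best_c)
        d1 = np.minimum(d1, dist.rows([best_c])[0])
    return np.asarray(medoids, dtype=int)


def _exact_swap_delta(dist, c, i, n1, d1, d2):
    dc = dist.rows([c])[0]
    in_i = n1 == i
    delta = np.minimum(dc - d1, 0.0)[~in_i].sum(dtype=np.float64)
    delta += (np.minimum(dc, d2) - d1)[in_i].sum(dtype=np.float64)
    return float(delta), dc


def _swap_phase(dist: _CorrDistance, medoids: np.ndarray, max_iter: int = 200):
    """PAM swap phase: evaluate all (candidate, medoid) swaps per pass.

    Per pass, the best swap per medoid is located in one chunked sweep of
    the distance rows; accepted swaps are re-verified exactly against the
    updated caches, so the objective is monotonically nonincreasing.
    """
    k = medoids.shape[0]
    medoids = medoids.copy()
    dm = dist.rows(medoids)
    n1, d1, d2 = _assign(dm, medoids)
    history = [float(d1.sum(dtype=np.float64))]
    # monotone descent is exact up to the rounding of the cache dtype
    descent_slack = 1e-8 if d1.dtype == np.float64 else 1e-3
    for _ in range(max_iter):
        onehot = np.zeros((dist.n_frames, k), dtype=d1.dtype)
        onehot[np.arange(dist.n_frames), n1] = 1.0
        best_delta = np.full(k, np.inf)
        best_cand = np.full(k, -1, dtype=int)
        for lo in range(0, dist.n_frames, dist.chunk):
            hi = min(lo + dist.chunk, dist.n_frames)
            dc = dist.block(lo, hi)
            g = dc - d1[None, :]
            np.minimum(g, 0.0, out=g)
            base = g.sum(axis=1, dtype=np.float64)
            h = np.minimum(dc, d2[None, :])
            h -= d1[None, :]
            h -= g
            delta = base[:, None] + (h @ onehot).astype(np.float64)
            delta[np.isin(np.arange(lo, hi), medoids)] = np.inf
            block_best = np.argmin(delta, axis=0)
            vals = delta[block_best, np.arange(k)]
            better = vals < best_delta
            best_delta[better] = vals[better]
            best_cand[better] = lo + block_best[better]
        improved = False
        for i in np.argsort(best_delta):
            if best_delta[i] >= -_TOL or best_cand[i] < 0:
                break
            delta_exact, dc = _exact_swap_delta(dist, best_cand[i], i, n1, d1, d2)
            if delta_exact >= -_TOL:
                continue
            medoids[i] = best_cand[i]
            dm[i] = dc
            n1, d1, d2 = _assign(dm, medoids)
            obj = float(d1.sum(dtype=np.float64))
            assert obj <= history[-1] + descent_slack, "swap increased the objective"
            history.append(obj)
            improved = True
        if not improved:
            break
        # guard: a duplicated frame chosen as two medoids can empty a cluster
        counts = np.bincount(n1, minlength=k)
        for i in np.flatnonzero(counts == 0):
            far = int(np.argmax(d1))
            logger.warning("empty cluster %d; re-seeding medoid to frame %d", i, far)
            medoids[i] = far
            dm[i] = dist.rows([far])[0]
            n1, d1, d2 = _assign(dm, medoids)
            history.append(float(d1.sum(dtype=np.float64)))
    return medoids, n1, d1, history


def kmedoids(
    dataset: ConcatenatedDataset | np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    restart_rule: str = "min",
    _dist: _CorrDistance | None = None,
) -> ClusterSolution:
    """PAM k-medoids under correlation distance.

    The first restart is initialized with the deterministic greedy BUILD
    procedure; subsequent restarts draw random initial medoid sets from
    the seeded generator. Each restart runs the swap phase to
    convergence; the returned solution is the restart minimizing the
    total within-cluster distance (``restart_rule="max"`` selects the
    maximum instead, for compatibility with a maximum-inertia reading).
    Deterministic given ``seed``. States are relabelled so medoid frame
    indices are ascending.
    """
    dist = _dist or _CorrDistance(dataset)
    t = dist.n_frames
    if k < 2:
        raise ValidationError("k must be >= 2")
    if t <= k:
        raise ValidationError(f"need more frames than clusters (T={t}, k={k})")
    if restart_rule not in ("min", "max"):
        raise ValidationError("restart_rule must be 'min' or 'max'")
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        if r == 0:
            init = _build_init(dist, k)
        else:
            init = rng.choice(t, size=k, replace=False)
        medoids, n1, d1, history = _swap_phase(dist, np.asarray(init))
        obj = float(d1.sum(dtype=np.float64))
        take = best is None or (
            obj < best[0] - _TOL if restart_rule == "min" else obj > best[0] + _TOL
        )
        if take:
            best = (obj, medoids, n1, history, r)
    obj, medoids, n1, history, r_best = best
    order = np.argsort(medoids)
    medoids = medoids[order]
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[n1] + 1
    x = _as_matrix(dataset)
    centroids = np.stack([
        x[:, labels == c + 1].mean(axis=1) for c in range(k)
    ])
    return ClusterSolution(
        k=k,
        medoid_frame_indices=medoids,
        labels=labels,
        mean_centroids=centroids,
        total_within_distance=obj,
        restart_seed=r_best,
        n_iterations=len(history) - 1,
        objective_history=history,
    )


# ---------------------------------------------------------------------------
# K-selection battery


def explained_variance(
    dataset: ConcatenatedDataset | np.ndarray,
    solution: ClusterSolution,
    _dist: _CorrDistance | None = None,
) -> float:
    """Fraction of squared correlation distance absorbed by the medoids.

    EV = 1 - sum_t d(t, medoid(t))^2 / sum_t d(t, grand medoid)^2, where
    the grand medoid minimizes the total squared distance; a k=1
    solution therefore has EV exactly 0, and k=T gives EV 1.
    """
    dist = _dist or _CorrDistance(dataset)
    dm = dist.rows(solution.medoid_frame_indices)
    d_to_own = dm[solution.labels - 1, np.arange(dist.n_frames)]
    num = float(np.sum(d_to_own**2))
    ssd = dist.sum_squared_distances()
    den = float(ssd.min())
    if den == 0:
        return 1.0
    return 1.0 - num / den


def medoid_silhouette(
    dataset: ConcatenatedDataset | np.ndarray,
    solution: ClusterSolution,
    _dist: _CorrDistance | None = None,
) -> tuple[np.ndarray, float]:
    """Per-frame medoid silhouette s = (d2 - d1) / max(d1, d2).

    d1/d2 are the distances to the nearest and second-nearest medoid;
    the degenerate 0/0 case is defined as 0 (logged).
    """
    if solution.k < 2:
        raise ValidationError("medoid silhouette needs k >= 2")
    dist = _dist or _CorrDistance(dataset)
    dm = dist.rows(solution.medoid_frame_indices)
    n1, d1, d2 = _assign(dm, solution.medoid_frame_indices)
    denom = np.maximum(d1, d2)
    zero = denom == 0
    if zero.any():
        logger.info("%d frame(s) with d1 = d2 = 0; silhouette set to 0", zero.sum())
    s = np.where(zero, 0.0, (d2 - d1) / np.where(zero, 1.0, denom))
    return s, float(s.mean())


def state_absence_fraction(
    solution: ClusterSolution, frame_subject_index: np.ndarray
) -> float:
    """Fraction of subjects with at least one state absent from their frames."""
    df = pd.DataFrame({
        "subject": np.asarray(frame_subject_index),
        "label": solution.labels,
    })
    per_subject = df.groupby("subject", sort=False)["label"].nunique()
    return float(np.mean(per_subject < solution.k))


def max_centroid_correlation(solution: ClusterSolution) -> float:
    """Largest pairwise Pearson correlation between distinct state centroids."""
    corr = np.corrcoef(solution.mean_centroids)
    off = corr[~np.eye(solution.k, dtype=bool)]
    return float(off.max()) if off.size else np.nan


@dataclass
class KSelectionReport:
    """Selection metrics over a contiguous range of k."""

    table: pd.DataFrame  # columns: k, explained_variance, variance_gain,
    #          mean_medoid_silhouette, state_absence_fraction, max_centroid_correlation
    solutions: dict[int, ClusterSolution] = field(default_factory=dict)

    def variance_gain(self, k: int) -> float:
        row = self.table.loc[self.table["k"] == k, "variance_gain"]
        return float(row.iloc[0]) if len(row) else np.nan


def scan_k(
    dataset: ConcatenatedDataset,
    k_min: int = 2,
    k_max: int = 8,
    n_restarts: int = 10,
    seed: int = 0,
) -> KSelectionReport:
    """Run k-medoids across a contiguous k range and tabulate the
    selection criteria (explained variance and its gain, mean medoid
    silhouette, per-subject state absence, centroid overlap)."""
    dist = _CorrDistance(dataset)
    rows = []
    solutions: dict[int, ClusterSolution] = {}
    prev_ev = None
    for k in range(k_min, k_max + 1):
        sol = kmedoids(dataset, k, n_restarts=n_restarts, seed=seed + k, _dist=dist)
        ev = explained_variance(dataset, sol, _dist=dist)
        _, mean_sil = medoid_silhouette(dataset, sol, _dist=dist)
        rows.append({
            "k": k,
            "explained_variance": ev,
            "variance_gain": np.nan if prev_ev is None else ev - prev_ev,
            "mean_medoid_silhouette": mean_sil,
            "state_absence_fraction": state_absence_fraction(
                sol, dataset.frame_subject_index
            ),
            "max_centroid_correlation": max_centroid_correlation(sol),
        })
        solutions[k] = sol
        prev_ev = ev
    return KSelectionReport(table=pd.DataFrame(rows), solutions=solutions)


@dataclass
class SelectionThresholds:
    gain_below: float = 0.01
    silhouette_drop_tol: float = 0.01
    absence_max: float = 0.25
    centroid_corr_max: float = 0.5


@dataclass
class KSelection:
    k: int
    conclusive: bool
    log: list[str]


def k_scan_ceiling(scan_duration_seconds: float = 600.0, tr_seconds: float = 2.1) -> int:
    """Smallest k whose k^2 possible ordered transitions exceed the frame
    count of one scan — the upper end of a meaningful k scan."""
    frames = int(round(scan_duration_seconds / tr_seconds))
    k = 2
    while k * k <= frames:
        k += 1
    return k


def select_k(
    report: KSelectionReport,
    thresholds: SelectionThresholds | None = None,
) -> KSelection:
    """Pick K: the smallest k whose variance gain has tapered (next gain
    below threshold), whose silhouette is locally maximal or plateaued,
    with acceptable per-subject state absence and centroid overlap. If no
    k satisfies all criteria the best-compromise k (highest silhouette
    among admissible-absence k) is returned flagged non-conclusive."""
    th = thresholds or SelectionThresholds()
    t = report.table.sort_values("k").reset_index(drop=True)
    ks = t["k"].to_numpy()
    if np.any(np.diff(ks) != 1):
        raise ValidationError("selection report must span a contiguous k range")
    log: list[str] = []
    for i, k in enumerate(ks):
        reasons = []
        if i + 1 < len(ks):
            next_gain = t["variance_gain"].iloc[i + 1]
            if not next_gain < th.gain_below:
                reasons.append(f"gain({k + 1})={next_gain:.4f} >= {th.gain_below}")
        else:
            reasons.append("no k+1 in range to evaluate gain taper")
        sil = t["mean_medoid_silhouette"].iloc[i]
        if i + 1 < len(ks):
            sil_next = t["mean_medoid_silhouette"].iloc[i + 1]
            if sil < sil_next - th.silhouette_drop_tol:
                reasons.append(f"silhouette rises after k={k}")
        absence = t["state_absence_fraction"].iloc[i]
        if absence > th.absence_max:
            reasons.append(f"absence {absence:.2f} > {th.absence_max}")
        corr = t["max_centroid_correlation"].iloc[i]
        if corr > th.centroid_corr_max:
            reasons.append(f"max centroid corr {corr:.2f} > {th.centroid_corr_max}")
        if not reasons:
            log.append(f"k={k}: all criteria satisfied")
            for line in log:
                logger.info("select_k: %s", line)
            return KSelection(k=int(k), conclusive=True, log=log)
        log.append(f"k={k}: rejected ({'; '.join(reasons)})")
    admissible = t[t["state_absence_fraction"] <= th.absence_max]
    pool = admissible if len(admissible) else t
    k_best = int(pool.loc[pool["mean_medoid_silhouette"].idxmax(), "k"])
    log.append(f"non-conclusive: best-compromise k={k_best} by silhouette")
    for line in log:
        logger.info("select_k: %s", line)
    return KSelection(k=k_best, conclusive=False, log=log)


# ---------------------------------------------------------------------------
# Stability and matching


@dataclass
class StateMatch:
    """Optimal bijection between two solutions' states."""

    permutation: np.ndarray  # index into B for each state of A
    matched_correlations: np.ndarray


def match_states(centroids_a: np.ndarray, centroids_b: np.ndarray) -> StateMatch:
    """Match two centroid sets by maximizing total Pearson correlation
    (Hungarian assignment), so matching is deterministic and
    order-independent."""
    a = np.atleast_2d(np.asarray(centroids_a, dtype=float))
    b = np.atleast_2d(np.asarray(centroids_b, dtype=float))
    if a.shape != b.shape:
        raise ValidationError("centroid sets must share K and N")
    k = a.shape[0]
    corr = np.corrcoef(a, b)[:k, k:]
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return StateMatch(permutation=perm, matched_correlations=corr[rows, cols])


def split_half_stability(
    dataset: ConcatenatedDataset,
    k: int,
    n_splits: int = 50,
    seed: int = 0,
    n_restarts: int = 5,
) -> np.ndarray:
    """Random split-half reliability of the extracted states.

    For each split the frames are randomly permuted and divided into two
    equal halves (one frame trimmed if T is odd, logged once); both
    halves are clustered with the same pipeline, and the matched
    centroid correlations recorded. Returns an (n_splits, k) array."""
    x = _as_matrix(dataset)
    t = x.shape[1]
    half = t // 2
    if t % 2:
        logger.info("odd frame count %d: trimming one frame per split", t)
    rng = np.random.default_rng(seed)
    out = np.empty((n_splits, k))
    for s in range(n_splits):
        perm = rng.permutation(t)
        ia, ib = perm[:half], perm[half: 2 * half]
        sol_a = kmedoids(x[:, ia], k, n_restarts=n_restarts,
                         seed=int(rng.integers(2**31)))
        sol_b = kmedoids(x[:, ib], k, n_restarts=n_restarts,
                         seed=int(rng.integers(2**31)))
        match = match_states(sol_a.mean_centroids, sol_b.mean_centroids)
        out[s] = match.matched_correlations
    return out


def map_state_to_networks(
    centroid: np.ndarray,
    parcellation: ParcellationTable,
    roi_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Cosine similarity of a state's above/below-baseline components
    with each resting-state network's indicator vector.

    The positive part x+ = max(x, 0) and the magnitude of the negative
    part |x-| are mapped separately; both similarities lie in [0, 1].
    Returns a tidy frame with columns network, positive, negative.
    """
    x = np.asarray(centroid, dtype=float)
    if roi_labels is not None:
        nets = parcellation.labels_for(roi_labels)
    else:
        if len(parcellation.table) != x.size:
            raise ValidationError("centroid length does not match parcellation")
        nets = parcellation.table["network"].to_numpy()
    pos = np.maximum(x, 0.0)
    neg = np.abs(np.minimum(x, 0.0))
    rows = []
    for network in parcellation.networks:
        g = (nets == network).astype(float)
        rows.append({
            "network": network,
            "positive": _cosine(pos, g),
            "negative": _cosine(neg, g),
        })
    return pd.DataFrame(rows)


def _cosine(v: np.ndarray, g: np.ndarray) -> float:
    nv, ng = np.linalg.norm(v), np.linalg.norm(g)
    if nv == 0 or ng == 0:
        logger.info("all-zero component in cosine mapping; similarity set to 0")
        return 0.0
    return float(v @ g / (nv * ng))
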