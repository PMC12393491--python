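"""Temporal statistics of per-subject brain-state sequences.

All metrics are computed strictly within one subject's scan — a cohort
label vector is first cut at subject boundaries, so no phantom switches
are counted across subjects. Transition probabilities are joint switch
probabilities: the count of i->j switches divided by the TOTAL number of
switches (self-transition frame pairs are discarded first). Under the
alternative per-row conditioning every subject's exit probability would
be identically 1/(K-1); the joint convention is what lets exit and
enter probabilities vary across subjects and groups. The row-conditional
variant remains available via ``normalization="row"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ConcatenatedDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class StateSequence:
    """Frame-wise state labels (1..K) for one subject's scan."""

    subject_id: str
    labels: np.ndarray
    k: int
    tr_seconds: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size < 1:
            raise ValidationError(f"{self.subject_id}: empty state sequence")
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValidationError(f"{self.subject_id}: labels outside 1..{self.k}")
        if self.tr_seconds <= 0:
            raise ValidationError(f"{self.subject_id}: TR must be positive")


def sequences_from_solution(
    dataset: ConcatenatedDataset, labels: np.ndarray, k: int
) -> list[StateSequence]:
    """Cut a cohort-level label vector into per-subject sequences."""
    labels = np.asarray(labels, dtype=int)
    out = []
    for sid in dataset.subject_ids:
        idx = dataset.frames_of(sid)
        out.append(StateSequence(
            subject_id=str(sid),
            labels=labels[idx],
            k=k,
            tr_seconds=dataset.tr_by_subject[str(sid)],
        ))
    return out


def run_lengths(labels: np.ndarray) -> dict[int, list[int]]:
    """Maximal constant runs, grouped by state.

    The lengths of each state's runs sum to that state's frame count.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValidationError("empty label vector")
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    out: dict[int, list[int]] = {}
    for s, e in zip(starts, ends):
        out.setdefault(int(labels[s]), []).append(int(e - s))
    return out


def dwell_time(sequence: StateSequence) -> np.ndarray:
    """Mean duration (seconds) of consecutive stays in each state.

    States never visited get NaN (missing, not zero) so group averages
    are not biased toward zero; callers exclude them from tests.
    """
    runs = run_lengths(sequence.labels)
    out = np.full(sequence.k, np.nan)
    for state, lens in runs.items():
        out[state - 1] = float(np.mean(lens)) * sequence.tr_seconds
    missing = np.flatnonzero(np.isnan(out))
    if missing.size:
        logger.info(
            "%s: state(s) %s never visited; dwell time reported as missing",
            sequence.subject_id, (missing + 1).tolist(),
        )
    return out


def fractional_occupancy(sequence: StateSequence) -> np.ndarray:
    """Percentage of frames assigned to each state (sums to 100)."""
    counts = np.bincount(sequence.labels - 1, minlength=sequence.k)
    return 100.0 * counts / sequence.labels.size


def transition_probabilities(
    sequence: StateSequence, normalization: str = "joint"
) -> tuple[np.ndarray, int]:
    """K x K switch probabilities with zero diagonal.

    Frame pairs (t, t+1) with no label change are discarded; with
    ``normalization="joint"`` (default) each count of i->j switches is
    divided by the total switch count, so the off-diagonal sums to 1;
    ``"row"`` conditions each row on its source state instead. Returns
    the matrix and the number of switches; a switch-free sequence yields
    an all-zero matrix (flagged by n_switches == 0).
    """
    if normalization not in ("joint", "row"):
        raise ValidationError("normalization must be 'joint' or 'row'")
    lab = sequence.labels
    src, dst = lab[:-1], lab[1:]
    moved = src != dst
    n_switches = int(moved.sum())
    counts = np.zeros((sequence.k, sequence.k))
    np.add.at(counts, (src[moved] - 1, dst[moved] - 1), 1.0)
    if n_switches == 0:
        logger.info("%s: no state switches; zero transition matrix",
                    sequence.subject_id)
        return counts, 0
    if normalization == "joint":
        p = counts / n_switches
    else:
        row = counts.sum(axis=1, keepdims=True)
        row[row == 0] = 1.0
        p = counts / row
    return p, n_switches


def exit_probability(p: np.ndarray, state: int) -> float:
    """Mean of P(state -> j) over the other states j (1-based state)."""
    k = p.shape[0]
    i = state - 1
    others = [j for j in range(k) if j != i]
    return float(np.mean(p[i, others]))


def enter_probability(p: np.ndarray, state: int) -> float:
    """Mean of P(j -> state) over the other states j (1-based state)."""
    k = p.shape[0]
    i = state - 1
    others = [j for j in range(k) if j != i]
    return float(np.mean(p[others, i]))


@dataclass
class DynamicsSummary:
    """All temporal metrics for one subject."""

    subject_id: str
    dwell_time: np.ndarray  # seconds, NaN for unvisited states
    fractional_occupancy: np.ndarray  # percent, sums to 100
    transition_probabilities: np.ndarray  # zero diagonal
    exit_probability: np.ndarray
    enter_probability: np.ndarray
    n_switches: int


def summarize(sequence: StateSequence, normalization: str = "joint") -> DynamicsSummary:
    p, n_switches = transition_probabilities(sequence, normalization)
    k = sequence.k
    return DynamicsSummary(
        subject_id=sequence.subject_id,
        dwell_time=dwell_time(sequence),
        fractional_occupancy=fractional_occupancy(sequence),
        transition_probabilities=p,
        exit_probability=np.array([exit_probability(p, s + 1) for s in range(k)]),
        enter_probability=np.array([enter_probability(p, s + 1) for s in range(k)]),
        n_switches=n_switches,
    )


def cohort_table(summaries: list[DynamicsSummary]) -> pd.DataFrame:
    """Long-format cohort table keyed by subject, state, metric."""
    rows = []
    for s in summaries:
        for state in range(s.fractional_occupancy.size):
            rows.append({
                "subject": s.subject_id,
                "state": state + 1,
                "dwell_time_s": s.dwell_time[state],
                "fractional_occupancy_pct": s.fractional_occupancy[state],
                "exit_probability": s.exit_probability[state],
                "enter_probability": s.enter_probability[state],
            })
    return pd.DataFrame(rows)


def transition_table(summaries: list[DynamicsSummary]) -> pd.DataFrame:
    """Long-format per-pair transition probabilities across subjects."""
    rows = []
    for s in summaries:
        k = s.transition_probabilities.shape[0]
        for i in range(k):
            for j in range(k):
                if i != j:
                    rows.append({
                        "subject": s.subject_id,
                        "from_state": i + 1,
                        "to_state": j + 1,
                        "probability": s.transition_probabilities[i, j],
                    })
    return pd.DataFrame(rows)


def permutation_null_transitions(
    sequence: StateSequence,
    n_perm: int = 1000,
    seed: int = 0,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Permutation test of each pair's transition probability.

    The null permutes the ORDER of the sequence's maximal runs, which
    preserves the run-length multiset and every state's occupancy while
    destroying which state follows which. Adjacent same-state runs that
    arise under permutation merge naturally (they contribute no switch).
    p = (1 + #{null >= observed}) / (1 + n_perm); the two-sided option
    doubles the smaller tail. Sequences with fewer than 3 runs carry no
    permutable order and are skipped with a flag.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    obs, n_switch = transition_probabilities(sequence)
    k = sequence.k
    runs_states = []
    lab = sequence.labels
    change = np.flatnonzero(np.diff(lab) != 0)
    starts = np.concatenate(([0], change + 1))
    runs_states = lab[starts]
    if runs_states.size < 3:
        logger.info("%s: fewer than 3 runs; permutation test skipped",
                    sequence.subject_id)
        return pd.DataFrame(
            columns=["from_state", "to_state", "observed", "p_value", "skipped"]
        )
    rng = np.random.default_rng(seed)
    ge = np.zeros((k, k))
    le = np.zeros((k, k))
    for _ in range(n_perm):
        perm = rng.permutation(runs_states)
        src, dst = perm[:-1], perm[1:]
        moved = src != dst
        total = moved.sum()
        counts = np.zeros((k, k))
        if total:
            np.add.at(counts, (src[moved] - 1, dst[moved] - 1), 1.0)
            counts /= total
        ge += counts >= obs - 1e-15
        le += counts <= obs + 1e-15
    rows = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            p_ge = (1.0 + ge[i, j]) / (1.0 + n_perm)
            p_le = (1.0 + le[i, j]) / (1.0 + n_perm)
            p = min(1.0, 2.0 * min(p_ge, p_le)) if two_sided else p_ge
            rows.append({
                "from_state": i + 1, "to_state": j + 1,
                "observed": obs[i, j], "p_value": p, "skipped": False,
            })
    return pd.DataFrame(rows)
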