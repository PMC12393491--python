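"""Synthetic resting-state cohorts with planted brain-state structure.

The generator emits everything the analysis consumes — per-subject ROI x
frame BOLD matrices, modular weighted connectomes, parcellation and
clinical tables — from a known ground truth: K planted co-activation
patterns visited through a Markov state sequence, with AR(1) Gaussian
noise on top. Group membership changes only the transition matrix, and
clinical scores are linearly coupled to the planted fractional occupancy
of a designated state, so every downstream stage (clustering, dynamics,
control energy, inference) has a recoverable target.

Defaults mirror a 7T resting-state depression cohort: 38 + 38 subjects,
85 ROIs over 8 resting-state networks, 286 frames at TR 2.1 s, K = 4
states.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, sparse

from .datatypes import (
    CLINICAL_SCORE_COLUMNS,
    ClinicalTable,
    Connectome,
    ParcellationTable,
    RegionalTimeSeries,
    RSN_LABELS,
    ValidationError,
)

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-12

#: Per-state network sign design used for the default K=4 patterns:
#: (positive networks, negative networks). State 1 is visually/attention
#: driven, state 2 fronto-default, state 3 salience/somatomotor with
#: suppressed default-mode, state 4 limbic-default.
DEFAULT_STATE_DESIGN = (
    (("VIS", "DAT"), ("SOM", "DMN", "LIM")),
    (("FPN", "DMN"), ("VIS", "DAT")),
    (("VAT", "SOM", "SUB"), ("DMN", "FPN")),
    (("LIM", "DMN", "VIS"), ("VAT", "FPN", "SUB")),
)


def default_network_partition(n_rois: int) -> np.ndarray:
    """Assign ``n_rois`` ROIs to the 8 canonical networks in contiguous
    blocks of near-equal size."""
    base, rem = divmod(n_rois, len(RSN_LABELS))
    sizes = [base + (1 if i >= len(RSN_LABELS) - rem else 0)
             for i in range(len(RSN_LABELS))]
    return np.repeat(RSN_LABELS, sizes)


def default_transition_matrices(k_states: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Planted group-specific Markov matrices (rows: from-state).

    The patient group dwells less in state 3 (lower self-transition),
    switches in and out of it more (especially 2<->3), and transitions
    between states 1 and 4 less often than controls. For K other than 4
    a generic analogue is built: uniform off-diagonal switching for
    controls, with the patient group destabilized on one designated
    state.
    """
    if k_states != 4:
        if k_states < 2:
            raise ValidationError("need at least 2 states")
        k = k_states
        hc = np.full((k, k), 0.25 / (k - 1))
        np.fill_diagonal(hc, 0.75)
        mdd = np.full((k, k), 0.25 / (k - 1))
        np.fill_diagonal(mdd, 0.75)
        target = min(2, k - 1)  # 0-based designated state
        mdd[target, :] = 0.35 / (k - 1)
        mdd[target, target] = 0.65
        return hc, mdd
    hc = np.array([
        [0.75, 0.07, 0.07, 0.11],
        [0.085, 0.75, 0.08, 0.085],
        [0.085, 0.08, 0.75, 0.085],
        [0.11, 0.07, 0.07, 0.75],
    ])
    mdd = np.array([
        [0.75, 0.09, 0.09, 0.07],
        [0.07, 0.75, 0.12, 0.06],
        [0.085, 0.18, 0.65, 0.085],
        [0.07, 0.09, 0.09, 0.75],
    ])
    return hc, mdd


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``clinical_coupling`` maps planted fractional occupancy (percent) of
    ``coupled_state`` to the mean of each score column, in score units
    per percentage point.
    """

    k_states: int = 4
    n_rois: int = 85
    n_subjects_per_group: int = 38
    frames_per_subject: int = 286
    tr_seconds: float = 2.1
    ar_coefficient: float = 0.45
    noise_sd: float = 1.0
    group_transition_matrices: tuple[np.ndarray, np.ndarray] = field(
        default_factory=default_transition_matrices
    )
    clinical_coupling: np.ndarray = field(
        default_factory=lambda: np.array([0.5, 0.5, 0.3, 0.3, 0.3, 0.3, 0.2])
    )
    clinical_noise_sd: float = 2.0
    coupled_state: int = 3  # 1-based state whose occupancy drives scores
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if not 0 <= self.ar_coefficient < 1:
            raise ValidationError("ar_coefficient must be in [0, 1)")
        if self.frames_per_subject < self.k_states:
            raise ValidationError("frames_per_subject must be >= k_states")
        self.clinical_coupling = np.asarray(self.clinical_coupling, dtype=float)
        if (self.k_states != 4
                and np.shape(self.group_transition_matrices[0])[0] != self.k_states):
            # factory default is the 4-state design; rebuild for this K
            self.group_transition_matrices = default_transition_matrices(self.k_states)
        self.coupled_state = min(self.coupled_state, self.k_states)
        mats = []
        for m in self.group_transition_matrices:
            m = np.asarray(m, dtype=float)
            _check_stochastic(m, self.k_states)
            mats.append(m)
        self.group_transition_matrices = (mats[0], mats[1])


def _check_stochastic(m: np.ndarray, k: int | None = None) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"transition matrix must be square, got {m.shape}")
    if k is not None and m.shape[0] != k:
        raise ValidationError(f"transition matrix is {m.shape[0]}x{m.shape[0]}, expected {k}")
    if np.any(m < 0):
        raise ValidationError("transition matrix has negative entries")
    bad = np.abs(m.sum(axis=1) - 1.0) > _ROW_SUM_TOL
    if bad.any():
        raise ValidationError(
            f"transition matrix rows {np.flatnonzero(bad).tolist()} do not sum to 1"
        )


@dataclass
class CohortBundle:
    """Everything a pipeline run consumes, in memory."""

    subjects: list[RegionalTimeSeries]
    connectomes: list[Connectome]
    clinical: ClinicalTable
    parcellation: ParcellationTable


@dataclass
class SyntheticGroundTruth:
    """Planted quantities recovery tests compare against."""

    centroids: np.ndarray  # K x N, z-scored across ROIs
    state_sequences: dict[str, np.ndarray]  # subject -> 1-based labels
    specified_transition_matrices: dict[str, np.ndarray]  # group -> K x K
    realized_transition_matrices: dict[str, np.ndarray]  # group -> K x K
    fractional_occupancy: dict[str, np.ndarray]  # subject -> percent per state
    clinical_coupling: np.ndarray
    coupled_state: int


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary law of an ergodic Markov chain (left unit eigenvector)."""
    m = np.asarray(transition_matrix, dtype=float)
    _check_stochastic(m)
    vals, vecs = np.linalg.eig(m.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def generate_state_patterns(
    k_states: int,
    n_rois: int,
    network_partition: np.ndarray | None = None,
    seed: int = 0,
    design: tuple | None = None,
    max_correlation: float = 0.3,
) -> np.ndarray:
    """Planted K x N co-activation patterns, z-scored across ROIs.

    Each state sets designated networks to high (positive) amplitude and
    others to low (negative); remaining networks sit at baseline. For the
    canonical 8-network partition at K<=4 a fixed design is used;
    otherwise random sign assignments are drawn until all pairwise
    Pearson correlations between distinct states fall below
    ``max_correlation``.

    Raises
    ------
    ValidationError
        If ``n_rois < 2 * k_states`` or no acceptably separated design is
        found (too few ROIs/networks for the requested number of states).
    """
    if n_rois < 2 * k_states:
        raise ValidationError(
            f"need n_rois >= 2*k_states for separable patterns "
            f"({n_rois} < {2 * k_states})"
        )
    if network_partition is None:
        network_partition = default_network_partition(n_rois)
    network_partition = np.asarray(network_partition)
    if network_partition.shape[0] != n_rois:
        raise ValidationError("network partition must cover every ROI")
    networks = list(dict.fromkeys(network_partition))

    if design is None and k_states <= len(DEFAULT_STATE_DESIGN) and set(
        networks
    ) == set(RSN_LABELS):
        design = DEFAULT_STATE_DESIGN[:k_states]

    rng = np.random.default_rng(seed)
    for attempt in range(500):
        if design is not None:
            chosen = design
        else:
            chosen = []
            for _ in range(k_states):
                signs = rng.choice([-1, 0, 1], size=len(networks))
                while not (np.any(signs > 0) and np.any(signs < 0)):
                    signs = rng.choice([-1, 0, 1], size=len(networks))
                pos = tuple(n for n, s in zip(networks, signs) if s > 0)
                neg = tuple(n for n, s in zip(networks, signs) if s < 0)
                chosen.append((pos, neg))
        centroids = np.zeros((k_states, n_rois))
        for s, (pos, neg) in enumerate(chosen):
            centroids[s, np.isin(network_partition, pos)] = 1.0
            centroids[s, np.isin(network_partition, neg)] = -1.0
        sd = centroids.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            if design is not None:
                raise ValidationError("design produced a constant pattern")
            continue
        centroids = (centroids - centroids.mean(axis=1, keepdims=True)) / sd
        corr = np.corrcoef(centroids)
        off = corr[~np.eye(k_states, dtype=bool)]
        if off.size == 0 or np.max(off) < max_correlation:
            return centroids
        if design is not None:
            raise ValidationError(
                f"fixed design violates max pairwise correlation "
                f"{max_correlation} (max {np.max(off):.3f})"
            )
    raise ValidationError(
        f"could not separate {k_states} states over {len(networks)} networks "
        f"after 500 attempts (infeasible separation)"
    )


def simulate_state_sequence(
    transition_matrix: np.ndarray,
    n_frames: int,
    seed: int = 0,
    initial_distribution: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate a 1-based Markov state label sequence.

    The initial state is drawn from the chain's stationary distribution
    (overridable) so short scans carry no burn-in bias.
    """
    m = np.asarray(transition_matrix, dtype=float)
    _check_stochastic(m)
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    k = m.shape[0]
    rng = np.random.default_rng(seed)
    pi = stationary_distribution(m) if initial_distribution is None else np.asarray(
        initial_distribution, dtype=float
    )
    cum_rows = np.cumsum(m, axis=1)
    u = rng.random(n_frames)
    labels = np.empty(n_frames, dtype=int)
    state = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
    state = min(state, k - 1)
    labels[0] = state
    for t in range(1, n_frames):
        state = int(np.searchsorted(cum_rows[state], u[t], side="right"))
        state = min(state, k - 1)
        labels[t] = state
    return labels + 1


def emit_bold(
    labels: np.ndarray,
    centroids: np.ndarray,
    ar_coefficient: float = 0.45,
    noise_sd: float = 1.0,
    seed: int = 0,
    tr_seconds: float = 2.1,
    subject_id: str = "synthetic",
) -> RegionalTimeSeries:
    """Emit a raw ROI x frame BOLD matrix from a state label sequence.

    Frame t equals the centroid of its state plus AR(1) noise
    ``eps_t = phi * eps_{t-1} + eta_t`` with ``eta ~ N(0, noise_sd^2)``
    independently per ROI; the recursion starts from its stationary law,
    so the marginal noise variance is ``noise_sd^2 / (1 - phi^2)`` at
    every frame.
    """
    if not abs(ar_coefficient) < 1:
        raise ValidationError("|ar_coefficient| must be < 1")
    labels = np.asarray(labels, dtype=int)
    centroids = np.asarray(centroids, dtype=float)
    k, n = centroids.shape
    if labels.min() < 1 or labels.max() > k:
        raise ValidationError("labels outside 1..K")
    signal_part = centroids[labels - 1].T  # N x T
    rng = np.random.default_rng(seed)
    t_frames = labels.shape[0]
    if noise_sd == 0:
        noise = np.zeros((n, t_frames))
    else:
        phi = ar_coefficient
        eta = rng.normal(0.0, noise_sd, size=(n, t_frames))
        eps0 = rng.normal(0.0, noise_sd / np.sqrt(1 - phi**2), size=n)
        noise = np.empty((n, t_frames))
        noise[:, 0] = eps0
        if t_frames > 1:
            out, _ = signal.lfilter(
                [1.0], [1.0, -phi], eta[:, 1:], axis=1, zi=(phi * eps0)[:, None]
            )
            noise[:, 1:] = out
    return RegionalTimeSeries(
        subject_id=subject_id,
        matrix=signal_part + noise,
        tr_seconds=tr_seconds,
        roi_labels=[f"roi{i:03d}" for i in range(n)],
    )


def generate_connectome(
    n_rois: int,
    module_partition: np.ndarray | None = None,
    seed: int = 0,
    p_within: float = 0.8,
    p_between: float = 0.25,
    within_weight_scale: float = 2.0,
    subject_id: str = "synthetic",
    max_retries: int = 20,
) -> Connectome:
    """Modular weighted structural connectome.

    Edges occur with higher probability and carry stochastically larger
    (log-normal) weights within modules than between them. The matrix is
    symmetric, nonnegative, zero-diagonal and connected; a disconnected
    realization is regenerated with an incremented seed (logged).
    """
    if n_rois < 2:
        raise ValidationError("connectome needs at least 2 ROIs")
    if module_partition is None:
        module_partition = default_network_partition(n_rois)
    module_partition = np.asarray(module_partition)
    same = module_partition[:, None] == module_partition[None, :]
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        prob = np.where(same, p_within, p_between)
        present = rng.random((n_rois, n_rois)) < prob
        weights = rng.lognormal(mean=0.0, sigma=0.5, size=(n_rois, n_rois))
        weights *= np.where(same, within_weight_scale, 1.0)
        w = np.triu(present * weights, k=1)
        w = w + w.T
        n_comp, _ = sparse.csgraph.connected_components(sparse.csr_matrix(w > 0))
        if n_comp == 1:
            if attempt > 0:
                logger.info(
                    "connectome %s: regenerated %d time(s) to obtain a "
                    "connected graph", subject_id, attempt,
                )
            return Connectome(subject_id=subject_id, weights=w)
    raise ValidationError(
        f"connectome {subject_id}: disconnected after {max_retries} attempts"
    )


def _empirical_transition_matrix(sequences: list[np.ndarray], k: int) -> np.ndarray:
    """Pooled row-normalized transition counts (self-transitions included)."""
    counts = np.zeros((k, k))
    for labels in sequences:
        np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1)
    row = counts.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    return counts / row


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[CohortBundle, SyntheticGroundTruth]:
    """Generate the two-group cohort: BOLD, connectomes, clinical table.

    Clinical scores are ``group_base + coupling * FO% + N(0, noise)``,
    where FO% is the subject's realized fractional occupancy (percent) of
    ``config.coupled_state``; the patient group carries higher symptom
    baselines.
    """
    rng = np.random.default_rng(config.seed)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    partition = default_network_partition(config.n_rois)
    centroids = generate_state_patterns(
        config.k_states, config.n_rois, partition,
        seed=int(seeds[0].generate_state(1)[0] % 2**31),
    )
    parcellation = ParcellationTable(pd.DataFrame({
        "roi_label": [f"roi{i:03d}" for i in range(config.n_rois)],
        "network": partition,
    }))

    groups = ("HC", "MDD")
    subjects: list[RegionalTimeSeries] = []
    connectomes: list[Connectome] = []
    sequences: dict[str, np.ndarray] = {}
    occupancy: dict[str, np.ndarray] = {}
    rows = []
    bold_seeds = np.random.SeedSequence(
        int(seeds[1].generate_state(1)[0] % 2**31)
    ).spawn(2 * config.n_subjects_per_group * 3)
    si = 0
    per_group_sequences: dict[str, list[np.ndarray]] = {g: [] for g in groups}
    for g_idx, group in enumerate(groups):
        tmat = config.group_transition_matrices[g_idx]
        for j in range(config.n_subjects_per_group):
            sid = f"sub-{group}{j:02d}"
            s_seq, s_bold, s_conn = bold_seeds[3 * si: 3 * si + 3]
            si += 1
            labels = simulate_state_sequence(
                tmat, config.frames_per_subject,
                seed=int(s_seq.generate_state(1)[0] % 2**31),
            )
            ts = emit_bold(
                labels, centroids, config.ar_coefficient, config.noise_sd,
                seed=int(s_bold.generate_state(1)[0] % 2**31),
                tr_seconds=config.tr_seconds, subject_id=sid,
            )
            conn = generate_connectome(
                config.n_rois, partition,
                seed=int(s_conn.generate_state(1)[0] % 2**31), subject_id=sid,
            )
            fo = np.array([
                100.0 * np.mean(labels == s + 1) for s in range(config.k_states)
            ])
            subjects.append(ts)
            connectomes.append(conn)
            sequences[sid] = labels
            occupancy[sid] = fo
            per_group_sequences[group].append(labels)

            fo_c = fo[config.coupled_state - 1]
            base = {"HC": 3.0, "MDD": 14.0}[group]
            scores = {}
            for c_idx, col in enumerate(CLINICAL_SCORE_COLUMNS):
                coup = config.clinical_coupling[c_idx % len(config.clinical_coupling)]
                scores[col] = (
                    base + coup * fo_c + rng.normal(0.0, config.clinical_noise_sd)
                )
            rows.append({
                "subject": sid,
                "group": group,
                "age": float(np.clip(rng.normal(38, 12), 18, 65)),
                "sex": int(rng.integers(0, 2)),
                "medication": int(rng.integers(0, 2)) if group == "MDD" else 0,
                **scores,
            })

    clinical = ClinicalTable(pd.DataFrame(rows))
    truth = SyntheticGroundTruth(
        centroids=centroids,
        state_sequences=sequences,
        specified_transition_matrices={
            g: config.group_transition_matrices[i] for i, g in enumerate(groups)
        },
        realized_transition_matrices={
            g: _empirical_transition_matrix(per_group_sequences[g], config.k_states)
            for g in groups
        },
        fractional_occupancy=occupancy,
        clinical_coupling=config.clinical_coupling,
        coupled_state=config.coupled_state,
    )
    bundle = CohortBundle(
        subjects=subjects, connectomes=connectomes,
        clinical=clinical, parcellation=parcellation,
    )
    return bundle, truth


def write_cohort(
    bundle: CohortBundle,
    truth: SyntheticGroundTruth,
    out_dir: str | Path,
) -> None:
    """Write the full bundle as plain-text files (TSV matrices, CSV
    tables, ground-truth JSON)."""
    from . import io as capio

    out = Path(out_dir)
    (out / "bold").mkdir(parents=True, exist_ok=True)
    (out / "connectomes").mkdir(parents=True, exist_ok=True)
    for ts in bundle.subjects:
        capio.write_matrix(out / "bold" / f"{ts.subject_id}.tsv", ts)
    for conn in bundle.connectomes:
        capio.write_matrix(out / "connectomes" / f"{conn.subject_id}.tsv", conn)
    capio.write_clinical(out / "clinical.csv", bundle.clinical)
    capio.write_parcellation(out / "parcellation.csv", bundle.parcellation)
    payload = {
        "centroids": truth.centroids.tolist(),
        "coupled_state": truth.coupled_state,
        "clinical_coupling": truth.clinical_coupling.tolist(),
        "specified_transition_matrices": {
            g: m.tolist() for g, m in truth.specified_transition_matrices.items()
        },
        "realized_transition_matrices": {
            g: m.tolist() for g, m in truth.realized_transition_matrices.items()
        },
        "state_sequences": {
            s: seq.tolist() for s, seq in truth.state_sequences.items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(payload))
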