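"""Phase-randomized surrogate BOLD series and the real-vs-null
cluster-quality comparison.

A surrogate keeps every ROI's Fourier amplitude spectrum — hence its
full autocorrelation function, mean and variance — while randomizing
the phases, so temporal structure survives but the spatial
co-activation geometry the clustering feeds on is destroyed. With
``mode="independent"`` (default) every ROI draws its own phases, which
also breaks cross-ROI zero-lag correlation; ``mode="locked"`` applies
one shared phase draw to all ROIs and preserves it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import RegionalTimeSeries, ValidationError
from . import clustering as cl
from .io import concatenate_cohort, normalize_subject

logger = logging.getLogger(__name__)


@dataclass
class SurrogateSeries(RegionalTimeSeries):
    """Phase-randomized copy of a subject's series, with provenance."""

    source_subject_id: str = ""
    seed: int = 0


def phase_randomize(
    ts: RegionalTimeSeries, seed: int = 0, mode: str = "independent"
) -> SurrogateSeries:
    """Phase-randomized surrogate of one subject's ROI x frame matrix.

    Per ROI: FFT, multiply every positive-frequency coefficient by a
    random unit phase, mirror the conjugate onto negative frequencies,
    keep the DC term (and the Nyquist term when T is even) real, inverse
    transform. A constant series has only a DC component and is returned
    unchanged.
    """
    if mode not in ("independent", "locked"):
        raise ValidationError("mode must be 'independent' or 'locked'")
    x = ts.matrix
    n_rois, t = x.shape
    if t < 4:
        raise ValidationError("phase randomization needs at least 4 frames")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(x, axis=1)
    n_freq = spec.shape[1]
    # indices 1..n_freq-1 are positive frequencies; the last one is the
    # real Nyquist bin when T is even and must stay real
    has_nyquist = t % 2 == 0
    hi = n_freq - 1 if has_nyquist else n_freq
    n_random = hi - 1
    if mode == "independent":
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_rois, n_random))
    else:
        theta = np.tile(rng.uniform(0.0, 2.0 * np.pi, size=n_random), (n_rois, 1))
    spec[:, 1:hi] = np.abs(spec[:, 1:hi]) * np.exp(1j * theta)
    if has_nyquist:
        # random sign keeps the bin real while randomizing its phase mod pi
        if mode == "independent":
            sign = rng.choice([-1.0, 1.0], size=n_rois)
        else:
            sign = np.repeat(rng.choice([-1.0, 1.0]), n_rois)
        spec[:, -1] = np.abs(spec[:, -1]) * sign
    out = np.fft.irfft(spec, n=t, axis=1)
    return SurrogateSeries(
        subject_id=f"{ts.subject_id}_surr{seed}",
        matrix=out,
        tr_seconds=ts.tr_seconds,
        roi_labels=list(ts.roi_labels),
        source_subject_id=ts.subject_id,
        seed=seed,
    )


def surrogate_cohort(
    subjects: list[RegionalTimeSeries], seed: int = 0, mode: str = "independent"
) -> list[SurrogateSeries]:
    """One surrogate per subject (surrogates are built per subject, before
    concatenation, so subject boundaries match the real pipeline)."""
    ss = np.random.SeedSequence(seed).spawn(len(subjects))
    return [
        phase_randomize(ts, seed=int(s.generate_state(1)[0] % 2**31), mode=mode)
        for ts, s in zip(subjects, ss)
    ]


def within_cluster_variance(dataset, solution: cl.ClusterSolution) -> np.ndarray:
    """Mean squared correlation distance to the medoid, per cluster."""
    dist = cl._CorrDistance(dataset)
    dm = dist.rows(solution.medoid_frame_indices)
    d_own = dm[solution.labels - 1, np.arange(dist.n_frames)]
    out = np.empty(solution.k)
    for c in range(solution.k):
        out[c] = float(np.mean(d_own[solution.labels == c + 1] ** 2))
    return out


def compare_cluster_quality(
    subjects: list[RegionalTimeSeries],
    n_surrogates: int,
    k: int,
    seed: int = 0,
    n_restarts: int = 5,
    mode: str = "independent",
) -> dict:
    """Cluster the real cohort and ``n_surrogates`` surrogate cohorts with
    the identical pipeline and compare quality.

    Reports the real-minus-null difference in mean medoid silhouette and
    in per-cluster within-cluster variance, with permutation-style
    p-values p = (1 + #{null >= real}) / (1 + n); a surrogate whose
    clustering fails is skipped and counted.
    """
    if n_surrogates < 2:
        raise ValidationError("need at least 2 surrogate cohorts")
    normalized = [normalize_subject(ts) for ts in subjects]
    real = concatenate_cohort(normalized)
    sol = cl.kmedoids(real, k, n_restarts=n_restarts, seed=seed)
    _, real_sil = cl.medoid_silhouette(real, sol)
    real_wcv = within_cluster_variance(real, sol)

    ss = np.random.SeedSequence(seed + 1).spawn(n_surrogates)
    null_sil, null_wcv = [], []
    n_failed = 0
    for s in ss:
        sub_seed = int(s.generate_state(1)[0] % 2**31)
        try:
            surr = surrogate_cohort(subjects, seed=sub_seed, mode=mode)
            surr_norm = [normalize_subject(t) for t in surr]
            surr_cat = concatenate_cohort(surr_norm)
            surr_sol = cl.kmedoids(surr_cat, k, n_restarts=n_restarts, seed=sub_seed)
            _, sil = cl.medoid_silhouette(surr_cat, surr_sol)
            null_sil.append(sil)
            null_wcv.append(within_cluster_variance(surr_cat, surr_sol))
        except Exception:  # noqa: BLE001 - a failed surrogate is skipped, not fatal
            logger.warning("surrogate clustering failed (seed %d); skipped", sub_seed)
            n_failed += 1
    null_sil = np.asarray(null_sil)
    null_wcv = np.asarray(null_wcv)
    n_ok = null_sil.size
    p_sil = (1.0 + np.sum(null_sil >= real_sil)) / (1.0 + n_ok)
    # per-cluster comparison of real within-cluster variance against the
    # surrogate distribution (cluster labels are matched by index)
    wcv_delta = real_wcv - null_wcv.mean(axis=0)
    p_wcv = (1.0 + np.sum(null_wcv >= real_wcv[None, :], axis=0)) / (1.0 + n_ok)
    return {
        "real_mean_silhouette": real_sil,
        "null_mean_silhouette": float(null_sil.mean()),
        "delta_silhouette": real_sil - float(null_sil.mean()),
        "p_silhouette": float(p_sil),
        "real_within_cluster_variance": real_wcv,
        "delta_within_cluster_variance": wcv_delta,
        "p_within_cluster_variance": p_wcv,
        "n_surrogates_used": int(n_ok),
        "n_surrogates_failed": int(n_failed),
    }
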