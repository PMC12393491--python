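"""Core containers shared across the pipeline.

Every stage speaks in terms of these types: per-subject regional BOLD
matrices, the cohort-level concatenated point cloud that clustering
consumes, structural connectomes, and the parcellation / clinical side
tables. ROI order is the contract that links a subject's time series,
connectome, and parcellation row-for-row; it is validated by label
equality wherever two objects meet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical resting-state network labels: seven cortical systems plus a
#: subcortical grouping.
RSN_LABELS = ("VIS", "SOM", "DAT", "VAT", "LIM", "FPN", "DMN", "SUB")

CLINICAL_SCORE_COLUMNS = (
    "QIDS", "MASQ_AD", "MASQ_AA", "MASQ_GD", "RRS_DEP", "RRS_BRO", "RRS_REF",
)


class ValidationError(ValueError):
    """An input violated a structural invariant (shape, symmetry, finiteness)."""


@dataclass
class RegionalTimeSeries:
    """One subject's ROI x frame BOLD matrix.

    ``matrix`` has one row per ROI and one column per frame; values are in
    z-units after :func:`capdyn.io.normalize_subject`.
    """

    subject_id: str
    matrix: np.ndarray
    tr_seconds: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError(
                f"subject {self.subject_id}: expected a 2-D ROI x frame matrix, "
                f"got shape {self.matrix.shape}"
            )
        if self.tr_seconds <= 0:
            raise ValidationError(f"subject {self.subject_id}: TR must be positive")
        if not self.roi_labels:
            self.roi_labels = [f"roi{i:03d}" for i in range(self.matrix.shape[0])]
        if len(self.roi_labels) != self.matrix.shape[0]:
            raise ValidationError(
                f"subject {self.subject_id}: {len(self.roi_labels)} ROI labels "
                f"for {self.matrix.shape[0]} rows"
            )
        bad = ~np.isfinite(self.matrix)
        if bad.any():
            i, t = np.argwhere(bad)[0]
            raise ValidationError(
                f"subject {self.subject_id}: non-finite value at ROI "
                f"{self.roi_labels[i]!r}, frame {t}"
            )

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ConcatenatedDataset:
    """Cohort point cloud: all subjects' frames stacked along time.

    ``matrix`` is N x T_total; ``frame_subject_index`` maps each column to
    its subject id; ``subject_boundaries`` are the frame offsets at which a
    new subject starts (excluding 0 and T_total).
    """

    matrix: np.ndarray
    frame_subject_index: np.ndarray
    subject_boundaries: np.ndarray
    roi_labels: list[str]
    tr_by_subject: dict[str, float]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.frame_subject_index = np.asarray(self.frame_subject_index)
        self.subject_boundaries = np.asarray(self.subject_boundaries, dtype=int)
        if self.frame_subject_index.shape[0] != self.matrix.shape[1]:
            raise ValidationError("frame->subject map length != number of frames")
        if np.any(np.diff(self.subject_boundaries) <= 0):
            raise ValidationError("subject boundaries must be strictly increasing")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.frame_subject_index:
            seen.setdefault(str(s))
        return list(seen)

    def frames_of(self, subject_id: str) -> np.ndarray:
        """Column indices belonging to one subject."""
        return np.flatnonzero(self.frame_subject_index == subject_id)


@dataclass
class Connectome:
    """Symmetric weighted structural connectivity matrix for one subject.

    Weights are nonnegative streamline strengths; the diagonal is exactly
    zero. ROI labels must match the time-series order.
    """

    subject_id: str
    weights: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(
                f"connectome {self.subject_id}: expected square matrix, got {w.shape}"
            )
        if not self.roi_labels:
            self.roi_labels = [f"roi{i:03d}" for i in range(w.shape[0])]
        if not np.all(np.isfinite(w)):
            raise ValidationError(f"connectome {self.subject_id}: non-finite weights")
        asym = np.max(np.abs(w - w.T)) if w.size else 0.0
        if asym > 1e-9:
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise ValidationError(
                f"connectome {self.subject_id}: asymmetric at ({i},{j}): "
                f"{w[i, j]} vs {w[j, i]}"
            )
        if np.any(np.diag(w) != 0):
            raise ValidationError(f"connectome {self.subject_id}: nonzero diagonal")
        if np.any(w < 0):
            raise ValidationError(f"connectome {self.subject_id}: negative weights")

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


@dataclass
class ParcellationTable:
    """Mapping from each ROI to its resting-state network label."""

    table: pd.DataFrame  # columns: roi_label, network

    def __post_init__(self) -> None:
        required = {"roi_label", "network"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"parcellation needs columns {sorted(required)}")
        unknown = set(self.table["network"]) - set(RSN_LABELS)
        if unknown:
            raise ValidationError(f"unknown network labels: {sorted(unknown)}")
        if self.table["roi_label"].duplicated().any():
            raise ValidationError("ROI assigned to more than one network")

    @property
    def networks(self) -> list[str]:
        return [n for n in RSN_LABELS if n in set(self.table["network"])]

    def indicator(self, network: str) -> np.ndarray:
        """Binary ROI-membership vector for one network, in table order."""
        return (self.table["network"].to_numpy() == network).astype(float)

    def labels_for(self, roi_labels: list[str]) -> np.ndarray:
        """Network label per ROI, reordered to match ``roi_labels``."""
        lut = dict(zip(self.table["roi_label"], self.table["network"]))
        missing = [r for r in roi_labels if r not in lut]
        if missing:
            raise ValidationError(f"ROIs without a network assignment: {missing[:5]}")
        return np.array([lut[r] for r in roi_labels])


@dataclass
class ClinicalTable:
    """Per-subject group membership, demographics and symptom scores.

    Expected columns: subject, group (HC/MDD), age, sex (0/1),
    medication (0/1), and the QIDS / MASQ / RRS score columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "group", "age", "sex", "medication"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"clinical table needs columns {sorted(required)}")
        if self.table["group"].isna().any():
            raise ValidationError("missing group labels")
        bad_groups = set(self.table["group"]) - {"HC", "MDD"}
        if bad_groups:
            raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")
        for col in CLINICAL_SCORE_COLUMNS:
            if col in self.table.columns:
                vals = self.table[col].dropna()
                if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
                    raise ValidationError(f"non-finite values in score column {col}")

    def group_mask(self, group: str) -> np.ndarray:
        return (self.table["group"] == group).to_numpy()
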