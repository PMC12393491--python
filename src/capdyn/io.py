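"""Reading, writing, normalization and concatenation of cohort data.

On-disk conventions: matrices are tab-delimited text with ROIs as rows
and frames as columns (a ``transpose`` flag covers the other
orientation); parcellation and clinical tables are CSV. Normalization
z-scores each ROI's time course with the population (1/T) standard
deviation — correlation distance is invariant to that choice, it is
fixed here only so outputs are bit-reproducible.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ConcatenatedDataset,
    Connectome,
    ParcellationTable,
    RegionalTimeSeries,
    ValidationError,
)

logger = logging.getLogger(__name__)


def normalize_subject(ts: RegionalTimeSeries) -> RegionalTimeSeries:
    """Z-score each ROI's time course to mean 0, sd 1.

    Constant ROIs (zero variance) are mapped to all-zeros with a warning
    rather than rejected, so a degraded region does not abort a cohort
    run. The operation is idempotent.
    """
    if ts.n_frames < 2:
        raise ValidationError(
            f"subject {ts.subject_id}: need at least 2 frames to normalize"
        )
    x = ts.matrix
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population (1/T) convention
    constant = sd[:, 0] == 0
    if constant.any():
        rois = [ts.roi_labels[i] for i in np.flatnonzero(constant)]
        logger.warning(
            "subject %s: constant ROI(s) %s zeroed during normalization",
            ts.subject_id, rois,
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[constant, :] = 0.0
    return RegionalTimeSeries(
        subject_id=ts.subject_id,
        matrix=z,
        tr_seconds=ts.tr_seconds,
        roi_labels=list(ts.roi_labels),
    )


def concatenate_cohort(subjects: list[RegionalTimeSeries]) -> ConcatenatedDataset:
    """Stack all subjects' frames along the temporal axis.

    All subjects must share ROI count and label order; per-frame values
    are copied bit-exactly.
    """
    if not subjects:
        raise ValidationError("cannot concatenate an empty cohort")
    ref = subjects[0].roi_labels
    for ts in subjects[1:]:
        if ts.roi_labels != ref:
            raise ValidationError(
                f"ROI order mismatch between subjects {subjects[0].subject_id!r} "
                f"and {ts.subject_id!r}"
            )
    matrix = np.concatenate([ts.matrix for ts in subjects], axis=1)
    frame_subject = np.concatenate(
        [np.repeat(ts.subject_id, ts.n_frames) for ts in subjects]
    )
    boundaries = np.cumsum([ts.n_frames for ts in subjects])[:-1]
    return ConcatenatedDataset(
        matrix=matrix,
        frame_subject_index=frame_subject,
        subject_boundaries=boundaries,
        roi_labels=list(ref),
        tr_by_subject={ts.subject_id: ts.tr_seconds for ts in subjects},
    )


def _read_rectangular(path: str | Path, delimiter: str = "\t") -> np.ndarray:
    path = Path(path)
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split(delimiter)
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: non-numeric cell on line {lineno}: {exc}"
                ) from None
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise ValidationError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(rows[-1])} cells, expected {len(rows[0])})"
                )
    if not rows:
        raise ValidationError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def read_matrix(
    path: str | Path,
    kind: str = "timeseries",
    *,
    subject_id: str | None = None,
    tr_seconds: float = 1.0,
    roi_labels: list[str] | None = None,
    transpose: bool = False,
) -> RegionalTimeSeries | Connectome | np.ndarray:
    """Read a tab-delimited matrix as a typed object.

    ``kind`` is one of ``timeseries`` (ROI x frame, validated through
    :class:`RegionalTimeSeries`), ``connectome`` (square symmetric,
    validated through :class:`Connectome`) or ``raw``.
    """
    values = _read_rectangular(path)
    if transpose:
        values = values.T
    sid = subject_id or Path(path).stem
    if kind == "timeseries":
        return RegionalTimeSeries(
            subject_id=sid, matrix=values, tr_seconds=tr_seconds,
            roi_labels=roi_labels or [],
        )
    if kind == "connectome":
        return Connectome(subject_id=sid, weights=values, roi_labels=roi_labels or [])
    if kind == "raw":
        return values
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(path: str | Path, matrix: np.ndarray | RegionalTimeSeries | Connectome) -> None:
    """Write a matrix as tab-delimited text (17 significant digits, so a
    write -> read round trip reproduces values to within 1e-12)."""
    if isinstance(matrix, RegionalTimeSeries):
        values = matrix.matrix
    elif isinstance(matrix, Connectome):
        values = matrix.weights
    else:
        values = np.asarray(matrix, dtype=float)
    np.savetxt(path, np.atleast_2d(values), delimiter="\t", fmt="%.17g")


def read_parcellation(path: str | Path) -> ParcellationTable:
    return ParcellationTable(pd.read_csv(path))


def write_parcellation(path: str | Path, parc: ParcellationTable) -> None:
    parc.table.to_csv(path, index=False)


def read_clinical(path: str | Path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path))


def write_clinical(path: str | Path, clin: ClinicalTable) -> None:
    clin.table.to_csv(path, index=False)
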