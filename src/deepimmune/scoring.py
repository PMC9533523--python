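"""Stroma-fraction (deep_tsr) and infiltration (deep_til) scores, tertile
calibration, and the 4-level composite immune score.

deep_tsr = #STR cells / (#STR + #TUM cells); patients split at a 50% cutoff
(boundary assigned to the *high* stroma group).  deep_til = mean P(LYM) over
grid cells labelled STR; patients split at the 33rd/66th percentiles of a
reference cohort (boundaries inclusive on the lower group).  Stroma-high
scores 0 points, stroma-low 1; infiltration low/middle/high score 1/2/3;
the composite is their sum, 1-4.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from deepimmune.tissue_maps import ProbabilityMap, SegmentationMap, TissueClass

log = logging.getLogger(__name__)

SCORES_CSV_COLUMNS = [
    "patient_id", "deep_tsr", "tsr_group", "deep_til", "til_group", "immune_score",
]


@dataclass(frozen=True)
class TertileCalibration:
    """33rd/66th percentile thresholds fitted once on a reference cohort."""

    t33: float
    t66: float
    reference_cohort_id: str
    n_reference: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.t33 > self.t66:
            raise ValueError("t33 must not exceed t66")
        if self.n_reference < 3:
            raise ValueError("calibration requires at least 3 reference scores")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TertileCalibration":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ScoreRecord:
    patient_id: str
    deep_tsr: float
    tsr_group: str
    tsr_points: int
    deep_til: float
    til_group: str
    til_points: int
    immune_score: int


def deep_tsr(seg: SegmentationMap) -> float:
    """Stroma fraction of the tumour bed: #STR / (#STR + #TUM) grid cells."""
    n_str = int(np.sum(seg.labels == TissueClass.STR))
    n_tum = int(np.sum(seg.labels == TissueClass.TUM))
    if n_str + n_tum == 0:
        raise ValueError("no tumor-bed tissue on slide (zero STR and TUM cells)")
    return n_str / (n_str + n_tum)


def tsr_group(fraction: float, cutoff: float = 0.5) -> tuple[str, int]:
    """Split the stroma fraction at ``cutoff``; >= cutoff -> high (0 points)."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie strictly inside (0, 1)")
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must lie in [0, 1]")
    if fraction >= cutoff:
        return "high", 0
    return "low", 1


def deep_til(pmap: ProbabilityMap, seg: SegmentationMap) -> float:
    """Mean P(LYM) over grid cells labelled STR (the stroma mask)."""
    if pmap.shape != seg.shape:
        raise ValueError(
            f"probability map shape {pmap.shape} != segmentation shape {seg.shape}"
        )
    mask = seg.labels == TissueClass.STR
    if not mask.any():
        raise ValueError("no stroma mask; Deep-TIL undefined")
    return float(pmap.grid[:, :, TissueClass.LYM][mask].mean())


def calibrate_tertiles(
    reference_scores: Iterable[float], cohort_id: str
) -> TertileCalibration:
    """Fit 33rd/66th percentile thresholds (linear interpolation) on a
    reference cohort.  Fit once on the primary cohort and reuse elsewhere."""
    scores = np.asarray(list(reference_scores), dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 reference scores to calibrate tertiles")
    if not np.all(np.isfinite(scores)):
        raise ValueError("reference scores must be finite")
    t33, t66 = np.percentile(scores, [33.0, 66.0], method="linear")
    return TertileCalibration(
        t33=float(t33),
        t66=float(t66),
        reference_cohort_id=cohort_id,
        n_reference=int(scores.size),
        degenerate=bool(t33 == t66),
    )


def til_group(score: float, cal: TertileCalibration) -> tuple[str, int]:
    """3-level grouping against a calibration; boundaries go to the lower
    group.  Degenerate calibrations collapse the middle group."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    if cal.degenerate:
        return ("low", 1) if score <= cal.t33 else ("high", 3)
    if score <= cal.t33:
        return "low", 1
    if score <= cal.t66:
        return "middle", 2
    return "high", 3


def immune_score(tsr_points: int, til_points: int) -> int:
    """Composite 4-level score: sum of stroma points (0/1) and
    infiltration points (1/2/3)."""
    if tsr_points not in (0, 1):
        raise ValueError(f"tsr_points must be 0 or 1, got {tsr_points}")
    if til_points not in (1, 2, 3):
        raise ValueError(f"til_points must be 1, 2 or 3, got {til_points}")
    return tsr_points + til_points


def score_patient(
    patient_id: str,
    pmap: ProbabilityMap,
    seg: SegmentationMap,
    cal: TertileCalibration,
    cutoff: float = 0.5,
) -> ScoreRecord:
    f = deep_tsr(seg)
    g_tsr, p_tsr = tsr_group(f, cutoff)
    t = deep_til(pmap, seg)
    g_til, p_til = til_group(t, cal)
    return ScoreRecord(
        patient_id=patient_id,
        deep_tsr=f,
        tsr_group=g_tsr,
        tsr_points=p_tsr,
        deep_til=t,
        til_group=g_til,
        til_points=p_til,
        immune_score=immune_score(p_tsr, p_til),
    )


def score_cohort(
    maps: Mapping[str, tuple[ProbabilityMap, SegmentationMap]],
    cal: TertileCalibration | None = None,
    cohort_id: str = "cohort",
    cutoff: float = 0.5,
) -> tuple[pd.DataFrame, TertileCalibration | None, list[tuple[str, str]]]:
    """Score every patient in a cohort.

    If ``cal`` is None the tertile calibration is fitted on this cohort's
    deep_til scores (the reference-cohort mode); otherwise the supplied
    calibration is applied unchanged.  Per-patient failures (no stroma, no
    tumour bed) are collected and returned, not raised.

    Returns (records table, calibration used, [(patient_id, error), ...]).
    """
    errors: list[tuple[str, str]] = []
    raw: dict[str, tuple[float, float]] = {}
    for pid, (pmap, seg) in maps.items():
        try:
            raw[pid] = (deep_tsr(seg), deep_til(pmap, seg))
        except ValueError as exc:
            errors.append((pid, str(exc)))
    if not raw:
        log.warning("score_cohort: no scoreable patients in cohort %s", cohort_id)
        return pd.DataFrame(columns=SCORES_CSV_COLUMNS + ["tsr_points", "til_points"]), cal, errors
    if cal is None:
        cal = calibrate_tertiles((t for _, t in raw.values()), cohort_id)
    rows = []
    for pid, (f, t) in raw.items():
        g_tsr, p_tsr = tsr_group(f, cutoff)
        g_til, p_til = til_group(t, cal)
        rows.append(
            {
                "patient_id": pid,
                "deep_tsr": f,
                "tsr_group": g_tsr,
                "tsr_points": p_tsr,
                "deep_til": t,
                "til_group": g_til,
                "til_points": p_til,
                "immune_score": immune_score(p_tsr, p_til),
            }
        )
    return pd.DataFrame(rows), cal, errors


def write_scores(records: pd.DataFrame, path: str | Path) -> None:
    """Write the public scores-table dialect."""
    records[SCORES_CSV_COLUMNS].to_csv(path, index=False, float_format="%.10g")
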