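"""Well-level quality control, per-group detection calls, and imputation.

A well passes QC if its amplification score and Cq confidence meet
inclusive minimums and its Ct falls strictly inside the quantifiable
window. A miRNA is *detected* in a group when enough replicates carry a
passing measurement (2 of 3 in the reference design). Detected pairs
with a single missing replicate are imputed with the mean of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CtMatrix, DetectionMatrix, GroupDesign, WellRecord

__all__ = ["QcThresholds", "filter_wells", "call_detection", "impute_missing"]

#: Drop-attribution order: a failing record is charged to the first rule
#: it violates. Diagnostic only — the passing set does not depend on it.
DROP_RULES = ("amp_score", "cq_conf", "ct_window", "missing_ct")


@dataclass(frozen=True)
class QcThresholds:
    """QC cutoffs: score minimums are inclusive, the Ct window exclusive."""

    amp_score_min: float = 1.24
    cq_conf_min: float = 0.8
    ct_low: float = 10.0
    ct_high: float = 35.0

    def __post_init__(self) -> None:
        if not self.ct_low < self.ct_high:
            raise ValueError(
                f"ct_low ({self.ct_low}) must be < ct_high ({self.ct_high})"
            )

    def passes(self, record: WellRecord) -> bool:
        return self.failing_rule(record) is None

    def failing_rule(self, record: WellRecord) -> str | None:
        """First violated rule in DROP_RULES order, or None if passing."""
        if record.amp_score < self.amp_score_min:
            return "amp_score"
        if record.cq_conf < self.cq_conf_min:
            return "cq_conf"
        if record.ct is not None and not (self.ct_low < record.ct < self.ct_high):
            return "ct_window"
        if record.ct is None:
            return "missing_ct"
        return None


def filter_wells(
    records: Sequence[WellRecord], thresholds: QcThresholds | None = None
) -> tuple[list[WellRecord], dict[str, int]]:
    """Split well records into QC-passing records and per-rule drop counts.

    A record passes iff amp_score >= amp_score_min, cq_conf >= cq_conf_min,
    ct_low < ct < ct_high, and a Ct is present. Drop counts partition the
    removed records by the first failing rule.
    """
    thresholds = thresholds or QcThresholds()
    passing: list[WellRecord] = []
    drops = {rule: 0 for rule in DROP_RULES}
    for r in records:
        rule = thresholds.failing_rule(r)
        if rule is None:
            passing.append(r)
        else:
            drops[rule] += 1
    return passing, drops


def call_detection(
    matrix: CtMatrix, design: GroupDesign, min_fraction: float = 2.0 / 3.0
) -> DetectionMatrix:
    """Call a miRNA detected in a group when enough replicates measured it.

    The threshold is ``ceil(min_fraction * group_size)`` non-missing
    replicates; with 3 replicates and the default fraction this is the
    2-of-3 rule.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError(f"min_fraction must lie in (0, 1], got {min_fraction}")
    cols = {}
    for g in design.groups:
        samples = [s for s in design.members[g] if s in matrix.values.columns]
        if not samples:
            raise ValueError(f"group {g!r} has no samples in the matrix")
        need = math.ceil(min_fraction * len(samples))
        cols[g] = matrix.values[samples].notna().sum(axis=1) >= need
    return DetectionMatrix(pd.DataFrame(cols, columns=design.groups))


def impute_missing(
    matrix: CtMatrix, detection: DetectionMatrix, design: GroupDesign
) -> CtMatrix:
    """Fill missing replicates of detected (miRNA, group) pairs.

    Each missing cell of a detected pair becomes the arithmetic mean of
    that group's present replicate Cts (the mean of the other two, in the
    3-replicate design). Non-detected pairs stay missing; present cells
    are never altered.
    """
    out = matrix.values.copy()
    for g in design.groups:
        samples = [s for s in design.members[g] if s in out.columns]
        block = out[samples]
        det = detection.detected[g].reindex(block.index, fill_value=False)
        needs = det & block.isna().any(axis=1)
        if not needs.any():
            continue
        means = block.loc[needs].mean(axis=1, skipna=True)
        filled = block.loc[needs].apply(lambda col: col.fillna(means))
        out.loc[needs, samples] = filled
    return CtMatrix(out, matrix.sample_groups.copy())
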