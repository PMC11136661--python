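"""GATK-style hard filtering of variant records.

A record is removed iff any annotation violates its threshold; an
annotation absent from a record passes that criterion (the GATK
convention for un-annotated sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HardFilterThresholds:
    """Removal thresholds; a record fails on any single violated criterion."""

    qd_min: float = 2.0
    qual_min: float = 30.0
    sor_max: float = 3.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0


# annotation column -> (threshold attribute, removal direction)
_RULES = {
    "QD": ("qd_min", "lt"),
    "QUAL": ("qual_min", "lt"),
    "SOR": ("sor_max", "gt"),
    "FS": ("fs_max", "gt"),
    "MQ": ("mq_min", "lt"),
    "MQRankSum": ("mq_rank_sum_min", "lt"),
    "ReadPosRankSum": ("read_pos_rank_sum_min", "lt"),
}


def hard_filter_mask(
    records: pd.DataFrame, thresholds: HardFilterThresholds | None = None
) -> np.ndarray:
    """Boolean keep-mask over ``records`` (True = record retained)."""
    thresholds = thresholds or HardFilterThresholds()
    fail = np.zeros(len(records), dtype=bool)
    for col, (attr, direction) in _RULES.items():
        if col not in records.columns:
            logger.info("hard filter: annotation %s absent, treated as passing", col)
            continue
        vals = pd.to_numeric(records[col], errors="coerce")
        thr = getattr(thresholds, attr)
        if direction == "lt":
            fail |= (vals < thr).to_numpy(dtype=bool, na_value=False)
        else:
            fail |= (vals > thr).to_numpy(dtype=bool, na_value=False)
    return ~fail


def apply_hard_filters(
    records: pd.DataFrame, thresholds: HardFilterThresholds | None = None
) -> pd.DataFrame:
    """Return the records surviving every hard-filter criterion."""
    keep = hard_filter_mask(records, thresholds)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("hard filter: removed %d of %d records", n_removed, len(records))
    return records.loc[keep].reset_index(drop=True)
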