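"""Glucose-stimulated insulin secretion: enhancement index and group summary.

Each condition is a triplicate of five-islet batches incubated at one
glucose concentration from the series 3, 6, 8, 10, 15, 30 mM.  The
physiological readout is the enhancement index: mean insulin content at the
stimulating condition (15 mM) over the basal condition (3 mM); a healthy
response is roughly 10-20x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .multimodal import TestResult, welch_t

__all__ = [
    "BASAL_GLUCOSE_MM",
    "STIMULATED_GLUCOSE_MM",
    "GLUCOSE_SERIES_MM",
    "enhancement_index",
    "summarize",
]

log = logging.getLogger(__name__)

GLUCOSE_SERIES_MM = (3, 6, 8, 10, 15, 30)
BASAL_GLUCOSE_MM = 3
STIMULATED_GLUCOSE_MM = 15

_REP_COLS = ["rep1", "rep2", "rep3"]


def _condition_mean(records: pd.DataFrame, glucose: float, agg: str) -> float:
    sel = records[records["glucose_mM"] == glucose]
    if sel.empty:
        raise ValueError(f"missing {glucose} mM condition")
    reps = sel[_REP_COLS].to_numpy(dtype=float).ravel()
    return float(np.median(reps)) if agg == "median" else float(np.mean(reps))


def enhancement_index(records: pd.DataFrame, agg: str = "mean") -> float:
    """Enhancement index for one mouse: content(15 mM) / content(3 mM).

    ``records`` holds that mouse's rows (columns glucose_mM, rep1..rep3);
    other glucose concentrations are ignored by the index.  Replicates are
    aggregated by the arithmetic mean (median by flag).
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    basal = _condition_mean(records, BASAL_GLUCOSE_MM, agg)
    stim = _condition_mean(records, STIMULATED_GLUCOSE_MM, agg)
    if basal <= 0:
        raise ValueError("basal (3 mM) mean must be positive")
    return stim / basal


def summarize(indices_by_group: dict[str, list[float]]) -> tuple[pd.DataFrame, TestResult | None]:
    """Per-group mean/SD/n of enhancement indices plus a Welch t comparison.

    With fewer than two groups of n >= 2 the test is skipped (logged) and
    only the summary table is returned.
    """
    rows = []
    for group, vals in indices_by_group.items():
        vals = np.asarray(vals, dtype=float)
        rows.append({
            "group": group,
            "n": int(vals.size),
            "mean_index": float(vals.mean()) if vals.size else np.nan,
            "sd_index": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        })
    table = pd.DataFrame(rows)
    eligible = [g for g, v in indices_by_group.items() if len(v) >= 2]
    if len(eligible) < 2:
        log.info("group comparison skipped: need two groups with n >= 2")
        return table, None
    a, b = (indices_by_group[g] for g in eligible[:2])
    return table, welch_t(a, b)
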