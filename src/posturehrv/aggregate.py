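"""Subject-level eligibility and per-posture summaries.

A subject enters the analysis only if the recording contains more than
5 h of lying-posture epochs inside the 22:00-08:00 night window and at
least 80% of the beats within those epochs are sinus. Eligible subjects
get per-posture means of every epoch index plus a per-posture CVHR rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import LYING_POSTURES, BeatSeries, EpochGrid
from .io_formats import Params

INDEX_COLUMNS = ("hr", "sdrr", "vlf_amp", "lf_amp", "hf_amp", "hf_freq", "lf_hf", "hsi")


def night_lying_mask(labels: np.ndarray, grid: EpochGrid, params: Params) -> np.ndarray:
    """Epochs that are lying postures and start inside the night window."""
    labels = np.asarray(labels, dtype=object)
    lying = np.isin(labels.astype(str), LYING_POSTURES)
    lo, hi = params.night_window
    starts = grid.starts
    return lying & (starts >= lo) & (starts < hi)


def eligibility(labels: np.ndarray, grid: EpochGrid, beats: BeatSeries,
                params: Params | None = None) -> tuple[bool, str]:
    """(eligible, reason). Reasons: 'ok', 'lying<5h', 'sinus<80%'."""
    params = params or Params()
    mask = night_lying_mask(labels, grid, params)
    lying_hours = mask.sum() * grid.epoch_s / 3600.0
    if lying_hours <= params.min_lying_hours:
        return False, "lying<5h"
    # beats falling inside qualifying epochs
    idx = grid.index_of(beats.beat_time)
    inside = (idx >= 0) & (idx < grid.n_epochs)
    in_lying = np.zeros(len(beats), dtype=bool)
    in_lying[inside] = mask[idx[inside]]
    if not in_lying.any():
        return False, "sinus<80%"
    is_n = beats.label[in_lying] == "N"
    if params.sinus_rule == "beats":
        frac = is_n.mean()
    else:  # duration-weighted by each beat's RR interval
        rr = beats.rr_ms[in_lying]
        ok = ~np.isnan(rr)
        frac = rr[ok & is_n].sum() / rr[ok].sum() if rr[ok].sum() > 0 else 0.0
    if frac < params.min_sinus_frac:
        return False, "sinus<80%"
    return True, "ok"


def per_posture_means(epoch_table: pd.DataFrame, params: Params | None = None,
                      columns: tuple[str, ...] = INDEX_COLUMNS) -> pd.DataFrame:
    """Mean of each index over the non-NaN epochs of each posture.

    A posture must hold at least ``min_epochs_per_posture`` epochs for its
    means to be reported; rows for absent/thin postures are NaN.
    """
    params = params or Params()
    cols = [c for c in columns if c in epoch_table.columns]
    rows = []
    for posture in LYING_POSTURES:
        sub = epoch_table[epoch_table["label"] == posture]
        row: dict = {"posture": posture, "n_epochs": len(sub)}
        for c in cols:
            row[c] = (sub[c].dropna().mean()
                      if len(sub) >= params.min_epochs_per_posture and sub[c].notna().any()
                      else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def cvhr_rate_per_posture(epoch_table: pd.DataFrame) -> dict[str, float]:
    """Apnea-positive epochs per hour spent in each posture (NaN if absent)."""
    rates = {}
    for posture in LYING_POSTURES:
        sub = epoch_table[epoch_table["label"] == posture]
        hours = len(sub) * 30.0 / 3600.0
        rates[posture] = float(sub["cvhr_pos"].sum()) / hours if hours > 0 else float("nan")
    return rates


def summarize_subject(subject_id: str, epoch_table: pd.DataFrame, grid: EpochGrid,
                      beats: BeatSeries, screen_result=None,
                      params: Params | None = None) -> dict:
    """Assemble the per-subject summary used by the cohort statistics."""
    from .posture import posture_percentages

    params = params or Params()
    eligible, reason = eligibility(epoch_table["label"].to_numpy(), grid, beats, params)
    summary: dict = {"subject_id": subject_id, "eligible": eligible, "reason": reason}
    if not eligible:
        return summary
    summary["posture_pct"] = posture_percentages(epoch_table["label"].to_numpy())
    summary["per_posture"] = per_posture_means(epoch_table, params)
    if "cvhr_pos" in epoch_table.columns:
        summary["cvhr_rate_per_posture"] = cvhr_rate_per_posture(epoch_table)
    if screen_result is not None:
        summary["ahi_est"] = screen_result.dips_per_hour
        summary["severity"] = screen_result.severity
    return summary
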