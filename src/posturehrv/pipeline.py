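"""End-to-end subject and cohort pipelines chaining all stages."""

from __future__ import annotations

import json
from pathlib import Path

from . import aggregate, cvhr, hrv, posture
from .core import AccelSeries, BeatSeries
from .io_formats import Params, log_params, read_accel, read_beats


def run_subject(accel: AccelSeries, beats: BeatSeries, subject_id: str = "subject",
                params: Params | None = None, compute_cvhr: bool = True) -> dict:
    """Posture classification, HRV indices and apnea screen for one subject.

    Returns ``epoch_table`` (one row per 30 s epoch: label, movement flag,
    HRV indices, CVHR flag), the epoch ``grid``, the ``screen`` result and
    the subject ``summary``.
    """
    params = params or Params()
    log_params(params, f"run_subject[{subject_id}]")
    cls = posture.classify_postures(accel, params)
    grid = cls["grid"]

    table = hrv.compute_epoch_hrv(beats, grid, params)
    table.insert(1, "t_start", grid.starts)
    table.insert(2, "label", cls["labels"])
    table.insert(3, "movement", cls["movement"])

    screen_result = None
    if compute_cvhr:
        nn = hrv.extract_nn(beats)
        if len(nn) >= 4:
            series = hrv.resample_2hz(nn, start_time=grid.start_time,
                                      duration_s=grid.n_epochs * grid.epoch_s, params=params)
            screen_result = cvhr.screen(nn, cls["labels"], grid, params, series=series)
            table["cvhr_pos"] = screen_result.epoch_positive
    if "cvhr_pos" not in table.columns:
        table["cvhr_pos"] = False

    summary = aggregate.summarize_subject(subject_id, table, grid, beats,
                                          screen_result=screen_result, params=params)
    return {"epoch_table": table, "grid": grid, "screen": screen_result,
            "summary": summary}


def run_subject_files(accel_path, beats_path, meta: dict | None = None,
                      params: Params | None = None, **kw) -> dict:
    accel = read_accel(accel_path)
    beats = read_beats(beats_path)
    meta = meta or {}
    result = run_subject(accel, beats, subject_id=meta.get("subject_id", "subject"),
                         params=params, **kw)
    result["summary"].update({k: meta[k] for k in ("age", "sex") if k in meta})
    return result


def run_cohort_dir(cohort_dir, params: Params | None = None, **kw) -> list[dict]:
    """Run every ``*_accel.csv``/``*_beats.csv``/``*_meta.json`` triplet in a
    directory (as written by ``synthetic.gen_cohort``); returns summaries."""
    cohort_dir = Path(cohort_dir)
    summaries = []
    for meta_path in sorted(cohort_dir.glob("*_meta.json")):
        meta = json.loads(meta_path.read_text())
        sid = meta["subject_id"]
        result = run_subject_files(cohort_dir / f"{sid}_accel.csv",
                                   cohort_dir / f"{sid}_beats.csv",
                                   meta=meta, params=params, **kw)
        summaries.append(result["summary"])
    return summaries
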