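"""End-to-end orchestration: raw recording -> bouts -> steps -> outcomes -> stats.

Each stage writes delimited-text artifacts plus a manifest (input hashes,
config hash, package version), so a rerun with identical inputs and config
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .bout_detection import (
    WalkingBout,
    bouts_to_table,
    classify_activity,
    lowpass_walking_filter,
    segment_bouts,
)
from .config import PipelineConfig
from .macro_metrics import DAY_S, BoutSet, participant_table
from .signal_io import (
    AccelRecording,
    detect_nonwear,
    orient_to_vertical,
    read_recording,
    resample_uniform,
    write_nonwear_bed,
)
from .step_detection import detect_contacts, lowpass_step_filter


@dataclass
class ProcessResult:
    participant: str
    bouts: list[WalkingBout]
    wear_hours_per_day: dict[int, float]
    nonwear: list[tuple[float, float]]

    def bout_set(self) -> BoutSet:
        return BoutSet(self.participant, self.bouts, self.wear_hours_per_day)


def _merge_runs(runs: list[tuple[float, float]], gap_s: float) -> list[list[float]]:
    merged: list[list[float]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def wear_hours_by_day(
    rec: AccelRecording, nonwear: list[tuple[float, float]], n_days: int | None = None
) -> dict[int, float]:
    """Worn hours per calendar day = recorded coverage minus non-wear overlap."""
    if len(rec) == 0:
        return {}
    t0, t1 = float(rec.t[0]), float(rec.t[-1])
    if n_days is None:
        n_days = int(t1 // DAY_S) + 1
    hours: dict[int, float] = {}
    for d in range(n_days):
        d0, d1 = max(d * DAY_S, t0), min((d + 1) * DAY_S, t1)
        cov = max(0.0, d1 - d0)
        off = sum(max(0.0, min(e, d1) - max(s, d0)) for s, e in nonwear)
        hours[d] = max(0.0, cov - off) / 3600.0
    return hours


def process_recording(
    rec: AccelRecording, cfg: PipelineConfig, participant: str = ""
) -> ProcessResult:
    """Run the detection chain on one recording (already in memory)."""
    rec, gaps = resample_uniform(rec, cfg.fs_hz, max_gap_s=cfg.nonwear_gap_s)
    nonwear = sorted(
        set(gaps)
        | set(
            detect_nonwear(
                rec,
                gap_s=cfg.nonwear_gap_s,
                still_window_min=cfg.nonwear_still_window_min,
                still_sd_g=cfg.nonwear_still_sd_g,
            )
        )
    )
    oriented = orient_to_vertical(
        rec, window_s=cfg.gravity_window_s, lowpass_hz=cfg.gravity_lowpass_hz
    )
    filtered = lowpass_walking_filter(
        oriented, cfg.walk_filter_cutoff_hz, cfg.walk_filter_order
    )
    mask = classify_activity(
        filtered, cfg.activity_window_s, cfg.upright_band_g, cfg.sd_threshold_g
    )
    runs = mask.candidate_runs(erode_s=cfg.activity_window_s / 2)

    v_step = lowpass_step_filter(
        oriented.v, oriented.fs, cfg.step_filter_cutoff_hz, cfg.step_filter_order
    )
    events: list[float] = []
    cadences: list[float] = []
    pad = 0.5  # s of context around each episode for the wavelet transform
    t0 = float(oriented.t[0])
    for s, e in _merge_runs(runs, cfg.rest_merge_s):
        i0 = max(0, int((s - pad - t0) * oriented.fs))
        i1 = min(len(v_step), int((e + pad - t0) * oriented.fs) + 1)
        seg = v_step[i0:i1]
        ev = detect_contacts(
            seg,
            oriented.fs,
            t0=t0 + i0 / oriented.fs,
            step_time_band_s=cfg.step_time_band_s,
            prominence_frac=cfg.prominence_frac,
            scale_factor=cfg.wavelet_scale_factor,
        )
        ic = ev.initial_contacts_s
        ic = ic[(ic >= s - pad) & (ic < e + pad)]
        events.extend(ic.tolist())
        if ic.size > 1:
            cadences.append((ic.size - 1) / (ic[-1] - ic[0]))

    cadence = float(np.median(cadences)) if cadences else 2.0
    bouts = segment_bouts(
        runs,
        sorted(set(events)),
        rest_merge_s=cfg.rest_merge_s,
        min_steps=cfg.min_steps,
        snap_halfstep_s=0.5 / cadence,
    )
    wear = wear_hours_by_day(rec, nonwear)
    return ProcessResult(participant, bouts, wear, nonwear)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, input_dir: str, out_dir: str) -> dict:
    """Process every ``*.csv`` recording in ``input_dir``; write artifacts + manifest.

    Returns the manifest dict.  Raises ``FileNotFoundError`` when the input
    directory holds no recordings.
    """
    files = sorted(
        f for f in os.listdir(input_dir)
        if f.endswith(".csv") and not f.endswith(("_bouts.csv", "_steps.csv"))
    )
    if not files:
        raise FileNotFoundError(f"no recordings found in {input_dir}")
    os.makedirs(out_dir, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(vars(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {},
        "stages": {},
    }
    bsets = []
    for fname in files:
        pid = os.path.splitext(fname)[0]
        path = os.path.join(input_dir, fname)
        manifest["inputs"][fname] = _hash_file(path)
        rec = read_recording(path, fs=cfg.fs_hz, range_g=cfg.accel_range_g)
        result = process_recording(rec, cfg, participant=pid)
        btab = bouts_to_table(result.bouts, pid)
        bout_path = os.path.join(out_dir, f"{pid}_bouts.tsv")
        btab.to_csv(bout_path, sep="\t", index=False, float_format="%.4f")
        nw_path = os.path.join(out_dir, f"{pid}_nonwear.bed")
        write_nonwear_bed(result.nonwear, pid, nw_path)
        manifest["stages"][pid] = {
            "bouts": _hash_file(bout_path),
            "n_bouts": len(result.bouts),
            "nonwear": _hash_file(nw_path),
        }
        bsets.append(result.bout_set())

    table, excluded = participant_table(
        bsets, cfg.min_valid_days, cfg.valid_day_wear_h, cfg.bout_bins_s
    )
    out_table = os.path.join(out_dir, "macro_outcomes.tsv")
    table.to_csv(out_table, sep="\t", index=False, float_format="%.6f")
    manifest["stages"]["macro_outcomes"] = {
        "path": _hash_file(out_table),
        "n_participants": len(table),
        "excluded": excluded,
    }
    man_path = os.path.join(out_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
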