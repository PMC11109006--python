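"""End-to-end orchestration: well table -> CSS -> DSS -> calls -> stats.

Every stage materializes its artifact (CSV tables) into the output
directory with a manifest recording the configuration hash and package
versions, so any run can be replayed and any stage inspected in
isolation.  Stages are pure functions of (inputs, config); the same
config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import (ThresholdSet, call_positive, classify_activity, robust_sd)
from .deconvolve import CssTrace, compensate_crosstalk, deconvolve
from .io import load_calibrations, read_well_table
from .kinetics import builtin_calibrations
from .preprocess import apply_coefficients, empty_well_coefficients, subtract_baseline

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (serialized verbatim to the output)."""

    well_table: str
    output_dir: str
    kinetics: dict[str, str] = field(
        default_factory=lambda: {"IL-5": "human-IL-5", "IL-13": "human-IL-13"}
    )
    calibration_file: str | None = None
    crosstalk: str | None = None        # e.g. "crosstalk-13to5" applied to IL-13
    crosstalk_target: str = "IL-13"
    crosstalk_reference: str = "IL-5"
    dt_frames: int = 5
    detect_mult: float = 3.0
    hyper_mult: float = 50.0
    min_run: int = 2
    max_gap: int = 3
    frame_interval: float = 1.0
    time_unit: str = "h"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate(self) -> None:
        if not Path(self.well_table).exists():
            raise FileNotFoundError(self.well_table)
        available = set(self._calibrations())
        for ch, name in self.kinetics.items():
            if name not in available:
                raise ValueError(f"unknown calibration {name!r} for channel {ch!r}")
        if self.crosstalk is not None and self.crosstalk not in available:
            raise ValueError(f"unknown cross-talk calibration {self.crosstalk!r}")

    def _calibrations(self) -> dict:
        cal = builtin_calibrations()
        if self.calibration_file:
            cal.update(load_calibrations(self.calibration_file))
        return cal

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    dss: pd.DataFrame
    css: pd.DataFrame
    thresholds: dict[str, ThresholdSet]
    output_dir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run preprocess -> deconvolve -> call -> classify on a well table.

    The cross-talk reference channel is always deconvolved first so its
    release train can compensate the affected channel.  Writes
    css.csv, dss.csv, calls.csv and manifest.json into ``output_dir``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)

    table = read_well_table(config.well_table)
    calibrations = config._calibrations()

    # --- preprocess ---------------------------------------------------
    coeffs = empty_well_coefficients(table)
    corrected = apply_coefficients(table, coeffs)
    traces, modes = subtract_baseline(
        corrected, frame_interval=config.frame_interval, time_unit=config.time_unit
    )

    # noise floor per channel from baseline-subtracted empty wells
    empty_ids = corrected.groupby("well_id")["cell_count"].max()
    empty_ids = set(empty_ids[empty_ids == 0].index)
    emp = corrected[corrected["well_id"].isin(empty_ids)].copy()
    thresholds: dict[str, ThresholdSet] = {}
    for ch, g in emp.groupby("channel"):
        # deviation of each empty-well frame from that well's initial value
        g = g.sort_values(["well_id", "frame"])
        init = g.groupby("well_id")["corrected_intensity"].transform("first")
        dev = (g["corrected_intensity"] - init).to_numpy()
        sd = robust_sd(dev)
        thresholds[ch] = ThresholdSet(
            sigma=sd.sigma, detect_mult=config.detect_mult,
            hyper_mult=config.hyper_mult, channel=ch, degenerate=sd.degenerate,
        )

    # --- deconvolve (cross-talk reference channel first) --------------
    channels = sorted({ch for (_, ch) in traces},
                      key=lambda c: c != config.crosstalk_reference)
    dss_by_key = {}
    ref_dss = {}
    for ch in channels:
        model = calibrations[config.kinetics[ch]].with_unit_check(config.time_unit)
        for (wid, tch), css in traces.items():
            if tch != ch:
                continue
            if (config.crosstalk is not None and ch == config.crosstalk_target
                    and wid in ref_dss):
                css = compensate_crosstalk(
                    css, ref_dss[wid], calibrations[config.crosstalk]
                )
            d = deconvolve(css, model, dt_frames=config.dt_frames)
            dss_by_key[(wid, ch)] = d
            if ch == config.crosstalk_reference:
                ref_dss[wid] = d

    # --- call + classify ----------------------------------------------
    call_rows = []
    for (wid, ch), css in traces.items():
        th = thresholds[ch]
        call = call_positive(css, th, min_run=config.min_run,
                             max_gap=config.max_gap, well_id=wid)
        cls = classify_activity(call, th)
        call_rows.append((
            wid, ch, call.positive, call.onset_frame, call.onset_time,
            call.max_css, cls, th.detection_limit, th.hyper_limit,
        ))
    calls = pd.DataFrame(
        call_rows,
        columns=["well_id", "channel", "positive", "onset_frame", "onset_time",
                 "max_css", "activity_class", "detection_limit", "hyper_limit"],
    ).sort_values(["channel", "well_id"]).reset_index(drop=True)

    css_rows = [
        (wid, ch, f, f * config.frame_interval, v)
        for (wid, ch), tr in sorted(traces.items())
        for f, v in enumerate(tr.values)
    ]
    css_df = pd.DataFrame(css_rows, columns=["well_id", "channel", "frame",
                                             "time", "css"])
    dss_rows = [
        (wid, ch, b, t, v, bool(c))
        for (wid, ch), d in sorted(dss_by_key.items())
        for b, (t, v, c) in enumerate(zip(d.bin_times, d.values, d.clamped))
    ]
    dss_df = pd.DataFrame(dss_rows, columns=["well_id", "channel", "bin",
                                             "time", "dss", "clamped"])

    calls.to_csv(out / "calls.csv", index=False)
    css_df.to_csv(out / "css.csv", index=False)
    dss_df.to_csv(out / "dss.csv", index=False)
    modes.to_csv(out / "baseline_modes.csv", index=False)
    manifest = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "inputs": {"well_table": str(config.well_table)},
        "thresholds": {ch: {"sigma": th.sigma,
                            "detection_limit": th.detection_limit,
                            "hyper_limit": th.hyper_limit}
                       for ch, th in thresholds.items()},
        "n_wells": int(calls["well_id"].nunique()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(calls=calls, dss=dss_df, css=css_df,
                          thresholds=thresholds, output_dir=out)
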