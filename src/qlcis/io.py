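"""File formats: calibration files, well tables, layout configs, image stacks.

Calibrations live in flat key-value text (one section per parameter set)
and round-trip exactly.  Well tables are long-format CSV; layouts are YAML;
image stacks are TIFF via tifffile.
"""

from __future__ import annotations

import configparser
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .kinetics import AntibodyKinetics, CrossTalkKernel
from .simulate import DishLayout

__all__ = [
    "save_calibrations", "load_calibrations",
    "read_well_table", "write_well_table",
    "load_layout", "save_layout",
    "read_stack", "write_stack",
]


def _fmt_floats(values) -> str:
    return ", ".join(repr(float(v)) for v in values)


def _parse_floats(s: str) -> tuple[float, ...]:
    return tuple(float(x) for x in s.split(","))


def save_calibrations(path, calibrations: dict) -> None:
    cp = configparser.ConfigParser()
    for name, cal in calibrations.items():
        if isinstance(cal, AntibodyKinetics):
            cp[name] = {
                "kind": "antibody",
                "analyte": cal.analyte,
                "time_unit": cal.time_unit,
                "decay_taus": _fmt_floats(cal.decay_taus),
                "decay_weights": _fmt_floats(cal.decay_weights),
                "assoc_taus": _fmt_floats(cal.assoc_taus),
                "assoc_weights": _fmt_floats(cal.assoc_weights),
            }
        elif isinstance(cal, CrossTalkKernel):
            cp[name] = {
                "kind": "crosstalk",
                "label": cal.label,
                "time_unit": cal.time_unit,
                "tau_decay": repr(float(cal.tau_decay)),
                "tau_fast": repr(float(cal.tau_fast)),
                "tau_slow": repr(float(cal.tau_slow)),
                "alpha": repr(float(cal.alpha)),
                "beta": repr(float(cal.beta)),
            }
        else:
            raise TypeError(f"cannot serialize {type(cal)}")
    with open(path, "w") as fh:
        cp.write(fh)


def load_calibrations(path) -> dict:
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    out: dict = {}
    for name in cp.sections():
        sec = cp[name]
        if sec["kind"] == "antibody":
            out[name] = AntibodyKinetics(
                analyte=sec["analyte"], time_unit=sec["time_unit"],
                decay_taus=_parse_floats(sec["decay_taus"]),
                decay_weights=_parse_floats(sec["decay_weights"]),
                assoc_taus=_parse_floats(sec["assoc_taus"]),
                assoc_weights=_parse_floats(sec["assoc_weights"]),
            )
        elif sec["kind"] == "crosstalk":
            out[name] = CrossTalkKernel(
                label=sec["label"], time_unit=sec["time_unit"],
                tau_decay=float(sec["tau_decay"]), tau_fast=float(sec["tau_fast"]),
                tau_slow=float(sec["tau_slow"]), alpha=float(sec["alpha"]),
                beta=float(sec["beta"]),
            )
        else:
            raise ValueError(f"unknown calibration kind {sec['kind']!r}")
    return out


def write_well_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_well_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"well_id", "chamber", "quadrant", "frame", "channel",
                "mean_intensity", "cell_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    return df


def save_layout(path, layout: DishLayout) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "chambers": layout.chambers,
                "wells_per_chamber": layout.wells_per_chamber,
                "well_size_um": layout.well_size_um,
                "pitch_um": layout.pitch_um,
                "grid_cols": layout.grid_cols,
            },
            fh,
        )


def load_layout(path) -> DishLayout:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return DishLayout(**d)


def write_stack(path, array: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)
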