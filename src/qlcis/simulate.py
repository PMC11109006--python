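"""Synthetic secretion experiments on a nanoliter-well array.

Generates everything the analysis pipeline consumes, with known ground
truth: the dish layout (4 chambers x 996 cubic wells, 80 um side, 115 um
pitch), a heterogeneous cell population with three secretory phenotypes,
the fluorescence traces those cells would produce through the staining
kinetics, stratified illumination drift, detection noise, and — in image
mode — Gaussian secretion spots near a wandering cell centroid.

Release model per phenotype (amplitudes in multiples of the detection
noise SD): a *silent* cell releases nothing; a *slightly active* cell
releases an onset burst (default 10x noise SD) followed by a low trickle
that ceases within a bounded window (default 10-30 h); a *hyperactive*
cell releases a large burst (default 100x) and sustains a high rate to
the observation horizon.  Onset times are log-normal, spanning roughly
1-12 h after stimulation.  The onset burst is what makes the phenotypes
separable by maximum cumulative signal while keeping the first
supra-threshold frame at the true onset.

All randomness flows from one ``numpy.random.default_rng`` seed
(PCG64); identical specs and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolve import CssTrace, DssTrace, forward_convolve
from .kinetics import AntibodyKinetics, CrossTalkKernel, StandardCurve, builtin_calibrations
from .preprocess import QUADRANTS

__all__ = [
    "DishLayout",
    "PopulationSpec",
    "make_dish_layout",
    "simulate_population",
    "render_observations",
    "render_spot_stack",
    "simulate_microinjection",
]

CLASSES = ("silent", "slightly_active", "hyperactive")


@dataclass(frozen=True)
class DishLayout:
    """Geometry of the well array."""

    chambers: int = 4
    wells_per_chamber: int = 996
    well_size_um: float = 80.0
    pitch_um: float = 115.0
    grid_cols: int = 36

    def __post_init__(self) -> None:
        if self.pitch_um <= self.well_size_um:
            raise ValueError("pitch must exceed well size")
        if self.chambers < 1 or self.wells_per_chamber < 1 or self.grid_cols < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """Study conditions for a synthetic population.

    Fractions apply to *occupied* wells; ``occupancy`` is the probability a
    well received a cell (empty wells are the normalization/threshold
    reference).  Scales are in multiples of ``noise_sd``.
    """

    fraction_silent: float = 0.33
    fraction_slight: float = 0.50
    fraction_hyper: float = 0.17
    occupancy: float = 0.5
    onset_log_mean: float = np.log(4.0)   # median onset ~4 h post stimulation
    onset_log_sd: float = 0.6             # bulk of onsets within ~1-12 h
    burst_slight: float = 10.0
    burst_hyper: float = 100.0
    trickle_slight: float = 0.1           # per-frame rate after the burst
    rate_hyper: float = 2.0               # sustained per-frame rate
    slight_duration_h: tuple[float, float] = (10.0, 30.0)
    noise_sd: float = 1.0
    baseline: float = 100.0
    drift_max: float = 1.0                # 1.0 = no drift; 2.0 = up to x2
    frame_interval: float = 1.0
    time_unit: str = "h"
    horizon: float = 72.0
    channels: tuple[str, ...] = ("IL-5",)
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.fraction_silent, self.fraction_slight, self.fraction_hyper)
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("class fractions must be non-negative and sum to 1")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must be in (0, 1]")
        if self.noise_sd < 0 or self.drift_max < 1.0:
            raise ValueError("noise_sd >= 0 and drift_max >= 1 required")

    @property
    def n_frames(self) -> int:
        return int(round(self.horizon / self.frame_interval)) + 1


def make_dish_layout(spec: DishLayout = DishLayout()) -> pd.DataFrame:
    """Deterministic well table: id, chamber, grid position, coordinates, quadrant.

    Wells fill a ``grid_cols``-wide raster per chamber.  Each 2x2 block of
    wells maps to one microscope field of view, so the quadrant (position
    within the field of view) alternates with row/column parity.
    """
    rows = []
    for ch in range(1, spec.chambers + 1):
        for i in range(spec.wells_per_chamber):
            r, c = divmod(i, spec.grid_cols)
            quadrant = QUADRANTS[(r % 2) * 2 + (c % 2)]
            rows.append((
                f"c{ch}w{i:04d}", ch, r, c,
                c * spec.pitch_um, r * spec.pitch_um, quadrant,
            ))
    return pd.DataFrame(
        rows, columns=["well_id", "chamber", "row", "col", "x_um", "y_um", "quadrant"],
    )


def _release_train(cls: str, onset_frame: int, n_frames: int,
                   spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    train = np.zeros(n_frames)
    if cls == "silent" or onset_frame >= n_frames:
        return train
    sigma = spec.noise_sd if spec.noise_sd > 0 else 1.0
    if cls == "slightly_active":
        train[onset_frame] = spec.burst_slight * sigma
        dur_h = rng.uniform(*spec.slight_duration_h)
        end = min(n_frames, onset_frame + int(round(dur_h / spec.frame_interval)))
        train[onset_frame + 1 : end] = spec.trickle_slight * sigma
    elif cls == "hyperactive":
        train[onset_frame] = spec.burst_hyper * sigma
        train[onset_frame + 1 :] = spec.rate_hyper * sigma
    else:
        raise ValueError(f"unknown class {cls!r}")
    return train


def simulate_population(
    layout: pd.DataFrame, spec: PopulationSpec
) -> pd.DataFrame:
    """Ground truth per well: occupancy, phenotype, onset, release train.

    Returns one row per (well, channel) with columns well_id, channel,
    cell_count, true_class, onset_frame, onset_time and the per-frame
    release train (column ``train``, an ndarray).  The same phenotype and
    onset drive every channel of a well (a cell secreting IL-5 and IL-13
    does so with the same activity pattern).
    """
    rng = np.random.default_rng(spec.seed)
    n = len(layout)
    occupied = rng.random(n) < spec.occupancy
    classes = np.where(
        occupied,
        rng.choice(CLASSES, size=n, p=[spec.fraction_silent, spec.fraction_slight,
                                       spec.fraction_hyper]),
        "empty",
    )
    onsets_h = rng.lognormal(spec.onset_log_mean, spec.onset_log_sd, size=n)
    n_frames = spec.n_frames
    rows = []
    for i, wid in enumerate(layout["well_id"]):
        cls = classes[i]
        if cls in ("empty", "silent"):
            onset_frame = None
        else:
            onset_frame = int(np.clip(round(onsets_h[i] / spec.frame_interval),
                                      1, n_frames - 2))
        for ch in spec.channels:
            train = _release_train(
                cls if cls != "empty" else "silent",
                onset_frame if onset_frame is not None else n_frames,
                n_frames, spec, rng,
            )
            rows.append((
                wid, ch, 0 if cls == "empty" else 1,
                "silent" if cls == "empty" else cls,
                onset_frame,
                None if onset_frame is None else onset_frame * spec.frame_interval,
                train,
            ))
    truth = pd.DataFrame(
        rows, columns=["well_id", "channel", "cell_count", "true_class",
                       "onset_frame", "onset_time", "train"],
    )
    return truth.merge(layout, on="well_id")


def _drift_field(spec: PopulationSpec, layout: pd.DataFrame,
                 rng: np.random.Generator) -> dict[tuple, np.ndarray]:
    """Per-(quadrant, chamber) multiplicative drift series over frames."""
    field = {}
    lo, hi = 1.0 / spec.drift_max, spec.drift_max
    for ch in sorted(layout["chamber"].unique()):
        for q in QUADRANTS:
            if spec.drift_max == 1.0:
                field[(q, ch)] = np.ones(spec.n_frames)
            else:
                # smooth log-uniform wander, clipped to [1/drift_max, drift_max]
                steps = rng.normal(0, 0.08, size=spec.n_frames)
                walk = np.exp(np.cumsum(steps) + rng.uniform(np.log(lo), np.log(hi)))
                field[(q, ch)] = np.clip(walk, lo, hi)
    return field


def render_observations(
    truth: pd.DataFrame,
    spec: PopulationSpec,
    kinetics: dict[str, AntibodyKinetics] | None = None,
    crosstalk: CrossTalkKernel | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Render the well-table observations the preprocessing stage consumes.

    Each well/channel release train is forward-convolved with its staining
    kernel; the clean CSS rides on ``baseline``, is multiplied by the
    (quadrant, chamber, frame) drift factor, and receives additive
    Gaussian detection noise.  With a ``crosstalk`` kernel and channels
    ("IL-5", "IL-13"), the IL-13 fluorescence additionally carries the
    cross-reaction signal of the captured IL-5.

    Returns (long-format well table, {(well_id, channel): clean CSS}).
    The clean (pre-noise, pre-drift) signals let tests check consistency
    exactly.
    """
    if kinetics is None:
        cal = builtin_calibrations()
        kinetics = {"IL-5": cal["human-IL-5"], "IL-13": cal["human-IL-13"]}
    rng = np.random.default_rng(spec.seed + 1)
    drift = _drift_field(spec, truth, rng)
    n_frames = spec.n_frames

    clean: dict[tuple[str, str], np.ndarray] = {}
    il5_dss: dict[str, DssTrace] = {}
    rows = []
    ordered = sorted(spec.channels, key=lambda c: c != "IL-5")  # IL-5 first
    for ch_name in ordered:
        model = kinetics[ch_name].with_unit_check(spec.time_unit)
        for _, rec in truth[truth["channel"] == ch_name].iterrows():
            dss = DssTrace(
                values=np.asarray(rec["train"], dtype=float)[: n_frames - 1],
                dt_frames=1, frame_interval=spec.frame_interval,
                time_unit=spec.time_unit, channel=ch_name, origin=rec["well_id"],
            )
            css = forward_convolve(dss, model).values  # length n_frames
            if ch_name == "IL-5":
                il5_dss[rec["well_id"]] = dss
            if ch_name == "IL-13" and crosstalk is not None:
                ref = il5_dss.get(rec["well_id"])
                if ref is not None:
                    from .deconvolve import crosstalk_signal
                    css = css + crosstalk_signal(ref, crosstalk, n_frames)
            clean[(rec["well_id"], ch_name)] = css
            d = drift[(rec["quadrant"], rec["chamber"])]
            noisy = (spec.baseline + css) * d + rng.normal(0, spec.noise_sd, n_frames)
            for f in range(n_frames):
                rows.append((
                    rec["well_id"], rec["chamber"], rec["quadrant"],
                    rec["row"], rec["col"], f, f * spec.frame_interval,
                    ch_name, noisy[f], rec["cell_count"],
                ))
    table = pd.DataFrame(
        rows, columns=["well_id", "chamber", "quadrant", "row", "col", "frame",
                       "time", "channel", "mean_intensity", "cell_count"],
    )
    return table, clean


def render_spot_stack(
    amplitudes: np.ndarray,
    cell_xy_um: np.ndarray,
    source_offset_um: tuple[float, float] = (0.0, 0.0),
    image_size_px: int = 16,
    pixel_size_um: float = 5.0,
    spot_sigma_um: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render per-frame secretion-spot images for one well.

    Frame t holds a 2D Gaussian of peak ``amplitudes[t]`` centered at the
    cell position plus ``source_offset_um``, with additive Gaussian noise.
    Spot shape is phenomenological (no diffusion physics).  Returns a
    (T, image_size_px, image_size_px) stack.
    """
    rng = np.random.default_rng(seed)
    amplitudes = np.asarray(amplitudes, dtype=float)
    cell_xy_um = np.asarray(cell_xy_um, dtype=float)
    T = amplitudes.size
    if cell_xy_um.shape != (T, 2):
        raise ValueError("cell_xy_um must be (T, 2)")
    coords = (np.arange(image_size_px) + 0.5) * pixel_size_um
    xx, yy = np.meshgrid(coords, coords)
    stack = np.empty((T, image_size_px, image_size_px))
    for t in range(T):
        cx = cell_xy_um[t, 0] + source_offset_um[0]
        cy = cell_xy_um[t, 1] + source_offset_um[1]
        stack[t] = amplitudes[t] * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * spot_sigma_um**2)
        )
        if noise_sd > 0:
            stack[t] += rng.normal(0, noise_sd, stack[t].shape)
    return stack


def simulate_microinjection(
    kinetics: AntibodyKinetics,
    amount: float,
    times: np.ndarray,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> StandardCurve:
    """Standard curve from an instantaneous release of ``amount`` at t=0.

    Intensities are amount * A(t) with multiplicative Gaussian noise of
    relative SD ``noise_frac`` — the calibration experiment a microinjected
    bolus of recombinant protein realizes.
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    y = amount * np.asarray(kinetics.evaluate(times), dtype=float)
    if noise_frac > 0:
        y = y * (1.0 + rng.normal(0, noise_frac, y.shape))
    return StandardCurve(
        times=times, intensities=y, time_unit=kinetics.time_unit,
        release_amount=amount,
        noise_sd=None if noise_frac == 0 else noise_frac,
    )
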