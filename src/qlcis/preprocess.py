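"""From raw frames / raw well traces to cumulative secretion signals.

Long time-lapse recordings on a scanned stage drift both geometrically
(pixel shifts between revisits of a field of view) and photometrically
(excitation intensity varies with field-of-view position, chamber and
time).  The empty wells of the dish — wells that received no cell — are the
in-situ photometric reference: their mean intensity per (field-of-view
quadrant, chamber, frame) stratum, divided by the grand mean, gives a
multiplicative correction coefficient for every well in that stratum.

After coefficient normalization each well's own initial intensity is the
baseline, except for wells whose initial intensity is an outlier above
Q3 + 1.5*IQR of the initial-intensity population (autofluorescent
contaminants); those fall back to the per-frame mean empty-well intensity.
The result is the cumulative secretion signal (CSS) trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deconvolve import CssTrace

__all__ = [
    "FrameStack",
    "WellRecord",
    "QUADRANTS",
    "align_stack",
    "denoise_and_bin",
    "empty_well_coefficients",
    "apply_coefficients",
    "subtract_baseline",
    "wells_from_table",
]

QUADRANTS = ("upper_left", "upper_right", "lower_left", "lower_right")

WELL_TABLE_COLUMNS = [
    "well_id", "chamber", "quadrant", "frame", "time",
    "channel", "mean_intensity", "cell_count",
]


@dataclass
class FrameStack:
    """Multi-channel time-lapse stack: channel -> (T, Y, X) array."""

    data: dict[str, np.ndarray]
    frame_interval: float
    time_unit: str
    pixel_size_um: float
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.data.items()}
        if not shapes:
            raise ValueError("stack needs at least one channel")
        first = next(iter(shapes.values()))
        if any(len(s) != 3 for s in shapes.values()):
            raise ValueError("each channel must be a (T, Y, X) array")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel geometries differ: {shapes}")
        if self.frame_interval <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_interval and pixel size must be positive")
        self.data = {ch: np.asarray(a, dtype=float) for ch, a in self.data.items()}

    @property
    def n_frames(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def channels(self) -> list[str]:
        return list(self.data)


@dataclass
class WellRecord:
    """One nanoliter well: position metadata, cell counts and intensity traces."""

    well_id: str
    chamber: int
    quadrant: str
    row: int
    col: int
    cell_count: np.ndarray
    traces: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"quadrant must be one of {QUADRANTS}")
        n = len(self.cell_count)
        if any(len(tr) != n for tr in self.traces.values()):
            raise ValueError("trace length must equal frame count")

    @property
    def empty(self) -> bool:
        return bool(np.all(np.asarray(self.cell_count) == 0))


# ---------------------------------------------------------------------------
# Frame alignment
# ---------------------------------------------------------------------------

def _best_shift(ref: np.ndarray, mov: np.ndarray, max_shift: int):
    """Integer (dy, dx) maximizing normalized cross-correlation within a window.

    Returns (dy, dx, confidence); confidence is the normalized correlation
    peak in [-1, 1].
    """
    a = ref - ref.mean()
    b = mov - mov.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0, 0, 0.0
    # circular FFT cross-correlation; window kept well under the image size
    corr = np.fft.irfft2(np.fft.rfft2(a) * np.conj(np.fft.rfft2(b)), s=a.shape)
    corr /= na * nb
    ny, nx = corr.shape
    dys = np.r_[0 : max_shift + 1, -max_shift:0]
    dxs = np.r_[0 : max_shift + 1, -max_shift:0]
    window = corr[np.ix_(dys % ny, dxs % nx)]
    k = np.unravel_index(np.argmax(window), window.shape)
    return int(dys[k[0]]), int(dxs[k[1]]), float(window[k])


def align_stack(
    stack: FrameStack,
    reference_channel: str,
    max_shift: int = 10,
    min_confidence: float = 0.2,
) -> tuple[FrameStack, list[tuple[int, int]], list[bool]]:
    """Register every frame to frame 0 by an integer translation.

    All channels receive the shift estimated on ``reference_channel``.
    Pixels shifted in from outside the frame become NaN (invalid), never
    zero.  Featureless or decorrelated frames (normalized correlation peak
    below ``min_confidence``) keep a zero shift and are flagged
    low-confidence.

    Returns (aligned stack, correction shifts applied, confident flags).
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames to align")
    ref = stack.data[reference_channel][0]
    shifts: list[tuple[int, int]] = []
    confident: list[bool] = []
    aligned = {ch: a.copy() for ch, a in stack.data.items()}
    for t in range(stack.n_frames):
        if t == 0:
            shifts.append((0, 0))
            confident.append(True)
            continue
        dy, dx, conf = _best_shift(ref, stack.data[reference_channel][t], max_shift)
        if conf < min_confidence:
            shifts.append((0, 0))
            confident.append(False)
            continue
        # the frame is displaced by (dy, dx); shift it back
        shifts.append((dy, dx))
        confident.append(True)
        for ch in aligned:
            frame = np.roll(stack.data[ch][t], shift=(dy, dx), axis=(0, 1))
            if dy > 0:
                frame[:dy, :] = np.nan
            elif dy < 0:
                frame[dy:, :] = np.nan
            if dx > 0:
                frame[:, :dx] = np.nan
            elif dx < 0:
                frame[:, dx:] = np.nan
            aligned[ch][t] = frame
    out = FrameStack(
        data=aligned, frame_interval=stack.frame_interval,
        time_unit=stack.time_unit, pixel_size_um=stack.pixel_size_um,
        timestamps=stack.timestamps,
    )
    return out, shifts, confident


# ---------------------------------------------------------------------------
# Denoising and binning
# ---------------------------------------------------------------------------

def denoise_and_bin(
    stack: FrameStack, median_window: int = 5, bin_factor: int = 5
) -> FrameStack:
    """Background-subtract, median-filter in time, and spatially bin.

    Order: the initial frame (background) is subtracted first; a
    ``median_window``-frame rolling median (symmetric window, shrinking at
    the edges, no padding) suppresses single-frame noise; then the image is
    cropped to a multiple of ``bin_factor`` and block-averaged.  Mean (not
    sum) binning keeps intensities on the unbinned calibration scale.
    """
    if median_window % 2 != 1:
        raise ValueError("median_window must be odd")
    if median_window > stack.n_frames:
        raise ValueError("median window exceeds frame count")
    if bin_factor < 1:
        raise ValueError("bin_factor must be >= 1")
    half = median_window // 2
    out: dict[str, np.ndarray] = {}
    for ch, arr in stack.data.items():
        sub = arr - arr[0]
        med = np.empty_like(sub)
        T = sub.shape[0]
        for t in range(T):
            h = min(half, t, T - 1 - t)
            med[t] = np.median(sub[t - h : t + h + 1], axis=0)
        ny = (med.shape[1] // bin_factor) * bin_factor
        nx = (med.shape[2] // bin_factor) * bin_factor
        c = med[:, :ny, :nx]
        binned = c.reshape(T, ny // bin_factor, bin_factor,
                           nx // bin_factor, bin_factor).mean(axis=(2, 4))
        out[ch] = binned
    return FrameStack(
        data=out, frame_interval=stack.frame_interval, time_unit=stack.time_unit,
        pixel_size_um=stack.pixel_size_um * bin_factor, timestamps=stack.timestamps,
    )


# ---------------------------------------------------------------------------
# Empty-well coefficient normalization
# ---------------------------------------------------------------------------

def _well_table(wells) -> pd.DataFrame:
    if isinstance(wells, pd.DataFrame):
        return wells
    rows = []
    for w in wells:
        for ch, tr in w.traces.items():
            for f, v in enumerate(tr):
                rows.append((w.well_id, w.chamber, w.quadrant, f, ch,
                             float(v), int(w.cell_count[f])))
    return pd.DataFrame(
        rows, columns=["well_id", "chamber", "quadrant", "frame", "channel",
                       "mean_intensity", "cell_count"],
    )


def empty_well_coefficients(wells) -> pd.DataFrame:
    """Illumination-drift coefficients from empty wells, per channel.

    For each (channel, quadrant, chamber, frame) stratum the coefficient is
    the mean empty-well intensity of the stratum divided by the grand mean
    over all empty wells and frames of that channel.  Dividing a well's
    intensity by its stratum coefficient removes multiplicative drift.
    Strata without any empty well fall back to the chamber-level
    coefficient (with a warning).

    ``wells`` is a list of WellRecord or a long-format table with columns
    well_id, chamber, quadrant, frame, channel, mean_intensity, cell_count.
    """
    df = _well_table(wells)
    empty_ids = df.groupby("well_id")["cell_count"].max()
    empty_ids = set(empty_ids[empty_ids == 0].index)
    if not empty_ids:
        raise ValueError("no empty wells available for normalization")
    emp = df[df["well_id"].isin(empty_ids)]

    grand = emp.groupby("channel")["mean_intensity"].mean()
    strat = (emp.groupby(["channel", "quadrant", "chamber", "frame"])
             ["mean_intensity"].mean().rename("stratum_mean").reset_index())
    strat["coefficient"] = strat.apply(
        lambda r: r["stratum_mean"] / grand[r["channel"]], axis=1
    )

    # fill missing strata with the chamber-level coefficient
    full_index = (df[["channel", "quadrant", "chamber", "frame"]]
                  .drop_duplicates())
    coeffs = full_index.merge(
        strat[["channel", "quadrant", "chamber", "frame", "coefficient"]],
        how="left", on=["channel", "quadrant", "chamber", "frame"],
    )
    if coeffs["coefficient"].isna().any():
        chamber_mean = (emp.groupby(["channel", "chamber", "frame"])
                        ["mean_intensity"].mean().rename("chamber_mean")
                        .reset_index())
        coeffs = coeffs.merge(chamber_mean, how="left",
                              on=["channel", "chamber", "frame"])
        fallback = coeffs["chamber_mean"] / coeffs["channel"].map(grand)
        n_missing = int(coeffs["coefficient"].isna().sum())
        warnings.warn(
            f"{n_missing} strata had no empty wells; using chamber-level "
            "coefficients", stacklevel=2,
        )
        coeffs["coefficient"] = coeffs["coefficient"].fillna(fallback)
        coeffs = coeffs.drop(columns=["chamber_mean"])
    return coeffs


def apply_coefficients(wells, coeffs: pd.DataFrame) -> pd.DataFrame:
    """Divide each intensity by its stratum coefficient.

    Returns the long-format table with a ``corrected_intensity`` column.
    """
    df = _well_table(wells).merge(
        coeffs, how="left", on=["channel", "quadrant", "chamber", "frame"],
    )
    if df["coefficient"].isna().any():
        raise ValueError("coefficient table does not cover all strata")
    df["corrected_intensity"] = df["mean_intensity"] / df["coefficient"]
    return df


# ---------------------------------------------------------------------------
# Baseline subtraction
# ---------------------------------------------------------------------------

def subtract_baseline(
    corrected: pd.DataFrame,
    frame_interval: float,
    time_unit: str,
    iqr_mult: float = 1.5,
) -> tuple[dict[tuple[str, str], CssTrace], pd.DataFrame]:
    """Baseline-subtract every occupied well's corrected trace into a CSS.

    The default baseline is the well's own initial (frame 0) corrected
    intensity.  Wells whose initial intensity exceeds Q3 + ``iqr_mult``*IQR
    of the initial-intensity population (per channel) instead subtract the
    per-frame mean empty-well corrected intensity — this removes
    autofluorescent contaminants that would otherwise inflate the baseline.
    The rule is one-sided (contaminants only brighten).

    Returns ({(well_id, channel): CssTrace}, per-well baseline-mode table).
    """
    df = corrected.sort_values(["channel", "well_id", "frame"])
    empty_ids = df.groupby("well_id")["cell_count"].max()
    empty_ids = set(empty_ids[empty_ids == 0].index)

    emp = df[df["well_id"].isin(empty_ids)]
    empty_by_frame = (emp.groupby(["channel", "frame"])["corrected_intensity"]
                      .mean())

    traces: dict[tuple[str, str], CssTrace] = {}
    modes = []
    for ch, chdf in df.groupby("channel"):
        initials = (chdf[chdf["frame"] == chdf["frame"].min()]
                    .set_index("well_id")["corrected_intensity"])
        q1, q3 = np.percentile(initials.to_numpy(), [25, 75])
        cutoff = q3 + iqr_mult * (q3 - q1)
        for wid, wdf in chdf.groupby("well_id"):
            if wid in empty_ids:
                continue
            vals = wdf.sort_values("frame")["corrected_intensity"].to_numpy()
            init = initials[wid]
            outlier = bool(init > cutoff)
            if outlier:
                base = empty_by_frame.loc[ch].reindex(
                    wdf.sort_values("frame")["frame"]).to_numpy()
            else:
                base = init
            traces[(wid, ch)] = CssTrace(
                values=vals - base, frame_interval=frame_interval,
                time_unit=time_unit, channel=ch, origin=str(wid),
            )
            modes.append((wid, ch, "empty_well" if outlier else "own_initial"))
    mode_df = pd.DataFrame(modes, columns=["well_id", "channel", "baseline_mode"])
    return traces, mode_df


def wells_from_table(df: pd.DataFrame) -> list[WellRecord]:
    """Build WellRecord objects from a long-format well table."""
    records = []
    for (wid, chamber, quadrant), g in df.groupby(["well_id", "chamber", "quadrant"]):
        g = g.sort_values("frame")
        frames = np.sort(g["frame"].unique())
        traces = {}
        for ch, cg in g.groupby("channel"):
            traces[ch] = cg.set_index("frame")["mean_intensity"].reindex(frames).to_numpy()
        counts = (g.groupby("frame")["cell_count"].max().reindex(frames)
                  .to_numpy(dtype=int))
        records.append(WellRecord(
            well_id=str(wid), chamber=int(chamber), quadrant=str(quadrant),
            row=int(g["row"].iloc[0]) if "row" in g else -1,
            col=int(g["col"].iloc[0]) if "col" in g else -1,
            cell_count=counts, traces=traces,
        ))
    return records
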