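"""Temporal deconvolution of cumulative secretion signals.

The fluorescence measured on a well floor is a *cumulative* secretion
signal (CSS): every past release still contributes through the staining
kernel A.  On the dt-binned time grid the forward model is the discrete
causal convolution

    CSS_{t+1} = sum_{i=0..t} DSS_i * A_{t+1-i},        A_k = A(k * dt)

and the deconvoluted secretion signal (DSS, the per-bin release amount) is
recovered by the triangular recursion

    DSS_t = (CSS_{t+1} - sum_{i<t} DSS_i * A_{t+1-i}) / A_1 .

Secretion cannot be negative, so negative intermediates are clamped to zero
and the clamped value is what enters later history sums; this also damps
noise amplification in the recursion.  An optional non-negative
least-squares solver over the whole trace is provided as a cross-check.

The IL-13 channel additionally carries a cross-reaction signal from
captured IL-5; `compensate_crosstalk` subtracts the predicted cross-signal
(IL-5 DSS convolved with the cross-talk kernel chi) from the raw IL-13
fluorescence before deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .kinetics import AntibodyKinetics, CrossTalkKernel, UnitError

__all__ = [
    "CssTrace",
    "DssTrace",
    "forward_convolve",
    "deconvolve",
    "crosstalk_signal",
    "compensate_crosstalk",
    "smooth_dss",
]

# intermediates above -CLAMP_FLOOR * scale are round-off, not real clamping
_CLAMP_FLOOR = 1e-12


@dataclass
class CssTrace:
    """Cumulative secretion signal sampled once per frame."""

    values: np.ndarray
    frame_interval: float
    time_unit: str
    channel: str = ""
    origin: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("CSS trace must be 1-D with length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("CSS values must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.values = v

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_interval


@dataclass
class DssTrace:
    """Per-bin release amounts; bin i covers frames [i*dt, (i+1)*dt)."""

    values: np.ndarray
    dt_frames: int
    frame_interval: float
    time_unit: str
    channel: str = ""
    origin: str = ""
    clamped: np.ndarray | None = None
    clamped_mass: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("DSS must be 1-D")
        if np.any(v < 0):
            raise ValueError("DSS values must be non-negative")
        self.values = v
        if self.clamped is None:
            self.clamped = np.zeros(v.size, dtype=bool)

    @property
    def bin_times(self) -> np.ndarray:
        """Start time of each bin, in ``time_unit``."""
        return np.arange(self.values.size) * self.dt_frames * self.frame_interval


def _kernel_samples(model: AntibodyKinetics, n: int, dt_time: float) -> np.ndarray:
    """A_k = A(k * dt_time) for k = 1..n."""
    return np.asarray(model.evaluate(np.arange(1, n + 1) * dt_time), dtype=float)


def forward_convolve(dss: DssTrace, model: AntibodyKinetics) -> CssTrace:
    """Forward model: render the CSS a release train would produce.

    Output is sampled on the same dt grid, length n+1 with CSS_0 = 0.
    """
    model.with_unit_check(dss.time_unit)
    d = dss.values
    if np.any(d < 0):
        raise ValueError("release train must be non-negative")
    n = d.size
    dt_time = dss.dt_frames * dss.frame_interval
    a = _kernel_samples(model, n, dt_time)
    css = np.zeros(n + 1)
    if n:
        css[1:] = np.convolve(d, a)[:n]
    return CssTrace(
        values=css,
        frame_interval=dt_time,
        time_unit=dss.time_unit,
        channel=dss.channel,
        origin=dss.origin,
    )


def deconvolve(
    css: CssTrace,
    model: AntibodyKinetics,
    dt_frames: int = 5,
    method: str = "recursive",
) -> DssTrace:
    """Invert the staining-kinetics convolution on a dt-binned grid.

    ``method="recursive"`` runs the clamped triangular recursion (clamped
    zeros propagate into later history sums); ``method="nnls"`` solves the
    whole-trace non-negative least-squares problem instead and is intended
    as a cross-check.  Returns the DSS with per-bin clamp flags and the
    total clamped (negative) mass discarded.
    """
    model.with_unit_check(css.time_unit)
    if dt_frames < 1:
        raise ValueError("dt_frames must be >= 1")
    n_bins = (css.values.size - 1) // dt_frames
    if n_bins < 1:
        raise ValueError("trace too short for the requested bin width")
    c = css.values[:: dt_frames][: n_bins + 1]
    dt_time = dt_frames * css.frame_interval
    a = _kernel_samples(model, n_bins, dt_time)
    if a[0] <= 1e-12:
        raise ValueError(
            f"A(dt)={a[0]:.3g} is numerically zero: kernel too slow for bin "
            f"width {dt_time} {css.time_unit}"
        )

    scale = max(np.max(np.abs(c)), 1.0)
    floor = -_CLAMP_FLOOR * scale

    if method == "nnls":
        mat = np.zeros((n_bins, n_bins))
        for t in range(n_bins):
            mat[t, : t + 1] = a[t::-1]
        d, _ = nnls(mat, c[1:])
        resid = mat @ d - c[1:]
        clamped = np.zeros(n_bins, dtype=bool)
        mass = float(np.sum(np.clip(-resid, 0, None)))
    elif method == "recursive":
        d = np.zeros(n_bins)
        clamped = np.zeros(n_bins, dtype=bool)
        mass = 0.0
        for t in range(n_bins):
            hist = np.dot(d[:t], a[t:0:-1]) if t else 0.0
            val = (c[t + 1] - hist) / a[0]
            if val < 0:
                if val < floor:
                    clamped[t] = True
                    mass += -val
                val = 0.0
            d[t] = val
    else:
        raise ValueError(f"unknown method {method!r}")

    return DssTrace(
        values=d, dt_frames=dt_frames, frame_interval=css.frame_interval,
        time_unit=css.time_unit, channel=css.channel, origin=css.origin,
        clamped=clamped, clamped_mass=float(mass),
    )


def crosstalk_signal(
    dss_ref: DssTrace, kernel: CrossTalkKernel, n_frames: int
) -> np.ndarray:
    """Predicted cross-signal on the frame grid.

    X_k = sum_{i : t_i <= t_k} DSS_i * chi(t_k - t_i), where t_i is the
    start time of release bin i.  chi(0) = 0, so the current bin never
    contributes.
    """
    if kernel.time_unit != dss_ref.time_unit:
        raise UnitError("cross-talk kernel and DSS trace use different time units")
    frames = np.arange(n_frames) * dss_ref.frame_interval
    bin_starts = dss_ref.bin_times
    # (frame, bin) matrix of elapsed times, causal part only
    lags = frames[:, None] - bin_starts[None, :]
    chi = np.where(lags >= 0, kernel.evaluate(np.clip(lags, 0, None)), 0.0)
    return chi @ dss_ref.values


def compensate_crosstalk(
    raw_fi: CssTrace, dss_ref: DssTrace, kernel: CrossTalkKernel
) -> CssTrace:
    """Subtract the predicted cross-reaction signal from a raw fluorescence trace.

    ``raw_fi`` is the uncorrected fluorescence of the affected channel
    (e.g. IL-13) and ``dss_ref`` the already-deconvolved release train of
    the channel it cross-reacts with (e.g. IL-5).  The corrected CSS is
    floored at zero, consistent with the DSS non-negativity clamp.
    """
    if raw_fi.time_unit != dss_ref.time_unit:
        raise UnitError("trace and reference DSS use different time units")
    if abs(raw_fi.frame_interval - dss_ref.frame_interval) > 1e-9 * raw_fi.frame_interval:
        raise ValueError("trace and reference DSS use different frame intervals")
    x = crosstalk_signal(dss_ref, kernel, raw_fi.values.size)
    corrected = np.maximum(raw_fi.values - x, 0.0)
    return CssTrace(
        values=corrected, frame_interval=raw_fi.frame_interval,
        time_unit=raw_fi.time_unit, channel=raw_fi.channel, origin=raw_fi.origin,
    )


def _shrinking_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving median; the window shrinks symmetrically at the edges."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    n = x.size
    out = np.empty_like(x, dtype=float)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = np.median(x[i - h : i + h + 1])
    return out


def smooth_dss(dss: DssTrace, window: int = 5) -> DssTrace:
    """Noise-filtered DSS for calling/visualization (never re-deconvolved).

    The dt binning of the deconvolution already integrates release in
    time; this adds a centered moving median over bins (symmetric window,
    shrinking at the edges) which rejects isolated single-bin outliers
    while leaving constant release exactly unchanged.
    """
    out = np.clip(_shrinking_median(dss.values, window), 0.0, None)
    return DssTrace(
        values=out, dt_frames=dss.dt_frames, frame_interval=dss.frame_interval,
        time_unit=dss.time_unit, channel=dss.channel, origin=dss.origin,
    )
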