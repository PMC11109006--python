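"""Antibody staining-kinetics kernels and their calibration.

A unit instantaneous release of cytokine into a nanoliter well produces a
fluorescence signal that rises as detection antibody binds the captured
immunocomplex and falls as the complex dissociates and the fluorophore
bleaches.  The normalized response to a unit bolus is modelled as a product
of weighted exponential association and weighted exponential decay,

    A(t) = [sum_j w_j exp(-t/tau_decay_j)] * [sum_k v_k (1 - exp(-t/tau_assoc_k))]

with one or two terms per part.  Two association terms capture the
polyclonal character of a detection antibody (fast and slow binding
populations); two decay terms capture mixed dissociation/photobleaching
time scales.  The cross-reaction kernel chi(dt) has the same product shape
scaled by an amplitude beta and describes the spurious signal one detection
antibody produces on another analyte's immunocomplex.

Calibrations are fitted from microinjection standard curves: a known amount
Q of recombinant protein released instantaneously gives an observed curve
Q*A(t), so nonlinear least squares on that curve identifies the time
constants and weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AntibodyKinetics",
    "CrossTalkKernel",
    "StandardCurve",
    "KineticsFitResult",
    "evaluate_kernel",
    "evaluate_crosstalk",
    "fit_kinetics",
    "builtin_calibrations",
    "UnitError",
]

_TIME_UNITS = ("min", "h")


class UnitError(ValueError):
    """Raised when time units of a trace and a kinetics model disagree."""


def _check_unit(unit: str) -> str:
    if unit not in _TIME_UNITS:
        raise UnitError(f"time_unit must be one of {_TIME_UNITS}, got {unit!r}")
    return unit


def _check_part(name: str, taus: Sequence[float], weights: Sequence[float]) -> None:
    taus = tuple(taus)
    weights = tuple(weights)
    if not 1 <= len(taus) <= 2 or len(taus) != len(weights):
        raise ValueError(f"{name}: need 1-2 taus with matching weights")
    if any(not math.isfinite(t) or t <= 0 for t in taus):
        raise ValueError(f"{name}: time constants must be positive and finite")
    if any(w < 0 or w > 1 for w in weights):
        raise ValueError(f"{name}: weights must lie in [0, 1]")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"{name}: weights must sum to 1, got {sum(weights)}")


def _sorted_part(taus, weights):
    order = np.argsort(taus, kind="stable")
    return tuple(float(taus[i]) for i in order), tuple(float(weights[i]) for i in order)


@dataclass(frozen=True)
class AntibodyKinetics:
    """Staining-kinetics kernel A(t) for one analyte.

    Time constants are expressed in ``time_unit`` (minutes or hours);
    every evaluation demands times in the same unit.  Association taus are
    stored sorted ascending (fast term first) so that parameter sets are
    canonical under the alpha <-> 1-alpha relabelling.
    """

    analyte: str
    decay_taus: tuple[float, ...]
    decay_weights: tuple[float, ...]
    assoc_taus: tuple[float, ...]
    assoc_weights: tuple[float, ...]
    time_unit: str = "min"

    def __post_init__(self) -> None:
        _check_unit(self.time_unit)
        _check_part("decay", self.decay_taus, self.decay_weights)
        _check_part("association", self.assoc_taus, self.assoc_weights)
        dt, dw = _sorted_part(np.asarray(self.decay_taus), np.asarray(self.decay_weights))
        at, aw = _sorted_part(np.asarray(self.assoc_taus), np.asarray(self.assoc_weights))
        object.__setattr__(self, "decay_taus", dt)
        object.__setattr__(self, "decay_weights", dw)
        object.__setattr__(self, "assoc_taus", at)
        object.__setattr__(self, "assoc_weights", aw)

    def evaluate(self, t):
        """Evaluate A(t); ``t`` is scalar or array, in ``self.time_unit``."""
        return evaluate_kernel(self, t)

    def with_unit_check(self, unit: str) -> "AntibodyKinetics":
        if unit != self.time_unit:
            raise UnitError(
                f"trace uses {unit!r} but kinetics for {self.analyte!r} is "
                f"calibrated in {self.time_unit!r}"
            )
        return self


@dataclass(frozen=True)
class CrossTalkKernel:
    """Cross-reaction kernel chi(dt): spurious signal per unit off-target release.

    chi(dt) = beta * exp(-dt/tau_decay) *
              [alpha (1 - exp(-dt/tau_fast)) + (1-alpha)(1 - exp(-dt/tau_slow))]
    """

    tau_decay: float
    tau_fast: float
    tau_slow: float
    alpha: float
    beta: float
    time_unit: str = "h"
    label: str = "crosstalk"

    def __post_init__(self) -> None:
        _check_unit(self.time_unit)
        for name, v in (("tau_decay", self.tau_decay), ("tau_fast", self.tau_fast),
                        ("tau_slow", self.tau_slow)):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def evaluate(self, dt):
        return evaluate_crosstalk(self, dt)


@dataclass(frozen=True)
class StandardCurve:
    """Microinjection calibration time course: intensities ~ Q * A(t)."""

    times: np.ndarray
    intensities: np.ndarray
    time_unit: str = "min"
    release_amount: float | None = None
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        _check_unit(self.time_unit)
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and intensities must be 1-D and equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)


def evaluate_kernel(model: AntibodyKinetics, t):
    """Normalized staining kinetics A(t) >= 0 with A(0) = 0.

    ``t`` must be non-negative and expressed in ``model.time_unit``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    decay = sum(w * np.exp(-t / tau)
                for tau, w in zip(model.decay_taus, model.decay_weights))
    assoc = sum(v * -np.expm1(-t / tau)
                for tau, v in zip(model.assoc_taus, model.assoc_weights))
    out = decay * assoc
    return float(out) if out.ndim == 0 else out


def evaluate_crosstalk(kernel: CrossTalkKernel, dt):
    """Cross-signal chi(dt) per unit off-target release; 0 <= chi <= beta."""
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("dt must be >= 0")
    assoc = (kernel.alpha * -np.expm1(-dt / kernel.tau_fast)
             + (1.0 - kernel.alpha) * -np.expm1(-dt / kernel.tau_slow))
    out = kernel.beta * np.exp(-dt / kernel.tau_decay) * assoc
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Built-in calibrations
# ---------------------------------------------------------------------------

def builtin_calibrations() -> dict[str, AntibodyKinetics | CrossTalkKernel]:
    """The four shipped calibrations, keyed by label.

    mouse IL-5 is calibrated in minutes (1-min imaging cycles), the human
    cytokines in hours (about 1-h cycles).  ``crosstalk-13to5`` is the
    anti-human-IL-13 detection antibody's cross-reaction to the captured
    human IL-5 immunocomplex.
    """
    return {
        "mouse-IL-5": AntibodyKinetics(
            analyte="mouse-IL-5",
            decay_taus=(3.4e4,), decay_weights=(1.0,),
            assoc_taus=(7.6, 8.4e1), assoc_weights=(0.599, 0.401),
            time_unit="min",
        ),
        "human-IL-5": AntibodyKinetics(
            analyte="human-IL-5",
            decay_taus=(2.8e2,), decay_weights=(1.0,),
            assoc_taus=(0.27,), assoc_weights=(1.0,),
            time_unit="h",
        ),
        # alpha = 0.71 weights the two decay exponentials here; association
        # is the single tau = 1.0 h term of the monoclonal detection antibody.
        "human-IL-13": AntibodyKinetics(
            analyte="human-IL-13",
            decay_taus=(0.84, 2.1e2), decay_weights=(0.71, 0.29),
            assoc_taus=(1.0,), assoc_weights=(1.0,),
            time_unit="h",
        ),
        "crosstalk-13to5": CrossTalkKernel(
            tau_decay=2.8e2, tau_fast=0.23, tau_slow=2.5e1,
            alpha=0.23, beta=0.33, time_unit="h", label="crosstalk-13to5",
        ),
    }


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class KineticsFitResult:
    kinetics: AntibodyKinetics
    amplitude: float
    residual_norm: float
    converged: bool
    message: str = ""
    n_starts: int = 0


def _pack_model(theta, n_decay, n_assoc, unit, analyte):
    """theta = [log decay taus..., log assoc taus..., (decay alpha), (assoc alpha), log Q]."""
    i = 0
    decay_taus = np.exp(theta[i:i + n_decay]); i += n_decay
    assoc_taus = np.exp(theta[i:i + n_assoc]); i += n_assoc
    if n_decay == 2:
        dw = (theta[i], 1.0 - theta[i]); i += 1
    else:
        dw = (1.0,)
    if n_assoc == 2:
        aw = (theta[i], 1.0 - theta[i]); i += 1
    else:
        aw = (1.0,)
    amp = np.exp(theta[i])
    model = AntibodyKinetics(
        analyte=analyte, decay_taus=tuple(decay_taus), decay_weights=dw,
        assoc_taus=tuple(assoc_taus), assoc_weights=aw, time_unit=unit,
    )
    return model, amp


def fit_kinetics(
    curve: StandardCurve,
    n_decay: int = 1,
    n_assoc: int = 2,
    analyte: str = "fitted",
    n_starts: int = 8,
    rng: np.random.Generator | None = None,
) -> KineticsFitResult:
    """Fit Q * A(t) to a microinjection standard curve by least squares.

    The model form is chosen by (n_decay, n_assoc) terms.  Initialization is
    a log-spaced multi-start over tau decades spanning the observed time
    range; association taus are kept below decay taus at initialization to
    guard identifiability, and the returned model is canonically sorted.
    """
    if len(curve.times) < 10:
        raise ValueError("need at least 10 time points spanning rise and decay")
    y = curve.intensities
    t = curve.times
    if np.ptp(y) <= 0:
        raise ValueError("degenerate (constant) standard curve; cannot fit")
    if not (n_decay in (1, 2) and n_assoc in (1, 2)):
        raise ValueError("n_decay and n_assoc must be 1 or 2")

    rng = rng if rng is not None else np.random.default_rng(0)
    span = (max(t[0], t[1] / 10.0), t[-1] * 100.0)
    log_lo, log_hi = math.log(span[0]), math.log(span[1])
    amp0 = max(np.max(np.abs(y)), 1e-12)

    def residuals(theta):
        model, amp = _pack_model(theta, n_decay, n_assoc, curve.time_unit, analyte)
        return amp * evaluate_kernel(model, t) - y

    # parameter bounds: taus within broad decades, weights in [0,1], log amp free
    lo = [log_lo - 3] * (n_decay + n_assoc)
    hi = [log_hi + 3] * (n_decay + n_assoc)
    if n_decay == 2:
        lo.append(0.0); hi.append(1.0)
    if n_assoc == 2:
        lo.append(0.0); hi.append(1.0)
    lo.append(math.log(amp0) - 10); hi.append(math.log(amp0) + 10)

    best = None
    grid = np.linspace(log_lo, log_hi, max(n_starts, 2))
    for s in range(n_starts):
        theta0 = []
        # decay taus start slow (upper decades), association fast (lower)
        for j in range(n_decay):
            theta0.append(float(np.clip(grid[-1 - s % len(grid)] + 0.5 * j, log_lo, log_hi)))
        for j in range(n_assoc):
            theta0.append(float(np.clip(grid[s % len(grid)] + 1.5 * j - 1.0, log_lo, log_hi)))
        if n_decay == 2:
            theta0.append(0.5)
        if n_assoc == 2:
            theta0.append(0.5)
        theta0.append(math.log(amp0))
        theta0 = np.clip(theta0, lo, hi)
        try:
            sol = least_squares(residuals, theta0, bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # pragma: no cover - optimizer edge failure
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        raise RuntimeError("all fit starts failed")

    model, amp = _pack_model(best.x, n_decay, n_assoc, curve.time_unit, analyte)
    resid = math.sqrt(2.0 * best.cost)
    converged = bool(best.success)
    msg = best.message
    # identifiability guard: association must be faster than decay
    if max(model.assoc_taus) >= min(model.decay_taus):
        converged = False
        msg = "association tau not below decay tau; fit poorly identified"
    return KineticsFitResult(
        kinetics=model, amplitude=float(amp), residual_norm=resid,
        converged=converged, message=msg, n_starts=n_starts,
    )
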