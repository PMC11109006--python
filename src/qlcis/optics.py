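"""Total-internal-reflection geometry checks for the imaging dish.

TIRF illumination only works if the excitation light hits the glass/sample
interface beyond the critical angle, and (with a through-the-objective
geometry) below the aperture limit of the objective.  These two angles
bracket the usable incidence window; a dish/illumination configuration is
viable only if the window is non-empty for every interface the light can
reach (aqueous sample, and any resin microstructure such as PDMS or an
index-matching fluoropolymer layer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["InterfaceSpec", "critical_angle", "aperture_limit_angle", "validation_table"]


@dataclass(frozen=True)
class InterfaceSpec:
    """One optical interface: light travels from ``n_incident`` (glass) toward
    ``n_transmitted`` (sample-side material)."""

    n_incident: float
    n_transmitted: float
    numerical_aperture: float | None = None

    def __post_init__(self) -> None:
        if self.n_incident <= 0 or self.n_transmitted <= 0:
            raise ValueError("refractive indices must be positive")
        if self.numerical_aperture is not None and self.numerical_aperture < 0:
            raise ValueError("NA must be >= 0")


def critical_angle(n_transmitted: float, n_incident: float) -> float:
    """Critical angle arcsin(n_transmitted / n_incident), in degrees.

    Beyond this incidence angle, light is totally internally reflected at
    the interface.  Requires n_transmitted <= n_incident; otherwise there is
    no total internal reflection and a ValueError is raised.
    """
    if n_incident <= 0 or n_transmitted <= 0:
        raise ValueError("refractive indices must be positive")
    if n_transmitted > n_incident:
        raise ValueError(
            "no total internal reflection: n_transmitted > n_incident"
        )
    return math.degrees(math.asin(n_transmitted / n_incident))


def aperture_limit_angle(numerical_aperture: float, n_incident: float) -> float:
    """Maximum incidence angle the objective can deliver: arcsin(NA / n), degrees."""
    if numerical_aperture < 0:
        raise ValueError("NA must be >= 0")
    if n_incident <= 0:
        raise ValueError("n_incident must be positive")
    if numerical_aperture >= n_incident:
        raise ValueError("NA must be below the incident-side index")
    return math.degrees(math.asin(numerical_aperture / n_incident))


def validation_table(
    n_glass: float = 1.52,
    n_sample: float = 1.33,
    n_structure: float | None = 1.40,
    n_matching_layer: float | None = 1.34,
    numerical_aperture: float = 1.49,
) -> list[tuple[str, float]]:
    """Angles (degrees, rounded to 0.1) relevant to a dish configuration.

    Returns (label, angle) rows: critical angles for each sample-side
    material present, and the objective aperture limit.  The configuration
    is TIRF-viable when every critical angle lies below the aperture limit.
    """
    rows: list[tuple[str, float]] = [
        ("critical water/glass", round(critical_angle(n_sample, n_glass), 1)),
    ]
    if n_structure is not None:
        rows.append(("critical structure/glass",
                     round(critical_angle(n_structure, n_glass), 1)))
    if n_matching_layer is not None:
        rows.append(("critical matching-layer/glass",
                     round(critical_angle(n_matching_layer, n_glass), 1)))
    rows.append(("aperture limit",
                 round(aperture_limit_angle(numerical_aperture, n_glass), 1)))
    return rows
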