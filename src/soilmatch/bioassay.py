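"""Endpoint mathematics of the three enzyme systems and impact classification.

Endpoints are residual percentages relative to a control: BChE residual
activity ``(A/A0)*100`` and bioluminescence residual luminescence
``(I/I0)*100``.  The residual-luminescence value maps onto a three-level
impact class with thresholds at 50% and 80%.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError


class ImpactClass(enum.Enum):
    """Three-level enzymatic impact category from a residual endpoint."""

    NO_IMPACT = "no impact"
    IMPACT = "impact"
    SIGNIFICANT_IMPACT = "significant impact"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AssayKinetics:
    """An optical-density time series from the Ellman-type kinetic read.

    ``times`` are seconds, strictly increasing; ``readings`` are OD units.
    """

    times: tuple[float, ...]
    readings: tuple[float, ...]

    def __init__(self, times: Sequence[float], readings: Sequence[float]):
        times = tuple(float(t) for t in times)
        readings = tuple(float(r) for r in readings)
        if len(times) < 2:
            raise ValidationError("kinetics require at least 2 points")
        if len(times) != len(readings):
            raise ValidationError(
                f"times and readings differ in length: {len(times)} vs {len(readings)}"
            )
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("times must be strictly increasing")
        if not all(math.isfinite(v) for v in times + readings):
            raise ValidationError("times and readings must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "readings", readings)


def residual_activity(a: float, a0: float) -> float:
    """Residual BChE activity (A/A0)*100, percent.

    ``a`` is the substrate-hydrolysis rate in the test solution, ``a0`` in the
    control; the control rate must be strictly positive.
    """
    if a0 <= 0:
        raise ValidationError(f"control rate must be positive, got {a0!r}")
    if a < 0:
        raise ValidationError(f"test rate must be >= 0, got {a!r}")
    return a / a0 * 100.0


def residual_luminescence(i: float, i0: float) -> float:
    """Residual luminescence (I/I0)*100, percent."""
    if i0 <= 0:
        raise ValidationError(f"control intensity must be positive, got {i0!r}")
    if i < 0:
        raise ValidationError(f"test intensity must be >= 0, got {i!r}")
    return i / i0 * 100.0


def classify_impact(residual: float) -> ImpactClass:
    """Map a residual percentage to its impact class.

    Above 80% -> no impact; below 50% -> significant impact; everything in
    between, including the exact boundaries 50 and 80, -> impact.  (The source
    thresholds are strict inequalities on both sides, leaving the boundary
    points unassigned; they are given to the middle class.)
    """
    if not (isinstance(residual, (int, float)) and math.isfinite(residual)):
        raise ValidationError(f"residual must be a finite number, got {residual!r}")
    if residual < 0:
        raise ValidationError(f"residual must be >= 0, got {residual!r}")
    if residual > 80.0:
        return ImpactClass.NO_IMPACT
    if residual >= 50.0:
        return ImpactClass.IMPACT
    return ImpactClass.SIGNIFICANT_IMPACT


def hydrolysis_rate(k: AssayKinetics) -> float:
    """Substrate-hydrolysis rate from an OD time series, OD units per second.

    The rate is the ordinary-least-squares slope of readings versus times over
    the full recorded window; exact (to floating tolerance) on linear series.
    """
    t = np.asarray(k.times, dtype=float)
    y = np.asarray(k.readings, dtype=float)
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def parse_kinetics(text: str) -> AssayKinetics:
    """Parse an inline ``time:od,time:od,...`` series (CLI convenience)."""
    pairs = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            t_str, v_str = chunk.split(":")
            pairs.append((float(t_str), float(v_str)))
        except ValueError as exc:
            raise ValidationError(f"bad kinetics pair {chunk!r}; expected 'time:od'") from exc
    if not pairs:
        raise ValidationError("empty kinetics series")
    return AssayKinetics([p[0] for p in pairs], [p[1] for p in pairs])
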