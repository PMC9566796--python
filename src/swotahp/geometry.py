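"""Strategy quadrilateral, azimuth, zone classification and intensity.

The four signed group totals place a quadrilateral in the plane with
vertices (S', 0), (0, O'), (W', 0), (0, T').  Its centroid
P(X, Y) = ((S' + W')/4, (O' + T')/4) points from the origin in the
*strategic azimuth* theta, computed with the two-argument arctangent so
that all four quadrants are distinguished.  The plane is partitioned into
eight azimuth zones (two per quadrant); theta selects the recommended
strategy type.  The *strategic intensity coefficient*
rho = U/(U + V), with positive intensity U = O' x S' and negative
intensity V = T' x W', grades how aggressively to pursue it: values near
0.5 recommend maintaining the current intensity of development.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

__all__ = [
    "StrategyResult",
    "ZONES",
    "build_strategy",
    "classify_zone",
    "intensity_interpretation",
]

#: The eight azimuth zones: (start, end, type label, quadrant-area name,
#: quadrant).  Intervals are half-open [start, end) except the printed
#: closed bound at pi/2, which belongs to the opportunity zone (the
#: aggressive zone of quadrant 2 therefore opens just above pi/2).
ZONES: tuple[tuple[float, float, str, str, int], ...] = (
    (0.0, math.pi / 4, "strength type", "pioneering strategic area", 1),
    (math.pi / 4, math.pi / 2, "opportunity type", "pioneering strategic area", 1),
    (math.pi / 2, 3 * math.pi / 4, "aggressive type", "ambitious strategic area", 2),
    (3 * math.pi / 4, math.pi, "adjustment type", "ambitious strategic area", 2),
    (math.pi, 5 * math.pi / 4, "retreating type", "conservative strategic area", 3),
    (5 * math.pi / 4, 3 * math.pi / 2, "avoidance type", "conservative strategic area", 3),
    (3 * math.pi / 2, 7 * math.pi / 4, "adjustment type", "resistant strategic area", 4),
    (7 * math.pi / 4, 2 * math.pi, "aggressive type", "resistant strategic area", 4),
)


@dataclass(frozen=True)
class StrategyResult:
    """Quadrilateral geometry and derived strategy recommendation."""

    vertices: tuple[tuple[float, float], ...]   # (S',0), (0,O'), (W',0), (0,T')
    centroid: tuple[float, float]               # P(X, Y)
    theta_deg: float                            # signed, in (-180, 180]
    theta_deg_normalized: float                 # in [0, 360)
    quadrant: int                               # 1..4
    zone_type: str                              # e.g. "aggressive type"
    zone_area: str                              # e.g. "resistant strategic area"
    u: float                                    # positive intensity O' x S'
    v: float                                    # negative intensity T' x W'
    rho: float                                  # u / (u + v)
    intensity_guidance: str                     # conservative / maintain / aggressive

    @property
    def zone_label(self) -> str:
        return f"{self.zone_area} / {self.zone_type}"

    def to_dict(self) -> dict:
        return {
            "vertices": [list(p) for p in self.vertices],
            "centroid": list(self.centroid),
            "theta_deg": self.theta_deg,
            "theta_deg_normalized": self.theta_deg_normalized,
            "quadrant": self.quadrant,
            "zone_type": self.zone_type,
            "zone_area": self.zone_area,
            "u": self.u,
            "v": self.v,
            "rho": self.rho,
            "intensity_guidance": self.intensity_guidance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def classify_zone(theta_rad: float) -> tuple[str, str, int]:
    """Map a normalized azimuth in [0, 2*pi) to (type, area, quadrant).

    The partition is total: every finite angle (taken mod 2*pi) falls in
    exactly one zone.  Boundaries are half-open [a, b) except pi/2, which
    is closed on the opportunity side.
    """
    if not math.isfinite(theta_rad):
        raise ValueError("azimuth must be finite")
    t = math.fmod(theta_rad, 2 * math.pi)
    if t < 0:
        t += 2 * math.pi
    if t == math.pi / 2:  # the single printed closed bound
        _, _, ztype, area, quad = ZONES[1]
        return ztype, area, quad
    for start, end, ztype, area, quad in ZONES:
        if start <= t < end:
            return ztype, area, quad
    # t can only reach here by floating rounding at 2*pi
    return ZONES[0][2], ZONES[0][3], ZONES[0][4]


def intensity_interpretation(rho: float,
                             maintain_band: tuple[float, float] = (0.45, 0.55)) -> str:
    """Grade the intensity coefficient: below the maintain band the stance
    is conservative, above it aggressive, inside it the current intensity
    of development should be maintained."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho = {rho} outside [0, 1]")
    lo, hi = maintain_band
    if rho < lo:
        return "conservative"
    if rho > hi:
        return "aggressive"
    return "maintain"


def build_strategy(totals: tuple[float, float, float, float],
                   maintain_band: tuple[float, float] = (0.45, 0.55)) -> StrategyResult:
    """Build the full strategy result from the quadruple (S', W', O', T').

    Sign preconditions: S', O' >= 0 and W', T' <= 0.  The all-zero
    quadruple has no direction and raises.
    """
    s, w, o, t = (float(x) for x in totals)
    if s < 0 or o < 0:
        raise ValueError(f"S' and O' must be nonnegative, got S'={s}, O'={o}")
    if w > 0 or t > 0:
        raise ValueError(f"W' and T' must be nonpositive, got W'={w}, T'={t}")
    x = (s + w) / 4.0
    y = (o + t) / 4.0
    if x == 0.0 and y == 0.0:
        raise ValueError(
            "degenerate quadrilateral: centroid at the origin, azimuth undefined"
        )
    theta = math.atan2(y, x)                       # signed, (-pi, pi]
    theta_deg = math.degrees(theta)
    theta_norm = theta_deg % 360.0
    ztype, area, quad = classify_zone(math.radians(theta_norm))
    u = o * s
    v = t * w
    rho = 0.5 if (u + v) == 0.0 else u / (u + v)   # no intensity signal either way
    return StrategyResult(
        vertices=((s, 0.0), (0.0, o), (w, 0.0), (0.0, t)),
        centroid=(x, y),
        theta_deg=theta_deg,
        theta_deg_normalized=theta_norm,
        quadrant=quad,
        zone_type=ztype,
        zone_area=area,
        u=u,
        v=v,
        rho=rho,
        intensity_guidance=intensity_interpretation(rho, maintain_band),
    )
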