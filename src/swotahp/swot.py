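"""SWOT factors, per-factor strengths and group totals.

Each SWOT sub-factor carries an expert-estimated *intensity* I, signed by
convention: positive for strengths (S) and opportunities (O), negative for
weaknesses (W) and threats (T), with |I| <= 9 on the Saaty scale.  The
strength of a sub-factor is its intensity times its AHP weight, and the
group total (S', W', O', T') is the sum over the group's sub-factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import AhpResult

__all__ = [
    "GROUPS",
    "POSITIVE_GROUPS",
    "SwotFactor",
    "GroupStrength",
    "SignConventionError",
    "factor_strengths",
    "assemble_swot",
]

GROUPS = ("S", "W", "O", "T")
POSITIVE_GROUPS = frozenset({"S", "O"})
MAX_INTENSITY = 9.0


class SignConventionError(ValueError):
    """An intensity violates the S/O positive, W/T negative convention."""


@dataclass(frozen=True)
class SwotFactor:
    """One SWOT sub-factor.

    Parameters
    ----------
    id:
        Short identifier, e.g. ``"S1"``.
    group:
        One of ``S``, ``W``, ``O``, ``T``.
    description:
        Free-text narrative of the factor (metadata only).
    estimated_intensity:
        Signed expected strength I.  Need not be integral: a Delphi panel
        mean of integer scores is accepted.
    """

    id: str
    group: str
    estimated_intensity: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"factor {self.id}: unknown group {self.group!r}")
        self.validate_sign()

    def validate_sign(self, allow_zero: bool = True) -> None:
        i = self.estimated_intensity
        if abs(i) > MAX_INTENSITY:
            raise SignConventionError(
                f"factor {self.id}: |intensity| = {abs(i)} exceeds the scale bound 9"
            )
        if allow_zero and i == 0:
            return
        positive = self.group in POSITIVE_GROUPS
        if positive and i < 0:
            raise SignConventionError(
                f"factor {self.id} (group {self.group}): intensity {i} must be positive"
            )
        if not positive and i > 0:
            raise SignConventionError(
                f"factor {self.id} (group {self.group}): intensity {i} must be negative"
            )


@dataclass(frozen=True)
class GroupStrength:
    """Per-factor strengths (weight x intensity) and their total for one group."""

    group: str
    factor_ids: tuple[str, ...]
    factor_strengths: np.ndarray
    total: float

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "factor_ids": list(self.factor_ids),
            "factor_strengths": [float(s) for s in self.factor_strengths],
            "total": float(self.total),
        }


def factor_strengths(factors: list[SwotFactor], ahp: AhpResult,
                     allow_inconsistent: bool = False) -> GroupStrength:
    """Combine intensities with AHP weights into per-factor strengths.

    ``factors`` must all belong to one group, in the same order as the
    weights in ``ahp``.  If the comparison matrix failed its consistency
    test the combination is refused unless ``allow_inconsistent`` is set,
    in which case a warning is emitted.
    """
    if not factors:
        raise ValueError("no factors given")
    groups = {f.group for f in factors}
    if len(groups) != 1:
        raise ValueError(f"factors span several groups: {sorted(groups)}")
    if len(factors) != ahp.n:
        raise ValueError(
            f"{len(factors)} factors but {ahp.n} weights in the AHP result"
        )
    ids = tuple(f.id for f in factors)
    if ids != ahp.factor_ids:
        raise ValueError(
            f"factor order {ids} does not match AHP weight order {ahp.factor_ids}"
        )
    if not ahp.consistent:
        msg = (f"group {factors[0].group}: comparison matrix failed the "
               f"consistency test (CR = {ahp.cr:.4f} >= 0.1)")
        if not allow_inconsistent:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    for f in factors:
        f.validate_sign()
    intensities = np.array([f.estimated_intensity for f in factors], dtype=float)
    strengths = intensities * ahp.weights
    return GroupStrength(
        group=factors[0].group,
        factor_ids=ids,
        factor_strengths=strengths,
        total=float(strengths.sum()),
    )


def assemble_swot(groups: list[GroupStrength]) -> tuple[float, float, float, float]:
    """Collect the four group totals into the ordered quadruple (S', W', O', T').

    Exactly one :class:`GroupStrength` per group letter is required.
    """
    by_group = {}
    for g in groups:
        if g.group in by_group:
            raise ValueError(f"duplicate group {g.group}")
        by_group[g.group] = g
    missing = [g for g in GROUPS if g not in by_group]
    if missing:
        raise ValueError(f"missing groups: {missing}")
    return tuple(by_group[g].total for g in GROUPS)  # type: ignore[return-value]
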