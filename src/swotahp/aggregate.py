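"""Delphi expert-panel aggregation.

A panel of experts scores, for each SWOT group, the upper triangle of the
pairwise-comparison matrix (reciprocity is a scale convention, so only one
direction of each pair is collected) and a signed intensity per factor.
Aggregation pools the panel into one comparison matrix and one intensity
vector per group by the arithmetic mean of the raw scores — the default —
or the geometric mean, the common alternative for ratio-scale judgments.
Aggregation acts on upper-triangle scores only and mirrors reciprocals
afterwards: averaging a_ij and a_ji independently would in general break
reciprocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ComparisonMatrix, parse_judgment
from .swot import SignConventionError

__all__ = ["ExpertPanel", "aggregate_judgments", "aggregate_intensities"]

Pair = tuple[str, str]


@dataclass
class ExpertPanel:
    """Raw per-expert Delphi scores for one study.

    ``judgments[expert][group][(i, j)]`` is the Saaty score expert gave the
    ordered factor pair (i, j) of that group's upper triangle;
    ``intensities[expert][group][factor]`` the signed intensity score.
    ``factor_ids[group]`` fixes the factor order shared by all experts.
    """

    factor_ids: dict[str, tuple[str, ...]]
    judgments: dict[str, dict[str, dict[Pair, float]]] = field(default_factory=dict)
    intensities: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)

    @property
    def expert_ids(self) -> tuple[str, ...]:
        return tuple(self.judgments.keys())

    def validate(self) -> None:
        """Every expert must score every pair and every factor of every group."""
        if not self.judgments:
            raise ValueError("empty panel: no expert judgments")
        for expert, per_group in self.judgments.items():
            if set(per_group) != set(self.factor_ids):
                raise ValueError(
                    f"expert {expert}: groups {sorted(per_group)} != {sorted(self.factor_ids)}"
                )
            for group, scores in per_group.items():
                ids = self.factor_ids[group]
                required = {(ids[i], ids[j])
                            for i in range(len(ids)) for j in range(i + 1, len(ids))}
                if set(scores) != required:
                    raise ValueError(
                        f"expert {expert}, group {group}: scored pairs do not match "
                        f"the upper triangle of {ids}"
                    )
                for pair, v in scores.items():
                    if v <= 0:
                        raise ValueError(
                            f"expert {expert}, group {group}, pair {pair}: "
                            f"judgment {v} is not positive"
                        )
        for expert, per_group in self.intensities.items():
            for group, scores in per_group.items():
                if set(scores) != set(self.factor_ids[group]):
                    raise ValueError(
                        f"expert {expert}, group {group}: intensity factors do not "
                        f"match {self.factor_ids[group]}"
                    )

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_csv(cls, judgment_path: str | Path,
                 intensity_path: str | Path | None = None) -> "ExpertPanel":
        """Read per-expert scores from CSV.

        Judgment file columns: ``expert, group, factor_i, factor_j, score``;
        intensity file columns: ``expert, group, factor, intensity``.
        Scores may be fraction strings such as ``1/7``.
        """
        jdf = pd.read_csv(judgment_path, dtype=str)
        factor_ids: dict[str, list[str]] = {}
        judgments: dict[str, dict[str, dict[Pair, float]]] = {}
        for _, row in jdf.iterrows():
            e, g, fi, fj = row["expert"], row["group"], row["factor_i"], row["factor_j"]
            judgments.setdefault(e, {}).setdefault(g, {})[(fi, fj)] = parse_judgment(row["score"])
            order = factor_ids.setdefault(g, [])
            for f in (fi, fj):
                if f not in order:
                    order.append(f)
        intensities: dict[str, dict[str, dict[str, float]]] = {}
        if intensity_path is not None:
            idf = pd.read_csv(intensity_path, dtype=str)
            for _, row in idf.iterrows():
                intensities.setdefault(row["expert"], {}).setdefault(
                    row["group"], {})[row["factor"]] = float(row["intensity"])
        return cls(
            factor_ids={g: tuple(sorted(ids, key=ids.index)) for g, ids in factor_ids.items()},
            judgments=judgments,
            intensities=intensities,
        )


def _pool(values: np.ndarray, method: str) -> float:
    if method == "arithmetic":
        return float(values.mean())
    if method == "geometric":
        return float(np.exp(np.log(values).mean()))
    raise ValueError(f"unknown aggregation method {method!r}")


def aggregate_judgments(panel: ExpertPanel,
                        method: str = "arithmetic") -> dict[str, ComparisonMatrix]:
    """Pool the panel's judgments into one comparison matrix per group.

    Cell (i, j) of the aggregate is the chosen mean of the experts' scores
    for the pair (i, j); the lower triangle is then the reciprocal of the
    aggregated upper triangle, so the result is reciprocal by construction.
    Aggregated values are not snapped back to the Saaty grid.
    """
    panel.validate()
    out: dict[str, ComparisonMatrix] = {}
    for group, ids in panel.factor_ids.items():
        upper: dict[Pair, float] = {}
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                pair = (ids[i], ids[j])
                scores = np.array([panel.judgments[e][group][pair]
                                   for e in panel.expert_ids])
                upper[pair] = _pool(scores, method)
        out[group] = ComparisonMatrix.from_upper_triangle(upper, ids, group_id=group)
    return out


def aggregate_intensities(panel: ExpertPanel) -> dict[str, dict[str, float]]:
    """Arithmetic mean of each factor's intensity scores across experts.

    All experts must agree on the sign of each factor (the S/O positive,
    W/T negative convention leaves no room for disagreement); the pooled
    mean may be non-integer.
    """
    if not panel.intensities:
        raise ValueError("panel carries no intensity scores")
    out: dict[str, dict[str, float]] = {}
    experts = tuple(panel.intensities.keys())
    for group in panel.factor_ids:
        out[group] = {}
        for factor in panel.factor_ids[group]:
            scores = np.array([panel.intensities[e][group][factor] for e in experts])
            signs = set(np.sign(scores[scores != 0]))
            if len(signs) > 1:
                raise SignConventionError(
                    f"experts disagree on the sign of factor {factor}: scores {scores.tolist()}"
                )
            out[group][factor] = float(scores.mean())
    return out
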