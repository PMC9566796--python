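"""End-to-end study runner: configuration, file I/O and report rendering.

A *study* is a factor definition table plus either one comparison-matrix
CSV per group or per-expert Delphi score files to be aggregated first.
``run_pipeline`` executes aggregation (if needed), AHP weights and
consistency per group, per-factor strengths and group totals, and the
strategy geometry, returning a :class:`StudyReport` that serializes to
JSON at full precision and renders as a text table rounded to 4 decimals
(half-even) for display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from .aggregate import ExpertPanel, aggregate_intensities, aggregate_judgments
from .core import AhpResult, ComparisonMatrix, consistency
from .geometry import StrategyResult, build_strategy
from .swot import GROUPS, GroupStrength, SwotFactor, assemble_swot, factor_strengths

__all__ = [
    "StudyConfig",
    "StudyReport",
    "InconsistencyError",
    "load_factors",
    "run_pipeline",
    "render_report",
    "load_example_study",
    "EXAMPLE_DIR",
]

#: Bundled worked example: a published SWOT-AHP study of new-media-enabled
#: public-health promotion (4 strengths, 3 weaknesses, 4 opportunities,
#: 3 threats scored by a 10-expert Delphi panel).
EXAMPLE_DIR = Path(__file__).parent / "data" / "new_media_health"


class InconsistencyError(RuntimeError):
    """A group's comparison matrix failed the CR < threshold test."""

    def __init__(self, group: str, cr: float):
        super().__init__(f"group {group}: consistency test failed (CR = {cr:.4f})")
        self.group = group
        self.cr = cr


class StudyConfig(BaseModel):
    """Configuration of one SWOT-AHP study.

    Exactly one of ``matrices`` (per-group matrix CSV paths) or
    ``expert_scores`` (judgment CSV + intensity CSV to aggregate) must be
    supplied.  Paths are resolved relative to ``base_dir`` when set.
    """

    factors: str
    matrices: Optional[dict[str, str]] = None
    expert_scores: Optional[dict[str, str]] = None   # keys: judgments, intensities
    aggregation: str = "arithmetic"
    cr_threshold: float = 0.1
    ri_table: Optional[dict[int, float]] = None
    allow_inconsistent: bool = False
    maintain_band: tuple[float, float] = (0.45, 0.55)
    output_dir: Optional[str] = None
    plot: bool = False
    seed: int = 0
    base_dir: Optional[str] = None

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "StudyConfig":
        if (self.matrices is None) == (self.expert_scores is None):
            raise ValueError("supply exactly one of 'matrices' or 'expert_scores'")
        if self.expert_scores is not None and "judgments" not in self.expert_scores:
            raise ValueError("expert_scores requires a 'judgments' file")
        return self

    def resolve(self, rel: str) -> Path:
        base = Path(self.base_dir) if self.base_dir else Path.cwd()
        p = Path(rel)
        return p if p.is_absolute() else base / p

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.setdefault("base_dir", str(path.parent))
        return cls(**raw)


@dataclass(frozen=True)
class StudyReport:
    """Complete results of one study run."""

    ahp: dict[str, AhpResult]                 # one per group letter
    strengths: dict[str, GroupStrength]
    totals: tuple[float, float, float, float]  # (S', W', O', T')
    strategy: StrategyResult
    factors: list[SwotFactor]

    def to_dict(self) -> dict:
        return {
            "groups": {g: self.ahp[g].to_dict() for g in GROUPS},
            "strengths": {g: self.strengths[g].to_dict() for g in GROUPS},
            "totals": dict(zip(("S", "W", "O", "T"), self.totals)),
            "strategy": self.strategy.to_dict(),
            "factors": [
                {"id": f.id, "group": f.group, "intensity": f.estimated_intensity,
                 "description": f.description}
                for f in self.factors
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def load_factors(path: str | Path) -> list[SwotFactor]:
    """Read the factor definition CSV: columns id, group, intensity and an
    optional description."""
    df = pd.read_csv(path)
    required = {"id", "group", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"factor file {path}: needs columns {sorted(required)}")
    return [
        SwotFactor(
            id=str(r["id"]),
            group=str(r["group"]),
            estimated_intensity=float(r["intensity"]),
            description=str(r.get("description", "") or ""),
        )
        for r in df.to_dict("records")
    ]


def _group_matrices(config: StudyConfig,
                    factors: list[SwotFactor]) -> dict[str, ComparisonMatrix]:
    if config.matrices is not None:
        out = {}
        for group, rel in config.matrices.items():
            out[group] = ComparisonMatrix.from_csv(config.resolve(rel), group_id=group)
        return out
    panel = ExpertPanel.from_csv(
        config.resolve(config.expert_scores["judgments"]),
        config.resolve(config.expert_scores["intensities"])
        if "intensities" in config.expert_scores else None,
    )
    matrices = aggregate_judgments(panel, method=config.aggregation)
    if panel.intensities:
        pooled = aggregate_intensities(panel)
        by_id = {f.id: f for f in factors}
        for group, per_factor in pooled.items():
            for fid, val in per_factor.items():
                old = by_id[fid]
                by_id[fid] = SwotFactor(old.id, old.group, val, old.description)
        factors[:] = [by_id[f.id] for f in factors]
    return matrices


def run_pipeline(config: StudyConfig) -> StudyReport:
    """Run the full study: (aggregate) -> weights/consistency -> strengths
    -> totals -> strategy.

    Raises :class:`InconsistencyError` naming the first failing group if a
    matrix fails the CR test and ``allow_inconsistent`` is off.
    """
    factors = load_factors(config.resolve(config.factors))
    matrices = _group_matrices(config, factors)
    missing = [g for g in GROUPS if g not in matrices]
    if missing:
        raise ValueError(f"no comparison matrix for groups {missing}")

    ahp: dict[str, AhpResult] = {}
    strengths: dict[str, GroupStrength] = {}
    for group in GROUPS:
        result = consistency(matrices[group], ri_table=config.ri_table,
                             cr_threshold=config.cr_threshold)
        if not result.consistent and not config.allow_inconsistent:
            raise InconsistencyError(group, result.cr)
        ahp[group] = result
        group_factors = [f for f in factors if f.group == group]
        order = {fid: k for k, fid in enumerate(result.factor_ids)}
        group_factors.sort(key=lambda f: order[f.id])
        strengths[group] = factor_strengths(
            group_factors, result, allow_inconsistent=config.allow_inconsistent)
    totals = assemble_swot([strengths[g] for g in GROUPS])
    strategy = build_strategy(totals, maintain_band=config.maintain_band)
    return StudyReport(ahp=ahp, strengths=strengths, totals=totals,
                       strategy=strategy, factors=factors)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _r4(x: float) -> str:
    """Half-even rounding to 4 decimals, the display convention."""
    return f"{x:.4f}"


def render_report(report: StudyReport, output_dir: str | Path | None = None,
                  plot: bool = False) -> dict[str, str]:
    """Render the report as text (4-decimal display) and JSON (full
    precision); optionally draw the quadrilateral plot.

    Returns the artifacts as strings keyed ``text`` and ``json`` (and
    ``plot`` with the written file path when requested); when
    ``output_dir`` is given the artifacts are also written there.
    """
    lines: list[str] = []
    lines.append("AHP weights and consistency")
    lines.append("group  factor  weight   AW       lambda_max  CI      CR      pass")
    for g in GROUPS:
        r = report.ahp[g]
        for k, fid in enumerate(r.factor_ids):
            tail = (f"  {r.lambda_max:.5f}   {_r4(r.ci)}  {_r4(r.cr)}  "
                    f"{'yes' if r.consistent else 'NO'}") if k == 0 else ""
            lines.append(f"{g:5s}  {fid:6s}  {_r4(r.weights[k])}  {_r4(r.aw[k])}{tail}")
    lines.append("")
    lines.append("Factor strengths (weight x intensity) and group totals")
    lines.append("group  factor  intensity  strength   total")
    by_id = {f.id: f for f in report.factors}
    for g in GROUPS:
        s = report.strengths[g]
        for k, fid in enumerate(s.factor_ids):
            tail = f"  {_r4(s.total)}" if k == len(s.factor_ids) - 1 else ""
            lines.append(f"{g:5s}  {fid:6s}  {by_id[fid].estimated_intensity:9g}  "
                         f"{_r4(s.factor_strengths[k]):>8s}{tail}")
    lines.append("")
    st = report.strategy
    lines.append("Strategy")
    lines.append(f"centroid P(X, Y) = ({st.centroid[0]:.5f}, {st.centroid[1]:.5f})")
    lines.append(f"azimuth theta    = {st.theta_deg:.3f} deg "
                 f"({st.theta_deg_normalized:.3f} deg normalized), quadrant {st.quadrant}")
    lines.append(f"zone             = {st.zone_label}")
    lines.append(f"U = {_r4(st.u)}, V = {_r4(st.v)}, rho = {st.rho:.5f} "
                 f"-> {st.intensity_guidance}")
    text = "\n".join(lines) + "\n"
    artifacts = {"text": text, "json": report.to_json(indent=2)}

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(artifacts["text"])
        (out / "report.json").write_text(artifacts["json"])
        if plot:
            artifacts["plot"] = str(out / "quadrilateral.svg")
            plot_quadrilateral(report, artifacts["plot"])
    return artifacts


def plot_quadrilateral(report: StudyReport, path: str | Path) -> None:
    """Draw the strategy quadrilateral, centroid and azimuth ray."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    st = report.strategy
    fig, ax = plt.subplots(figsize=(5, 5))
    order = [0, 1, 2, 3, 0]  # S' -> O' -> W' -> T' -> S'
    ax.plot([st.vertices[i][0] for i in order], [st.vertices[i][1] for i in order],
            "o-", color="tab:blue")
    ax.plot(*st.centroid, "r*", markersize=12, label="centroid")
    ax.annotate("", xy=st.centroid, xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color="red"))
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    for (x, y), lbl in zip(st.vertices, ("S'", "O'", "W'", "T'")):
        ax.annotate(lbl, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_title(f"theta = {st.theta_deg:.2f} deg, rho = {st.rho:.4f}")
    ax.set_aspect("equal")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def load_example_study() -> StudyConfig:
    """Configuration for the bundled new-media public-health worked example."""
    return StudyConfig.from_yaml(EXAMPLE_DIR / "config.yaml")
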