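"""Synthetic expert panels with controlled consistency.

Emulates the Delphi scoring process so every pipeline stage is testable
without external data, and supports Monte-Carlo sensitivity analysis.  A
group is described by a latent positive weight vector and a latent signed
intensity vector; a perfectly consistent judgment matrix has entries
w_i / w_j.  Expert disagreement is modelled as multiplicative log-normal
noise on the upper-triangle judgments — Saaty judgments are ratio-scaled,
so noise should act on the log scale — optionally snapped to the nearest
Saaty grid value (nearest in log space; a tie at a midpoint snaps toward
1, the less extreme judgment).  At noise level sigma = 0 with snapping
off, the synthetic pipeline reproduces the analytic one exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import SAATY_VALUES, ComparisonMatrix, consistency
from .geometry import build_strategy
from .swot import GROUPS, SwotFactor, factor_strengths, assemble_swot

__all__ = [
    "GroupSpec",
    "PanelSpec",
    "generate_consistent_matrix",
    "snap_to_saaty",
    "perturb_matrix",
    "simulate_strategy_distribution",
]

_LOG_SAATY = np.log(np.array(SAATY_VALUES))


@dataclass(frozen=True)
class GroupSpec:
    """Latent truth for one SWOT group: weights (positive, sum to 1) and
    signed intensities, one per factor."""

    group: str
    weights: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.intensities):
            raise ValueError(f"group {self.group}: weights and intensities differ in length")
        if not 2 <= len(w) <= 9:
            raise ValueError(f"group {self.group}: factor count {len(w)} outside 2..9")
        if np.any(w <= 0):
            raise ValueError(f"group {self.group}: weights must be positive")
        if not math.isclose(float(w.sum()), 1.0, rel_tol=1e-9):
            raise ValueError(f"group {self.group}: weights sum to {w.sum()}, not 1")

    @property
    def factor_ids(self) -> tuple[str, ...]:
        return tuple(f"{self.group}{k + 1}" for k in range(len(self.weights)))


@dataclass(frozen=True)
class PanelSpec:
    """Conditions of a synthetic study: latent group truths, panel size,
    judgment noise level sigma (std dev of the log-normal perturbation),
    Saaty snapping, intensity jitter, and the random seed."""

    groups: tuple[GroupSpec, ...]
    n_experts: int = 10
    sigma: float = 0.0
    snap: bool = False
    intensity_jitter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma = {self.sigma} must be nonnegative")
        if self.n_experts < 1:
            raise ValueError("need at least one expert")
        letters = [g.group for g in self.groups]
        if sorted(letters) != sorted(GROUPS):
            raise ValueError(f"need exactly one spec per group {GROUPS}, got {letters}")


def generate_consistent_matrix(weights, factor_ids=None, group_id: str = "",
                               seed: int | None = None) -> ComparisonMatrix:
    """Perfectly consistent matrix with entries w_i / w_j (CI = 0 exactly).

    ``seed`` is accepted for interface symmetry; the construction is
    deterministic.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    ids = tuple(factor_ids) if factor_ids is not None else tuple(
        f"F{k + 1}" for k in range(len(w)))
    return ComparisonMatrix(group_id=group_id, factor_ids=ids,
                            values=np.outer(w, 1.0 / w))


def snap_to_saaty(value: float) -> float:
    """Nearest Saaty grid value in log space; midpoint ties snap toward 1."""
    if value <= 0:
        raise ValueError("judgment must be positive")
    logv = math.log(value)
    d = np.abs(_LOG_SAATY - logv)
    best = d.min()
    candidates = np.flatnonzero(np.isclose(d, best, rtol=0.0, atol=1e-12))
    # among tied candidates pick the one closest to 1 (smallest |log|)
    k = candidates[int(np.argmin(np.abs(_LOG_SAATY[candidates])))]
    return float(SAATY_VALUES[int(k)])


def perturb_matrix(m: ComparisonMatrix, sigma: float, snap: bool = False,
                   seed: int | np.random.Generator | None = None) -> ComparisonMatrix:
    """Multiply each upper-triangle entry by exp(eps), eps ~ N(0, sigma^2),
    then mirror reciprocals (and optionally snap to the Saaty grid first).

    Deterministic under a fixed seed; ``sigma = 0`` without snapping
    returns an equal matrix.
    """
    if sigma < 0:
        raise ValueError(f"sigma = {sigma} must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = m.n
    a = np.eye(n)
    eps = rng.normal(0.0, sigma, size=(n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = m.values[i, j] * math.exp(eps[i, j]) if sigma > 0 else m.values[i, j]
            if snap:
                v = snap_to_saaty(v)
            a[i, j] = v
            a[j, i] = 1.0 / v
    return ComparisonMatrix(group_id=m.group_id, factor_ids=m.factor_ids, values=a)


def _jitter_intensity(value: float, rng: np.random.Generator) -> float:
    """Integer jitter of +/-1 on the magnitude, clamped to [1, 9], sign kept."""
    step = int(rng.integers(-1, 2))
    mag = min(9.0, max(1.0, abs(value) + step))
    return math.copysign(mag, value)


def simulate_strategy_distribution(spec: PanelSpec, replicates: int = 200) -> dict:
    """Monte-Carlo distribution of the strategy outputs under judgment noise.

    Per replicate: each expert's judgment matrix is a noisy copy of the
    latent consistent matrix; matrices are pooled by the arithmetic mean of
    upper-triangle scores; any replicate whose pooled matrix fails the
    CR < 0.1 test for some group is rejected (and counted).  Surviving
    replicates run the full strength + strategy pipeline with the latent
    (optionally jittered) intensities.

    Returns a summary dict with the empirical mean and (5%, 50%, 95%)
    quantiles of theta (signed degrees) and rho, a zone histogram, and the
    rejection count.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    thetas: list[float] = []
    rhos: list[float] = []
    zones: dict[str, int] = {}
    rejected = 0
    for _ in range(replicates):
        ok = True
        strengths = []
        for gspec in spec.groups:
            latent = generate_consistent_matrix(gspec.weights, gspec.factor_ids,
                                                group_id=gspec.group)
            # pool the experts' noisy upper triangles by arithmetic mean
            n = latent.n
            acc = np.zeros((n, n))
            for _e in range(spec.n_experts):
                acc += perturb_matrix(latent, spec.sigma, spec.snap, rng).values
            pooled = np.eye(n)
            for i in range(n):
                for j in range(i + 1, n):
                    pooled[i, j] = acc[i, j] / spec.n_experts
                    pooled[j, i] = 1.0 / pooled[i, j]
            matrix = ComparisonMatrix(group_id=gspec.group,
                                      factor_ids=gspec.factor_ids, values=pooled)
            result = consistency(matrix)
            if not result.consistent:
                ok = False
                break
            intensities = [
                _jitter_intensity(v, rng) if spec.intensity_jitter else v
                for v in gspec.intensities
            ]
            factors = [SwotFactor(fid, gspec.group, inten)
                       for fid, inten in zip(gspec.factor_ids, intensities)]
            strengths.append(factor_strengths(factors, result))
        if not ok:
            rejected += 1
            continue
        strategy = build_strategy(assemble_swot(strengths))
        thetas.append(strategy.theta_deg)
        rhos.append(strategy.rho)
        zones[strategy.zone_label] = zones.get(strategy.zone_label, 0) + 1
    if not thetas:
        raise RuntimeError(
            f"all {replicates} replicates rejected by the consistency test "
            f"(sigma = {spec.sigma} too large?)"
        )
    th = np.array(thetas)
    rh = np.array(rhos)
    return {
        "replicates": replicates,
        "accepted": len(thetas),
        "rejected": rejected,
        "theta_mean": float(th.mean()),
        "theta_quantiles": [float(q) for q in np.quantile(th, [0.05, 0.5, 0.95])],
        "theta_std": float(th.std()),
        "rho_mean": float(rh.mean()),
        "rho_quantiles": [float(q) for q in np.quantile(rh, [0.05, 0.5, 0.95])],
        "rho_std": float(rh.std()),
        "zone_counts": dict(sorted(zones.items())),
    }
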