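"""Particle swarm optimization over a bounded box, maximization convention.

The swarm follows the canonical velocity/position updates

    V'(i) = W V(i) + C1 R1(i) (pbest(i) - X(i)) + C2 R2(i) (gbest(i) - X(i))
    X'    = X + V'

with time-varying acceleration coefficients (TVAC) and a time-varying
inertia weight (TVIW), both linear in the generation index t in [0, t_max]:

    C1(t) = C1i + (t/t_max) (C1f - C1i)
    C2(t) = C2i + (t/t_max) (C2f - C2i)
    W(t)  = W_max - (t/t_max) (W_max - W_min)

Starting with a large cognitive coefficient C1, a small social coefficient
C2 and a large inertia pushes early exploration; the schedules cross over so
late generations contract onto the swarm's best find.  Velocities are capped
per dimension at a fraction of the box range, positions are clipped to the
box and the clipped components' velocities zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

Box = tuple[np.ndarray, np.ndarray]  # (lower, upper), one entry per dimension


@dataclass
class PSOSettings:
    """Swarm size, schedule endpoints and velocity cap.

    Defaults are the classic TVAC/TVIW settings: C1 2.5 -> 0.5, C2 0.5 -> 2.5,
    inertia 0.9 -> 0.4, 20 particles, 30 generations.
    """

    population_size: int = 20
    max_iterations: int = 30
    c1_initial: float = 2.5
    c1_final: float = 0.5
    c2_initial: float = 0.5
    c2_final: float = 2.5
    w_max: float = 0.9
    w_min: float = 0.4
    velocity_cap_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.w_max < self.w_min:
            raise ValueError("w_max must be >= w_min")
        if not 0.0 < self.velocity_cap_fraction <= 1.0:
            raise ValueError("velocity_cap_fraction must lie in (0, 1]")
        for name in ("c1_initial", "c1_final", "c2_initial", "c2_final"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_score: float = -np.inf


@dataclass
class SearchResult:
    """Best position/score, per-particle pbest records and the gbest trace."""

    gbest_position: np.ndarray
    gbest_score: float
    pbest_positions: list[np.ndarray]
    pbest_scores: list[float]
    gbest_history: list[float]
    trace: list[dict] = field(default_factory=list)

    def trace_csv(self) -> str:
        """Search trace as CSV: generation, schedules and score statistics."""
        lines = ["t,w,c1,c2,gbest_score,mean_score,std_score"]
        for row in self.trace:
            lines.append(
                f"{row['t']},{row['w']:.6g},{row['c1']:.6g},{row['c2']:.6g},"
                f"{row['gbest_score']:.10g},{row['mean_score']:.10g},{row['std_score']:.10g}"
            )
        return "\n".join(lines) + "\n"


def _check_t(t: float, settings: PSOSettings) -> float:
    if not 0 <= t <= settings.max_iterations:
        raise ValueError(f"generation index {t} outside [0, {settings.max_iterations}]")
    return t / settings.max_iterations


def tvac(t: float, settings: PSOSettings) -> tuple[float, float]:
    """Acceleration coefficients (C1, C2) at generation t."""
    frac = _check_t(t, settings)
    c1 = settings.c1_initial + frac * (settings.c1_final - settings.c1_initial)
    c2 = settings.c2_initial + frac * (settings.c2_final - settings.c2_initial)
    return c1, c2


def tviw(t: float, settings: PSOSettings) -> float:
    """Inertia weight at generation t, decreasing W_max -> W_min."""
    frac = _check_t(t, settings)
    return settings.w_max - frac * (settings.w_max - settings.w_min)


def update_velocity(
    p: Particle,
    gbest: np.ndarray,
    w: float,
    c1: float,
    c2: float,
    rng: np.random.Generator,
    box: Box | None = None,
    velocity_cap_fraction: float | None = None,
) -> np.ndarray:
    """New velocity from inertia plus cognitive and social attraction.

    R1, R2 are drawn independently per dimension.  If a box and cap fraction
    are given the result is clamped to +-cap*(upper-lower) per dimension.
    """
    m = p.position.shape[0]
    if gbest.shape[0] != m or p.velocity.shape[0] != m or p.pbest_position.shape[0] != m:
        raise ValueError("velocity update: dimension mismatch")
    r1 = rng.random(m)
    r2 = rng.random(m)
    v = (
        w * p.velocity
        + c1 * r1 * (p.pbest_position - p.position)
        + c2 * r2 * (gbest - p.position)
    )
    if box is not None and velocity_cap_fraction is not None:
        cap = velocity_cap_fraction * (box[1] - box[0])
        v = np.clip(v, -cap, cap)
    return v


def update_position(
    p: Particle, new_velocity: np.ndarray, box: Box
) -> tuple[np.ndarray, np.ndarray]:
    """X' = X + V', clipped to the box; clipped components get zero velocity.

    Returns (position, velocity) so the zeroing propagates to the particle.
    """
    lower, upper = box
    raw = p.position + new_velocity
    clipped = np.clip(raw, lower, upper)
    vel = np.where(raw == clipped, new_velocity, 0.0)
    return clipped, vel


def run_pso(fitness, box: Box, settings: PSOSettings) -> SearchResult:
    """Run the swarm for max_iterations generations (maximizing `fitness`).

    Each generation: evaluate all particles, update pbest/gbest under strict
    improvement, evaluate the schedules at t, then move the swarm.  A final
    evaluation happens at t = max_iterations, so the gbest history has
    max_iterations + 1 entries.  Non-finite fitness values score -inf.
    """
    lower = np.asarray(box[0], dtype=float)
    upper = np.asarray(box[1], dtype=float)
    if lower.shape != upper.shape or np.any(upper < lower) or not np.all(np.isfinite(lower)) or not np.all(np.isfinite(upper)):
        raise ValueError("box must be finite with lower <= upper")
    box = (lower, upper)
    rng = np.random.default_rng(settings.seed)

    particles = [
        Particle(
            position=rng.uniform(lower, upper),
            velocity=np.zeros_like(lower),
            pbest_position=np.empty_like(lower),
        )
        for _ in range(settings.population_size)
    ]
    for p in particles:
        p.pbest_position = p.position.copy()

    gbest_position = particles[0].position.copy()
    gbest_score = -np.inf
    history: list[float] = []
    trace: list[dict] = []

    for t in range(settings.max_iterations + 1):
        scores = []
        for i, p in enumerate(particles):
            s = float(fitness(p.position))
            if not np.isfinite(s):
                logger.warning("particle %d returned non-finite fitness at t=%d", i, t)
                s = -np.inf
            scores.append(s)
            if s > p.pbest_score:  # strict improvement; ties keep the incumbent
                p.pbest_score = s
                p.pbest_position = p.position.copy()
            if s > gbest_score:
                gbest_score = s
                gbest_position = p.position.copy()
        history.append(gbest_score)

        w = tviw(t, settings)
        c1, c2 = tvac(t, settings)
        finite = [s for s in scores if np.isfinite(s)]
        trace.append(
            {
                "t": t,
                "w": w,
                "c1": c1,
                "c2": c2,
                "gbest_score": gbest_score,
                "mean_score": float(np.mean(finite)) if finite else float("nan"),
                "std_score": float(np.std(finite)) if finite else float("nan"),
            }
        )
        logger.info(
            "generation %d/%d: gbest=%.6g mean=%.6g w=%.3f c1=%.3f c2=%.3f",
            t, settings.max_iterations, gbest_score, trace[-1]["mean_score"], w, c1, c2,
        )
        if t == settings.max_iterations:
            break
        for p in particles:
            v = update_velocity(
                p, gbest_position, w, c1, c2, rng, box, settings.velocity_cap_fraction
            )
            p.position, p.velocity = update_position(p, v, box)

    return SearchResult(
        gbest_position=gbest_position,
        gbest_score=gbest_score,
        pbest_positions=[p.pbest_position.copy() for p in particles],
        pbest_scores=[p.pbest_score for p in particles],
        gbest_history=history,
        trace=trace,
    )
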