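"""Coupled logistic competition between two populations.

The model is

    dX/dt = a X (1 - (X + Y) / m)
    dY/dt = b Y (1 - (X + Y) / n)

where a, b are intrinsic growth rates and m, n the equilibrium
(carrying-capacity) sizes; the species compete through the shared
resource term X + Y.  A run has three stages: stages 1 and 3 integrate
the equations unperturbed; at stage-2 entry species 2 (Y) is
instantaneously multiplied by the perturbation factor rho, and species
1 (X) receives the identical perturbation after a delay (default
5e5 model-time units), producing the characteristic asynchronous
crash-and-recovery of the two trajectories.

Integration is fixed-step (RK4 by default) so that perturbation times
land exactly on grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CompetitionConfig:
    a: float = 1e-5
    b: float = 1e-5
    m: float = 5e4
    n: float = 5e4
    x0: float = 100.0
    y0: float = 100.0
    t_stage1_end: float = 2e6
    t_stage2_end: float = 4e6
    t_final: float = 6e6
    rho: float = 0.1
    delay: float = 5e5
    dt: float = 500.0
    integrator: str = "rk4"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.m <= 0 or self.n <= 0:
            raise ValueError("growth rates and equilibrium sizes must be positive")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("initial sizes must be non-negative")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        if not (0 < self.t_stage1_end < self.t_stage2_end < self.t_final):
            raise ValueError("stage boundaries must be increasing and positive")
        shortest = min(
            self.t_stage1_end,
            self.t_stage2_end - self.t_stage1_end,
            self.t_final - self.t_stage2_end,
        )
        if self.dt <= 0 or self.dt >= shortest:
            raise ValueError("dt must be positive and smaller than the shortest stage")
        if self.delay < 0 or self.t_stage1_end + self.delay > self.t_final:
            raise ValueError("delayed perturbation must occur before t_final")
        for t_ev in (self.t_stage1_end, self.t_stage1_end + self.delay, self.t_final):
            if abs(round(t_ev / self.dt) - t_ev / self.dt) > 1e-9:
                raise ValueError(
                    f"event/end time {t_ev} must be an integer multiple of dt={self.dt} "
                    "so perturbations land exactly on grid points"
                )
        if self.integrator not in ("rk4", "euler"):
            raise ValueError("integrator must be 'rk4' or 'euler'")


@dataclass
class Trajectory:
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    events: list[tuple[float, str, float]] = field(default_factory=list)


def logistic_closed_form(x0: float, a: float, m: float, t) -> np.ndarray:
    """Single-species logistic solution X(t) = m x0 e^{at} / (m + x0 (e^{at} - 1))."""
    if x0 < 0 or m <= 0:
        raise ValueError("require x0 >= 0 and m > 0")
    t = np.asarray(t, dtype=float)
    # stable form: divide through by e^{at}
    return m * x0 / (m * np.exp(-a * t) + x0 * (1.0 - np.exp(-a * t)))


def _deriv(x: float, y: float, cfg: CompetitionConfig) -> tuple[float, float]:
    total = x + y
    return cfg.a * x * (1.0 - total / cfg.m), cfg.b * y * (1.0 - total / cfg.n)


def _step(x: float, y: float, cfg: CompetitionConfig) -> tuple[float, float]:
    h = cfg.dt
    if cfg.integrator == "euler":
        dx, dy = _deriv(x, y, cfg)
        return x + h * dx, y + h * dy
    k1x, k1y = _deriv(x, y, cfg)
    k2x, k2y = _deriv(x + h / 2 * k1x, y + h / 2 * k1y, cfg)
    k3x, k3y = _deriv(x + h / 2 * k2x, y + h / 2 * k2y, cfg)
    k4x, k4y = _deriv(x + h * k3x, y + h * k3y, cfg)
    return (
        x + h / 6 * (k1x + 2 * k2x + 2 * k3x + k4x),
        y + h / 6 * (k1y + 2 * k2y + 2 * k3y + k4y),
    )


def simulate_competition(config: CompetitionConfig) -> Trajectory:
    """Integrate the three-stage perturbed competition model.

    Perturbations multiply the population by ``rho`` exactly at
    stage-2 entry (species 2) and ``delay`` later (species 1).
    """
    n_steps = int(round(config.t_final / config.dt))
    t = np.arange(n_steps + 1) * config.dt
    x = np.empty(n_steps + 1)
    y = np.empty(n_steps + 1)
    x[0], y[0] = config.x0, config.y0
    i_pert_y = int(round(config.t_stage1_end / config.dt))
    i_pert_x = int(round((config.t_stage1_end + config.delay) / config.dt))
    events: list[tuple[float, str, float]] = []
    for i in range(n_steps):
        if i == i_pert_y:
            y[i] = y[i] * config.rho
            events.append((config.t_stage1_end, "Y", config.rho))
        if i == i_pert_x:
            x[i] = x[i] * config.rho
            events.append((config.t_stage1_end + config.delay, "X", config.rho))
        x[i + 1], y[i + 1] = _step(x[i], y[i], config)
        if x[i + 1] < 0 or y[i + 1] < 0:
            raise RuntimeError(
                f"population went negative at t={t[i + 1]:g}; use a smaller dt"
            )
    if n_steps == i_pert_y:
        y[-1] *= config.rho
        events.append((config.t_stage1_end, "Y", config.rho))
    if n_steps == i_pert_x:
        x[-1] *= config.rho
        events.append((config.t_stage1_end + config.delay, "X", config.rho))
    return Trajectory(t, x, y, events)
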