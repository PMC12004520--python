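"""Time integration: leapfrog dynamics with an implicit-solvent Langevin bath.

The deterministic part is the classic leapfrog update

    v(t+dt/2) = v(t-dt/2) + F(t)/m * dt,   r(t+dt) = r(t) + v(t+dt/2) * dt.

The Langevin drag/fluctuation terms are discretised with the GJF
(Grønbech-Jensen & Farago) leapfrog scheme rather than by adding the drag to
the explicit force: the glucose bead's velocity relaxation time m/c
(~2 fs in the 0.03 Pa·s solvent) is far below the 0.04 ps step, so explicit
damping would diverge.  The GJF half-step scheme is unconditionally stable,
reduces exactly to the plain leapfrog when the diffusion term is inactive,
and reproduces the free-particle diffusion coefficient k_B·T/c and the
half-step kinetic temperature k_B·T/m exactly at any c·dt/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (BeadSpec, DomainError, ForceField, SolventSpec,
                         SystemState, UNITS)
from .forces import build_neighbor_list, evaluate_forces

__all__ = [
    "IntegratorSettings",
    "AnnealingSchedule",
    "KineticsLog",
    "NumericalBlowupError",
    "anneal_temperature",
    "leapfrog_step",
    "maxwell_boltzmann_velocities",
    "run_segment",
]


class NumericalBlowupError(RuntimeError):
    """Non-finite coordinates or forces encountered during integration."""


@dataclass(frozen=True)
class IntegratorSettings:
    """Time step, seeding and neighbor-list housekeeping.

    dt_ps defaults to 0.04 ps, the largest step for which the discrete
    dynamics of the glucose bead system converges.
    """

    dt_ps: float = 0.04
    seed: int = 0
    skin_nm: float = 0.3
    rebuild_check_stride: int = 1   # steps between displacement checks

    def __post_init__(self) -> None:
        if self.dt_ps <= 0:
            raise DomainError(f"dt must be > 0, got {self.dt_ps}")
        if self.skin_nm < 0:
            raise DomainError("skin must be >= 0")


@dataclass(frozen=True)
class AnnealingSchedule:
    """Linear cooling ramp used to relax freshly generated chains.

    T(0) = t_max_k, decreasing linearly to t_eq_k at ramp_ps and constant
    afterwards.
    """

    t_max_k: float = 2000.0
    t_eq_k: float = 300.0
    ramp_ps: float = 5.0e6

    def __post_init__(self) -> None:
        if self.t_max_k < self.t_eq_k:
            raise DomainError("annealing peak must be >= equilibrium temperature")
        if self.ramp_ps <= 0:
            raise DomainError("ramp duration must be > 0")


def anneal_temperature(t_ps: float, schedule: AnnealingSchedule) -> float:
    """Piecewise-linear annealing temperature at elapsed stage time t."""
    if t_ps < 0:
        raise DomainError(f"time must be >= 0, got {t_ps}")
    if t_ps >= schedule.ramp_ps:
        return schedule.t_eq_k
    frac = t_ps / schedule.ramp_ps
    return schedule.t_max_k + frac * (schedule.t_eq_k - schedule.t_max_k)


@dataclass
class KineticsLog:
    """Stage time series: temperatures, per-term force norms, interactions."""

    time_ps: list = field(default_factory=list)
    temperature_k: list = field(default_factory=list)
    temperature_kinetic_k: list = field(default_factory=list)
    interactions: list = field(default_factory=list)
    term_norms: dict = field(default_factory=dict)   # term -> list

    def append(self, t: float, t_target: float, t_kin: float, inter: int,
               norms: dict) -> None:
        self.time_ps.append(t)
        self.temperature_k.append(t_target)
        self.temperature_kinetic_k.append(t_kin)
        self.interactions.append(inter)
        for term, value in norms.items():
            self.term_norms.setdefault(term, []).append(value)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "time_ps": self.time_ps,
            "temperature_K": self.temperature_k,
            "temperature_kinetic_K": self.temperature_kinetic_k,
            "interactions": self.interactions,
        }
        for term, values in self.term_norms.items():
            data[f"force_{term}"] = values
        return pd.DataFrame(data)

    def to_csv(self, path, normalized=None) -> None:
        df = self.to_dataframe()
        if normalized is not None:
            df["interactions_normalized"] = normalized
        df.to_csv(path, index=False)


def maxwell_boltzmann_velocities(n_beads: int, mass_amu: float,
                                 temperature_k: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Draw half-step velocities from the Maxwell-Boltzmann distribution."""
    sigma = np.sqrt(UNITS.boltzmann * temperature_k / mass_amu)
    return sigma * rng.standard_normal((n_beads, 3))


def leapfrog_step(state: SystemState, forces, settings: IntegratorSettings,
                  mass_amu: float = 162.14) -> SystemState:
    """One deterministic leapfrog step (no solvent coupling).

    Velocities are advanced by F/m*dt, positions by v*dt, then wrapped into
    the periodic box.  Raises NumericalBlowupError on non-finite values.
    """
    f = forces.forces if hasattr(forces, "forces") else np.asarray(forces)
    if not np.all(np.isfinite(f)):
        raise NumericalBlowupError(
            f"non-finite force at t = {state.time_ps} ps")
    dt = settings.dt_ps
    state.velocities += f / mass_amu * dt
    state.positions += state.velocities * dt
    state.wrap()
    state.time_ps += dt
    if not np.all(np.isfinite(state.positions)):
        raise NumericalBlowupError(
            f"non-finite position at t = {state.time_ps} ps")
    return state


def _count_interactions_fast(state: SystemState, d_int_nm: float) -> int:
    # local import to avoid a cycle; structure_analysis owns the public op
    from .structure_analysis import count_interactions
    count, _ = count_interactions(state, d_int_nm)
    return count


def run_segment(state: SystemState, ff: ForceField, solvent: SolventSpec,
                settings: IntegratorSettings, duration_ps: float,
                active_terms=("bond", "bending", "lj", "diffusion"),
                schedule: AnnealingSchedule | None = None,
                bead: BeadSpec | None = None,
                rng: np.random.Generator | None = None,
                log_stride: int = 250,
                count_interactions_in_log: bool = True):
    """Integrate ``state`` for ``duration_ps`` with the named force terms.

    Returns the advanced state (mutated in place) and a KineticsLog sampled
    every ``log_stride`` steps.  ``active_terms`` is a subset of
    {"bond", "bending", "lj", "diffusion"}.
    """
    bead = bead or BeadSpec()
    dt = settings.dt_ps
    n_steps = int(round(duration_ps / dt))
    if abs(n_steps * dt - duration_ps) > 1e-9 * max(1.0, duration_ps):
        raise DomainError(
            f"duration {duration_ps} ps is not a multiple of dt = {dt} ps")
    log = KineticsLog()
    if n_steps == 0:
        return state, log
    rng = rng if rng is not None else np.random.default_rng(settings.seed)

    mass = bead.mass_amu
    det_terms = tuple(t for t in active_terms if t != "diffusion")
    diffusion = "diffusion" in active_terms
    if diffusion:
        c = solvent.drag_internal(bead.stokes_radius_nm)
        gamma_dt = c / mass * dt
        b = 1.0 / (1.0 + 0.5 * gamma_dt)
        a = (1.0 - 0.5 * gamma_dt) * b
        sqrt_b = np.sqrt(b)
    else:
        c, b, a, sqrt_b = 0.0, 1.0, 1.0, 1.0

    use_lj = "lj" in det_terms
    nlist = build_neighbor_list(state, ff.cutoff_nm, settings.skin_nm) if use_lj else None

    def temperature_at(t_local: float) -> float:
        if schedule is not None:
            return anneal_temperature(t_local, schedule)
        return solvent.temperature_k

    def noise(t_local: float) -> np.ndarray:
        t_k = temperature_at(t_local)
        amp = np.sqrt(2.0 * c * UNITS.boltzmann * t_k * dt)
        return amp * rng.standard_normal((state.n_beads, 3))

    beta_prev = noise(0.0) if diffusion else None
    t0 = state.time_ps

    for step in range(n_steps):
        t_local = step * dt
        logging_step = (step + 1) % log_stride == 0 or step == n_steps - 1
        if use_lj and step % settings.rebuild_check_stride == 0 and nlist.needs_rebuild(state):
            nlist = build_neighbor_list(state, ff.cutoff_nm, settings.skin_nm)
        acc = evaluate_forces(state, ff, nlist, det_terms,
                              diagnostics=logging_step)
        if diffusion:
            beta_next = noise(t_local + dt)
            state.velocities = (a * state.velocities
                                + (sqrt_b * dt / mass) * acc.forces
                                + (sqrt_b / (2.0 * mass)) * (beta_prev + beta_next))
            beta_prev = beta_next
            state.positions += sqrt_b * dt * state.velocities
            state.wrap()
            state.time_ps += dt
        else:
            leapfrog_step(state, acc, settings, mass_amu=mass)

        if logging_step:
            if not np.all(np.isfinite(state.positions)):
                raise NumericalBlowupError(
                    f"non-finite position at t = {state.time_ps} ps "
                    f"(stage step {step + 1}/{n_steps})")
            v2 = float(np.mean(np.einsum("ij,ij->i",
                                         state.velocities, state.velocities)))
            t_kin = mass * v2 / (3.0 * UNITS.boltzmann)
            inter = (_count_interactions_fast(state, ff.d_int_nm)
                     if count_interactions_in_log else 0)
            log.append(state.time_ps - t0, temperature_at(t_local + dt), t_kin,
                       inter, acc.term_norms)
    return state, log
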