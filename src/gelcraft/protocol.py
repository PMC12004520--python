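"""The virtual production pipeline for cellulose (aero)gels.

Stages mirror the laboratory route: straight chains are generated at random
orientations in the periodic box, relaxed under an annealing ramp with only
the bond/bending and diffusion terms active, equilibrated with a purely
repulsive excluded-volume interaction to remove generation overlap, gelled
with the full Lennard-Jones attraction switched on, then washed (solvent →
water) and solvent-exchanged (→ ethanol), which only swap the implicit
solvent's viscosity.  Drying to the aerogel is a simplistic isotropic
deformation matching the experimentally observed volumetric shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_model import (BeadSpec, ChainTopology, DomainError, ForceField,
                         SolventSpec, SystemState, NAOH_UREA, WATER, ETHANOL,
                         minimum_image)
from .integrator import (AnnealingSchedule, IntegratorSettings, KineticsLog,
                         maxwell_boltzmann_velocities, run_segment,
                         anneal_temperature)

__all__ = [
    "StageSpec",
    "DeformationGradient",
    "PipelineConfig",
    "PipelineResult",
    "generate_chains",
    "apply_drying",
    "volume_shrinkage",
    "run_pipeline",
    "mini_config",
    "paper_config",
    "default_stages",
    "STAGE_LABELS",
]

LJ_MODES = ("off", "repulsive_only", "full")

#: material labels of the snapshots taken after each stage
STAGE_LABELS = {
    "gelation": "gel",
    "washing": "hydrogel",
    "solvent_exchange": "alcogel",
    "drying": "aerogel",
}


@dataclass(frozen=True)
class StageSpec:
    """One stage of the production protocol."""

    name: str
    duration_ps: float
    solvent: str = "naoh_urea"
    bonded_terms: tuple = ("bond", "bending")
    diffusion: bool = True
    lj_mode: str = "off"
    annealing: AnnealingSchedule | None = None

    def __post_init__(self) -> None:
        if self.duration_ps < 0:
            raise DomainError("stage duration must be >= 0")
        if self.lj_mode not in LJ_MODES:
            raise DomainError(f"lj_mode must be one of {LJ_MODES}")

    @property
    def active_terms(self) -> tuple:
        terms = list(self.bonded_terms)
        if self.lj_mode != "off":
            terms.append("lj")
        if self.diffusion:
            terms.append("diffusion")
        return tuple(terms)


@dataclass(frozen=True)
class DeformationGradient:
    """Isotropic deformation F = λ·I; det F = λ³ is the volume ratio."""

    stretch: float

    def __post_init__(self) -> None:
        if not 0 < self.stretch <= 1:
            raise DomainError(f"stretch must lie in (0, 1], got {self.stretch}")

    @property
    def tensor(self) -> np.ndarray:
        return self.stretch * np.eye(3)

    @property
    def volume_ratio(self) -> float:
        return self.stretch**3


def default_stages(scale: str = "paper") -> list[StageSpec]:
    """Stage protocol at paper scale or the ns-scale desk (`mini`) variant.

    Paper scale: relaxation 15 μs containing the 5 μs annealing ramp at its
    start, equilibration 700 ns with repulsive-only LJ, gelation 5 μs with the
    full interaction, then washing/solvent exchange (durations not reported;
    1 μs each) swapping only the solvent viscosity.  The mini protocol keeps
    the same stage structure at nanosecond durations.
    """
    if scale == "paper":
        return [
            StageSpec("relaxation", 15.0e6, "naoh_urea",
                      annealing=AnnealingSchedule(2000.0, 300.0, 5.0e6)),
            StageSpec("equilibration", 7.0e5, "naoh_urea", lj_mode="repulsive_only"),
            StageSpec("gelation", 5.0e6, "naoh_urea", lj_mode="full"),
            StageSpec("washing", 1.0e6, "water", lj_mode="full"),
            StageSpec("solvent_exchange", 1.0e6, "ethanol", lj_mode="full"),
        ]
    if scale == "mini":
        return [
            StageSpec("relaxation", 300.0, "naoh_urea",
                      annealing=AnnealingSchedule(2000.0, 300.0, 100.0)),
            StageSpec("equilibration", 60.0, "naoh_urea", lj_mode="repulsive_only"),
            StageSpec("gelation", 2000.0, "naoh_urea", lj_mode="full"),
            StageSpec("washing", 150.0, "water", lj_mode="full"),
            StageSpec("solvent_exchange", 150.0, "ethanol", lj_mode="full"),
        ]
    raise DomainError(f"unknown protocol scale {scale!r}")


@dataclass
class PipelineConfig:
    """Everything needed to run the virtual production pipeline."""

    bead: BeadSpec = field(default_factory=BeadSpec)
    forcefield: ForceField = field(default_factory=lambda: ForceField.from_si(
        bond_stiffness_n_m=1.18479, bond_length_nm=0.4615,
        bending_stiffness_n_m_rad=1.15375e-19, epsilon_kj_mol=30.0,
        d_eq_nm=0.4, cutoff_nm=1.5, d_int_nm=1.5))
    solvents: dict = field(default_factory=lambda: {
        s.name: s for s in (NAOH_UREA, WATER, ETHANOL)})
    box_nm: float = 100.0
    n_chains: int = 764
    beads_per_chain: int = 360
    stages: list = field(default_factory=lambda: default_stages("paper"))
    integrator: IntegratorSettings = field(default_factory=IntegratorSettings)
    drying_shrinkage: float = 0.395
    seed: int = 0
    log_stride: int = 250

    def with_seed(self, seed: int) -> "PipelineConfig":
        import copy
        cfg = copy.copy(self)
        cfg.seed = seed
        return cfg


@dataclass
class PipelineResult:
    final_state: SystemState
    logs: dict              # stage name -> KineticsLog
    snapshots: dict         # stage name and material label -> SystemState


def mini_config(seed: int = 0, epsilon_kj_mol: float = 30.0,
                d_eq_nm: float = 0.4) -> PipelineConfig:
    """Desk-scale preset: 10 chains × 20 beads in a 9 nm box, ns durations.

    The 9 nm box keeps the bead number density at the full-scale system's
    7 wt% solution value (200/9³ ≈ 0.274 nm⁻³ vs 275040/100³ ≈ 0.275 nm⁻³),
    so inter-chain contact statistics — and hence gelation kinetics — remain
    representative at desk scale.
    """
    ff = ForceField.from_si(
        bond_stiffness_n_m=1.18479, bond_length_nm=0.4615,
        bending_stiffness_n_m_rad=1.15375e-19, epsilon_kj_mol=epsilon_kj_mol,
        d_eq_nm=d_eq_nm, cutoff_nm=1.5, d_int_nm=1.5)
    return PipelineConfig(forcefield=ff, box_nm=9.0, n_chains=10,
                          beads_per_chain=20, stages=default_stages("mini"),
                          seed=seed, log_stride=250)


def paper_config(seed: int = 0, epsilon_kj_mol: float = 30.0,
                 d_eq_nm: float = 0.4) -> PipelineConfig:
    """Full-scale preset matching the published system (cluster-scale runtime)."""
    ff = ForceField.from_si(
        bond_stiffness_n_m=1.18479, bond_length_nm=0.4615,
        bending_stiffness_n_m_rad=1.15375e-19, epsilon_kj_mol=epsilon_kj_mol,
        d_eq_nm=d_eq_nm, cutoff_nm=1.5, d_int_nm=1.5)
    return PipelineConfig(forcefield=ff, seed=seed)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def generate_chains(n_chains: int, beads_per_chain: int, bond_length_nm: float,
                    box_nm: float, seed: int | np.random.Generator = 0) -> SystemState:
    """Generate straight chains at uniformly random positions and orientations.

    Chain start points are uniform in the box; orientations are uniform on the
    sphere.  Overlap between chains is permitted — the equilibration stage
    resolves it.  Velocities are initialized to zero.
    """
    if n_chains < 1 or beads_per_chain < 1:
        raise DomainError("need at least one chain with one bead")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    topo = ChainTopology(n_chains, beads_per_chain)
    starts = rng.uniform(0.0, box_nm, size=(n_chains, 3))
    u = rng.standard_normal((n_chains, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    steps = np.arange(beads_per_chain)[None, :, None] * bond_length_nm
    pos = (starts[:, None, :] + steps * u[:, None, :]).reshape(-1, 3)
    state = SystemState(pos, np.zeros_like(pos), topo, box_nm)
    state.wrap()
    return state


def volume_shrinkage(v_aerogel: float, v_hydrogel: float) -> float:
    """Volume shrinkage in percent: 100·(1 − V_aerogel/V_hydrogel)."""
    if v_aerogel <= 0 or v_hydrogel <= 0:
        raise DomainError("volumes must be > 0")
    return 100.0 * (1.0 - v_aerogel / v_hydrogel)


def apply_drying(state: SystemState, volumetric_shrinkage: float) -> SystemState:
    """Isotropic drying transform: scale box and positions by λ = (1−V_s)^⅓.

    Bead diameters are untouched; only the geometry shrinks, mimicking the
    volume loss observed during supercritical drying.
    """
    if not 0 <= volumetric_shrinkage < 1:
        raise DomainError(
            f"volumetric shrinkage must lie in [0, 1), got {volumetric_shrinkage}")
    lam = (1.0 - volumetric_shrinkage) ** (1.0 / 3.0)
    dried = state.copy()
    dried.positions *= lam
    dried.box_nm = state.box_nm * lam
    dried.wrap()
    return dried


def run_pipeline(config: PipelineConfig,
                 count_interactions_in_log: bool = True) -> PipelineResult:
    """Execute the staged protocol and return the final state plus stage logs.

    A master seed spawns independent RNG streams per stage (generation first),
    so stages are individually reproducible.  Snapshots taken after gelation,
    washing, solvent exchange and drying carry the material labels gel /
    hydrogel / alcogel / aerogel.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.stages) + 2)
    gen_rng = np.random.default_rng(seeds[0])
    state = generate_chains(config.n_chains, config.beads_per_chain,
                            config.forcefield.l_eq_nm, config.box_nm, gen_rng)
    snapshots = {"generation": state.copy()}
    logs: dict[str, KineticsLog] = {}

    # Maxwell-Boltzmann start at the first stage's initial temperature
    first = config.stages[0] if config.stages else None
    if first is not None:
        t0 = (anneal_temperature(0.0, first.annealing) if first.annealing
              else config.solvents[first.solvent].temperature_k)
        state.velocities = maxwell_boltzmann_velocities(
            state.n_beads, config.bead.mass_amu, t0,
            np.random.default_rng(seeds[1]))

    for k, stage in enumerate(config.stages):
        solvent = config.solvents[stage.solvent]
        ff = config.forcefield
        if stage.lj_mode == "repulsive_only":
            ff = ff.replace(repulsive_only=True)
        rng = np.random.default_rng(seeds[k + 2])
        try:
            state, log = run_segment(
                state, ff, solvent, config.integrator, stage.duration_ps,
                active_terms=stage.active_terms, schedule=stage.annealing,
                bead=config.bead, rng=rng, log_stride=config.log_stride,
                count_interactions_in_log=count_interactions_in_log)
        except Exception as exc:
            raise RuntimeError(
                f"stage '{stage.name}' failed at t = {state.time_ps} ps; "
                f"last completed snapshot: "
                f"{list(snapshots)[-1]!r}") from exc
        logs[stage.name] = log
        snapshots[stage.name] = state.copy()
        if stage.name in STAGE_LABELS:
            snapshots[STAGE_LABELS[stage.name]] = snapshots[stage.name]

    if config.drying_shrinkage is not None:
        state = apply_drying(state, config.drying_shrinkage)
        snapshots["drying"] = state.copy()
        snapshots["aerogel"] = snapshots["drying"]
    return PipelineResult(final_state=state, logs=logs, snapshots=snapshots)
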