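"""Domain types, unit conventions and physically motivated parameter derivations.

The simulation represents each d-glucose repeating unit of a cellulose chain as
a sphere of diameter ``d_g`` connected to its chain neighbours by elastic bonds
with a normal (stretch) and a bending degree of freedom.  The solvent is
implicit: it enters only through a Stokes drag coefficient and the matching
fluctuating (Langevin) force.

All quantities inside the simulation are kept in a reduced unit system
(nm / ps / amu) whose derived energy unit happens to equal 1 kJ/mol per
particle, so molar interaction energies from the literature can be used
verbatim.  The derivation helpers in this module accept and return SI values;
conversion to internal units happens once, at configuration load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants

__all__ = [
    "AVOGADRO",
    "UnitSystem",
    "UNITS",
    "BeadSpec",
    "ForceField",
    "SolventSpec",
    "ChainTopology",
    "SystemState",
    "derive_bond_stiffness",
    "derive_monomer_mass",
    "derive_repeat_units",
    "derive_chain_count",
    "derive_drag_coefficient",
]

AVOGADRO = constants.Avogadro  # 1/mol


class DomainError(ValueError):
    """Raised when a physically meaningless parameter value is supplied."""


@dataclass(frozen=True)
class UnitSystem:
    """Internal reduced units: nm (length), ps (time), amu (mass).

    The derived energy unit amu·nm²/ps² equals 1.66054e-21 J, which is exactly
    1 kJ/mol divided by Avogadro's number — i.e. internal energies are
    numerically kJ/mol-per-particle.
    """

    length_si: float = 1e-9            # m per internal length (nm)
    time_si: float = 1e-12             # s per internal time (ps)
    mass_si: float = constants.atomic_mass  # kg per internal mass (amu)

    @property
    def energy_si(self) -> float:
        """J per internal energy unit (= 1.66054e-21 J = 1 kJ/mol/particle)."""
        return self.mass_si * self.length_si**2 / self.time_si**2

    @property
    def force_si(self) -> float:
        """N per internal force unit."""
        return self.energy_si / self.length_si

    @property
    def velocity_si(self) -> float:
        return self.length_si / self.time_si

    @property
    def stiffness_si(self) -> float:
        """N/m per internal (energy/length²) stiffness unit."""
        return self.force_si / self.length_si

    @property
    def torque_si(self) -> float:
        """N·m (per rad) per internal torque unit."""
        return self.energy_si

    @property
    def viscosity_si(self) -> float:
        """Pa·s per internal (mass / length / time) viscosity unit."""
        return self.mass_si / (self.length_si * self.time_si)

    @property
    def drag_si(self) -> float:
        """kg/s per internal (mass/time) drag unit."""
        return self.mass_si / self.time_si

    @property
    def boltzmann(self) -> float:
        """Boltzmann constant in internal energy units per kelvin."""
        return constants.Boltzmann / self.energy_si

    # generic converters -------------------------------------------------
    def to_internal(self, value: float, si_per_internal: float) -> float:
        return value / si_per_internal

    def to_si(self, value: float, si_per_internal: float) -> float:
        return value * si_per_internal


#: Shared unit system instance used throughout the package.
UNITS = UnitSystem()


# ---------------------------------------------------------------------------
# Parameter derivations (SI in, SI out)
# ---------------------------------------------------------------------------

def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise DomainError(f"{name} must be a positive finite number, got {value!r}")


def derive_bond_stiffness(persistence_length: float, chain_stiffness: float,
                          bond_length: float) -> float:
    """Normal bond stiffness k_b^n = l_p·s / l_b² (all SI: m, N, m → N/m).

    The single-molecule persistence length l_p and chain stiffness s measured
    for cellulose are redistributed over the l_p/l_b spring elements that make
    up one persistence length of the bead-spring chain.
    """
    _require_positive(persistence_length=persistence_length,
                      chain_stiffness=chain_stiffness, bond_length=bond_length)
    return persistence_length * chain_stiffness / bond_length**2


def derive_monomer_mass(molar_mass: float) -> float:
    """Mass of one repeating unit in grams from its molar mass in g/mol."""
    _require_positive(molar_mass=molar_mass)
    return molar_mass / AVOGADRO


def derive_repeat_units(degree_of_polymerization: int) -> int:
    """Glucose repeat units per chain, n_g = 2·DP.

    The experimental degree of polymerization counts cellobiose units, each of
    which contributes two glucose rings.
    """
    dp = degree_of_polymerization
    if isinstance(dp, float) and not float(dp).is_integer():
        raise DomainError(f"degree of polymerization must be an integer, got {dp!r}")
    dp = int(dp)
    if dp < 1:
        raise DomainError(f"degree of polymerization must be >= 1, got {dp}")
    return 2 * dp


def derive_chain_count(mass_fraction: float, solution_density: float,
                       box_volume: float, beads_per_chain: int,
                       bead_mass: float) -> int:
    """Number of chains in the periodic box from the solution composition.

    n_c = round(w_c · ρ_sol · V_box / (n_g · m_g)), with ρ_sol in g/cm³,
    V_box in cm³ and m_g in g.
    """
    _require_positive(mass_fraction=mass_fraction, solution_density=solution_density,
                      box_volume=box_volume, beads_per_chain=beads_per_chain,
                      bead_mass=bead_mass)
    return int(round(mass_fraction * solution_density * box_volume
                     / (beads_per_chain * bead_mass)))


def derive_drag_coefficient(viscosity: float, stokes_radius: float) -> float:
    """Stokes translational drag c = 6π·μ·r_s (SI: Pa·s, m → kg/s)."""
    _require_positive(viscosity=viscosity, stokes_radius=stokes_radius)
    return 6.0 * np.pi * viscosity * stokes_radius


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadSpec:
    """Geometry and mass of one coarse-grained glucose bead.

    diameter_nm : sphere diameter d_g (also the equilibrium bond length).
    mass_amu    : bead mass in internal mass units (numerically the molar
                  mass in g/mol).
    """

    diameter_nm: float = 0.4615
    mass_amu: float = 162.14

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise DomainError(f"bead diameter must be > 0, got {self.diameter_nm}")
        if self.mass_amu <= 0:
            raise DomainError(f"bead mass must be > 0, got {self.mass_amu}")

    @property
    def stokes_radius_nm(self) -> float:
        """Hydrodynamic (Stokes) radius, half the bead diameter."""
        return self.diameter_nm / 2.0


@dataclass(frozen=True)
class SolventSpec:
    """Implicit solvent: a name, a dynamic viscosity and a temperature."""

    name: str
    viscosity_pa_s: float
    temperature_k: float = 300.0

    def __post_init__(self) -> None:
        _require_positive(viscosity_pa_s=self.viscosity_pa_s,
                          temperature_k=self.temperature_k)

    @property
    def viscosity_internal(self) -> float:
        return UNITS.to_internal(self.viscosity_pa_s, UNITS.viscosity_si)

    def drag_internal(self, stokes_radius_nm: float) -> float:
        """Stokes drag 6πμr in internal (amu/ps) units."""
        return 6.0 * np.pi * self.viscosity_internal * stokes_radius_nm


# canonical solvents of the virtual production pipeline
NAOH_UREA = SolventSpec("naoh_urea", viscosity_pa_s=0.03)
WATER = SolventSpec("water", viscosity_pa_s=0.00089)
ETHANOL = SolventSpec("ethanol", viscosity_pa_s=0.001074)


@dataclass(frozen=True)
class ForceField:
    """Bonded and non-bonded interaction parameters, in internal units.

    k_bond   : normal bond stiffness (energy / nm², i.e. kJ/mol/nm²)
    l_eq_nm  : equilibrium bond length
    k_bend   : bending stiffness (energy / rad², torque per rad)
    epsilon  : Lennard-Jones well depth (kJ/mol ≡ internal energy, already
               per-particle in internal units)
    d_eq_nm  : location of the LJ minimum
    cutoff_nm: interaction truncation distance
    d_int_nm : distance below which an inter-chain pair counts as an
               "interaction" for gelation kinetics / coordination numbers
    repulsive_only : clamp the attractive LJ branch to zero (equilibration)
    """

    k_bond: float
    l_eq_nm: float
    k_bend: float
    epsilon: float
    d_eq_nm: float
    cutoff_nm: float
    d_int_nm: float = 1.5
    repulsive_only: bool = False

    def __post_init__(self) -> None:
        _require_positive(k_bond=self.k_bond, l_eq_nm=self.l_eq_nm,
                          k_bend=self.k_bend, epsilon=self.epsilon,
                          d_eq_nm=self.d_eq_nm, cutoff_nm=self.cutoff_nm,
                          d_int_nm=self.d_int_nm)
        if self.cutoff_nm < self.d_eq_nm:
            raise DomainError("cutoff must be >= LJ equilibrium distance")
        if self.d_int_nm > self.cutoff_nm:
            raise DomainError("interaction distance must be <= cutoff")

    @classmethod
    def from_si(cls, bond_stiffness_n_m: float, bond_length_nm: float,
                bending_stiffness_n_m_rad: float, epsilon_kj_mol: float,
                d_eq_nm: float, cutoff_nm: float, d_int_nm: float = 1.5,
                repulsive_only: bool = False) -> "ForceField":
        return cls(
            k_bond=UNITS.to_internal(bond_stiffness_n_m, UNITS.stiffness_si),
            l_eq_nm=bond_length_nm,
            k_bend=UNITS.to_internal(bending_stiffness_n_m_rad, UNITS.torque_si),
            epsilon=epsilon_kj_mol,
            d_eq_nm=d_eq_nm,
            cutoff_nm=cutoff_nm,
            d_int_nm=d_int_nm,
            repulsive_only=repulsive_only,
        )

    def replace(self, **changes) -> "ForceField":
        from dataclasses import replace as _replace
        return _replace(self, **changes)


class ChainTopology:
    """Connectivity of a system of linear bead-spring chains.

    Each of ``n_chains`` chains contributes ``beads_per_chain - 1`` bonded
    pairs and ``beads_per_chain - 2`` angle triplets.  Interior beads have two
    bonds, chain ends one.
    """

    def __init__(self, n_chains: int, beads_per_chain: int):
        if n_chains < 1 or beads_per_chain < 1:
            raise DomainError("need at least one chain with one bead")
        self.n_chains = int(n_chains)
        self.beads_per_chain = int(beads_per_chain)
        n, g = self.n_chains, self.beads_per_chain
        self.chain_index = np.repeat(np.arange(n), g)
        base = np.arange(n)[:, None] * g
        if g >= 2:
            first = np.arange(g - 1)
            self.bonds = np.column_stack([
                (base + first).ravel(), (base + first + 1).ravel()])
        else:
            self.bonds = np.empty((0, 2), dtype=int)
        if g >= 3:
            first = np.arange(g - 2)
            self.angles = np.column_stack([
                (base + first).ravel(), (base + first + 1).ravel(),
                (base + first + 2).ravel()])
        else:
            self.angles = np.empty((0, 3), dtype=int)

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.beads_per_chain

    @property
    def bond_counts(self) -> np.ndarray:
        """Number of bonds attached to each bead (N_b, 1 at ends, 2 inside)."""
        counts = np.zeros(self.n_beads, dtype=int)
        np.add.at(counts, self.bonds.ravel(), 1)
        return counts

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, ChainTopology)
                and self.n_chains == other.n_chains
                and self.beads_per_chain == other.beads_per_chain)


@dataclass
class SystemState:
    """Positions/velocities of all beads plus topology, box and clock.

    Positions are wrapped into the cubic periodic box [0, box_nm) per
    coordinate; velocities live at the leapfrog half-step.
    """

    positions: np.ndarray        # (N, 3) nm
    velocities: np.ndarray       # (N, 3) nm/ps
    topology: ChainTopology
    box_nm: float
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        n = self.topology.n_beads
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise DomainError(
                f"positions/velocities must have shape ({n}, 3); got "
                f"{self.positions.shape} and {self.velocities.shape}")
        if self.box_nm <= 0:
            raise DomainError(f"box length must be > 0, got {self.box_nm}")

    @property
    def n_beads(self) -> int:
        return self.topology.n_beads

    @property
    def box_volume_nm3(self) -> float:
        return self.box_nm**3

    def wrap(self) -> None:
        """Wrap positions into [0, box) in place."""
        np.mod(self.positions, self.box_nm, out=self.positions)
        # guard against x == box after rounding
        self.positions[self.positions >= self.box_nm] = 0.0

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.topology, self.box_nm, self.time_ps)


def minimum_image(dr: np.ndarray, box_nm: float) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return dr - box_nm * np.round(dr / box_nm)
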