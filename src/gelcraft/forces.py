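"""Force terms acting on the bead-spring system.

Four contributions drive the dynamics: Hookean bond stretching, linear-elastic
bond bending, a truncated 12-6 Lennard-Jones interaction between non-bonded
beads, and the Langevin (drag + fluctuating) force of the implicit solvent.
The first three are deterministic pairwise/triplet terms that obey Newton's
third law; the Langevin term is handled separately by the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core_model import (DomainError, ForceField, SolventSpec, SystemState,
                         UNITS, minimum_image)

__all__ = [
    "ForceAccumulator",
    "NeighborList",
    "build_neighbor_list",
    "bond_force",
    "bending_forces",
    "lj_force",
    "lj_potential",
    "bond_potential",
    "bending_potential",
    "langevin_force",
    "evaluate_forces",
]

DETERMINISTIC_TERMS = ("bond", "bending", "lj")


class SingularGeometryError(ValueError):
    """Coincident beads or degenerate bonds make a force direction undefined."""


class ConfigurationError(ValueError):
    pass


@dataclass
class ForceAccumulator:
    """Per-bead force vectors plus per-term magnitude diagnostics."""

    forces: np.ndarray                       # (N, 3) internal force units
    term_norms: dict = field(default_factory=dict)  # term -> sum of |F|

    @classmethod
    def zeros(cls, n_beads: int) -> "ForceAccumulator":
        return cls(np.zeros((n_beads, 3)))


# ---------------------------------------------------------------------------
# Neighbor list
# ---------------------------------------------------------------------------

@dataclass
class NeighborList:
    """Candidate non-bonded pairs within cutoff + skin under periodic images.

    Built with a periodic k-d tree; directly bonded (1-2) pairs are excluded.
    The list stays valid until some bead has moved more than skin/2 since the
    last build.
    """

    pairs: np.ndarray            # (M, 2) int, i < j
    cutoff_nm: float
    skin_nm: float
    box_nm: float
    reference_positions: np.ndarray

    def needs_rebuild(self, state: SystemState) -> bool:
        disp = minimum_image(state.positions - self.reference_positions,
                             state.box_nm)
        max_sq = float(np.max(np.einsum("ij,ij->i", disp, disp))) if len(disp) else 0.0
        return max_sq > (0.5 * self.skin_nm) ** 2


def _pair_keys(pairs: np.ndarray, n: int) -> np.ndarray:
    lo = np.minimum(pairs[:, 0], pairs[:, 1])
    hi = np.maximum(pairs[:, 0], pairs[:, 1])
    return lo.astype(np.int64) * n + hi


def build_neighbor_list(state: SystemState, cutoff_nm: float,
                        skin_nm: float = 0.3) -> NeighborList:
    """Build the candidate pair list at cutoff + skin, excluding bonded pairs."""
    reach = cutoff_nm + skin_nm
    if reach >= state.box_nm / 2:
        raise ConfigurationError(
            f"cutoff + skin = {reach} nm must be < box/2 = {state.box_nm / 2} nm "
            "for the minimum-image convention to hold")
    pos = np.mod(state.positions, state.box_nm)
    pos[pos >= state.box_nm] = 0.0
    tree = cKDTree(pos, boxsize=state.box_nm)
    pairs = tree.query_pairs(reach, output_type="ndarray")
    if len(pairs) and len(state.topology.bonds):
        n = state.n_beads
        excluded = np.isin(_pair_keys(pairs, n),
                           _pair_keys(state.topology.bonds, n))
        pairs = pairs[~excluded]
    return NeighborList(pairs=np.asarray(pairs, dtype=int).reshape(-1, 2),
                        cutoff_nm=cutoff_nm, skin_nm=skin_nm,
                        box_nm=state.box_nm,
                        reference_positions=state.positions.copy())


# ---------------------------------------------------------------------------
# Bond stretching
# ---------------------------------------------------------------------------

def _bond_term(positions: np.ndarray, bonds: np.ndarray, ff: ForceField,
               box_nm: float):
    """Vectorised Hookean bond forces; returns (force_on_a, force_on_b, dr, d)."""
    dr = minimum_image(positions[bonds[:, 1]] - positions[bonds[:, 0]], box_nm)
    d = np.sqrt(np.einsum("ij,ij->i", dr, dr))
    if not d.all():
        raise SingularGeometryError("coincident bonded beads: bond direction undefined")
    # stretched bond (d > l_eq): force on a points toward b (+dr)
    scalar = ff.k_bond * (d - ff.l_eq_nm)
    f_a = scalar[:, None] * dr / d[:, None]
    return f_a, -f_a, dr, d


def bond_force(pos_a: np.ndarray, pos_b: np.ndarray, ff: ForceField,
               box_nm: float):
    """Hookean restoring force on one bonded pair → (force_on_a, force_on_b)."""
    bonds = np.array([[0, 1]])
    f_a, f_b, _, _ = _bond_term(np.array([pos_a, pos_b], dtype=float),
                                bonds, ff, box_nm)
    return f_a[0], f_b[0]


def bond_potential(d: float | np.ndarray, ff: ForceField):
    """Harmonic bond energy ½ k (d − l_eq)² (internal units)."""
    return 0.5 * ff.k_bond * (np.asarray(d, dtype=float) - ff.l_eq_nm) ** 2


# ---------------------------------------------------------------------------
# Bond bending
# ---------------------------------------------------------------------------

def _bending_term(positions: np.ndarray, angles: np.ndarray, ff: ForceField,
                  box_nm: float):
    """Forces from the linear-elastic bending torque τ = k_bend·α.

    α is the deviation from collinearity: a straight chain has α = 0 and zero
    torque.  The force on each terminal bead is perpendicular to its bond with
    magnitude τ/l_bond; the central bead carries the balancing counter-force,
    so each triplet exerts zero net force and zero net torque.
    """
    r_ab = minimum_image(positions[angles[:, 0]] - positions[angles[:, 1]], box_nm)
    r_cb = minimum_image(positions[angles[:, 2]] - positions[angles[:, 1]], box_nm)
    l1 = np.sqrt(np.einsum("ij,ij->i", r_ab, r_ab))
    l2 = np.sqrt(np.einsum("ij,ij->i", r_cb, r_cb))
    if not (l1.all() and l2.all()):
        raise SingularGeometryError("degenerate bond in angle triplet")
    e1 = r_ab / l1[:, None]
    e2 = r_cb / l2[:, None]
    cos_t = np.clip(np.einsum("ij,ij->i", e1, e2), -1.0, 1.0)
    theta = np.arccos(cos_t)          # a-b-c angle; straight chain: theta = pi
    alpha = np.pi - theta             # bending deviation from collinearity
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
    # F_a = k·alpha · (e1 cosθ − e2) / (l1 sinθ); |(e1 cosθ − e2)| = sinθ,
    # so |F_a| = k·alpha/l1 (torque over lever arm).  alpha/sinθ → 1 as α → 0.
    with np.errstate(invalid="ignore", divide="ignore"):
        coeff = np.where(sin_t > 1e-12, ff.k_bend * alpha / np.maximum(sin_t, 1e-300), 0.0)
    f_a = coeff[:, None] * (e1 * cos_t[:, None] - e2) / l1[:, None]
    f_c = coeff[:, None] * (e2 * cos_t[:, None] - e1) / l2[:, None]
    f_b = -(f_a + f_c)
    return f_a, f_b, f_c


def bending_forces(pos_a: np.ndarray, pos_b: np.ndarray, pos_c: np.ndarray,
                   ff: ForceField, box_nm: float):
    """Bending forces on one consecutive triplet → (f_a, f_b, f_c)."""
    tri = np.array([[0, 1, 2]])
    f_a, f_b, f_c = _bending_term(
        np.array([pos_a, pos_b, pos_c], dtype=float), tri, ff, box_nm)
    return f_a[0], f_b[0], f_c[0]


def bending_potential(pos_a, pos_b, pos_c, ff: ForceField, box_nm: float) -> float:
    """Bending energy ½ k_bend α² of one triplet (internal units)."""
    r_ab = minimum_image(np.asarray(pos_a, float) - pos_b, box_nm)
    r_cb = minimum_image(np.asarray(pos_c, float) - pos_b, box_nm)
    cos_t = np.dot(r_ab, r_cb) / (np.linalg.norm(r_ab) * np.linalg.norm(r_cb))
    alpha = np.pi - np.arccos(np.clip(cos_t, -1.0, 1.0))
    return 0.5 * ff.k_bend * alpha**2


# ---------------------------------------------------------------------------
# Lennard-Jones interaction
# ---------------------------------------------------------------------------

def lj_potential(d, ff: ForceField):
    """12-6 LJ energy with minimum −ε at d_eq, truncated at the cutoff."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise DomainError("LJ distance must be > 0")
    x6 = (ff.d_eq_nm / d) ** 6
    u = ff.epsilon * (x6 * x6 - 2.0 * x6)
    return np.where(d <= ff.cutoff_nm, u, 0.0)


def lj_force(d, ff: ForceField):
    """Signed scalar LJ force along the centre line (positive = repulsive).

    F(d) = 12 ε/d · [(d_eq/d)¹² − (d_eq/d)⁶]; zero beyond the cutoff.  With
    ``repulsive_only`` the attractive branch is clamped to zero.
    """
    scalar_input = np.isscalar(d)
    d = np.atleast_1d(np.asarray(d, dtype=float))
    if np.any(d <= 0):
        raise DomainError("LJ distance must be > 0")
    x6 = (ff.d_eq_nm / d) ** 6
    f = 12.0 * ff.epsilon / d * (x6 * x6 - x6)
    f = np.where(d <= ff.cutoff_nm, f, 0.0)
    if ff.repulsive_only:
        f = np.maximum(f, 0.0)
    return float(f[0]) if scalar_input else f


# ---------------------------------------------------------------------------
# Langevin (diffusion) force
# ---------------------------------------------------------------------------

def langevin_force(velocity: np.ndarray, drag: float, solvent: SolventSpec,
                   dt_ps: float, rng_draw: np.ndarray,
                   temperature_k: float | None = None) -> np.ndarray:
    """Per-component Langevin force −c·v + ξ·sqrt(2 c k_B T / Δt).

    ``rng_draw`` supplies standard-normal variates ξ, one per degree of
    freedom.  The temperature defaults to the solvent temperature but can be
    overridden by an annealing schedule.
    """
    if dt_ps <= 0:
        raise DomainError(f"time step must be > 0, got {dt_ps}")
    if drag <= 0:
        raise DomainError(f"drag coefficient must be > 0, got {drag}")
    t = solvent.temperature_k if temperature_k is None else temperature_k
    amplitude = np.sqrt(2.0 * drag * UNITS.boltzmann * t / dt_ps)
    return -drag * np.asarray(velocity, dtype=float) + amplitude * np.asarray(rng_draw, dtype=float)


# ---------------------------------------------------------------------------
# Full force evaluation
# ---------------------------------------------------------------------------

def _scatter_add(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    n = out.shape[0]
    for k in range(3):
        out[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


def evaluate_forces(state: SystemState, ff: ForceField, nlist: NeighborList | None,
                    terms=DETERMINISTIC_TERMS,
                    diagnostics: bool = False) -> ForceAccumulator:
    """Evaluate the requested deterministic force terms on the whole system.

    ``terms`` is any subset of {"bond", "bending", "lj"}; the Langevin term is
    applied inside the integrator, not here.  With ``diagnostics`` the summed
    force magnitude per term is recorded in ``term_norms``.
    """
    acc = ForceAccumulator.zeros(state.n_beads)
    pos = state.positions
    box = state.box_nm
    topo = state.topology
    if "bond" in terms and len(topo.bonds):
        f_a, f_b, _, _ = _bond_term(pos, topo.bonds, ff, box)
        _scatter_add(acc.forces, topo.bonds[:, 0], f_a)
        _scatter_add(acc.forces, topo.bonds[:, 1], f_b)
        if diagnostics:
            acc.term_norms["bond"] = float(np.linalg.norm(f_a, axis=1).sum() * 2)
    if "bending" in terms and len(topo.angles):
        f_a, f_b, f_c = _bending_term(pos, topo.angles, ff, box)
        _scatter_add(acc.forces, topo.angles[:, 0], f_a)
        _scatter_add(acc.forces, topo.angles[:, 1], f_b)
        _scatter_add(acc.forces, topo.angles[:, 2], f_c)
        if diagnostics:
            acc.term_norms["bending"] = float(
                np.linalg.norm(f_a, axis=1).sum() + np.linalg.norm(f_b, axis=1).sum()
                + np.linalg.norm(f_c, axis=1).sum())
    if "lj" in terms and nlist is not None and len(nlist.pairs):
        i, j = nlist.pairs[:, 0], nlist.pairs[:, 1]
        dr = pos[i] - pos[j]
        dr -= box * np.round(dr / box)
        d2 = np.einsum("ij,ij->i", dr, dr)
        within = d2 <= ff.cutoff_nm * ff.cutoff_nm
        if np.any(within):
            i, j, dr = i[within], j[within], dr[within]
            d = np.sqrt(d2[within])
            x6 = (ff.d_eq_nm / d) ** 6
            f = 12.0 * ff.epsilon / d * (x6 * x6 - x6)
            if ff.repulsive_only:
                np.maximum(f, 0.0, out=f)
            fvec = (f / d)[:, None] * dr
            _scatter_add(acc.forces, i, fvec)
            _scatter_add(acc.forces, j, -fvec)
            if diagnostics:
                acc.term_norms["lj"] = float(np.linalg.norm(fvec, axis=1).sum() * 2)
        elif diagnostics:
            acc.term_norms["lj"] = 0.0
    return acc
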