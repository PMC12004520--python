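"""Configuration files, snapshot/trajectory I/O, checkpoints and fixtures.

Configuration is a YAML file with SI values and explicit unit suffixes in the
key names; everything is converted to internal units on load.  Snapshots are
extended-XYZ text files (readable by common molecular viewers) written at full
float precision, with a JSON sidecar carrying the box, clock and topology so a
round trip is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core_model import (BeadSpec, ChainTopology, DomainError, ForceField,
                         SolventSpec, SystemState)
from .integrator import AnnealingSchedule, IntegratorSettings
from .protocol import PipelineConfig, StageSpec, default_stages

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "write_snapshot",
    "read_snapshot",
    "save_checkpoint",
    "load_checkpoint",
    "make_fixture",
    "RunManifest",
]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


_KNOWN_SECTIONS = {"bead", "forcefield", "solvents", "box", "chains",
                   "integrator", "stages", "drying", "seed", "log_stride"}

# Defaults are the published system: glucose beads of 0.4615 nm / 162.14 g/mol,
# bond stiffness 1.18479 N/m, cutoff 1.5 nm, dt 0.04 ps, 100 nm box with
# 764 chains x 360 beads in 0.03 Pa*s NaOH-urea solvent at 300 K.
# rho_sol = 1.058 g/cm3 is NOT printed in the source material; it is
# back-derived so that the chain-count relation reproduces n_c = 764 at
# w_c = 0.07, and is flagged as an assumption.
_DEFAULTS = {
    "bead": {"diameter_nm": 0.4615, "molar_mass_g_mol": 162.14},
    "forcefield": {
        "bond_stiffness_n_m": 1.18479,
        "bond_length_nm": 0.4615,
        "bending_stiffness_n_m_rad": 1.15375e-19,
        "lj_epsilon_kj_mol": 30.0,
        "lj_d_eq_nm": 0.4,
        "cutoff_nm": 1.5,
        "interaction_distance_nm": 1.5,
    },
    "solvents": {
        "naoh_urea": {"viscosity_pa_s": 0.03, "temperature_k": 300.0},
        "water": {"viscosity_pa_s": 0.00089, "temperature_k": 300.0},
        "ethanol": {"viscosity_pa_s": 0.001074, "temperature_k": 300.0},
    },
    "box": {"length_nm": 100.0},
    "chains": {"mass_fraction": 0.07, "solution_density_g_cm3": 1.058,
               "degree_of_polymerization": 180},
    "integrator": {"dt_ps": 0.04, "skin_nm": 0.3},
    "drying": {"volumetric_shrinkage": 0.395},
    "stages": None,      # "paper" | "mini" | explicit stage list
    "seed": 0,
    "log_stride": 250,
}


def _merge(defaults, overrides, problems, path=""):
    merged = {}
    overrides = overrides or {}
    for key, default in defaults.items():
        if isinstance(default, dict) and not path.startswith("solvents"):
            merged[key] = _merge(default, overrides.get(key), problems,
                                 f"{path}{key}.")
        else:
            merged[key] = overrides.get(key, default)
    for key in overrides:
        if key not in defaults:
            problems.append(f"unknown key {path}{key!r}")
    return merged


def _stages_from_raw(raw_stages, problems) -> list[StageSpec]:
    if raw_stages is None:
        return default_stages("paper")
    if isinstance(raw_stages, str):
        try:
            return default_stages(raw_stages)
        except DomainError as exc:
            problems.append(str(exc))
            return []
    stages = []
    for entry in raw_stages:
        try:
            ann = entry.get("annealing")
            schedule = (AnnealingSchedule(ann["t_max_k"], ann["t_eq_k"],
                                          ann["ramp_ps"]) if ann else None)
            stages.append(StageSpec(
                name=entry["name"],
                duration_ps=float(entry["duration_ps"]),
                solvent=entry.get("solvent", "naoh_urea"),
                lj_mode=entry.get("lj_mode", "off"),
                diffusion=bool(entry.get("diffusion", True)),
                annealing=schedule))
        except (KeyError, DomainError, TypeError, ValueError) as exc:
            problems.append(f"stage entry {entry!r}: {exc}")
    return stages


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML configuration; empty file → full defaults.

    Validation collects *all* violations before raising a single ConfigError.
    """
    from .core_model import (derive_chain_count, derive_monomer_mass,
                             derive_repeat_units)
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError([f"top level must be a mapping, got {type(raw).__name__}"])
    problems: list[str] = []
    merged = _merge(_DEFAULTS, raw, problems)
    raw_stages = raw.get("stages")

    cfg = None
    try:
        bead = BeadSpec(diameter_nm=float(merged["bead"]["diameter_nm"]),
                        mass_amu=float(merged["bead"]["molar_mass_g_mol"]))
    except (DomainError, ValueError, TypeError) as exc:
        problems.append(f"bead: {exc}")
        bead = BeadSpec()
    f = merged["forcefield"]
    try:
        ff = ForceField.from_si(
            bond_stiffness_n_m=float(f["bond_stiffness_n_m"]),
            bond_length_nm=float(f["bond_length_nm"]),
            bending_stiffness_n_m_rad=float(f["bending_stiffness_n_m_rad"]),
            epsilon_kj_mol=float(f["lj_epsilon_kj_mol"]),
            d_eq_nm=float(f["lj_d_eq_nm"]),
            cutoff_nm=float(f["cutoff_nm"]),
            d_int_nm=float(f["interaction_distance_nm"]))
    except (DomainError, ValueError, TypeError) as exc:
        problems.append(f"forcefield: {exc}")
        ff = None
    solvents = {}
    for name, spec in merged["solvents"].items():
        try:
            solvents[name] = SolventSpec(
                name, float(spec["viscosity_pa_s"]),
                float(spec.get("temperature_k", 300.0)))
        except (DomainError, ValueError, TypeError, KeyError, AttributeError) as exc:
            problems.append(f"solvent {name!r}: {exc}")
    try:
        settings = IntegratorSettings(
            dt_ps=float(merged["integrator"]["dt_ps"]),
            seed=int(merged["seed"]),
            skin_nm=float(merged["integrator"]["skin_nm"]))
    except (DomainError, ValueError, TypeError) as exc:
        problems.append(f"integrator: {exc}")
        settings = IntegratorSettings()
    stages = _stages_from_raw(raw_stages, problems)
    for stage in stages:
        if stage.solvent not in solvents:
            problems.append(f"stage {stage.name!r} references unknown solvent "
                            f"{stage.solvent!r}")
    box_nm = float(merged["box"]["length_nm"])
    if box_nm <= 0:
        problems.append(f"box length must be > 0, got {box_nm}")
    shrink = float(merged["drying"]["volumetric_shrinkage"])
    if not 0 <= shrink < 1:
        problems.append(f"volumetric shrinkage must be in [0, 1), got {shrink}")

    chains = merged["chains"]
    try:
        n_g = derive_repeat_units(chains["degree_of_polymerization"])
        m_g = derive_monomer_mass(bead.mass_amu)     # amu numerically = g/mol
        n_c = derive_chain_count(float(chains["mass_fraction"]),
                                 float(chains["solution_density_g_cm3"]),
                                 (box_nm * 1e-7) ** 3,   # nm³ → cm³
                                 n_g, m_g)
    except (DomainError, ValueError, TypeError, KeyError) as exc:
        problems.append(f"chains: {exc}")
        n_g, n_c = 360, 764
    if problems:
        raise ConfigError(problems)
    return PipelineConfig(bead=bead, forcefield=ff, solvents=solvents,
                          box_nm=box_nm, n_chains=n_c, beads_per_chain=n_g,
                          stages=stages, integrator=settings,
                          drying_shrinkage=shrink, seed=settings.seed,
                          log_stride=int(merged["log_stride"]))


def save_config(config_dict: dict, path) -> None:
    """Write a raw configuration mapping back to YAML."""
    Path(path).write_text(yaml.safe_dump(config_dict, sort_keys=False))


# ---------------------------------------------------------------------------
# Snapshots (extended XYZ + JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_snapshot(state: SystemState, path, species: str = "C") -> None:
    """Write an extended-XYZ snapshot plus a JSON metadata sidecar.

    Positions are printed with 17 significant digits, which round-trips IEEE
    doubles exactly; the sidecar stores box, time, topology and velocities.
    """
    path = Path(path)
    lines = [str(state.n_beads),
             f'Lattice="{state.box_nm} 0.0 0.0 0.0 {state.box_nm} 0.0 0.0 0.0 '
             f'{state.box_nm}" Properties=species:S:1:pos:R:3:chain:I:1 '
             f'Time={state.time_ps}']
    chain = state.topology.chain_index
    for (x, y, z), c in zip(state.positions, chain):
        lines.append(f"{species} {x:.17g} {y:.17g} {z:.17g} {c}")
    path.write_text("\n".join(lines) + "\n")
    meta = {
        "box_nm": state.box_nm,
        "time_ps": state.time_ps,
        "n_chains": state.topology.n_chains,
        "beads_per_chain": state.topology.beads_per_chain,
        "velocities_nm_ps": state.velocities.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_snapshot(path) -> SystemState:
    """Read an extended-XYZ snapshot written by :func:`write_snapshot`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        n = int(lines[0])
    except (IndexError, ValueError) as exc:
        raise DomainError(f"{path}:1: expected the atom count, got "
                          f"{lines[0] if lines else '<empty>'!r}") from exc
    meta = json.loads(_sidecar_path(path).read_text())
    positions = np.empty((n, 3))
    for k in range(n):
        lineno = k + 3
        try:
            parts = lines[k + 2].split()
            positions[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        except (IndexError, ValueError) as exc:
            raise DomainError(f"{path}:{lineno}: malformed atom record") from exc
    topo = ChainTopology(meta["n_chains"], meta["beads_per_chain"])
    velocities = np.asarray(meta["velocities_nm_ps"], dtype=float)
    return SystemState(positions, velocities, topo, meta["box_nm"],
                       meta["time_ps"])


# ---------------------------------------------------------------------------
# Checkpoints (HDF5)
# ---------------------------------------------------------------------------

def save_checkpoint(state: SystemState, path) -> None:
    import h5py
    with h5py.File(path, "w") as fh:
        fh.create_dataset("positions", data=state.positions)
        fh.create_dataset("velocities", data=state.velocities)
        fh.attrs["box_nm"] = state.box_nm
        fh.attrs["time_ps"] = state.time_ps
        fh.attrs["n_chains"] = state.topology.n_chains
        fh.attrs["beads_per_chain"] = state.topology.beads_per_chain


def load_checkpoint(path) -> SystemState:
    import h5py
    with h5py.File(path, "r") as fh:
        topo = ChainTopology(int(fh.attrs["n_chains"]),
                             int(fh.attrs["beads_per_chain"]))
        return SystemState(fh["positions"][...], fh["velocities"][...], topo,
                           float(fh.attrs["box_nm"]), float(fh.attrs["time_ps"]))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("single_chain", "parallel_pair", "mini_gel", "sphere_pack_phantom")


def make_fixture(kind: str, seed: int = 0, **kwargs) -> SystemState:
    """Deterministic small systems shared across tests and examples.

    single_chain        one straight 3-bead chain at 0.4615 nm spacing
    parallel_pair       two parallel 3-bead chains 0.5 nm apart (9 inter-chain
                        contacts at d_int = 1.5 nm)
    mini_gel            freshly generated mini-preset system (10 × 20 beads,
                        9 nm box)
    sphere_pack_phantom 8 well-separated 4 nm spheres on a staggered grid in a
                        20 nm box: analytic solid fraction 8·(π/6)·4³/20³
    """
    l_b = kwargs.get("bond_length_nm", 0.4615)
    if kind == "single_chain":
        n = kwargs.get("n_beads", 3)
        topo = ChainTopology(1, n)
        pos = np.zeros((n, 3))
        pos[:, 0] = 5.0 + np.arange(n) * l_b
        return SystemState(pos, np.zeros_like(pos), topo,
                           kwargs.get("box_nm", 20.0))
    if kind == "parallel_pair":
        topo = ChainTopology(2, 3)
        pos = np.zeros((6, 3))
        pos[:3, 0] = 5.0 + np.arange(3) * l_b
        pos[3:, 0] = 5.0 + np.arange(3) * l_b
        pos[3:, 1] = 0.5
        pos[:, 1] += 5.0
        pos[:, 2] += 5.0
        return SystemState(pos, np.zeros_like(pos), topo,
                           kwargs.get("box_nm", 20.0))
    if kind == "mini_gel":
        from .protocol import generate_chains
        return generate_chains(10, 20, l_b, 9.0, seed)
    if kind == "sphere_pack_phantom":
        centers = np.array([[x, y, z] for x in (5.0, 15.0)
                            for y in (5.0, 15.0) for z in (5.0, 15.0)])
        rng = np.random.default_rng(seed)
        centers = centers + rng.uniform(-0.5, 0.5, size=centers.shape)
        topo = ChainTopology(8, 1)
        return SystemState(centers, np.zeros_like(centers), topo, 20.0)
    raise DomainError(f"unknown fixture kind {kind!r}; "
                      f"choose from {FIXTURE_KINDS}")


#: analytic solid fraction of the sphere_pack_phantom at 4 nm sphere diameter
SPHERE_PACK_DIAMETER_NM = 4.0
SPHERE_PACK_SOLID_FRACTION = 8 * (np.pi / 6.0) * SPHERE_PACK_DIAMETER_NM**3 / 20.0**3


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record emitted by every CLI run."""

    config_hash: str
    seed: int
    version: str
    stages: list
    outputs: list = field(default_factory=list)
    created: str = ""

    @classmethod
    def create(cls, config_text: str, seed: int, stages) -> "RunManifest":
        digest = hashlib.sha256(config_text.encode()).hexdigest()[:16]
        stage_list = [{"name": s.name, "duration_ps": s.duration_ps}
                      for s in stages]
        return cls(config_hash=digest, seed=seed, version=__version__,
                   stages=stage_list,
                   created=_time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:
            raise RuntimeError(f"manifest lists missing outputs: {missing}")
        Path(path).write_text(json.dumps(asdict(self), indent=2))
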