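"""Microstructure characterization of gel and aerogel states.

Covers gelation kinetics (inter-chain interaction counts, coordination
numbers), voxelization of the bead system into a 3D binary image, porosity
from the image or from measured skeletal/envelope densities, SNOW-style
pore-network extraction (distance transform + marker watershed), and the
moving-window pore-size-distribution machinery used to compare simulated
networks with discrete experimental (BJH-type) pore-size tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .core_model import DomainError, SystemState
from .forces import ConfigurationError
from .integrator import KineticsLog

__all__ = [
    "BinaryImage",
    "PoreNetwork",
    "PoreSizeDistribution",
    "count_interactions",
    "normalize_kinetics",
    "aggregation_onset_time",
    "voxelize",
    "porosity_image",
    "porosity_from_densities",
    "extract_pore_network",
    "psd_from_network",
    "experimental_psd_to_counts",
    "read_experimental_psd",
]


class NotGelledWarning(UserWarning):
    """The kinetics series ends at zero interactions: no network formed."""


class EmptyNetworkError(ValueError):
    """An all-solid image contains no pore space to extract a network from."""


# ---------------------------------------------------------------------------
# Gelation kinetics
# ---------------------------------------------------------------------------

def count_interactions(state: SystemState, d_int_nm: float):
    """Count inter-chain bead pairs within the interaction distance.

    Returns ``(I, coordination)`` where I is the number of unordered pairs of
    beads from *different* chains at minimum-image distance <= d_int, and
    ``coordination[i]`` is the number of inter-chain partners of bead i.
    """
    if d_int_nm > state.box_nm / 2:
        raise ConfigurationError(
            f"d_int = {d_int_nm} nm exceeds box/2 = {state.box_nm / 2} nm")
    pos = np.mod(state.positions, state.box_nm)
    pos[pos >= state.box_nm] = 0.0
    tree = cKDTree(pos, boxsize=state.box_nm)
    pairs = tree.query_pairs(d_int_nm, output_type="ndarray")
    coordination = np.zeros(state.n_beads, dtype=int)
    if len(pairs) == 0:
        return 0, coordination
    chain = state.topology.chain_index
    inter = chain[pairs[:, 0]] != chain[pairs[:, 1]]
    pairs = pairs[inter]
    np.add.at(coordination, pairs.ravel(), 1)
    return int(len(pairs)), coordination


def normalize_kinetics(log: KineticsLog | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Normalize an interaction time series by its final value I_max.

    I_max is the interaction count at the *end* of the series (the end of the
    gelation stage), not the running maximum.  A series ending at zero is
    flagged as not gelled and returned unnormalized.
    """
    if isinstance(log, KineticsLog):
        series = np.asarray(log.interactions, dtype=float)
    elif isinstance(log, pd.DataFrame):
        series = log["interactions"].to_numpy(dtype=float)
    else:
        series = np.asarray(log, dtype=float)
    if series.size == 0:
        raise DomainError("empty kinetics series")
    i_max = series[-1]
    if i_max == 0:
        warnings.warn("final interaction count is zero: system not gelled; "
                      "returning the unnormalized series", NotGelledWarning)
        return series
    return series / i_max


def aggregation_onset_time(log: KineticsLog, growth_factor: float = 1.25) -> float:
    """Desk-scale aggregation onset: time for I(t) to grow past a threshold.

    At small system sizes the gelation stage starts from a non-negligible
    population of random inter-chain contacts, so a level on I/I_max alone
    does not separate aggregating from non-aggregating systems.  The onset is
    therefore defined as the first (linearly interpolated) time at which the
    interaction count exceeds ``growth_factor`` times its initial value — a
    run whose contacts never grow beyond statistical fluctuation is censored
    at the stage duration (onset = end time, i.e. "no onset observed").
    """
    if growth_factor <= 1.0:
        raise DomainError("growth factor must exceed 1")
    t = np.asarray(log.time_ps, dtype=float)
    series = np.asarray(log.interactions, dtype=float)
    if series.size == 0:
        raise DomainError("empty kinetics series")
    threshold = growth_factor * max(series[0], 1.0)
    above = np.nonzero(series >= threshold)[0]
    if len(above) == 0:
        return float(t[-1])
    k = above[0]
    if k == 0:
        return float(t[0])
    frac = (threshold - series[k - 1]) / (series[k] - series[k - 1])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


# ---------------------------------------------------------------------------
# Voxelization and porosity
# ---------------------------------------------------------------------------

@dataclass
class BinaryImage:
    """Periodic 3D binary image: True = solid, False = pore."""

    grid: np.ndarray             # (nx, ny, nz) bool
    voxel_nm: float
    origin_nm: tuple = (0.0, 0.0, 0.0)

    @property
    def n_total(self) -> int:
        return int(self.grid.size)

    @property
    def n_pore(self) -> int:
        return int(self.grid.size - np.count_nonzero(self.grid))

    def save_npy(self, path) -> None:
        np.save(path, self.grid)

    def save_tiff(self, path) -> None:
        """Multi-page 8-bit TIFF (one page per z-slice; solid = 255)."""
        import tifffile
        tifffile.imwrite(path, (self.grid.astype(np.uint8) * 255))


def voxelize(state: SystemState, voxel_nm: float, bead_diameter_nm: float) -> BinaryImage:
    """Voxelize the bead system on a regular grid spanning the periodic box.

    A voxel is solid iff its center lies within one bead radius of any bead
    center under the minimum-image convention.
    """
    if voxel_nm <= 0:
        raise DomainError(f"voxel size must be > 0, got {voxel_nm}")
    if voxel_nm >= state.box_nm:
        raise ConfigurationError(
            f"voxel size {voxel_nm} nm must be smaller than the box "
            f"{state.box_nm} nm")
    box = state.box_nm
    n = int(np.ceil(box / voxel_nm))
    grid = np.zeros((n, n, n), dtype=bool)
    if state.n_beads == 0:
        return BinaryImage(grid, voxel_nm)
    radius = bead_diameter_nm / 2.0
    reach = int(np.floor(radius / voxel_nm)) + 1
    offsets = np.arange(-reach, reach + 1)
    ox, oy, oz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    stamp = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    centers = (np.arange(n) + 0.5) * voxel_nm
    pos = np.mod(state.positions, box)
    # nearest voxel index per bead along each axis
    base = np.round(pos / voxel_nm - 0.5).astype(int)
    for bead_pos, bead_idx in zip(pos, base):
        cells = bead_idx + stamp                        # may run off the grid
        cell_centers = (cells + 0.5) * voxel_nm
        d = cell_centers - bead_pos
        d -= box * np.round(d / box)
        inside = np.einsum("ij,ij->i", d, d) <= radius**2
        if np.any(inside):
            wrapped = np.mod(cells[inside], n)
            grid[wrapped[:, 0], wrapped[:, 1], wrapped[:, 2]] = True
    return BinaryImage(grid, voxel_nm)


def porosity_image(img: BinaryImage) -> float:
    """Porosity in percent: 100 · pore voxels / total voxels."""
    if img.n_total == 0:
        raise DomainError("empty image")
    return 100.0 * img.n_pore / img.n_total


def porosity_from_densities(rho_s: float, rho_e: float) -> float:
    """Porosity (%) from skeletal and envelope densities: 100·(1 − ρ_e/ρ_s)."""
    if rho_s <= 0 or rho_e <= 0:
        raise DomainError("densities must be > 0")
    if rho_e > rho_s:
        raise DomainError("envelope density cannot exceed skeletal density")
    return 100.0 * (1.0 - rho_e / rho_s)


# ---------------------------------------------------------------------------
# Pore-network extraction (SNOW-style)
# ---------------------------------------------------------------------------

@dataclass
class PoreNetwork:
    """Spherical pores connected by cylindrical throats.

    pore_centers_nm : (P, 3) location of each pore's maximal inscribed sphere
    pore_diameters_nm : (P,) 2 × the peak distance-transform value
    pore_volumes_nm3 : (P,) watershed-region voxel volume
    throats : (T, 2) indices of connected pore pairs
    throat_diameters_nm : (T,)
    """

    pore_centers_nm: np.ndarray
    pore_diameters_nm: np.ndarray
    pore_volumes_nm3: np.ndarray
    throats: np.ndarray
    throat_diameters_nm: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.pore_diameters_nm <= 0):
            raise DomainError("pore diameters must be > 0")
        if len(self.throats):
            t = np.asarray(self.throats)
            if np.any(t[:, 0] == t[:, 1]) or t.max() >= self.n_pores or t.min() < 0:
                raise DomainError("throats must reference two distinct existing pores")

    @property
    def n_pores(self) -> int:
        return int(len(self.pore_diameters_nm))

    @property
    def mean_pore_width_nm(self) -> float:
        """Count-weighted mean pore diameter d̄_P."""
        return float(np.mean(self.pore_diameters_nm))

    @property
    def total_sphere_volume_nm3(self) -> float:
        """Total pore volume under the spherical-pore assumption."""
        return float(np.sum(np.pi / 6.0 * self.pore_diameters_nm**3))

    def pores_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(self.n_pores),
            "x": self.pore_centers_nm[:, 0],
            "y": self.pore_centers_nm[:, 1],
            "z": self.pore_centers_nm[:, 2],
            "diameter_nm": self.pore_diameters_nm,
            "volume_nm3": self.pore_volumes_nm3,
        })

    def throats_dataframe(self) -> pd.DataFrame:
        t = np.asarray(self.throats).reshape(-1, 2)
        return pd.DataFrame({
            "pore_a": t[:, 0].astype(int) if len(t) else np.array([], int),
            "pore_b": t[:, 1].astype(int) if len(t) else np.array([], int),
            "diameter_nm": self.throat_diameters_nm,
        })

    def to_csv(self, pores_path, throats_path) -> None:
        self.pores_dataframe().to_csv(pores_path, index=False)
        self.throats_dataframe().to_csv(throats_path, index=False)


def _periodic_edt(pore: np.ndarray, periodic: bool) -> np.ndarray:
    """Euclidean distance transform of the pore phase (voxel units).

    Periodic boundaries are handled by tiling the image with wrapped margins
    and cropping back (tile-and-crop): distances near faces then see the
    periodic continuation of the structure.
    """
    if not periodic:
        return ndimage.distance_transform_edt(pore)
    pads = tuple(min(s // 2, 64) for s in pore.shape)
    padded = np.pad(pore, tuple((p, p) for p in pads), mode="wrap")
    edt = ndimage.distance_transform_edt(padded)
    slices = tuple(slice(p, p + s) for p, s in zip(pads, pore.shape))
    return edt[slices]


def extract_pore_network(img: BinaryImage, sigma: float = 0.4,
                         min_peak_separation: int = 4,
                         periodic: bool = True) -> PoreNetwork:
    """SNOW-style pore-network extraction from a binary image.

    Steps: Euclidean distance transform of the pore phase, Gaussian smoothing,
    local-maximum detection with suppression of spurious nearby peaks,
    marker-based watershed segmentation, then per-region pore properties
    (diameter = 2 × peak distance) and face-shared throats (periodic faces
    included).
    """
    solid = img.grid
    pore = ~solid
    n_pore = int(np.count_nonzero(pore))
    if n_pore == 0:
        raise EmptyNetworkError("image is entirely solid: no pore network")
    h = img.voxel_nm
    if not np.any(solid):
        # degenerate all-pore image: a single pore spanning the periodic domain
        center = np.array([[s * h / 2.0 for s in pore.shape]])
        vol = n_pore * h**3
        d_equiv = (6.0 * vol / np.pi) ** (1.0 / 3.0)
        return PoreNetwork(center, np.array([d_equiv]), np.array([vol]),
                           np.empty((0, 2), int), np.array([]))

    dt = _periodic_edt(pore, periodic)
    dt_smooth = ndimage.gaussian_filter(dt, sigma=sigma, mode="wrap" if periodic else "reflect")
    peaks = peak_local_max(dt_smooth, min_distance=min_peak_separation,
                           exclude_border=False, labels=pore)
    if len(peaks) == 0:
        peaks = np.array([np.unravel_index(np.argmax(dt_smooth * pore), pore.shape)])
    # suppress spurious peaks: drop a peak lying within the inscribed sphere
    # of a larger peak (they belong to the same pore body)
    peak_dt = dt[tuple(peaks.T)]
    order = np.argsort(-peak_dt)
    kept: list[int] = []
    shape = np.array(pore.shape, dtype=float)
    for idx in order:
        p = peaks[idx].astype(float)
        ok = True
        for k in kept:
            q = peaks[k].astype(float)
            delta = p - q
            if periodic:
                delta -= shape * np.round(delta / shape)
            if np.dot(delta, delta) <= peak_dt[k] ** 2:
                ok = False
                break
        if ok:
            kept.append(idx)
    peaks = peaks[kept]
    peak_dt = dt[tuple(peaks.T)]

    markers = np.zeros(pore.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dt_smooth, markers=markers, mask=pore)

    n_pores = len(peaks)
    volumes = np.bincount(labels.ravel(), minlength=n_pores + 1)[1:] * h**3
    diameters = 2.0 * peak_dt * h
    centers = (peaks + 0.5) * h

    # throats: adjacent label pairs across voxel faces (incl. periodic wrap)
    throat_best: dict[tuple[int, int], float] = {}
    for axis in range(3):
        l1 = labels
        l2 = np.roll(labels, -1, axis=axis)
        d1 = dt
        d2 = np.roll(dt, -1, axis=axis)
        mask = (l1 > 0) & (l2 > 0) & (l1 != l2)
        if not periodic:
            sl = [slice(None)] * 3
            sl[axis] = slice(0, labels.shape[axis] - 1)
            keep = np.zeros_like(mask)
            keep[tuple(sl)] = True
            mask &= keep
        if not np.any(mask):
            continue
        a = l1[mask]
        b = l2[mask]
        face_dt = np.minimum(d1[mask], d2[mask])
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        for key_lo, key_hi, fdt in zip(lo, hi, face_dt):
            key = (int(key_lo) - 1, int(key_hi) - 1)
            if fdt > throat_best.get(key, 0.0):
                throat_best[key] = float(fdt)
    if throat_best:
        throats = np.array(sorted(throat_best), dtype=int)
        throat_d = np.array([2.0 * throat_best[tuple(t)] * h for t in throats])
        throat_d = np.maximum(throat_d, h)   # resolution floor: one voxel
    else:
        throats = np.empty((0, 2), dtype=int)
        throat_d = np.array([])
    return PoreNetwork(centers, np.maximum(diameters, h), volumes, throats, throat_d)


# ---------------------------------------------------------------------------
# Pore-size distributions
# ---------------------------------------------------------------------------

@dataclass
class PoreSizeDistribution:
    """Windowed pore-size distribution under the spherical-pore assumption.

    Incremental volumes follow V_P,i = n_P,i · (π/6) · d_P,av,i³ with
    d_P,av,i the volume-equivalent mean diameter of the pores in window i,
    so that the summed incremental volumes reproduce the total spherical
    pore volume of the network exactly.
    """

    window_edges_nm: np.ndarray      # (W+1,) strictly increasing boundaries
    counts: np.ndarray               # (W,) pores per window
    avg_diameters_nm: np.ndarray     # (W,) volume-equivalent mean diameter
    incremental_volumes_nm3: np.ndarray   # (W,)
    mean_pore_width_nm: float        # count-weighted mean over all pores
    overflow_count: int = 0          # pores outside every window

    @property
    def total_volume_nm3(self) -> float:
        return float(np.sum(self.incremental_volumes_nm3))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_lo": self.window_edges_nm[:-1],
            "window_hi": self.window_edges_nm[1:],
            "d_av_nm": self.avg_diameters_nm,
            "count": self.counts,
            "volume_nm3": self.incremental_volumes_nm3,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def psd_from_network(net: PoreNetwork, windows,
                     volume_weighted_mean: bool = False) -> PoreSizeDistribution:
    """Discretize the continuous pore diameters onto experimental windows.

    ``windows`` are strictly increasing boundary values (W+1 edges for W
    windows).  Pores falling outside every window are counted in an overflow
    bin and reported; the conservation invariant covers the in-window pores.
    """
    edges = np.asarray(windows, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise DomainError("windows must be a strictly increasing boundary list")
    d = np.asarray(net.pore_diameters_nm, dtype=float)
    n_w = len(edges) - 1
    counts = np.zeros(n_w, dtype=int)
    d_av = np.zeros(n_w)
    vols = np.zeros(n_w)
    idx = np.searchsorted(edges, d, side="right") - 1
    idx[(d == edges[0])] = 0
    in_range = (idx >= 0) & (idx < n_w) & (d <= edges[-1])
    overflow = int(np.count_nonzero(~in_range))
    if overflow:
        warnings.warn(f"{overflow} pore(s) outside the window range "
                      f"[{edges[0]}, {edges[-1]}] nm counted in overflow bin")
    for w in range(n_w):
        sel = d[in_range & (idx == w)]
        counts[w] = len(sel)
        if len(sel):
            # volume-equivalent mean keeps Eq-form V = n·(π/6)·d_av³ exact
            d_av[w] = float(np.mean(sel**3) ** (1.0 / 3.0))
            vols[w] = counts[w] * np.pi / 6.0 * d_av[w] ** 3
        else:
            d_av[w] = 0.5 * (edges[w] + edges[w + 1])
    if volume_weighted_mean and d.size:
        mean_width = float(np.sum(d**4) / np.sum(d**3))
    else:
        mean_width = float(np.mean(d)) if d.size else 0.0
    return PoreSizeDistribution(edges, counts, d_av, vols, mean_width, overflow)


def experimental_psd_to_counts(incremental_volumes, avg_diameters_nm,
                               porosity_percent: float, v_rve_nm3: float,
                               v_p_tot=None) -> np.ndarray:
    """Convert an experimental incremental-pore-volume table to RVE-scale counts.

    The experimental pore volume is downscaled to the simulation domain with
    the volume scaling factor f_V = Φ_exp·V_rve / V_P,tot (porosity as a
    fraction of the RVE volume), assuming pore-volume fractions are
    scale-invariant; counts follow from the spherical-pore volume:
    n_P,i = f_V · V_P,i / ((π/6) · d_P,av,i³).
    """
    v_i = np.asarray(incremental_volumes, dtype=float)
    d_i = np.asarray(avg_diameters_nm, dtype=float)
    if v_i.shape != d_i.shape:
        raise DomainError("volume and diameter lists must be conformable")
    if np.any(d_i <= 0):
        raise DomainError("average pore diameters must be > 0")
    if porosity_percent <= 0 or v_rve_nm3 <= 0:
        raise DomainError("porosity and RVE volume must be > 0")
    v_p_tot = float(np.sum(v_i)) if v_p_tot is None else float(v_p_tot)
    if v_p_tot <= 0:
        raise DomainError("total experimental pore volume must be > 0")
    f_v = (porosity_percent / 100.0) * v_rve_nm3 / v_p_tot
    return f_v * v_i / (np.pi / 6.0 * d_i**3)


def read_experimental_psd(path) -> pd.DataFrame:
    """Read a discrete experimental pore-size table (BJH-type) from CSV.

    Expected columns: ``pore_width_nm`` and
    ``incremental_pore_volume_cm3_per_g``.
    """
    df = pd.read_csv(path)
    required = {"pore_width_nm", "incremental_pore_volume_cm3_per_g"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"experimental PSD file {path} lacks columns {sorted(missing)}")
    return df
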