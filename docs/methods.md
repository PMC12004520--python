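# Methods

## Model overview

`gelcraft` follows the gelation of cellulose with a discrete-element /
coarse-grained molecular dynamics model. One sphere represents one d-glucose
repeating unit; a chain of `n_g` beads connected by elastic bonds represents
one cellulose molecule. The solvent is implicit: it acts only through a
Stokes drag on each bead and the thermodynamically matched fluctuating force.
The model is deliberately minimal — no torsional potential, no hydrodynamic
interactions, no rotational diffusion, no hydrogen-bond chemistry and no
crystallinity; aggregation is driven entirely by a pairwise Lennard-Jones
attraction competing with chain elasticity and diffusion.

## Units

Internal units are nm / ps / amu. The derived energy unit amu·nm²/ps² equals
1 kJ/mol per particle (1.66054×10⁻²¹ J), so literature interaction energies
in kJ/mol are internal energies verbatim, and k_B is numerically the molar
gas constant in kJ/(mol·K). All configuration values are SI with unit
suffixes in the key names and are converted once on load. This avoids the
catastrophic float scales that SI magnitudes (10⁻²² g, 10⁻¹² s) would
introduce.

## Parameters

| parameter | default | provenance |
|---|---|---|
| bead diameter d_g, bond length l_b^eq | 0.4615 nm | length of the glucose unit |
| bead mass m_g | 162.14 amu (= M_g/N_A g) | glucose molar mass |
| bond stiffness k_b^n | 1.18479 N/m | l_p·s/l_b² from single-molecule l_p = 6.2 nm, s = 40.7 pN |
| bending stiffness k_b^α | 1.15375×10⁻¹⁹ N·m/rad | see note below |
| LJ well depth ε | 30 kJ/mol (sweep 5–42) | sensitivity-analysis range; 30 gels robustly |
| LJ minimum d_eq | 0.4 nm (sweep 0.3–0.425) | sensitivity-analysis range |
| cutoff, interaction distance d_int | 1.5 nm | truncation / contact definition |
| solvent viscosities μ | 0.03 (solution), 0.00089 (water), 0.001074 (ethanol) Pa·s | measured / tabulated |
| temperature | 300 K (annealing peak 2000 K, ramp 5 μs at full scale) | protocol |
| time step | 0.04 ps | largest converging step for this system |
| volumetric shrinkage V_s | 39.5 % | measured on aerogel beads |

Notes on provenance:

- The published bending stiffness is printed as 1.15375×10⁺¹⁹ N·m/rad, which
  would make chains infinitely rigid; we read this as a sign-of-exponent typo
  and default to 1.15375×10⁻¹⁹ N·m/rad, consistent with the k_B·T·l_p/l_b
  persistence-length estimate (~5.6×10⁻²⁰ J/rad²) within a factor ~2. It is
  a configuration field, not a constant.
- The solution density ρ_sol needed by the chain-count relation
  n_c = round(w_c·ρ_sol·V_box/(n_g·m_g)) is not reported; the default
  1.058 g/cm³ is back-derived so that the 7 wt% solution in the 100 nm box
  contains 764 chains, and is flagged as an assumption in the configuration.
- The quoted full-scale chain length 415.35 nm is inconsistent with
  n_g·l_b = 360×0.4615 = 166.14 nm; the geometric value is used.
- The drag law is the standard Stokes form c = 6πμr_s with r_s = d_g/2 =
  0.23075 nm.

## Forces

- **Bond**: F = k_b^n(|d| − l_b^eq) along the bond axis, equal and opposite on
  the two beads; minimum-image convention throughout.
- **Bending**: α = π − (a-b-c angle), so a straight chain is torque-free.
  Torque τ = k_b^α·α is converted to forces with the exact gradient of
  ½k_b^α α²: terminal beads receive τ/l_bond perpendicular to their bond, the
  central bead the balancing counter-force; each triplet exerts zero net
  force and zero net torque. Near-folded triplets (sin θ → 0) keep the exact
  bounded magnitude k·α/l with a numerically clamped direction.
- **Lennard-Jones**: U(d) = ε[(d_eq/d)¹² − 2(d_eq/d)⁶] (minimum −ε at d_eq,
  i.e. σ = d_eq/2^{1/6}), plainly truncated at 1.5 nm without shifting; the
  force discontinuity at the cutoff is tiny (≲2 % of the characteristic force
  scale, measured in the tests) and tolerated, matching the stated truncation
  scheme. Directly bonded (1-2) pairs are excluded; 1-3 pairs are not, since
  the bending term already penalizes close 1-3 approach. A repulsive-only
  mode clamps the attractive branch to zero.
- **Langevin**: per component F = −c·v + ξ·sqrt(2·c·k_B·T/Δt) with ξ standard
  normal. The annealing temperature enters only the fluctuation amplitude;
  the drag coefficient is held at its solvent value (temperature dependence
  of μ is not modelled).

Neighbor search uses a periodic k-d tree at cutoff + skin (default skin
0.3 nm) with displacement-triggered rebuilds (any bead moving farther than
skin/2 invalidates the list); bonded pairs are excluded at build time.

## Integration

The deterministic part is the classic leapfrog (velocities at half steps).
The Langevin terms cannot be added to the explicit force at the working
conditions: c·Δt/m ≈ 19.4 for a glucose bead in the 0.03 Pa·s solvent at
Δt = 0.04 ps, far beyond the stability limit (≈2) of explicit damping.  We
therefore use the Grønbech-Jensen–Farago (GJF) leapfrog discretization, which
is unconditionally stable in c·Δt/m, reduces exactly to plain leapfrog when
the diffusion term is switched off, and reproduces two key observables
*exactly* at any time step: the free-particle diffusion coefficient
D = k_B·T/c and the half-step kinetic temperature k_B·T/m. Both properties
are verified in the test suite (D within 10 % and velocity variance within
5 % on seeded ensembles). Velocities are initialized from a Maxwell–Boltzmann
distribution at the first stage's initial temperature.

A master seed spawns independent RNG streams per stage, so identical
seed + configuration gives bit-identical trajectories on one platform, and
individual stages can be rerun.

## Protocol

Stages mirror the laboratory route (generation → relaxation → equilibration
→ gelation → washing → solvent exchange → drying):

- *Generation*: straight chains, uniform random start points, orientations
  uniform on the sphere; overlap permitted.
- *Relaxation* (15 μs full scale): bond + bending + diffusion, LJ off;
  annealing 2000 K → 300 K linearly over the first 5 μs (the ramp is read as
  contained in the relaxation stage).
- *Equilibration* (700 ns): adds repulsive-only LJ to remove overlap.
- *Gelation* (5 μs): full LJ; the inter-chain interaction count I(t) within
  d_int = 1.5 nm tracks network formation, normalized by its end-of-stage
  value I_max.
- *Washing* / *solvent exchange*: identical force terms, only the solvent
  viscosity changes (water, then ethanol). Durations are not reported for
  the source system; 1 μs each at full scale, proportionally short in the
  desk preset.
- *Drying*: isotropic deformation F = λI, λ = (1 − V_s)^⅓; positions and box
  scale by λ, bead diameters do not. No capillary-pressure physics is
  attempted.

Snapshots after gelation / washing / solvent exchange / drying carry the
material labels gel / hydrogel / alcogel / aerogel.

## Desk-scale (`mini`) preset

Full-scale runs are ~10⁸ steps of 275,040 beads — cluster territory. The
`mini` preset keeps the protocol structure with 10 chains × 20 beads and
nanosecond durations (relaxation 300 ps with a 100 ps ramp, equilibration
60 ps, gelation 2 ns, washing/solvent exchange 150 ps each; ~20 s on one
CPU core). Two choices matter:

- **Box size 9 nm.** At 10×20 beads this reproduces the full-scale solution's
  bead number density (200/9³ ≈ 0.274 nm⁻³ vs 0.275 nm⁻³ at 7 wt%), so
  inter-chain contact statistics are representative. A more dilute box (at
  this bead count) leaves entire realizations with no inter-chain contacts
  at all on nanosecond timescales, making gelation unobservable.
- **Aggregation onset metric.** At full scale I(t) rises from ~0, and the
  time to I/I_max = 0.5 is a natural onset. A 200-bead stage instead opens
  with a substantial random-contact population, so we define onset as the
  first (interpolated) time I(t) ≥ 1.25·I(0), censored at the stage end when
  never reached. Under this metric ε = 30 kJ/mol systems show onset within
  ~1 ns while ε = 5 systems never cross the threshold, reproducing the
  full-scale ordering (aggregation accelerates with ε).

What mini-preset results do **not** show: pore-size distributions comparable
to experiment (the 9 nm box cannot hold mesopores of tens of nm), long-range
fibril bundling, or the slow washing/solvent-exchange rearrangements — those
require the full-scale run.

## Microstructure analysis

- **Voxelization**: a voxel (default edge 0.25 nm) is solid iff its center
  lies within one bead radius of any bead center (minimum image). The
  center-in-sphere rule is exact for the single-bead unit test and converges
  to the true solid fraction as the voxel shrinks.
- **Porosity**: 100·n_pore/n_tot from the image, or 100·(1 − ρ_e/ρ_s) from
  measured skeletal/envelope densities.
- **Pore network (SNOW-style)**: Euclidean distance transform of the pore
  phase (periodicity via tile-and-crop padding), Gaussian smoothing
  (σ = 0.4 voxels), local maxima with a minimum separation of 4 voxels,
  suppression of any peak lying inside a larger peak's inscribed sphere,
  marker-based watershed on the negated distance map. Pore diameter =
  2 × peak distance value; pore volume = region voxel volume; throats connect
  regions sharing voxel faces (periodic faces included) with diameter
  2 × the largest face-level distance value. The all-pore image degenerates
  to a single domain-spanning pore with the volume-equivalent diameter. Note
  that the distance-transform radius of a digital sphere overestimates the
  nominal radius by about half a voxel — within the method's resolution.
- **Pore-size distribution**: pores are binned into the experimental window
  boundaries; the per-window average diameter is the volume-equivalent mean
  (cube root of the mean cubed diameter) so that the incremental volumes
  V_P,i = n_P,i·(π/6)·d_P,av,i³ sum exactly to the network's spherical pore
  volume. The mean pore width d̄_P is the count-weighted mean diameter
  (volume weighting available as an option). Experimental incremental-volume
  tables are downscaled to the simulation domain with
  f_V = Φ_exp·V_rve/V_P,tot (assuming pore-volume fractions are
  scale-invariant) and converted to counts n_P,i = f_V·V_P,i/((π/6)·d_P,av,i³).

## Numerical choices and degenerate inputs

- Coincident bonded beads or degenerate angle bonds raise a singular-geometry
  error rather than producing NaNs; non-finite positions/forces raise a
  blow-up error carrying the stage time.
- Duration must be a multiple of the time step; zero-duration stages are
  identities with empty logs.
- A gelation log ending at I = 0 is flagged "not gelled" and returned
  unnormalized with a warning.
- Pores outside every distribution window go to a reported overflow bin.
- Throat and pore diameters are floored at one voxel (resolution limit).

## Known limitations

- The washing/solvent-exchange physics is reduced to a viscosity change; any
  solvent-specific interaction chemistry is out of scope.
- Drying ignores capillary pressure and possible anisotropy; it cannot
  produce the pore-count reduction mechanism beyond pure geometric scaling.
- The LJ parameterization permits bead interpenetration (d_eq < d_g), as in
  the source model; contact mechanics is not resolved.
- Periodic watershed segmentation is approximate near faces (the distance
  transform is periodic, the region growing is not), which can split a pore
  that straddles a face when its interior peaks are far apart.
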