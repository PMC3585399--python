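# Methods

## The model systems

An abstract coordination cage is a single fixed cation (Li+, Na+ or K+,
Joung–Cheatham Lennard-Jones parameters, charge +1) at the origin,
surrounded by `n = 4…8` small dipolar ligands modelled on formaldehyde
(partial charges C +0.5, O −0.5, H 0.0; harmonic bonds and angles
transcribed from a standard all-atom protein force field into
`rlfsim/data/*.csv`). Every coordinating oxygen is confined to the ion by a
one-sided flat-bottom spherical wall of radius 3.5 Å (default stiffness
100 kcal/mol/Å², configurable): the wall fixes the *composition* of the
coordination shell without dictating geometry. Ligand thermal fluctuations
are reduced by per-atom harmonic anchors of stiffness `kf` (all atoms,
hydrogens included), placed at the vertices of optimal coordination
polyhedra (tetrahedron, octahedron, square antiprism for n = 4, 6, 8; a
deterministic sphere-packing optimisation for n = 5, 7) at radius `R_opt`.

`R_opt` is the first-peak position of the ion–oxygen radial distribution
function of the *unconstrained* cage (wall only), measured per ion and per
n. Anchoring each ion at its own `R_opt` is what makes the cage
strain-free: the anchors restrict motion without displacing the ligands
from the positions they would choose anyway. Re-using one ion's anchors
for another ion is the strained-cavity protocol and must be requested
explicitly (`allow_strain=True` / `--strained-for`).

Transporter-site models replace the uniform ligand set with the
composition of four real Na+ binding sites (three carbonyl + two hydroxyl
for LeuT Na2, a bidentate carboxylate in Glt Na1, etc.). Their starting
coordinates are idealised — coordinating atoms on packed directions at
chemically sensible distances — and then energy-minimised with each ion,
which defines the per-ion anchor geometry. This synthetic construction
stands in for coordinates extracted from crystal structures; it preserves
composition, coordination distances, and charge, but not the exact
crystallographic arrangement, so site results are qualitative
(selectivity signs and their kf-dependence), not quantitative binding
free energies.

Nonbonded interactions use a 12 Å cutoff with CHARMM-style polynomial
switching from 10 Å on both the Coulomb and Lennard-Jones terms
(Lorentz–Berthelot combining; Coulomb constant 332.0637 kcal·Å/mol·e²).
All harmonic terms use the ½k(Δ)² convention. The systems are droplets in
vacuo: no water, no periodic boundaries, no polarisability.

## Thermodynamic cycle and sign conventions

Selectivity between ions A and B at anchor stiffness `kf` is the exchange
free energy

```
ddG_exchange(kf) = dG_c,B(kf) − dG_c,A(kf) − dG_site(A→B) + ddG_hydr(A→B)
```

where `dG_c,X` is the restraint-morph free energy (anchored → free cage
around X), `dG_site(A→B)` the ion-identity morph in the unanchored cage,
and `ddG_hydr(A→B) = dG_hydr(B) − dG_hydr(A)` the bulk-water constant,
shipped as a data file with the conventional real hydration free energies
(Li −113.5, Na −87.2, K −70.5 kcal/mol) that the ion parameter set was
calibrated against. Positive values mean B is preferred in the site. The
purely fluctuation-driven part is

```
ddG_RLF(kf) = ddG_exchange(kf) − ddG_exchange(0) = dG_c,B(kf) − dG_c,A(kf),
```

identically zero at kf = 0 (the morph endpoints coincide). Pairs are
ordered (Na, K) and (Na, Li), so negative values are Na+-selective and
positive values K+- or Li+-selective.

The restraint morph is dual-topology: two identical ligand sets, one
anchored (coupling 1−λ) and one free (coupling λ), mutually
non-interacting; both endpoints are an n-ligand cage. A dual-topology leg
value contains an ion-independent offset — the confinement free energy of
whichever set is decoupled — that cancels exactly in every ΔΔ quantity
because both legs of a pair share the same ligand composition. Single-leg
values are therefore reported but only differences are physical.

Enthalpy is estimated from endpoint window mean potential energies
(`dH = ⟨U⟩_{λ=1} − ⟨U⟩_{λ=0}`), combined across legs with the same
arithmetic as the free energy; `−TΔΔS = ΔΔG − ΔΔH` is the arithmetic
remainder, never an independent estimate. On non-interacting anchored
toys equipartition makes the mean harmonic energy stiffness-independent,
so a kf₁→kf₂ morph has dH = 0 and dG = −TdS exactly — the entropic
mechanism in its cleanest limit, used as an analytic oracle throughout
the tests.

## Alchemical coupling

Per-pair couplings are linear in λ. The Lennard-Jones term of partially
coupled pairs uses the shifted-distance softcore
`r² → r² + shift·(1−w)·σ²` (shift coefficient 1). The Coulomb term scales
linearly with the coupling *and shares the same shifted distance*: with
softcore applied to the dispersion term alone, a half-coupled oxygen's
full 1/r attraction to the cation exceeds the bounded softcore repulsion
and the particles fuse (we observed exactly this divergence). The shared
shift is exact at both endpoints and removes the singularity everywhere.

Ion-identity morphs interpolate the two ions' full 12-6 pair energies
linearly, `U = (1−λ)U_A(r) + λU_B(r)`, with no softcore and the charge
fixed at +1: the ion never vanishes, so a hard repulsive core persists at
every λ and no endpoint singularity exists. (The softcore variant is
unstable in carboxylate-bearing sites for the same fusion reason.)

λ schedules: restraint morphs default to 29 windows, dense at the
endpoints ({0, 1e−5, 1e−4, 1e−3, 1e−2, 0.05 … 0.95, 0.99, 0.999, 0.9999,
0.99999, 1}), because whole ligand sets appear and disappear there; ion
morphs use 0…1 in 0.05 steps. Windows are visited as a ladder, each
starting from the previous window's final coordinates and velocities —
this equilibration chaining is what makes short windows usable, and it is
why legs run serially rather than window-parallel; reproducibility comes
from the per-window seeds, not from execution order.

## Estimators and errors

The default estimator is exponential averaging (EXP/Zwanzig) over adjacent
windows, `ΔG_i = −kT ln⟨exp(−ΔU/kT)⟩_i`, with per-window standard errors
from ten-block averaging and leg errors summed in quadrature. Bennett's
acceptance ratio (BAR) over matched forward/backward cross-evaluations is
available as a cross-check; its variance uses the Bennett estimator with
sample counts deflated by the integrated-autocorrelation statistical
inefficiency of the work series. Forward and reverse legs provide the
hysteresis diagnostic `|ΔG_fw + ΔG_rv|`, reported per leg and aggregated
(max, mean) over a campaign.

## Sampling

Dynamics are BAOAB-discretised Langevin at 310 K, 1 fs timestep, friction
5 ps⁻¹ — a friction high enough for robust canonical sampling of stiffly
anchored atoms yet low enough not to slow configurational diffusion of
the wall-confined decoupled ligands. The ion never moves. The first 10%
of every window is discarded as equilibration. Hydrogens carry their real
mass and are unconstrained; at 1 fs the stiffest modes (O–H, C–H plus
strong anchors) have ωΔt ≈ 0.5–0.65, which BAOAB integrates stably but
whose *full-step kinetic* temperature reads ~2–5% low (a known
discretisation artifact; configurational averages, which are what FEP
consumes, are much less affected). Equipartition benchmarks in the test
suite therefore use soft-mode toys where the bias is negligible.

## Analyses

* **RDF / R_opt** — ion–oxygen histogram normalised by shell volume and
  mean density; the optimum radius is the first local maximum of the
  3-bin-smoothed g(r) above 1, deliberately *not* the global maximum, so
  second-shell peaks of crowded cages cannot capture it.
* **RMSF** — per-atom RMS deviation from trajectory-mean positions,
  pooled over the selection; maps kf onto observable fluctuation sizes.
* **Occupancy volume** — union-of-spheres voxelisation (0.1 Å spacing,
  Bondi radii). Default mode is *cumulative* (a voxel counts once it is
  ever covered), reading the grid as configurational space explored;
  `frame_fraction` mode with an isovalue reproduces time-averaged
  (VolMap-style) maps. Cumulative volumes grow with trajectory length, so
  only matched-length comparisons are meaningful.

## Problem sizes and defaults

Full-protocol sampling is 4 ns per λ window; campaigns apply a scale
factor (`scale=0.05` → 200 ps/window). The packaged kf grid is 0 plus
log₁₀ kf from −1 to 3 in 0.5 steps (kcal/mol/Å²); the plateau of the
selectivity curves sits at the top of this range, so single-point studies
use kf = 1000. The acceptance script runs 29 windows × 150 ps per leg
(4.35 ns aggregate) with 200 ps unconstrained runs for R_opt; the test
suite uses 20–100 ps windows, the longer ones reserved for the 8-fold
cage, whose K+-ward shift is enthalpy-driven (second-shell packing around
the small ion) and converges more slowly than the entropy-driven cages.

## What the generator does and does not emulate

The synthetic systems reproduce the composition, coordination distances,
charges and restraint physics of ion binding sites, and they are the
*intended* model: the claims under test are about these toy models, not
about full proteins. They do not include water, protein scaffold,
polarisation, or crystallographic coordinates; transporter-site results
validate the mechanism (sign changes and entropy dominance), not absolute
affinities. Passing tests demonstrate that reduced ligand fluctuations
generate small-ion-ward, entropy-dominated selectivity in these models —
they do not by themselves quantify the effect in real transporters.

## Known limitations

* EXP between adjacent windows is biased for poorly overlapping windows;
  the dense-endpoint schedule and hysteresis checks mitigate but do not
  eliminate this at desk scale.
* Dual-topology leg values carry the (cancelling) dummy-set offset; do
  not interpret single legs in isolation.
* The kinetic-temperature readout is biased low for stiff modes at 1 fs
  (see Sampling); free energies are unaffected at the accuracy targeted
  here.
* Site models are idealised reconstructions; their kf = 0 selectivities
  depend on fragment charges at the ~1 kcal/mol level.
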