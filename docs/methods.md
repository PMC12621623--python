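# Methods

`setascale` simulates the adhesion of a gecko seta — a branched, micrometre-
scale keratin hair ending in nanoscale adhesive pads (spatulae) — using a
concurrent multiscale scheme: the branched seta is a linear-elastic finite
element (FE) body, each spatula is a coarse-grained bead–spring molecular
dynamics (MD) network, and the two descriptions are coupled in a bridging
domain (BD) on each terminal branch.

## 1. Geometry

The seta skeleton is a binary tree between two guiding hyperbolas

x² / C1² − y² / C2² = 1,  C1 ∈ {0.5·D0, 1.5·D0},  C2 = C1·tan α,

with branch level heights H_i = η^(n−i)·H_sp and widths W_i = γ^(n+1−i)·R_sp.
Level i holds 2^(i−1) branch points at the midpoints of the interval defined
by the two guides; the 2^n terminal tips rest on the substrate plane y = 0.

Defaults (`GeometryParams`): D0 = 13.5 µm, α = 30°, η = γ = 2.417,
H_sp = 0.67 µm, R_sp = 50 nm, n_levels = 4 ⇒ total height
H0 = η⁴·H_sp ≈ 22.87 µm and 16 tips. The width-decay factor γ is a free
parameter of the model; the default ties it to the height decay η.

Each skeleton edge becomes a tapered frustum. The solid is meshed by
sampling structured, golden-angle-rotated rings on the frusta (with a
deterministic, translation-invariant hash jitter to break coplanarity),
taking a global Delaunay tetrahedralization in a local frame, and keeping
tets whose centroid lies inside the union of frusta. The top of the shaft is
cut by a flat horizontal cap; nodes on that plane are the **driver nodes**
that receive the prescribed displacement. Terminal branches are truncated at
`trunc_fraction` of their length, and the band of nodes within
`bd_fraction` of the cut defines the per-branch **BD node set**. Straight-
edge quadratic tets (P2) are available by midpoint promotion.

Known limitation: at branch junctions the triangulated boundary has a few
non-manifold pinch edges, and the tilted shaft frustum's upper rim can
protrude slightly above the flat driver cap. Neither affects volume
(validated against the closed-form frusta-volume oracle to ~1 %),
connectivity, element quality, or the FE solution.

## 2. Material model

Isotropic small-strain linear elasticity with E = 4.518 ± 0.036 GPa and
ν = 0.401 ± 0.002 (keratin); each run samples one (E, ν) pair from these
normals (`sample_material`). Lamé parameters follow the standard relations.
Internal FE units are nm / nN / GPa (1 GPa = 1 nN/nm²).

## 3. Spatula model

A spatula is a jittered cubic-lattice bead fill of a pad plate, tip strip
and 45° shaft, bonded by harmonic springs between symmetrised 30-nearest
neighbours. Bond stiffness is anisotropic,

K(bond) = k + k_b·|cos θ|,

where θ is the angle to the fibril (shaft) axis; default
k = k_b = 0.28 nN/nm. The full-scale preset (spacing 4.32 nm) has ~15 260
beads of 65 228 Da, shortest bond ≈ 3 nm, mean ≈ 7.2 nm. The `mini` preset
(spacing 6 nm, 204 beads) is a desk-scale stand-in with the same
architecture. Orientations `tip-first` and `pad-parallel` differ by a 90°
rigid rotation about the shaft axis.

A virtual tensile test (static minimisation of a gripped specimen) measures
the network's effective E and ν; `tune_stiffness` inverts it for (k, k_b).
Because the network is a central-force (pair-spring) system, its Poisson
ratio is bounded near the Cauchy value (~0.25): the keratin target ν = 0.401
is structurally unattainable, so `tune_stiffness` recovers E exactly and
reports the best achievable ν with `converged=False`. The tensile test is
only meaningful on prismatic specimens; applied to the L-shaped spatula
itself, the transverse fit is dominated by shape effects.

## 4. Molecular dynamics

Velocity Verlet with Δt = 20 fs in units of nm / Da / kJ·mol⁻¹ (derived time
unit exactly 1 ps). Spatula–substrate interaction is Lennard-Jones with
ε = 290 kJ/mol, σ = 4 nm, cut off at 12 nm and **energy-shifted** so
V(r_cut) = 0 — a bare truncation leaks ~1.6 kJ/mol per cutoff crossing,
which becomes a visible artificial energy loss during snap-in; the shift
changes no forces. The substrate is a rigid monolayer (optionally with an
amorphous bulk slab) at y = 0; pairs are found with a KD-tree plus 2 nm
Verlet skin.

Thermostats at T = 300 K: canonical-sampling velocity rescaling (τ = 2 ps)
outside the bridging domain, Berendsen (τ = 10 ps) inside. All noise comes
from seeded generators, so runs are bitwise deterministic per seed. At T = 0
both degenerate to exponential damping (used for statics checks). Measured
NVE drift without thermostats: ~0.003 % of |E| over 10⁴ steps.

## 5. FEM

Standard displacement FEM on P1/P2 tets (Voigt assembly, 4-point Gauss for
P2), Dirichlet elimination on the driver nodes, one sparse LU factorisation
reused for every iteration of a run. Reactions are recovered from the
residual; the reported driver force is −Σ reactions_y (compression
positive). Verified: rigid-motion null space at machine precision, patch
test exact to 1e-16, quadratic cantilever within 0.5 % of Euler–Bernoulli.

## 6. Coupling and load protocol

At assembly, every BD node becomes an **anchor point** (AP): a virtual,
spatially fixed particle tethered to its own nearest unpaired spatula bead
(greedy pairing in ascending node index, distance cap twice the mean bond
length, injective) by a harmonic spring of stiffness 0.28 nN/nm whose rest
length is the pairing-time distance.

One FEM–MD iteration: (1) run an MD phase of n_md steps with APs fixed,
time-averaging the AP spring forces over the final 50 %; (2) apply those
averaged forces as nodal loads and solve the static FE problem with the
driver displacement prescribed (incremented by ±ε_ls only on a load step's
first iteration) and per-iteration penalty springs k_FE = 0.08 nN/nm
re-anchored at the previous BD node positions,
(K + K_FE)·u = f_ext + K_FE·u_prev; (3) move the APs to the displaced BD
node positions. A load step is n_iter such iterations; defaults
n_iter = 10, n_md = 7000, ε_ls = 1 nm give Δt_ls = 1.4 ns per load step and
a pull-off speed of 0.7 m/s.

The protocol is preload (drive −Y until the windowed substrate reaction
reaches the target while in contact, or for a fixed number of steps), relax
(no displacement), pull-off (+Y until every spatula has had zero contacts
for 3 consecutive load steps). Contacts are spatula–substrate pairs closer
than 12 nm. A divergence guard aborts if any AP moves more than 10·ε_ls in
one iteration.

`run_shear` is a pure-MD variant for friction: a single anchored spatula is
lowered to a compressive normal-force target, then the anchors slide along
+X at a prescribed speed; the apparent friction coefficient is
μ = mean|F_x| / mean|F_y| over the steady part.

## 7. The mini preset

`fixtures.make_mini_system(seed)` builds a two-level seta with four thinned
terminal fibrils (R_sp = 30 nm, H_sp = 200 nm — paired BDs require the
fibril and the mini spatula shaft to overlap geometrically) carrying four
mini spatulae in alternating tip-first / pad-parallel orientation, over a
monolayer substrate. Shortened schedule: n_iter = 6, n_md = 2000,
max 250 load steps. Because the scaled force target (≈1 nN) is crossed
before the higher-hanging pad-parallel spatulae reach the substrate, the
preset fixes the preload depth geometrically at build time: descend until
the highest spatula's lowest bead is one LJ σ above the substrate. The
whole protocol runs in minutes and reproduces the full-scale signatures:
compressive preload, snap-in contact jumps of ~3000 contacts for
pad-parallel spatulae (vs ~tens for tip-first initial contact), a single
adhesion minimum of tens of nN, two-stage pad-parallel contact plateaus,
and sequential detachment.

Mini-scale stochasticity: the detachment ordering "all tip-first before all
pad-parallel" is a statistical tendency, not a per-seed certainty. The
pad-parallel spatulae hang ~26 nm higher than the tip-first ones (the
terminal branches are tilted ~45–56° from vertical, and the two
orientations present different extents along a tilted shaft), so the
geometric preload presses the tip-first spatulae well past first contact;
on some seeds they flatten into full pad contact and then detach pad-like.
With only four spatulae there is no self-averaging, so single-seed runs can
violate the ordering (e.g. seed 2) while others (e.g. the default seed 1)
show it cleanly.

## 8. Analysis conventions

- **Adhesion force**: most negative windowed substrate reaction during
  pull-off (seta level and per spatula).
- **Averaging conventions**: the naive per-spatula force is |seta
  minimum|/n_spatulae; the per-spatula average is the mean of each
  spatula's own |F_min| (these differ because minima are asynchronous, so
  the per-spatula average is always ≥ the naive one).
- **Detachment**: the load step starting the final all-zero contact run of
  a spatula, confirmed over a 3-step horizon; events carry a
  tip-dominant/pad-dominant contact-mode label.
- **Contact plateaus**: `contact_plateau_levels` finds sliding windows with
  < 10 % relative spread and merges them into levels separated by ≥ 1.4×.
- **Friction**: μ from steady-state force ratios in shear runs; μ decreases
  with sliding speed in the mini system (e.g. 0.13 at 2 m/s vs 0.04 at
  20 m/s).

## 9. Limitations

- Central-force bead networks cap ν near 0.25 (see §3); the FE body uses
  the sampled keratin ν directly, so the two descriptions agree on E but
  not on ν.
- The LJ potential is energy-shifted (not force-shifted); forces are exact
  for the truncated potential but have the usual cutoff discontinuity.
- Junction meshes contain non-manifold boundary pinch edges (§1).
- Mini-scale runs are single realisations: detachment ordering and exact
  force minima vary with seed (§7).
- The full-scale 16-spatula system (~250 000 beads, hundreds of ns) is out
  of desk-scale reach; the package exposes it through the same APIs but the
  CLI deliberately refuses to launch it.
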