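# Methods

`mechanofate` simulates a mesenchymal stem cell (MSC) migrating through a
three-dimensional linear-elastic substrate, probing its stiffness by
contracting against it, and choosing a fate — osteogenic, chondrogenic or
neurogenic commitment, proliferation, or apoptosis — from the deformation it
senses. This note records the model, its numerical treatment, and the design
choices made where the underlying formulation is open or under-determined.

## Substrate

The substrate is a box (default 400 x 200 x 200 um) of a homogeneous,
isotropic, linear-elastic material with Young's modulus `E` (the experimental
variable, 0.1-45 kPa), Poisson ratio `nu = 0.3` and viscosity
`eta = 1000 Pa s` (entering only through Stokes drag). It is meshed by a
regular grid of 8-node trilinear hexahedra (default 40 x 20 x 20: 16,000
elements, 18,081 nodes, 10 um edge), integrated with 2x2x2 Gauss quadrature.
All surfaces are traction-free. Because free-floating elasticity has a
six-dimensional rigid-body nullspace, three corner nodes carry a standard
3-2-1 constraint set (3 + 2 + 1 translational components). Sensing loads are
self-equilibrated, so the constraint choice only fixes the rigid motion; a
unit test verifies the strain field is insensitive to the corner chosen. The
constrained stiffness is factorised once per scenario (SuperLU) and reused by
every solve of every step. Units are um / kPa / nN / hours, which are
mutually consistent (kPa um^2 = nN).

## Cell and mechano-sensing

The cell is a sphere of radius `r_cell` with `n_mem = 24` membrane nodes.
The radius is not part of the published parameter set; the default is 20 um
(twice the element edge), configurable. The 24 directions are the vertices of
a rhombicuboctahedron: deterministic, vertex-symmetric, summing to zero
exactly, with a 30.3 deg covering radius — chosen so that two touching cells
share between one and four "common" membrane nodes under the contact rule
below. Each node represents an equal share `S_node = 4 pi r^2 / n_mem` of the
membrane area.

The stress a node transmits is the sum of a passive (microtubule/membrane)
and an active (actin-myosin) contribution: passive `K_pas * eps` outside the
active strain window `[eps_min, eps_max]`, and inside it an additional active
branch that peaks at `sigma_max` when `eps = sigma_max / K_act`. The law is
continuous at its three breakpoints (tested to 1e-12). Contraction is
measured by the per-node internal strain `eps_i` — the node's inward
displacement divided by the radius — stored positive under contraction, while
the 1-D stress law is evaluated on the signed axial strain (compression
negative). With this sign the active stress falls as the cell deforms,
making the sensing loop self-limiting on arbitrarily soft substrates; this
sign convention is a deliberate resolution of an ambiguity in the source
formulation and is flagged as such below.

Mechano-sensing is a self-consistent loop: every active node pulls the
substrate toward the centroid with force `sigma(eps_i) * S_node`, the FE
system is solved, and `eps_i` is re-read from the displacement at the node.
Because the stress law is affine on each branch and the substrate linear,
the fixed point is well-defined; numerically it is found by a warm-started
quasi-Newton iteration whose Jacobian uses the membrane compliance matrix
`C[i,j]` (inward strain at node i per unit inward force at node j),
tabulated on a ~40 um grid of cell positions and interpolated trilinearly.
The naive sweep diverges when the collective cell/substrate stiffness ratio
exceeds one (soft substrates); the quasi-Newton update converges in 2-3 FE
solves per step everywhere, with an exact direct solve of the
piecewise-affine system as fallback. Convergence tolerance is 1e-6 on the
strain, cap 50 sweeps, with a warning (never observed in practice) on
failure.

## Traction, protrusion, migration

Each node carries a traction force `sigma(eps_i) * S * zeta_i` along its
inward direction, where the adhesivity `zeta = k n_r psi` differs between the
cell front (`n_rf = 1.5e5` receptors) and back (`n_rb = 1e5`); a node is
"front" when its outward direction has non-negative projection on the
previous polarisation. The protrusion force is random: magnitude
`kappa |F_trac_net|` with `kappa ~ U[0,1)`, direction uniform on the sphere.
The force balance `F_trac + F_prot + F_drag = 0` defines the drag, the
polarisation `e_pol = -F_drag/|F_drag|`, the Stokes speed
`v = |F_drag| / (6 pi r eta)` and the translocation `d = v tau e_pol` per
step (`tau = 6 h`).

A known dimensional inconsistency of the formulation is inherited
deliberately: with `zeta ~ 1e8` the traction forces are ~1e9 nN, so the
Stokes step length vastly exceeds the box and every translocation is clamped
by the box/separation constraints. The cell therefore explores the box in
large jumps rather than by smooth crawling. All fate outcomes depend on the
force *ratios* and on the sensed strain field, neither of which is affected
by the overall traction scale; traction traces are meaningful up to that
constant factor, and the discontinuity detection used on them is scale-free.

## Cell-cell interaction

Cells are impenetrable: after every step all centroid pairs satisfy
`|x_ij| >= 2r` (violations are resolved by symmetric projection along the
pair axis, swept in id order) and centroids stay at least `r` inside the box.
When two cells approach within `2r + delta_c` (`delta_c = 0.25 r`), membrane
nodes within `r + delta_c` of the partner's centroid become "common" nodes:
they stop exerting sensing forces, but keep their traction contribution.
Flags are recomputed each step, so nodes reactivate on separation.

## Mechanical signal, maturation and fate

The decision variable is the mechanical signal
`gamma = | sum_i e_pol . eps_i . e_pol |`, the substrate strain tensors at
all membrane nodes projected on the polarisation direction. The raw sum is
negative under contraction while the published thresholds are positive, so
its absolute value is used (an explicitly flagged interpretation).

Maturation time falls linearly with signal strength inversely:
`t_mat = t_min + t_p gamma` (`t_min = 4 d`, `t_p = 200 d`). Each cell carries
a maturation index MI in [0,1], accrued incrementally as
`dMI = tau / t_mat(gamma(t))` and capped at one. For constant gamma this
reproduces `MI = t / t_mat` exactly; the incremental form honours the
irreversibility of maturation under a time-varying signal (MI resets only on
differentiation). A fully mature MSC differentiates by signal band —
osteoblast for `gamma in (0.005, 0.04]`, chondrocyte in `(0.04, 0.1]`,
neuroblast in `(0.1, 0.5]`; any cell dies when `gamma > 1`; any fully mature
cell divides when `gamma <= gamma_prof` (0.2 for MSCs; the same default is
used for the differentiated phenotypes, whose limits are not published, and
each is configurable). When an MSC satisfies differentiation and division
simultaneously, the default resolution is to divide with both daughters
carrying the new phenotype at MI = 0; `differentiate_only` and a
probabilistic 50/50 variant are available as configuration switches. One
daughter keeps the mother's position; the other is placed at
`x + 2 r e_rand`, redrawing the random direction (up to 100 times) until the
position is inside the box and clear of every other cell, deferring the
division one step otherwise.

Differentiated phenotypes keep the MSC mechanical parameter set: no
published values exist for lineage-specific contractility. Consequently the
traction trace does not intrinsically shift at a differentiation event that
is not accompanied by a division — see limitations.

## Stepping and reproducibility

Per step, cells are processed in id order: sensing, traction, protrusion,
force balance, signal, maturation accrual, fate decision; then the
separation constraints are enforced, events applied, and the clock advanced
by tau. One seeded PCG64 generator drives each replicate, with kappa and the
random directions drawn in fixed order, so a replicate is bitwise
reproducible from its seed. Replicate seeds are spawned from the scenario
seed via `SeedSequence`.

## The reference protocol and its scale

The bundled six-scenario protocol (E = 0.1, 1, 20, 25, 30, 45 kPa; one MSC
at a corner; 10 seeds each) is the package's standing experiment. It runs on
a 200 x 100 x 100 um box meshed 20 x 10 x 10 — half the full domain at the
*same* 10 um element size. The element size sets the effective substrate
stiffness a point-loaded membrane node feels, and hence every sensed strain
and fate time; keeping it native preserves those quantities while cutting
each sweep to minutes on one CPU. Only the weak interaction with the distant
walls differs from the full-size domain. Horizons are 50-200 days by
scenario class, with early stopping a few steps after the last event the
protocol measures. Replicate-to-replicate variance is small (the signal is
dominated by geometry, not noise), so ten seeds give tight means.

## Known limitations

- The cell is rigid and spherical; contact is purely geometric (no adhesion
  energy, no shape change).
- The substrate is purely elastic with no degradation or remodelling;
  viscosity enters only through drag.
- Migration is dominated by the clamped large-step regime discussed above;
  trajectories should be read as "which part of the box the cell samples",
  not as literal crawling paths.
- Phenotype does not (yet) modulate contractility, so neurogenic
  differentiation leaves no signature in the traction trace; and because the
  front/back adhesivity split re-partitions as the polarisation reorients
  each step, the mean-traction trace carries a few-percent noise floor that
  can mask the (otherwise visible) up-jump cell-cell contact produces at a
  division.
- Fatigue apoptosis under cyclic strain, chemotaxis, oxygen/nutrient
  limitation and myogenic/adipogenic lineages are out of scope.
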