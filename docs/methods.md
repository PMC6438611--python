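# Methods

`acinusfsi` simulates quiet breathing of an idealized human pulmonary
acinus and compares acinar mechanics and lung function between healthy
tissue and two fibrosing interstitial-pneumonia patterns (NSIP-like
uniform septal thickening; IPF-like thickening confined to the primary
septa). This note records the model, its assumptions, the numerical
choices, and what the reduced desk-scale fidelity does and does not
establish.

## Geometry and disease scenarios

The acinus is assembled from truncated octahedra (14-hedra) packed
space-fillingly on a body-centred-cubic lattice, the classic idealization
of the alveolar duct tree. One parent duct cell (generation 1) opens into
two sac-duct cells (generation 2); each alveolar sac is an elongated
two-cell lumen carrying 12 alveolar cells that open into it through
removed interconnecting faces (hexagonal faces preferred — they are the
larger openings; the pattern is a deterministic hex-first greedy walk
along each sac axis). One hexagonal face of the parent duct, symmetric
between the two sacs, is the single open (mouth) boundary. In total:
29 cells, 28 opened interconnections, 24 alveoli.

Walls are classified *primary* (facing the acinus exterior) or
*secondary* (partitioning the interior). Every septum is centred on its
lattice interface — the mid-surface convention — so each lumen face
recedes by half the local wall thickness. Scenario parameters (septal
thicknesses, the equivalent small-strain modulus E = 35,714 Pa, Poisson
ratio 0.42, and target resting volumes 0.512 / 0.493 / 0.465 mm^3 for
healthy / NSIP / IPF) are data; the one free geometric parameter, the
lattice edge length, is calibrated by a root solve so the resting lumen
volume (sum of per-cell half-space-intersection volumes) matches the
scenario target with thicknesses held in absolute mm. This is equivalent
to "thicken inward, then rescale globally" and reproduces the targets to
much better than 1%. A consequence worth noting: thickening narrows the
duct orifices even after the rescale, which is the mechanism behind the
elevated diseased airway resistance.

The nominal anatomical dimensions (duct diameter 0.274 mm, sac length
1 mm) are carried as metadata; the calibrated model lands close to them
(mouth diameter ~0.19 mm, sac span ~1.3 mm) without being constrained by
them.

## Solid: Neo-Hookean septal shell

Tissue follows the modified compressible Neo-Hookean law
W = K U(J) + (G/2)(J^(-2/3) I_C - 3), U(J) = (J^2 - 1 - 2 ln J)/4, with
K = E/(3(1-2nu)) and G = E/(2(1+nu)). The walls are thin (0.025-0.050 mm
against a ~1 mm acinus), so the solid is solved in a reduced shell mode:
constant-strain-triangle membranes at plane stress (the thickness
stretch is condensed per element by a scalar Newton solve of S33 = 0)
plus discrete-shell hinge bending on interior manifold edges with
stiffness k_b = E t^3 / (12 (1 - nu^2)). The bending term is not a
regularization convenience only: a pure membrane on a faceted surface
has zero-energy unfolding modes, and the measured compliance of the
model is genuinely membrane-plus-bending. Edges where three or more
walls meet (septal junction lines) carry no hinge; the junction is held
by the membranes themselves.

Loads are follower pressures per element: the intrapleural pressure acts
on the outside of the primary septa, alveolar air pressures on the inner
faces; interior septa see the (near-zero) pressure difference between
their two compartments. The mouth rim is clamped — the acinus hangs off
its feeding bronchiole. Inertia is dropped (quasi-static stepping):
breathing at 0.25 Hz with tissue densities of order 1e3 kg/m^3 gives
inertial stresses many orders below elastic ones, and no tissue density
is part of the scenario data. Equilibria are found by Newton iteration
(relative residual 1e-8, maximum 25 iterations, load sub-stepping on
divergence) with a finite-difference consistent tangent assembled
element-wise, step capping along soft modes, and reuse of the factorized
stiffness across the small per-time-step load increments.

Verification: the membrane sphere under internal pressure matches the
Lamé thin-shell closed form within 5% at small strain and an exact
scalar Neo-Hookean membrane solution within 2% at finite strain;
doubling the thickness halves the inflation.

## Fluid: duct network (default) and 3D Stokes

The in-model Reynolds number is ~0.07, so airflow is viscous and
instantaneous. The default cycle-time fluid is a Kirchhoff network on
the compartment graph: each opened face is a thin-wall orifice with
Sampson resistance 3 mu / r^3 in series with Hagen-Poiseuille lumen
segments (compartment volume-equivalent radii); compartment wall motion
enters as volume sources dV/dt and the mouth node is pinned at zero
(open-boundary) pressure. Mass conservation per step is then exact up to
the sparse-solver tolerance. Air properties default to humid air at
37 C (rho = 1.145 kg/m^3, mu = 1.86e-5 Pa s), configurable.

A 3D stabilized MINI-element (P1+bubble / P1) Stokes solver provides the
field-level reference on tet meshes: it reproduces Poiseuille tube flow
within 3% at modest resolution (monotone under refinement), and wall
shear stress within 5% away from the ends via variationally consistent
boundary-flux recovery. The network conductances agree with the 3D
solve on the same tube within 10%. The convective term is omitted
(Stokes) — at Re ~ 0.08 its contribution is far below discretization
error; this is the package's default and only 3D regime.

The Reynolds number reported for a run uses the conventional
characteristic scales of a lumped model: peak flow over the nominal
acinar-duct cross-section, with the 1 mm sac length.

## Coupling

A partitioned Gauss-Seidel exchange per time step: solid solve under the
current loads, envelope volume update, BDF2 volume rates (BDF1 on the
first step), network flow solve, alveolar pressures fed back — with
Aitken dynamic under-relaxation until the interface displacement
residual falls below 1e-6 relative (a loose single-exchange mode mimics
classic explicit staggering; at this coupling strength the two agree to
0.1%). The air gains the volume the outer envelope sweeps (tissue
treated as volume-preserving at these strains), distributed over
compartments by resting share; per-compartment re-partitioning of the
deformation is a fidelity the lumped fluid does not need.

The driving waveform is p_IP(t) = -p0 (1 - cos(omega t))/2 with p0 =
244 Pa (~2.5 cmH2O) and omega = pi/2 1/s (4 s cycle), starting from the
resting volume. Because the tissue is quasi-static and elastic, the
nodal volume trajectory is independent of dt and cycles repeat exactly
(periodicity is asserted at 1%); the time-step error enters through the
BDF2 flow differentiation, which converges at second order on
dt in {0.02, 0.01, 0.005} s once solver tolerances are tightened below
the truncation error. Identical configurations reproduce bit-identical
scalar histories.

RBF interface transfer (Wendland C2 kernel, linear polynomial
augmentation; displacement forward, traction by the transpose operator)
is provided for non-conforming interface meshes and verified to
reproduce affine fields to 1e-10 and conserve total force exactly; the
default shell + network pipeline exchanges on conforming surfaces, where
the map reduces to the identity. Fluid-mesh motion for the 3D mode is a
graph-Laplacian diffusion of boundary displacement with inversion
detection.

## Problem sizes and defaults

Defaults were chosen once as a desk-scale compromise: shell subdivision
level 1 (~5,800 triangles, ~8,600 hinges, ~8,300 dofs), dt = 0.01 s,
2 cycles (metrics on the last), full trio ~10-12 minutes on one CPU.
The conforming "hydraulic" fluid tet mesh (scaled to the exact lumen
volume; the exact per-cell offset lumina are non-conforming at shared
openings and serve all volume bookkeeping instead) stays below 2.1k
cells at level 0 and 17k at level 1 — far below the published
multi-million-element meshes this model is scaled down from. Property
tests and parameter-recovery runs use level 0 and dt = 0.04-0.05 s.

## What the model reproduces, and what it does not

At the reference protocol the model reproduces healthy tidal volume
(+6% of the published 0.0766 mm^3), NSIP tidal volume (+7%), peak flows
(+9%), the ~47% compliance decrease (45.5%), the ~43% maximum
pressure-drop decrease (33.5%), the NSIP-over-IPF resistance contrast
(+4.4% against the published +4.5%), the resistance ordering
NSIP > IPF > healthy, the healthy-over-diseased wall-shear ordering, a
peak principal stress of the same magnitude as published (7.7 kPa vs
8.4 kPa, with the primary-septa region near the duct junction maximal),
and Re_max ~ 0.067 (published 0.08).

Known limitations, all consequences of the desk-scale shell idealization
with flat walls:

- **IPF is too compliant.** With secondary septa at half thickness, the
  IPF shell is ~20% softer (size-corrected) than NSIP, so its tidal
  volume overshoots (+30% of the published value) and the published
  near-equality TV_NSIP = TV_IPF — which the original study obtained by
  construction when assigning resting volumes — does not emerge: here
  TV_IPF > TV_NSIP by ~20%. Downstream, the NSIP-vs-IPF maximum
  pressure-drop contrast flips sign (-13% instead of +5.5%).
- **Diseased resistance increases are overstated** (+20-26% instead of
  +6-11%): in this geometry the septal rims encroach the duct orifices
  more strongly, in relative terms, than in the published CAD model
  whose duct caliber was largely preserved.
- Surface tension and surfactant dynamics, viscoelasticity, septal
  contact, and alveolar-wall perforations (pores of Kohn) are not
  modelled; secondary septa are complete walls rather than partial
  ridges, which overweights their mechanical share.
- The synthetic geometry is an idealized lattice: passing tests
  establish the solver chain and the scenario contrasts above at desk
  scale, not patient-level predictions.
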