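# Methods

## Model and discretisation

Both tissue compartments satisfy the monodomain equation; the myocardium
in three dimensions on a uniform lattice of cubic control volumes
(spacing `h_M`, unknowns at volume centres), the Purkinje system in one
dimension on segment volumes of length `h_P` arranged in a rooted tree.
Only *active* lattice sites are stored, so wedges and irregular shapes
are the same data type as full cuboids; neighbour lookup is a hash (in
practice a sorted-code binary search) over integer lattice indices.

Finite-volume face fluxes are assembled as follows. For a myocardial
face shared by volumes i and j along axis a, the conductivity tensor at
the face is the arithmetic mean of the two adjacent tensors; the normal
flux uses the two face-adjacent volumes, and the tensor's off-diagonal
(cross-derivative) components use centred differences over the face's
four lateral neighbour pairs. A pair with a missing member is dropped
whole, which preserves zero row sums and hence exact no-flux boundaries.
For axis-aligned fibres the scheme reduces exactly to the classical
7-point anisotropic Laplacian (verified against an independent oracle in
the tests). Because the cross-term stencil is not symmetric volume by
volume in heterogeneous tissue, the assembled stiffness is explicitly
symmetrised, `K <- (K + K')/2`, and the maximum relative asymmetry is
recorded; if it exceeds 1e-8 the solver switches from CG to BiCG.
Purkinje faces use the harmonic mean of the two adjacent segment
conductivities; a branching volume accumulates one downstream flux per
child, and a terminal volume carries only its upstream flux plus the
junction source.

Units are closed in uA: the mass term `h^3 beta C_m / dt` multiplies mV
and yields uA-scale quantities, face couplings are `sigma * h` (mS * cm),
and junction currents are mV/kOhm = uA. Purkinje control volumes are
treated as regular hexahedra of side `h_P` for their volume measure.

## PMJ coupling

Each terminal couples to its `N_PMJ` nearest myocardial volume centres
(Euclidean distance; exact ties broken by ascending lattice (i, j, k)
order, making the map deterministic and independent of storage order).
At each step the junction current to coupled volume k is
`(V_P - V_Mk)/R_PMJ` uA, applied to the myocardial volume, with the
equal-and-opposite sum applied to the terminal volume. The reciprocal
myocardial term is required by flux continuity across the junction —
without it anterograde activation cannot occur at all — even though the
formulation is usually written only for the terminal side. Conservation
(all junction currents summing to zero) is asserted at every step in the
tests.

## Time integration

Godunov splitting per PDE step of length `dt_pde`: an integer number of
reaction sub-steps of length `dt_ode` (forward Euler, or Rush–Larsen for
Hodgkin–Huxley gates, which is exact for frozen rates and keeps gates in
[0, 1] for any dt), junction currents evaluated at the half step, then
two independent backward-Euler diffusion solves with the junction
currents as right-hand-side sources. The scheme is first order in dt;
the tests confirm the error halves when both steps halve. Defaults
`dt_ode = 0.01 ms`, `dt_pde = 0.02 ms`.

Evaluating the junction explicitly decouples the two linear systems but
bounds the stable timestep from below in `R_PMJ`: the junction
conductance `N_PMJ / R_PMJ` against the terminal's small mass
`h_P^3 beta C_m` produces an amplification factor proportional to
`dt * N_PMJ / (R_PMJ h_P^3 beta C_m)`. Divergence is detected by a
|V| > 500 mV guard (and a non-finite check) at every step; an unstable
run stops, is flagged, and never emits silent NaNs. Instability is
reported distinctly from propagation block.

## Linear solvers

Jacobi-preconditioned conjugate gradient with an explicit convergence
contract (relative tolerance 1e-10 on the preconditioned residual,
maxit 5000, warm start from the previous time level; both raw and
preconditioned residuals reported, breakdown causes named), plus an
unpreconditioned BiCG for operators whose assembly asymmetry exceeds the
symmetrisation tolerance. Both are cross-checked against dense direct
solves and scipy's implementations in the tests.

## Ionic models

* `mitchell_schaeffer` — a two-variable phenomenological model rescaled
  to physiological voltages (`V = -85 + 110 u` mV). Parameters (ms):
  `tau_in = 0.15`, `tau_out = 6`, `tau_open = 120`, `tau_close = 150`,
  `u_gate = 0.13`. `tau_in` sets the maximum upstroke (~100 mV/ms at the
  default, in the physiological range for working myocardium); the rest
  state (−85 mV, 1) is an exact fixed point. This is the default for
  both domains: calibration experiments only need the depolarisation
  sequence, for which the model is adequate and roughly two orders of
  magnitude cheaper than a biophysical cell.
* `tentusscher` — the ten Tusscher–Panfilov 2006 epicardial human
  ventricular cell, 19 state variables, all twelve gates integrated with
  Rush–Larsen. The shipped rest state is the model's quiescent (unpaced)
  equilibrium, polished to machine precision with a Newton solve; it
  differs from the paced steady state usually quoted (notably lower
  intracellular Na+), because without pacing the Na+/K+ pump drains
  sodium until the fluxes balance.

Currents use the per-capacitance convention (pA/pF = mV/ms at
C_m = 1 uF/cm2), so stimulus amplitudes are specified directly in pA/pF;
`C_m` enters the PDE mass term separately.

## Delay measurement and sweeps

Activation time is the first recorded sample with V >= −40 mV, without
interpolation; PMJ-site traces are recorded every PDE step, so delays
are quantised at `dt_pde` (0.02 ms by default). The anterograde PMJ
delay is the activation-time difference between a terminal's nearest
coupled myocardial volume (first entry of its distance-sorted coupling
list) and the terminal itself. A terminal that activates while that
volume never does is a block; a run that tripped the voltage guard is
unstable; delays are defined only for `ok` records. Calibration runs use
a 50 ms window, long enough for anterograde activation and short enough
to keep a full sweep cheap.

Factorial sweeps are the Cartesian product over named configuration
fields in lexicographic axis order, with equispaced values inclusive of
both endpoints; each run's directory name encodes its parameter values
and is stable across platforms. The dispatcher executes each run once in
its own directory over a process pool, isolates failures, and sorts
aggregates by run name so output tables are byte-identical for any
worker count.

## Synthetic fixtures: what they do and do not show

The generators produce cuboid/cable/wedge voxel grids and cable or
symmetric-binary-tree Purkinje networks (bifurcations at ±45 degrees in
a plane; coordinates only matter for PMJ distances). The wedge fixture —
a 0.5 × 0.5 × 0.25 cm slab at h = 250 um activated by one cable
terminal, transversely anisotropic bulk (1.334 / 0.176 mS/cm), optional
isotropic endocardial layer — reproduces the qualitative junction
physics: delay grows with `R_PMJ` up to block, falls with `N_PMJ`, falls
under myocardial refinement, grows under Purkinje refinement, and grows
with endocardial conductivity, with delays in the physiological few-ms
range. Two caveats. First, an end-of-cable terminal has no downstream
network to support it, so under very strong coupling (R_PMJ well below
~300 kOhm combined with large N_PMJ) the terminal itself can be dragged
subthreshold — trend experiments therefore use moderate resistances,
well inside the 100–2500 kOhm calibration range. Second, fixtures are
not anatomical: passing trend tests demonstrates the coupling model and
numerics, not patient-specific activation patterns, fibre fields or
clinical ECG morphology.

The spatial-convergence experiment runs on a 0.4 cm cable with one-voxel
cross-section rather than a full 1 cm cuboid: with no-flux boundaries
the planar-wave problem is effectively one-dimensional, so the
activation-time error at h = 250 um and 500 um against the 50 um
reference can be measured in seconds at the same physics. Problem sizes
throughout the test suite (4000-volume wedges, 8–100-volume cables) were
chosen so the full suite and the acceptance script each run in about a
minute on a single CPU.

## Numerical choices and edge cases

* Lattice indexing is 0-based; centres at `(index + 1/2) h`; region and
  stimulus boxes are half-open `[lo, hi)`.
* Fibre triads default to canonical axes; an explicit fibre axis is
  completed to an orthonormal triad using the least-aligned canonical
  axis as seed.
* The network text format stores conductivity per edge; internally each
  node takes its incoming edge's value (the root its first outgoing
  one), and faces use the harmonic mean of the two adjacent node values,
  which reproduces the two-segment composite-cable face exactly.
* CG declares convergence on the preconditioned residual; a warm start
  that already satisfies the tolerance returns with zero iterations
  (this happens at rest, where the uniform state is an exact solution).
* The activation map records −1 for volumes that never cross threshold.
* EnSight Gold output is binary (little-endian, 80-byte padded record
  headers, float32 payloads), one hexa8 part per domain, per-element
  scalars — matching the control-volume-centred unknowns; VTK legacy
  output offers ascii and big-endian binary modes with identical content
  at float32.

## Known limitations

Voxelised geometry introduces staircase boundaries; only activation
propagation is modelled (no extracellular stimulation or bath loading,
and the pseudo-ECG ignores torso geometry entirely). The explicit
junction coupling bounds the usable timestep at small `R_PMJ`. The
ten Tusscher implementation follows the published epicardial variant but
its exact waveform is not load-bearing anywhere in the package's
guarantees; anatomical Purkinje networks must be supplied as files (the
built-in generators produce idealised fixtures only).
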