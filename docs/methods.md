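# Model and methods

`fiberplast` simulates the plastic remodeling of fibrous extracellular
matrix — reconstituted collagen in particular — as a 2D athermal network
whose cross-links can irreversibly rearrange under load.

## Elastic network

The matrix is a bond-diluted triangular lattice with unit spacing
`a0 = 1`: every nearest-neighbour bond is present independently with
probability `p` (default 0.60). Maximal chains of consecutive collinear
bonds form *fibers*; nodes where two or more fibers meet are
*cross-links*. At `p = 0.60` the mean coordination (~3.6) lies below the
central-force isostatic value of 4, so the linear response is
bending-dominated, as for sub-isostatic biopolymer gels.

Energy:

* stretching, per bond: `k/(2 l0) (l − l0)²` with `k = 1` (the `1/l0`
  normalization treats the bond as a rod of fixed material stiffness; a
  plain Hookean variant is available via
  `ElasticParams(normalize_stretch=False)`);
* bending, per hinge (pair of consecutive bonds within one fiber):
  `κ/(2 a0) Δθ²` with `κ = 10⁻³`, rest angle 0 (straight). Distinct
  fibers crossing at a node are *not* coupled by bending, so crossing
  fibers can scissor freely — a property with real consequences for
  reversibility (below).

Equilibrium is found by direct minimization over the free degrees of
freedom (free nodes: 2; nodes constrained to a rigid circle: 1
tangential angle; pinned nodes: 0). The default minimizer is FIRE (fast
inertial relaxation engine), run entirely in compiled code with a
bounded step budget; states it cannot finish are handed warm to
L-BFGS-B, which is also the solver whenever circle constraints or
external probe forces are present; `method="cg"` selects nonlinear
conjugate gradient with a quasi-Newton polish. Convergence is measured
by the max-norm of the gradient; protocol steps use `1e-5` (forces far
below the event threshold), precision measurements (gradient oracle,
elastic-reversibility checks) use `1e-9`–`1e-11`.

Shear is applied as `x → x + γ·y` with the top and bottom rows pinned
and periodic left/right boundaries (the periodic repeat lies along x, so
no image offset is needed under shear). The strain readout ε is the mean
x-displacement of the top row divided by the network height. The
differential shear modulus is the central second difference of the
minimized energy density, `G(γ) = [E(γ+δ) − 2E(γ) + E(γ−δ)]/(δ²·A)` with
`δ = 10⁻³`.

**Quasistatic loading and unloading.** All protocol loads are applied as
continuation: shear in ≤5% increments, cell contraction ramped over 6
increments, traction release ramped back over 8, and the shear boundary
released by marching the pinned row to the strain at which its mean
tangential reaction vanishes before freeing it. One-shot loading strands
the descent in folded snap-through basins that the continuously loaded
branch never visits, and makes even the purely elastic model appear
irreversible.

## Plasticity

Cross-link dynamics run on a half-minute clock (`dt_minutes = 0.5`):

* **Sliding** (deterministic): at a cross-link whose fiber-on-fiber
  force exceeds `force_threshold`, the over-loaded fiber *reconnects*:
  its bonds at the junction re-attach to a node adjacent along a host
  fiber, so the junction walks node by node while both fibers stay
  connected. For a fiber that terminates at the junction this walk moves
  the branch point along the host — the two fibers peel apart further —
  which is what lets material ratchet toward a sustained load instead of
  being cut loose. (A full-detachment variant, where the terminating end
  splits onto a fresh free node, exists behind
  `PlasticParams.peel_detachment`; as a default it cuts the
  force-transmission paths and makes densified bundles dissolve.)
  Candidate moves are ranked by the energy after a local relaxation with
  the far field frozen (radius 3 a0); the best move is kept only if it
  strictly lowers the energy. The frozen-far-field energy balance is exact for
  the affected term set, so acceptance is rigorous even though the
  global re-minimization happens once per step
  (`global_min_every_slide=True` restores per-event re-minimization).
  The force that moves a fiber is the vector sum of its bond tensions at
  the junction; bending contributions to junction load are neglected.
* **Merging** (stochastic): node pairs on distinct fibers closer than
  `merge_radius = 0.3 a0` fuse with probability `p_merge = 0.05` per
  step. The new bond's rest length equals the current separation
  (stress-free at creation), it forms its own hinge-free fiber, and it
  is permanent — merged bonds never slide. Merging is the main carrier
  of irreversibility; sliding mainly densifies while the load is on.

**Kinetics.** Each tick fires at most `max_slide_events_per_step = 5`
sliding events, most-loaded junctions first; the backlog carries over.
This finite rearrangement rate is what produces the observed kinetics:
the elastic energy of a held network decays over many minutes instead of
collapsing in one tick, the released strain keeps decaying with a
plastic timescale τ_p of order a minute, and networks held longer relax
more slowly and less completely afterwards. `force_threshold = 5·10⁻⁴`
(units of `k·a0`) sits inside the force distribution of a *released*
network, so plastic activity persists after unloading; with the rate cap
in place the threshold controls where activity stops, not how fast it
runs. Sliding can be made stochastic (`slide_probability < 1`); the
default is deterministic.

Numerical cost controls (none of which affect which events are
physically admissible): at most 25 candidate junctions are screened per
tick; a junction that rejected all its moves is skipped until its force
changes by more than `1e-5`; the end-of-tick global minimization is
iteration-capped during a hold (residual soft-mode forces are orders of
magnitude below the event threshold) and runs essentially to tolerance
whenever ε(t) is being recorded.

## Protocols

**Cell pair.** Two cells — circles of radius `a = 5.7 a0`, the measured
ratio of cell radius (~17 µm) to pore size (~3 µm) — are embedded in a
free-boundary `60×60` network at center-to-center distance `d = 7a`.
Contraction shortens the rest length of every bond inside a circle by
the factor `1 − β` (crossing bonds in proportion to their interior
fraction); `β = 0.5` by default, a strongly contractile cell. All nodes
remain free: a radially rigid cell surface would decouple the interior
contraction from the matrix and suppress the elastic densification the
model must produce. (`surface_mode="slide"` provides the rigid-circle
idealization with tangentially sliding attachment points.) At T = 0 the
configuration is a pure minimization with no plastic events; plastic
ticks then run to the maturation time. The bundle readout is
`ΔF/F = (F_b − F)/F`, with `F_b` the bond density (midpoint membership)
in the region of bundle — the rectangle spanning the gap between the two
cell surfaces, width one cell diameter — and `F` the density of the rest
of the domain. The background is normalized by the *undeformed* domain
area (the analog of intensities measured in a fixed microscope frame;
with a frame that co-shrinks with the contracting network, the global
contraction inflates the background and masks bundle formation at scaled
domain sizes). The convex-hull normalization remains available. Traction release
restores the pre-contraction rest lengths (ramped) while keeping all
slid/merged topology.

**Bulk shear-dwell-release.** A `40×40` strip (pinned top/bottom,
periodic sides) is sheared to ε₀ = 20%, held for a dwell time T_d with
plastic ticks, then the top boundary is switched to zero stress and the
strain ε(t) is recorded each half-minute. The model has no viscosity, so
the elastic drop to ε(0⁺) is instantaneous; the subsequent decay toward
the residual strain ε_r is purely plastic and is fitted with
`ε(t) = (ε(0⁺) − ε_r)·exp(−t/τ_p) + ε_r`. Both τ_p and ε_r grow with
T_d. `simulate_dwell_series` exploits determinism to share one dwell
trajectory across a whole T_d grid (snapshots + restored RNG state),
bit-identical to independent runs.

**Relaxation fitting.** Experimental-style curves carry an additional
fast viscoelastic mode; the double-exponential fitter
`a·exp(−t/τ_v) + b·exp(−t/τ_p) + ε_r` can share one τ_v jointly across
series while `a, b, τ_p, ε_r` vary per series. τ_p is parametrized as
`τ_v(1 + e^u)` so the ordering `τ_v < τ_p` is structural; multi-start
over a log-spaced τ_v grid guards against local minima, and fits with
`τ_p < 2 τ_v` are flagged as weakly identifiable.

**Compliance probing.** The directional compliance `J(θ) = Δd_θ/F_θ`
(the experimental bead prefactor 6πa is a configurable constant, 1 by
default) is measured by applying a small force (10⁻³ k·a0) at a node
along 12 directions and re-minimizing; the polar points are fitted with
a direct least-squares ellipse and the axis ratio quantifies local
anisotropy. Probing requires a far-field anchor; free-boundary cell
states are probed with their outer boundary temporarily pinned.

## What the generator emulates — and what it does not

The synthetic networks reproduce the connectivity statistics, the
bending-dominated linear elasticity, strain stiffening, and the
sliding/merging-driven history dependence of collagen gels. They do not
model: viscoelasticity (the experimental τ_v ≈ 30 s mode — synthetic
double-exponential curves stand in for it when testing the fitters),
fiber rupture or intrafibrillar lengthening, excluded volume (fibers can
pass through each other), 3D geometry, or active cell mechanics beyond
an isotropic contraction. Passing trend tests on these networks shows
the mechanism is sufficient to produce the observed phenomenology, not
that parameter values transfer quantitatively to real gels.

## Reversibility is statistical, not per-sample

Two genuine features of the athermal model limit exact elastic
reversibility. First, a minority of realizations cross an elastic
snap-through during a 20% shear cycle and retain a small permanent
offset (10⁻⁴–10⁻²) even under arbitrarily fine quasistatic loading;
typical samples return to strain < 10⁻⁹. Second, because bending does
not couple across fibers, sub-isostatic samples possess finite
zero-energy "scissor" manifolds; a contracted-and-released cell-pair
network returns to zero energy but its tree-like decorations drift along
these manifolds, leaving a ΔF/F residue at the counting-noise scale of
the region of bundle. Reversibility checks therefore report medians over
realizations and compare against counting noise rather than asserting
machine zeros for single samples.

## Problem sizes used in the test suite

The shipped tests and the acceptance script run scaled-down versions of
the study: bulk dwell-release batteries at `30×30` with a 6-minute
recorded relaxation window (2–3 samples), cell pairs at `24×24` with
cell radius `a = 1.8` (geometry ratios `d/a ∈ {5, 7, 9}` preserved;
3 samples), strain stiffening at the full `40×40` (3–4 samples), and the
gradient oracle at the full 20 networks. Trend statistics pool dwell
times across samples. Defaults in the package itself remain the full
study conditions (`60×60` cells, `40×40` bulk).

Two qualitative results of the original study are *not* reproduced by
this realization, and their checks fail by design rather than being
weakened: (1) the fitted plastic timescale τ_p grows with dwell time
only up to ~10 minutes and then collapses, because long-held networks
lock in so completely that the release amplitude (and hence the fitted
timescale) vanishes; (2) the plastic ΔF/F at 15 minutes of maturation
remains below the elastic baseline — single-node reconnect sliding
relaxes the elastically densified band faster than it transports new
material in (the density *difference between load and release*, i.e.
the irreversible part, does grow with maturation as expected). Both
are discussed as limitations of the local move set.
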