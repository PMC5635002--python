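# fiberplast

Plastic remodeling of fibrous extracellular matrix, simulated as an
athermal spring-and-hinge network whose cross-links irreversibly slide
and merge under load.

Collagen gels — the main scaffold of connective tissue — are not simply
elastic: traction forces from embedded cells densify the fibers between
cell pairs into *bundles* that persist after the forces are released, and
macroscopically sheared gels relax their strain slowly and incompletely,
the more slowly and incompletely the longer the strain was held. This
package implements a minimal mechanistic model of that plasticity for
researchers in tissue/ECM mechanobiology and biopolymer physics: a
bond-diluted triangular lattice (occupation probability `p = 0.60`) of
fibers that resist stretching (`k = 1`) and bending (`κ = 10⁻³`), whose
cross-links rearrange on a half-minute clock — an over-loaded junction
*slides* (its attachment walks along the crossing fiber, strictly
lowering the elastic energy), and nearby fibers *merge* with probability
`P_merging` per step into a permanent, initially stress-free bond.

Energy per bond and per hinge (consecutive bond pair in a fiber):

```
E_stretch = Σ  k/(2 l₀) (l − l₀)²,      E_bend = Σ  κ/(2 a₀) Δθ²
```

with the bond-density readout `ΔF/F = (F_b − F)/F` between two
contracting cells (region-of-bundle density `F_b` vs background `F`,
`F = 3p/2S` with triangle area `S = √3/4` for the uniform lattice), and
post-release strain fitted by
`ε(t) = (ε(0⁺) − ε_r)·exp(−t/τ_p) + ε_r` (single mode) or
`ε(t) = a·exp(−t/τ_v) + b·exp(−t/τ_p) + ε_r` with a shared fast
timescale across dwell times (double mode, for curves that also carry a
viscoelastic transient).

See `docs/methods.md` for the full model description, the numerical
choices, and known limitations.

## Worked example

Shear a 20×20 strip to 20%, hold it for two minutes of plastic
remodeling, release the top boundary, and fit the strain decay:

```python
from fiberplast.protocols import simulate_bulk_relaxation
from fiberplast.analysis import fit_single_exponential

r = simulate_bulk_relaxation(seed=9, dwell_minutes=2.0, nx=20, ny=20,
                             relax_minutes=6.0)
s = r.relaxation_series()
fit = fit_single_exponential(s.t, s.strain)
print(f"eps0={r.eps0:.3f}  eps(0+)={r.eps0_plus:.4f}  "
      f"tau_p={fit.tau:.2f} min  eps_r={fit.offset:.4f}  "
      f"events={len(r.events)}")
```

```
eps0=0.200  eps(0+)=0.0897  tau_p=0.16 min  eps_r=0.0662  events=78
```

The held strain (20%) drops instantaneously to 9.0% on release — the
elastic part recovers at once because the model has no viscosity — and
the remaining strain decays plastically over a fraction of a minute
toward a permanent residual of about 6.6%: the two-minute hold and its
78 sliding/merging events have irreversibly reconfigured the network.
Longer dwell times give larger residuals and slower decays.

The same physics from the command line:

```
fiberplast simulate bulk-relax --dwell 2 --seed 9 --out run/
fiberplast simulate cell-pair --config cells.yaml --out run/
fiberplast fixtures list
```

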