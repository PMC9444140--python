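# Methods

`nvusim` simulates how changes of capillary blood flow reshape glucose
gradients around a single brain capillary.  The computational domain is
an axisymmetric "virtual phantom" of a neurovascular unit: four
concentric cylindrical shells sharing the axis of a capillary segment
of length `L_capillary` = 25 μm — the lumen (radius `R0` = 7 μm), the
endothelium (1 μm), the basal lamina (100 nm) and 25 μm of brain
parenchyma.  Pericytes and vascular networks are outside the model's
scope.  All internal quantities are SI; concentrations are carried in
mol/m³, numerically equal to mM.

## Hemodynamics

**Lumen.**  Blood is a Carreau shear-thinning fluid,

μ(γ̇) = μ∞ + (μ0 − μ∞)[1 + (λγ̇)²]^((n−1)/2),

with μ0 = 5.6×10⁻² Pa·s, μ∞ = 3.45×10⁻³ Pa·s, λ = 3.131 s,
n = 0.3568.  The scalar shear-rate magnitude is the standard
|γ̇| = √(2 ε:ε), which reduces to |du_z/dr| in simple shear.  At
capillary scale the Reynolds number is ~10⁻³ and the viscous
relaxation time ρR²/μ ≈ 15 μs, far below the 0.5 s pressure ramp, so
the default solver is the quasi-steady generalized Stokes balance:
fully developed axisymmetric flow, 1-D in radius on the lumen rings of
the mesh, with the nonlinear viscosity converged by damped fixed-point
iteration (relaxation 0.7, relative tolerance 10⁻⁸, at most 200
iterations).  A transient option retains ρ∂u/∂t (backward Euler) and
is used in tests to confirm that the transient solution collapses onto
the quasi-steady one after the viscous time scale.

An independent reference solution ("radial oracle") exploits the fact
that the shear stress profile of developed pipe flow is statically
determinate, τ_rz = Δp·r/(2L): the shear rate is obtained by a
bracketed root find of μ(γ̇)γ̇ = τ at each radius and the velocity by
quadrature from the no-slip wall.  The finite-volume solver agrees
with it to <0.5% in mean velocity on the default grid; the oracle also
backs the pressure calibration (below).

**Drive.**  Inlet/outlet pressures are p_in/out = (p0 ± Δp)·f(t) with
p0 = 18.5 mmHg = 2466.5 Pa.  The shift function f(t) equals 1 before
the smoothing window, 1∓a after it, and follows a C¹ cosine ramp of
width Δt = 0.5 s centred on t0 = 2 s (so f(t0) = 1∓a/2).  The
amplitude obeys 0.5 ≤ a < 1; the study protocols are a = 0.7
(decrease, f → 0.3) and a = 0.5 (increase, f → 1.5).

Δp is not a measured quantity; it is calibrated once — with the radial
oracle, not the grid solver — so that the baseline volume-averaged
lumen speed equals the modelled literature value 1.28 mm/s.  The
frozen result, Δp = 10.1393 Pa (total baseline drop 20.28 Pa over
25 μm), is written into the packaged default configuration and used by
all runs; `nvusim calibrate-dp` re-derives it.

Because the flow is shear thinning, the mean speed is *not*
proportional to the drop at this operating point (wall shear ~700 s⁻¹,
μ ≈ 1.1·μ∞): rescaling the drop ×0.3 and re-converging the viscosity
gives a 73.8% speed reduction, and ×1.5 gives a +54.1% rise, slightly
beyond the nominal 70%/50% pressure amplitudes.  These are the model's
honest velocity responses; the package reports them as computed.

**Parenchyma.**  Interstitial flow follows Darcy's law
u = −(κ/μ_ISF)∇p with κ = 6.5×10⁻¹⁵ m², μ_ISF = 7×10⁻⁴ Pa·s; the
pressure solves the axisymmetric Laplace problem on the tissue annulus
with Dirichlet end caps and sealed cylindrical surfaces.  Nothing in
the study fixes the parenchymal drive, so the default axial pressure
difference (1.3462 Pa over 25 μm) is chosen to give the literature
percolation speed ~5×10⁻⁷ m/s; it is configurable and recorded in the
output metadata.  The Darcy field is static during a scenario.  The
endothelium and basal lamina carry no flow.

## Glucose transport

One concentration field spans all four regions, advanced by a
cell-centred finite-volume scheme on a structured (r, z) grid with the
axisymmetric measure 2πr·Δr·Δz.  Region physics:

* lumen / endothelium / basal lamina: ∂c/∂t = ∇·(D∇c) − u·∇c + f_con,
  with free-medium coefficients D_c = 3.1×10⁻¹⁰ (flowing blood),
  8.7×10⁻¹⁰ (endothelium, set to the cytosolic value — the study
  tabulates none for this layer) and 1.6×10⁻¹⁰ m²/s (basal lamina);
* parenchyma (porous): ∂(α c)/∂t = ∇·(D_eff∇c) − u·∇c + f_con with
  porosity α = 0.36, tortuosity θ = 1.635 and
  D_eff = (D_c/θ)(1 + α) — the tortuosity-reduced dispersion limit
  (velocity-dependent dispersivity is negligible at 5×10⁻⁷ m/s) plus
  the porosity-weighted porous-diffusion term.

All regions apply the diagonal anisotropy diag(σ_trans, σ_long) =
diag(0.33, 1), with the σ = 1 direction mapped to the capillary axis.
The orientation of the anisotropy relative to the axis is genuinely
unknown for a short capillary segment; the axial choice is a
documented default, not a measurement.

**Consumption.**  The lumped hexokinase–phosphofructokinase sink is
f_con = −ε·c/(c + K_glc), ε = k·c_ATP·[1 + (c_ATP/K_I)^nH]⁻¹, giving
ε = 0.06 mol/m³/s in endothelium and parenchyma (k = 0.12 s⁻¹,
c_ATP = K_I = 1 mM, nH = 4) and K_glc = 0.05 mM.  The basal lamina is
acellular (no sink); blood consumes at k_I = 0.01·k_E by default (the
study states only that the blood rate is much smaller).

**Barrier interfaces.**  The lumen|endothelium and
endothelium|basal-lamina interfaces carry saturable GLUT1 carrier flux
everywhere (no paracellular path); the basal-lamina|parenchyma
interface is striped into astrocyte end-feet (carrier flux, density
18 μm⁻²) and free-diffusion clefts (flux and concentration
continuity).  The per-area maximal carrier flux is
V_max = N·k_cat/N_A: 1.94×10⁻⁶ mol/m²/s for the endothelial membranes
(N = 10³ μm⁻², k_cat = 1166 s⁻¹) and 3.5×10⁻⁸ mol/m²/s for end-feet.
By default the carrier law is *symmetric* (net flux = difference of
the two one-sided saturable terms, Km = 8 mM), because GLUT1 is a
bidirectional facilitative carrier and a one-sided law cannot
equilibrate — it transports against nothing at equal concentrations.
The literal one-sided form is available as `carrier_mode: one_sided`.

End-feet striping: the requested coverage times the facet count is
rounded to the nearest facet and distributed over `n_bands` = 8
annular stripes (largest remainder), each centred in its axial
segment, so realized coverage matches the request to within one facet
(0.83% at nz = 120).

**Boundary and initial conditions.**  Danckwerts feed at the lumen
inlet (total flux = u·c̃ with c̃ = 5 mM), outflow (zero diffusive
flux, upwind advective closure) at the lumen outlet and the parenchyma
outer/end surfaces, no flux on the endothelium/basal-lamina end caps.
Where the static Darcy field *enters* a tissue cap the advective
closure is zero-gradient and handled explicitly; the induced step
limit is ~10³ s, far above any practical Δt.  Two documented variants
are off by default: fixed end-cap concentrations on the thin layers,
and a venous-type feed at the parenchyma caps.  Initial state: lumen
5 mM; endothelium, basal lamina and parenchyma 1 mM.

**Scheme.**  Backward Euler with implicit first-order upwind
advection.  The Michaelis–Menten nonlinearities (carrier fluxes and
sink) are linearised by lagging their denominators, which makes the
system matrix an M-matrix: the step is unconditionally stable,
positivity preserving, and conservative to solver round-off (the
per-step discrete mass-balance residual is ~10⁻¹⁵ relative; tests
require <10⁻¹⁰).  The linearisation is refreshed on a fixed step
schedule (default every 5 steps; the cached LU factorisation is reused
in between).  The schedule is tied to the absolute step index so
scenario comparisons share identical linearisation points; moving the
refresh from 5 to every step changes the 4 s parenchymal average by
~2×10⁻⁴ relative.

**Coupling.**  The drive is evaluated every transport step.  The
cached lumen solution is rescaled in proportion to the pressure drop
(exact for generalized Stokes flow at frozen viscosity) and fully
re-converged whenever the accumulated rescaling exceeds 5% — about 22
nonlinear re-solves across a ramp.

## Default problem sizes

Grid 60×120 cells (radial allocation 24/8/4/24 across
lumen/endothelium/basal lamina/parenchyma, at least four cells per
layer so the 100 nm basal lamina is always resolved), Δt = 1 ms, 4 s
simulated; a full coupled scenario runs in ~30 s on one CPU.  Scalar
diagnostics are recorded every 10 ms, field snapshots every 0.25 s.
Doubling the grid and halving Δt moves the reported region averages by
<2%.

## Reported statistics

"Mean ± SD" for a region is the volume-weighted mean and SD over the
region's cells at one instant (the study does not say whether its SDs
are over space, time or meshes; spatial-over-cells is assumed).
Pre-shift quantities average over [0, 1.5] s, post-shift over
[3.5, 4] s; plateau speeds are sampled at t = 1.5 s and 3.5 s.

## Emergent behaviour and known limitations

The parameter set has a built-in imbalance that dominates the
transport results: the parenchymal sink demand per unit abluminal
surface, ε·V_II/A ≈ 3.8×10⁻⁶ mol/m²/s, exceeds the maximal
trans-endothelial carrier supply (~3.7×10⁻⁷ mol/m²/s net through two
saturable membranes in series at 5 mM blood glucose) several-fold.
Combined with the porous storage (stored mass α·c, sink per bulk
volume — an effective per-concentration drain of ε/α ≈ 0.17 mM/s),
the volume-averaged parenchymal glucose falls from 1.0 to ≈0.44 mM
over the 4 s protocol at *both* end-feet coverages, and the coverage
itself moves the average by only ~3×10⁻⁴ mM (free-diffusion clefts
are orders of magnitude more conductive than the carrier supply that
feeds them, so neither striping fraction is limiting).  Likewise,
because the lumen is flushed in ~20 ms, blood glucose stays within
0.1% of the 5 mM feed at all flow levels, and the CBF protocols
modulate the tissue level only through that small composition change:
a flow decrease lowers the post-shift parenchymal average by ~4×10⁻⁶
mM relative to baseline at both coverages, a flow increase raises it
by ~1×10⁻⁶ mM.  Reported values are exactly these computed ones.

Other limitations: single species (glucose); no vascular network,
pericytes or smooth-muscle wall; no autoregulatory feedback of tissue
state on pressure; first-order upwind advection is diffusive for
sharp fronts (the acceptance-scale fields are smooth); the
end-feet/cleft geometry is a surface striping, not a resolved
cell-scale cleft network, so cleft conductance is an upper bound.
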