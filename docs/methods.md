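# Methods

This note records the models, the numerical choices behind them, and the
limits of what the test suite demonstrates.

## Swelling–erosion moving-boundary model

The film is a 1D slab. Below the glassy–rubbery front R(t) the polymer is
dry glass at solvent fraction φ0; between R(t) and the gel–solvent front
S(t) the solvent fraction obeys the nonlinear diffusion equation
∂φ/∂t = ∂z[Ds(φ)(1−φ)∂zφ]. Both fronts carry Stefan conditions: R at the
swelling threshold φg, S at the equilibrium fraction φeq with the
disentanglement (erosion) sink Rdis = C(1−φ)^1.625. Two wetting geometries
are supported: *symmetric* (both faces wetted; the computational domain is
the half-film with a symmetry plane at z = 0; used for swelling tests and
the paddle apparatus) and *anchored* (one face wetted, impermeable wall at
z = 0; the flow-through channel).

**Interface-flux convention.** As printed, dS/dt = DGs ∂φ/∂z|S − Rdis is
already exactly polymer-conserving, because the PDE flux carries the (1−φ)
factor: the total polymer column decreases at (1−φeq)·Rdis, i.e. by exactly
the polymer content of the eroded gel. This form is the default. A
`stefan_variant="scaled"` switch divides the influx term by (1−φeq) — the
alternative kinematic convention found in parts of the swelling literature —
but it is *not* volume- or polymer-conserving and is provided only for
comparison.

**A structural trade-off worth knowing.** In any polymer-conserving
implementation the complete-dissolution time is pinned by the polymer
budget, t_diss ≈ (1−φ0)·z_init/((1−φeq)·Rdis), and the peak swelling degree
is pulled toward the equilibrium ratio (1−φ0)/(1−φeq). For the plain-film
constants shipped in the examples (φ0 = 0.21, φeq = 0.89, C = 67.72 μm/s,
L0 = 87 μm) this gives t_diss ≈ 2.8 min and max W/W0 ≈ 5.1; a higher peak
with a longer lifetime cannot be produced simultaneously by adjusting C,
because C trades one against the other. Reported characterisations that
pair a lower peak (~3.5) with a longer lifetime (~4 min) at these same
constants are therefore not reachable by this model family; we compute and
report the model's own values.

**Numerics.** Front-fixing (Landau) map of [R, S] onto the unit interval;
conservative method-of-lines in space (61 nodes by default); stiff adaptive
integration (LSODA) with terminal events for glassy-core exhaustion and for
dissolution (declared at S < 10⁻³·L0, with the tiny residual S/Rdis added to
the reported time). The t = 0 contact discontinuity is regularised by
seeding a gel layer 10⁻³·L0 wide with a linear profile, split between the
two fronts in the ratio of their initial Stefan speeds. Validation: the
C = 0 equilibrium thickness ratio (1−φ0)/(1−φeq) is met to 0.3%, polymer is
conserved to <0.1%, halving grid and seed width moves results by <1%, and
the early-time fronts match an independent similarity (shooting) solution
of the two-front Stefan problem to ≤2–3%.

When erosion dominates solvent uptake the gel layer does not collapse:
because the influx scales as 1/h, the layer thickness self-stabilises and
the film dissolves as a quasi-steady thin-gel wave. A front-crossing guard
exists for genuinely degenerate numerics but is unreachable for physical
parameters.

**Weight ratio.** W(t)/W0 integrates ρp(1−φ) + ρs·φ over glassy core plus
gel. Densities default to equal (ρp = ρs = 1000 kg/m³), making W/W0 a
thickness ratio; both are configurable.

## Franz-cell hierarchy

Models I (uniform donor, sink), IIa/IIb/IIc (resolved donor+membrane with
sink / finite-volume / withdrawal-event receptor closures) and III
(imperfect mixing) share a conservative finite-volume chain with
position-dependent cross-section and two-half-cell flux resistances, so
concentration and mass-flux continuity hold by construction; the linear
systems are integrated with BDF and an analytic sparse Jacobian between
withdrawal events. Withdrawals are instantaneous: Model IIc multiplies the
receptor concentration by (1 − Vp/Vres); Model III records the cone average
cp = c̄tc and zeroes the cone (withdrawal plus fresh-solvent replacement).
The withdrawal volume defaults to the cone volume — the assumption that
makes "empty the cone" the exact representation of a withdrawal.

**Receptor geometry.** Only compartment volumes are known for the
apparatus (cylinder ≈ 7.1 mL, cone ≈ 0.25 mL, arm ≈ 0.55 mL of a 7.9 mL
receptor); the 1D chain uses a 1.77 cm² cylinder, an arm of 0.28 cm², and a
cone that tapers linearly between those areas with its *length set by the
cone volume* (≈2.4 mm). The stirred body is modelled by a large effective
diffusivity Dcil = mix_factor·D0 with mix_factor ∈ [10⁵, 10⁷] (default
10⁶); results are insensitive (<1% in cp) across that range — tested.

**Mixing-decay constant.** The transition of the effective diffusivity from
the stirred to the quiescent value, Dtc(s) = D0 + (Dcil−D0)exp(−βD·s), must
be sharp on the scale of the cone: with a decay length comparable to the
cone length the cone would be effectively stirred, cp ≈ c̄cil, and the
imperfect-mixing phenomenology (withdrawal concentrations below the
perfect-mixing prediction; experimental integral curves undershooting the
true release) would vanish. The default is βD = 5×10⁵ m⁻¹ (decay length
2 μm), i.e. the stirred zone ends essentially at the cylinder–cone
junction; βD is configurable.

**Ordering Mts ≤ Mt.** The perfect-mixing estimator Mts = Vres·cp + ΣVp·cp
undershoots the model's true release Mt whenever the sampling interval is
shorter than the cone re-equilibration time L_tc²/D0 (≈3 h for furosemide);
after much longer gaps the cone refills to the stirred-body level while the
arm still lags and the ordering can reverse slightly. Tests therefore use
the dense (hourly) part of a realistic schedule, and a dedicated test
documents the regime boundary. Withdrawal sums in both estimators use the
pre-withdrawal concentrations over earlier samples (Σ_{j<i}), the
convention that makes the estimator equal to the post-withdrawal receptor
state bookkeeping.

Membrane partitioning is unity (hindrance lives entirely in Dm ≤ D0). A
film donor is treated as fully swollen from the first instants: thickness
Th from the swollen-thickness relation and diffusivity DG.

## Flow-through device (MFTD)

Gel diffusion (with the drug Stefan condition at the receding glassy front)
couples to 2D convection–diffusion in the shrinking lumen through
concentration/flux continuity at S(t); the lubrication profile
vx = 6Q(z−S)(Lz−z)/(Ly(Lz−S)³) keeps the flow rate exact as the film
swells. Front kinematics come from the independently solved anchored
swelling problem (one-way coupling). The channel is 2×9×30 mm with the
film across the full 9 mm width; outlet sampling defaults to every 2 s.

**Numerics.** Both layers are moving-mesh finite volumes in conservative
form, ∂t(hc) = ∂s[(D/h)∂s c + v(s)c], on unit grids stretched geometrically
toward the shared interface (stretch 4.5; 24 gel and 32 fluid cells, 32
axial cells by default). The stretching matters: the concentration boundary
layers on each side of the interface have thickness ~D/|dS/dt| — microns
during the fast early swelling — and resolving them is what keeps the
interface exchange conservative. All z-terms (diffusion, mesh advection,
the stiff drug Stefan relaxation ~(dR/dt)²/DG, and a single shared
interface flux with upwinded capture) are advanced implicitly as one
tridiagonal solve per column spanning gel and fluid; axial upwind
convection and axial diffusion are explicit. The step is limited by the
axial CFL and by a cap of 4% of the gel thickness on front displacement per
step. With this construction the global balance glassy + gel + lumen +
outflow closes to <0.01% (the 1% test tolerance is generous), and the
release curve self-converges to ~1% under grid refinement.

The drug carried by eroded gel reaches the fluid through the kinematic
interface flux itself (the v·c capture term with dS/dt < 0): no separate
erosion-source closure is needed, and the "literal" and "conservative"
variants coincide. Eq-numbering aside, this is the discrete statement that
material crossing a moving interface carries its local concentration. At
complete dissolution the residual gel inventory (already negligible) is
handed to the bottom fluid cells and the lumen is conservatively rebinned
to the full channel height.

## USP II (paddle)

Drug diffuses on the moving gel domain of the symmetric swelling solution
with a perfect sink at S(t) and the Stefan hand-over at R(t) (which turns
into the symmetry condition automatically when R reaches 0, since the front
rate vanishes). Cumulative release is inventory-based,
Mt = A[c0L0 − 2(c0R + ∫cG dz)], so erosion releases the residual drug of
removed gel without any extra flux term — in contrast to the flow-through
device, where the eroded drug must transit the lumen before it is counted
at the outlet. The solver is validated against the classical eigenfunction
series for a frozen fully swollen slab (≤2×10⁻³ absolute in release
fraction).

## Parameter estimation

All fits are bounded least squares (scipy trf) on O(1)-normalised
residuals, with an explicit finite-difference step of 10⁻³ (the forward
solvers carry ~10⁻⁶ relative integration noise; smaller steps produce
garbage Jacobians). Multi-starts are deterministic given the seed.

* **(DGs, C) from W(t)/W0:** the search runs over (log10 DGs, C). The
  start is physics-informed — the observed dissolution time inverts the
  polymer-budget relation for C, then a 7-point log scan fixes DGs — which
  is essential because the objective valley is narrow (the dissolution
  cliff makes residuals near-discontinuous in the parameters). Noise-free
  self-consistency recovers both to <1%; at 10% multiplicative noise with
  5 replicates both are recovered within 15%.
* **DG from Franz withdrawal curves:** one-parameter fit of the
  imperfect-mixing model; cp is linear in M0, so jointly rescaling data and
  load leaves the estimate invariant (tested), and data generated at the
  free-solution diffusivity drive the estimate to its bound, which is
  flagged.
* **C (equivalently Rdis at φeq) from USP II / MFTD release curves:**
  one-parameter fit with all diffusivities held at their Franz-cell
  estimates, reporting the implied disentanglement rate.

Residual weighting is uniform-absolute by default (a relative switch
exists); with multiplicative noise both behaved comparably on synthetic
data and the simpler convention was kept.

## Synthetic data

The generator runs the forward models at stated truth parameters and
applies multiplicative Gaussian noise y(1 + σN(0,1)), σ = 0.10 by default —
the replicate-to-replicate scatter level of flow-through outlet readings.
Default swelling sampling is every 5 s over the first minute and every 15 s
thereafter (the rise carries the DGs information). All randomness flows
through one seeded generator; datasets are byte-reproducible and ship a
truth manifest.

What synthetic tests do *not* show about real data: film fragmentation
during swelling tests (which inflates apparent erosion), the "wavy"
flow-through signals from detaching gel pieces, membrane adsorption,
temperature drifts, and model error in the receptor geometry — the noise
model is i.i.d. multiplicative, which real replicates are not.

## Problem sizes

Default resolutions (swelling 61 nodes; Franz chain ~90 cells; flow-through
32×24×32) solve each forward problem in 0.3–4 s; the test suite uses
coarser grids for repeated fits (noted per test) after verifying
self-convergence at the defaults.
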