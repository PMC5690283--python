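# Methods

This note documents the models, numerical choices and limitations behind
`memtether`.  Units everywhere: lengths in nm, forces in pN, times in s,
energies in kBT, concentrations in mol/L.

## Physical setting

A protein domain (a C2 domain or C2-domain pair from synaptotagmin-1 or
extended synaptotagmin-2) is anchored to a lipid bilayer supported on a
trapped silica bead through a flexible N-terminal polypeptide linker of
40–81 amino acids, and pulled from its C terminus through a DNA handle
held by a second optical trap.  At constant trap separation the extension
flickers between a membrane-bound level and an unbound level; the
occupancies and transition rates of that two-state telegraph signal,
measured across a range of forces, determine the membrane-binding energy
and kinetics at zero force.  Because the linker keeps the unbound domain
near the membrane, the measured affinity is inflated relative to the
bimolecular (untethered) one; a Gaussian-chain theory of the tethered
ligand converts between the two frames.

## Tether theory

The linker is a Gaussian chain with contour length L (0.365 nm per
residue) and persistence length P = 0.6 nm, anchored at height h0 = 6 nm
above the outer membrane surface; the bound domain holds the chain end at
h1 = 2 nm.  The free-end density is an isotropic Gaussian around the
anchor with per-axis variance 2PL/3.  Treating each lipid (area per lipid
s = 0.7 nm²) as an independent binding site, integrating the end density
over the binding plane gives the average effective concentration

    c̄ = (1 / s N_A) (3 / 4πPL)^{1/2} exp(−3h² / 4PL),   h = h0 − h1,

and the frame conversions

    k_on = k_b / c̄,   K_on = K_b / c̄,   E_on = E_b + ΔEc,
    ΔEc = −ln(c̄ / 1 M).

The unbinding rate is tether-independent.  For a tandem domain pair
joined by a 13-aa linker (contour 4.7 nm), binding of one domain tethers
the other at the membrane with h = 0, giving a coupling energy ln(c/1 M)
in the pair's total binding energy, so the unmeasured domain's energy
follows by subtraction (uncertainties combine in quadrature; the
geometric coupling term is exact).

Boundary effect: the unbounded Gaussian ignores the membrane.  An
image-method variant places a mirror source at −h0 (subtracted for an
absorbing boundary, added for a reflecting one).  For all four linker
geometries the absorbing correction changes ΔEc by at most 0.14 kBT,
which justifies using the unbounded closed form; the package evaluates
both.  Note the correction is *not* monotone in L: c̄ itself decreases
with chain size only once the end fluctuation σ = sqrt(2PL/3) exceeds the
height gap (turning point at L = 3h²/2P).

Records are tagged `tethered`/`bimolecular` so a correction cannot be
applied twice.  Uncertainties pass through the correction unchanged (the
geometry is treated as exact), which is first-order propagation for a
purely additive/multiplicative transform.

## Polymer elasticity

Stretched segments (DNA handle, stretched polypeptide) use the
Marko–Siggia interpolation; the handle adds the enthalpic F/K term
(defaults: 2,260 bp × 0.34 nm/bp, P = 40 nm, K = 1200 pN — typical for
this assay class and fully configurable; the protein linker is
inextensible).  Force↔extension inversions use bracketed Brent iteration
at 1e-9 relative tolerance and close round trips to better than 1e-6 pN.
The stretching energy of an inextensible chain uses the exact closed-form
integral of the interpolation formula; the extensible variant integrates
x(F) by adaptive quadrature (absolute tolerance 1e-6 in native units).
Thermal energy defaults to kBT = 4.09 pN nm (≈23 °C, 296 K).

## Energy landscape on the contour-length coordinate

The reaction coordinate is the contour length l of stretched polypeptide:
l = 0 bound (linker slack), l = L unbound, l = l‡ at the unbinding
transition state.  Zero-force state energies are G(0) = −Eb,
G(l‡) = E‡, G(L) = 0 (unbound reference).  Under force,

    G̃(l, F) = G(l) + E_stretch(l, F) − F·x(l, F)/kBT,
    x(l, F) = x_WLC(l, F) + Δh·(l/L),

where Δh (default h0 − h1 = 4 nm) is the anchor-height change between the
bound and unbound geometries.  Distributing Δh proportionally along the
coordinate keeps the bound↔unbound extension change at
Δx(F) = x_WLC(L,F) + Δh while letting the transition-state distance
Δx‡ = x(l‡, F_eq) take the sub-nanometre-to-nanometre values these
measurements show; concentrating the whole offset at any l > 0 would
force Δx‡ > Δh, which is unphysical for a barrier close to the bound
state.  Unbinding probability follows the Boltzmann distribution over the
two wells, P_ub = 1/(1 + exp(ΔG̃)) with ΔG̃ = G̃(L) − G̃(0); rates follow
Kramers with a single attempt rate k_m (default 1e6 s⁻¹, optionally
fitted), k_ub = k_m exp(−[G̃(l‡) − G̃(0)]), k_b = k_m exp(−[G̃(l‡) − G̃(L)]),
so ln(k_b/k_ub) = ΔG̃ identically.

Key simplification: the full dumbbell Hamiltonian (two trap potentials
plus handle) is reduced to a constant-force description per state.  The
handle and trap terms are common to both states at fixed force and cancel
in state differences; what does not cancel is that at fixed *separation*
the two states sit at different forces.  The pipeline therefore (i)
carries the per-state mean forces from the idealized trajectories into
the force series and evaluates k_ub at the bound-state force and k_b at
the unbound-state force, with the occupancy prediction
k_ub/(k_ub + k_b) consistent with both; and (ii) corrects the observed
extension jump for handle contraction,
Δx_tether = Δx_obs + x_handle(F_bound) − x_handle(F_unbound), before
comparing it with the model's constant-force Δx(F).

The joint fit minimizes weighted residuals over {P_ub, log10 k_b,
log10 k_ub, Δx} with free parameters (Eb, E‡, l‡); block scales default
to 0.05 / 0.1 decades / 0.5 nm, standing in for typical measurement
scatter (the Δx block does not depend on the parameters in this
parameterization and acts as a mechanics consistency check).  Before
pooling molecules, each molecule's force axis is translated so its
logistic-interpolated equilibrium force matches the across-molecule mean,
reflecting the ~10% absolute force accuracy of dual-trap instruments
(larger shifts are flagged).  Parameter uncertainties come from a
bootstrap over molecules (200 replicates, seed-controlled, warm-started
at the full-data optimum).  Δx‡ is reported as x(l‡, F_eq) − x(0, F_eq).

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes,
not the instrument's optics or hydrodynamics:

* **Force balance.** At trap separation D the force satisfies
  D = x_handle(F) + x_state(F) + F/k_s with k_s the two traps in series
  (default 0.2 pN/nm per trap); solved to < 1e-6 pN.  The unbound state
  adds the stretched linker plus the 4 nm geometry offset, so unbinding
  drops the force and the observed jump is compliance-compressed —
  exactly the effect the analysis corrects for.
* **Kinetics.** Exact Gillespie dwell sampling with k_ub evaluated at the
  bound-state force and k_b at the unbound-state force.
* **Noise.** Ornstein–Uhlenbeck with correlation time 50 µs (the
  instrument-class ~0.3 nm/20 µs resolution scale).  The amplitude is
  specified as the *post-filter* standard deviation at the default 1.5 ms
  analysis window (default 2.5 nm, i.e. filtered signal-to-noise ratios
  of roughly 1.5–4 for these extension changes); the raw OU σ is derived
  from the exact variance of a boxcar mean of an AR(1) process.  Force
  noise is the extension noise scaled by −k_s.  Lipid-diffusion
  "thickening" of membrane traces can be mimicked with a per-state
  variance multiplier; bead hydrodynamics are not modeled.
* **Ramps.**  Constant-speed separation ramps interpolate the force
  balance on a grid; binding flicker emerges from the same kinetics, and
  optional irreversible unfolding events fire by Bell-rate first passage
  inside a configured force window (forced at the window top, so sampled
  unfolding forces are bounded by construction) and add contour length.

Ground truth (labels, state forces/extensions, rates, occupancies) is
returned with every trajectory and recorded in the benchmark manifest.

**Benchmark suite.**  Four reference parameter sets are built from the
shipped zero-force table (condition-matched 5% PI(4,5)P₂ rows): Eb and
k_ub(0) are taken directly, E‡ = ln(k_m/k_ub0) − Eb, and l‡ is placed so
Δx‡ at equilibrium equals the measured 1.0 / 0.7 / 1.4 nm (the fourth
construct's Δx‡ is unreported and set to the shared ~1 nm scale).  Per
construct, 5 molecules × 6 trap separations target unbinding
probabilities spanning 0.1–0.9, clipped so both mean dwell times stay
above ≈5 filter windows (rates ≤ 120 s⁻¹) — separations that violate
this are unresolvable at the analysis bandwidth and would only measure
the filter.  Durations are 30–60 s per trajectory, longer for the slow
constructs, chosen to give hundreds to thousands of transitions per
trace.  Random streams are counter-based per (construct, molecule,
separation), so suites are reproducible under partial regeneration.

## HMM idealization

Trajectories are boxcar mean-filtered with decimation (default window
1.5 ms, within the 1–3 ms range appropriate for these rates) and fitted
with a two-state Gaussian-emission HMM (Baum–Welch EM via `hmmlearn`,
independent per-state variances — membrane-side noise is state-dependent
and never pooled).  Initialization is a k-means split with randomized
kinetics; 5 restarts, best likelihood wins, ties broken toward the lower
unbinding rate.  A custom monitor keeps the full likelihood trace so
monotonicity is testable.  Continuous-time rates come from the exact
2-state matrix logarithm of the per-step transition matrix, falling back
to k = p/Δt when the logarithm is undefined.  Occupancy is reported both
as the posterior mean and as the Viterbi-path fraction (they agree within
0.02 on all fixtures).  Per-state mean forces are averaged over the
Viterbi states; their unweighted mean is the force coordinate of all
force-dependent plots.  Extension histograms are fitted by a two-Gaussian
mixture; Ashman's D < 2 flags unresolvable components.  No missed-event
correction is applied — a limitation shared with the analysis this
package implements; the benchmark shows its bias stays below ~10% for
rates up to the 120 s⁻¹ design cap.

## What the synthetic benchmark does and does not show

Passing the round trip (recovery of Eb within 1 kBT, Δx‡ within 0.4 nm,
zero-force log10 rates within 0.3 decades) demonstrates that the
estimator chain is consistent with its own generating assumptions at
realistic noise, sample sizes and dumbbell compliance.  It does not
validate those assumptions against a real instrument: drift, slow bead
or membrane relaxation, multi-state kinetics, anchor heterogeneity and
calibration error are all absent from the generator.  The measured
energies themselves are instrument results and are not reproducible at
desk scale; the analytic tether-theory numbers are.

## Numerical details and degenerate inputs

* Root finding: `brentq`, relative tolerance 1e-9 (1e-12 where inversions
  feed energy differences); quadrature `scipy.integrate.quad`.
* The landscape fit precomputes the dimensionless WLC inversion once per
  force set, making residuals closed-form; `least_squares` with bounds
  Eb ∈ (0.01, 60), E‡ ∈ (−10, 60), l‡ ∈ (0, L).
* Exponents are clipped at ±500 before `exp`; a barrier below either well
  is flagged (rates are then extrapolations).
* Trajectories shorter than 100 samples, mixture fits on < 1000 samples,
  filter windows under 2 samples or longer than the trace, non-positive
  forces in a series, and duplicated trap separations are rejected with
  errors; unreadable states (a Viterbi state with no samples) fall back
  with a warning.
* Text formats: '.' decimal, comma on write, tab/comma auto-detected on
  read, '#'-prefixed key=value metadata; extensions and forces stored at
  1e-3 precision.
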