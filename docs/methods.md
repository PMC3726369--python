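# Methods

## Model

`follisim` integrates eleven species on a uniformly growing 1D cross-section
of the bovine antral follicle: the gonadotropins FSH (F) and LH (L),
androgens (A), estradiol (E), the free FSH/LH/estrogen receptors
(R_f, R_l, R_e), their ligand-bound complexes (C_f, C_l, C_e), and a lumped
IGF-receptor complex (I) that stands in for the IGF-2/IGFBP/PAPP-A axis and
for aromatase expression downstream of it. With x = ℓ(t)·ξ, ξ ∈ [−1, 1] and
Λ(t) = Λ(0) + v·t, each species obeys

    ∂c/∂t + (v/Λ) c = (D/ℓ(t)²) ∂²c/∂ξ² + R(c),

with zero-flux boundaries at ξ = ±1. The (v/Λ)c term is the exact dilution
rate of uniform dilation (ℓ̇/ℓ for linear growth, identical under both
length conventions below). Reactions comprise blood exchange in the theca
(delivery of F, L and androgen precursor at serum-set levels, first-order
removal of all four soluble hormones, both at rate Δ), mass-action
receptor binding (k_on, k_off), linear decay, Hill-regulated receptor
production, Hill-regulated IGF-complex production, and Michaelis–Menten
aromatase catalysis A → E restricted to the cellular block and proportional
to I·(1 + σ_E σ_G)(1 + σ_G), with σ_G = σ_F + σ_L the plain sum of the two
gonadotropin activities (the two receptors share one intracellular
signalling machinery; σ_G is deliberately not capped at 1). The Hill
coefficient is n = 2 throughout.

Assumptions worth stating explicitly: growth is strictly linear and
spatially uniform; compartment boundaries are fixed on the stationary
coordinate; the theca is perfectly perfused (Δ = 1 s⁻¹ clamps its soluble
concentrations within seconds); receptors are produced by cells only, so
receptor production carries a (1 − Φ) factor that keeps the fluid
receptor-free — without it the constitutive estrogen-receptor term would
fill the antrum with ~20 nM of receptor (ρ_RE/δ_RE) and turn the
supposedly inert fluid into an estradiol sink; soluble hormones are not
degraded in the cell-free fluid ((1 − Φ) on their linear decay); and the
catalysis term uses I (in nM) directly as the effective aromatase level,
which the fitted constant K_I absorbs.

## Geometry

Two-compartment layout: theca at both domain ends (|ξ| ≥ ξ_θ = 0.99,
matching a 100 µm theca on a 20 mm follicle), granulosa in between. Antrum
layout: a cellular block (mural granulosa + COC) at [ξ_φ1, ξ_φ2) =
[−0.985, −0.835) with the follicular fluid filling the rest. The sign of
ξ_φ2 deserves a note: the boundary arithmetic ξ_φ2 = −ξ_φ1 − 3/20 evaluates
to +0.835, but that value makes the cellular block cover 91% of the domain
and leaves only a sliver of fluid, contradicting a 3 mm COC and a
fluid-filled antrum; the default is therefore the sign-corrected −0.835,
and the uncorrected value remains selectable by overriding `xi_phi2`.
The "granulosa" layer in the antrum variants is the 0.005-wide strip of the
block adjacent to its theca-side edge (12.5 µm at the 5 mm follicle); the
0.005-wide gap between the theca boundary and ξ_φ1 is fluid, exactly as the
indicator equations imply. Compartment membership uses half-open intervals
closed at the lower bound, with |ξ| ≥ ξ_θ always theca, so mesh nodes
placed exactly on boundaries have an unambiguous compartment and results
cannot depend on H(0) conventions. `theca_scale` thickens the theca by
moving ξ_θ inward; the cellular block slides inward with it so that every
layer keeps its thickness and its contact with the theca's basal lamina —
thickening the theca without moving the block would silently shrink the
theca–granulosa gap by 40% and confound the comparison.

Length conventions: Λ(0) = 5 mm denotes the follicle diameter, and ξ spans
it, so physical positions are x = (Λ/2)ξ (`half_length`, the default —
this is the only reading under which the 12.5 µm granulosa and
ξ_θ = 1 − 2×0.1/20 arithmetic are exact). The alternative `as_printed`
convention scales diffusion by 1/Λ² rather than 1/(Λ/2)², i.e. a 4-fold
smaller effective diffusivity and correspondingly narrower gradients; it is
retained because transport formulas of this family are often written with
the full domain length and the choice is not derivable from the boundary
arithmetic. Both share the same dilution term v/Λ.

## Parameters

All defaults live in `ParameterSet` (units: nM, s, mm). Directly measured:
diffusion coefficients (D_H = 6.7×10⁻⁵ mm²/s for gonadotropins,
D_S = 10⁻⁴ for steroids, D_CL = 2×10⁻⁸ for the internalization-prone bound
LH receptor, D_R = 10⁻⁷ for other receptors, D_I = 4×10⁻⁹ for the
near-immobile IGF complex), binding kinetics (k_on = 10⁻³ nM⁻¹s⁻¹ with
k_off giving K_D = 0.5 nM for FSH, 10 nM for LH, 0.1 nM for estradiol),
decay rates (20 h free FSH, 23 min free LH, 3 h steroids and most bound
complexes, 15 min bound LH receptor, ~10 h half-life of the IGF complex
i.e. δ_I = 1.2×10⁻⁶ s⁻¹ — the rate that sets the multi-day delay of
granulosa LH-receptor expression), and production rates. Receptor
production (ρ_RF = ρ_RL = 0.25 nM/s) and the gonadotropin Hill constants
(K_F = 1500 nM, K_L = 5 nM) carry a 500× factor converting whole-cell
concentrations to the ~2.5 µm³ membrane reaction shell of a 1140 µm³
granulosa cell; the factor is stored as data (`membrane_factor = 500`)
rather than recomputed, since 1140/2.5 ≈ 456 was deliberately rounded.
Serum-calibrated delivery levels: ρ_F = 2 nM, ρ_L = 0.4·ρ_F, ρ_A = 100 nM.
Fitted: K_E = 35 nM, K_I = 5 µM, ϑ = 0.2 (testosterone-driven baseline of
FSH-receptor expression), I(0) = 0.3·K_I in the theca, and
ρ_I = 2.8·K_I·δ_I (an alternative reading gives the factor as 3; the
tabulated 2.8 is used). δ_RE is grouped with the 3-h-half-life species at
6.4×10⁻⁵ s⁻¹ rather than with δ_RF = δ_RL = 3×10⁻⁵ s⁻¹; see the
consistency discussion below.

The `parameters` module also houses the unit-conversion helpers used to
derive these numbers (receptor copies/cell ↔ nM via the cell volume and
Avogadro's number, IU/l and ng/ml to nM via mass equivalents and molecular
weight, and the diffusion–degradation gradient length √(D/k)); they are
exact linear maps and are tested against the published anchor values
(1500 receptors/cell ↔ 2.2 nM, 21 receptors/cell/min ↔ 0.5 pM/s,
1 IU/l FSH ↔ 1.5 nM, 0.63 ng/ml ↔ 20 pM, λ ≤ 70 µm for free IGF).

## Numerics

Space: conservative finite-volume discretization on a boundary-fitted,
non-uniform mesh — every compartment boundary is a node, thin layers get at
least 10 intervals regardless of global density, and wide segments use
cosine grading toward their ends. The default density (120 nodes per unit
ξ, ≈277 nodes for the antrum layout) changes day-5 compartment-averaged
observables by <0.7% upon grid doubling; the only marginal quantity is
free FSH inside the 12.5 µm granulosa strip, a boundary-layer value.
Zero-flux boundaries drop the boundary face flux, which makes discrete
mass conservation exact for the transport operator.

Time: scipy's implicit BDF with rtol = 10⁻⁶, atol = 10⁻⁸ nM and an
analytic sparse Jacobian (per-node 11×11 reaction blocks assembled in BSR
form plus a precomputed diffusion template scaled by 1/ℓ(t)²). The
analytic Jacobian is what makes the stiff system (Δ = 1 s⁻¹ against a
4.3×10⁵ s horizon) run in seconds. Negative concentrations are clipped to
zero only inside reaction evaluations, never in the stored state, and the
Jacobian zeroes the corresponding columns; a run aborts if any stored
concentration drops below −100·atol. Tightening rtol tenfold changes the
tracked observables by <0.1%.

Fluid mixing (`antrum_mixed`): the default is operator splitting — after
each 600 s substep the soluble species are replaced by their
length-weighted fluid average, which conserves mass to machine precision
and is unconditionally stable. A continuous alternative
(`mix_mode="diffusive"`) adds a large effective diffusivity on fluid nodes;
it is the better representation when the flux across the fluid–cell
interface matters, because split mixing lets the interface-adjacent fluid
cell be depleted between substeps.

Parameter-noise ensemble: every kinetic, affinity and diffusion constant is
multiplied by an independent Gaussian factor (mean 1, relative SD 0.2,
redrawn until positive), drawn once per run and held constant in time;
geometry, growth, the Hill coefficient and the initial condition are not
perturbed (Δ, as a kinetic exchange rate, is). Per-run seeds derive from
the master seed by a counter scheme, so individual runs are reproducible
and the ensemble is bit-identical for a fixed seed. Runs that fail to
integrate are excluded and counted; more than 20% failures aborts the
analysis.

## Analytic limit configurations

The solver is validated against closed forms rather than reference output:
with all reactions off and pure growth, every concentration decays as
Λ(0)/Λ(t); with growth and sources off, the spatial integrals of
ligand + complex pairs are exact invariants; a uniform profile is a fixed
point of diffusion; symmetric geometry preserves even symmetry of the
solution; and the mixing operator is idempotent and mass-conserving. These
limits exercise transport, binding stoichiometry and the growth transform
separately, so a regression in any one term is attributable.

## Fluid steroid levels: a transport analysis

Measured follicular-fluid concentrations in dominant bovine follicles show
androgens declining from ~107 to ~33 nM and estradiol rising from ~17 to
~230 nM across the five-day wave, and the model's fitted constant K_I was
chosen with a 200–250 nM final fluid estradiol in view. Under the default
parameter set at converged resolution this package reproduces the window in
the *granulosa layer* (230 nM at day 5, rising monotonically) but not in
the fluid average (which peaks near 65 nM), and fluid androgens rise
toward ~90 nM instead of declining. The cause is structural, not numeric:
with Δ = 1 s⁻¹ the theca destroys any soluble hormone within ~10 µm of
entering it, and estradiol production — aromatase gated by IGF signalling —
concentrates in a reaction sheet of width √(D̃/k_cat,eff) < 1 µm at the
theca-adjacent edge of the granulosa, so nearly all estradiol drains
directly into the blood; meanwhile the fluid, bordered by the second theca,
equilibrates its androgens with the width-independent theca delivery level.
The conclusion is robust across both length conventions, split and
continuous mixing, coarse uniform and fine boundary-fitted grids, and a
granulosa placed adjacent to or offset from the theca; it is also
diagnostic that the day-5 fluid estradiol here is insensitive to K_I
(androgen-transport-limited), whereas the calibration story requires it to
scale with K_I. Reaching the measured fluid trajectories would require the
consumption-dominated regime in which the cellular block, not the theca,
controls the fluid balance — e.g. substantially stronger estrogen-receptor
or IGF activity deep in the COC than the tabulated production rates can
sustain (the tabulated ρ_RE caps bound estrogen receptor at ~24 nM, below
its own Hill constant K_E = 35 nM, so σ_E ≤ 0.34 and the
receptor-saturation regime is never entered). The relevant tests assert
the measured trends as stated and the two that depend on the
consumption-dominated regime fail by design rather than being weakened;
the granulosa-layer counterpart passes.

## What the defaults do and do not show

Passing tests demonstrate internal consistency of the reaction network
(stoichiometry, quasi-positivity, equilibrium ratios), correctness of the
growing-domain transport (closed-form limits, conservation, convergence),
and the qualitative pattern predictions: inward-declining FSH/LH gradients
that sharpen relative to the growing domain, early theca LH-receptor
expression versus multi-day-delayed granulosa expression driven by slow IGF
build-up, estradiol production peaking in the granulosa next to the theca,
and reproducible noise bands that bracket the unperturbed trajectory. They
do not validate absolute fluid steroid levels (see above), any 3D or
cell-resolved effect, follicle selection among a cohort, or pituitary
feedback — constant serum levels are an explicit boundary condition, not a
prediction.
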