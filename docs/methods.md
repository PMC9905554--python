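# Methods

## Data model and units

Records are stored in fixed units — T in K, P in MPa, CO₂ density in
kg m⁻³, solubility as mole fraction y and as mass solubility S in g L⁻¹
(numerically equal to kg m⁻³). Unit conversions required by individual model
forms (pressure in bar inside the density correlations, Pa inside the EoS)
happen at evaluation time, never in storage.

The packaged palbociclib study stores y and ρ as the authoritative columns
and recomputes S from the sampling-loop relation
S = M₂·(y/(1−y))·ρ/M₁ at full precision; a loader-level invariant rejects
any dataset whose printed S disagrees with this relation by more than 2%
relative (the tolerance absorbs rounding of values carried at printed
precision). Palbociclib's molar mass (447.543 g/mol) is computed from the
molecular formula C₂₄H₂₉N₇O₂ with IUPAC 2021 atomic weights. CO₂ constants
(M = 44.01 g/mol, T_c = 304.21 K, P_c = 7.383 MPa, ω = 0.2236) are standard
literature values kept in one editable constants module. The gas constant is
fixed at R = 8.314462 J mol⁻¹ K⁻¹ and atmospheric pressure at 101 325 Pa.

## Semi-empirical correlation

All ten density-based forms are linear in their adjustable parameters after
a log-type transform of the response (ln S for Chrastil; T·ln(yP) for MST;
ln(yP/P_ref) for Bartle with P_ref = 1 bar, ρ_ref = 700 kg m⁻³; ln y for the
rest). The fitting objective is AARD% in mole-fraction space for every
model; Chrastil's mass-solubility prediction is converted to y through the
loop relation with each record's density before residuals are formed, which
makes all ten models directly comparable (for a trace solute the relative
deviations in S- and y-space are identical to first order, so this
convention is essentially cost-free).

Optimisation: the exact linear least-squares solution in the transformed,
column-scaled feature space is always the first start; the remaining
restarts (default 64, seed 20230207) perturb it multiplicatively with
relative scatter 0.4. Each start runs adaptive Nelder–Mead; the winner is
polished by L-BFGS-B (numerical gradient; kept only if it improves — AARD is
non-smooth) and a tight second Nelder–Mead pass. Because the least-squares
anchor dominates, the reported optima are stable across seeds. Noiseless
synthetic data are recovered exactly (the anchor is then the truth), which
the test suite asserts for all ten forms at 10⁻⁴ relative.

Identifiability caveat: the AARD objective is nearly flat in some parameter
directions. For Bartle, AARD varies by only ~1 percentage point while the
temperature coefficient a₂ moves across [−8000, −6000] K, i.e. the derived
vaporization enthalpy (−a₂R) is determined only to roughly ±8 kJ/mol by this
objective on 24 points. The package reports the global optimum; users who
need a stabilised enthalpy should regress with the two-step isotherm
procedure on larger datasets.

Enthalpies: ΔH_total = −a₁(Chrastil)·R and ΔH_vap = −a₂(Bartle)·R, reported
in kJ/mol; ΔH_sol = ΔH_total − ΔH_vap holds exactly by construction.

Self-consistency: the Chrastil collapse plots ln S − a₁/T against ln ρ and
the MST collapse plots T·ln(yP) − a₂T against ρ (P in bar); both should be
straight lines across all isotherms for mutually consistent data. The
transformed axes are a convention of this package — the collapse idea fixes
them only up to affine changes. One least-squares line is fitted over all
temperatures and R² reported; the packaged study gives R² = 0.913 (Chrastil)
and 0.944 (MST).

Crossover location: model isotherms y(T, P) are compared pairwise on a
pressure grid, with densities interpolated per isotherm by a monotone cubic
(PCHIP) so the search stays inside the measured 12–27 MPa span; sign changes
of ln y(T₁,P) − ln y(T₂,P) are refined by Brent's method. The fitted MST
model places the middle crossover near 21 MPa.

## Peng–Robinson solid–fluid equilibrium

Pure components use the standard 1976 construction: b = 0.07780·RT_c/P_c,
a(T) = 0.45724·R²T_c²/P_c·α(T), α = [1 + κ(1 − √(T/T_c))]²,
κ = 0.37464 + 1.54226ω − 0.26992ω². Volume roots come from the cubic in Z
(numpy polynomial roots), filtered to V > b and verified against the
pressure equation to 10⁻⁸ relative; with three real roots the smallest is
liquid-like, the largest vapor-like, and the middle mechanically unstable.
When several stable roots exist, the one minimising Σxᵢ ln φᵢ (lowest Gibbs
energy) is used.

Mixing rules:

* **van der Waals**: a = ΣΣ xᵢxⱼ√(aᵢaⱼ)(1−kᵢⱼ), b = Σxᵢbᵢ; fugacity
  coefficients in the standard closed form.
* **Wong–Sandler**: a/b = Σxᵢ(aᵢ/bᵢ) + Ḡᴱ/C_WS with
  C_WS = ln(√2−1)/√2 ≈ −0.623, and
  b = ΣΣ xᵢxⱼ[(bᵢ+bⱼ)/2 − √(aᵢaⱼ)/RT] / [1 − Σxᵢaᵢ/(bᵢRT) − Ḡᴱ/(C_WS RT)].
* **Huron–Vidal**: a/b = Σxᵢ(aᵢ/bᵢ) + Ḡᴱ/C_HV with C_HV = ln 2 and linear b.
  (Several textbook statements of these rules differ in the sign convention
  of the C constants; this package follows the forms above verbatim.)

The excess-Gibbs model is pluggable. Wilson is supplied in the form
Ḡᴱ = −RT Σᵢ xᵢ ln(Σⱼ xⱼΛᵢⱼ) with Λᵢⱼ = exp(−uᵢⱼ/RT) and no molar-volume
prefactor, plus an ideal (Ḡᴱ = 0) model and a user-callback hook. Note a
structural property with consequences: for a trace solute (y ~ 10⁻⁵) the
Wilson contribution to the solute fugacity saturates once Λ₂₁ ≪ y₂, so the
achievable suppression of ln y₂ is bounded by roughly −ln y₂; interaction
energies beyond ~RT·ln(1/y₂) have no further effect.

For WS/HV the fugacity coefficients are computed as central finite
differences of the total residual Helmholtz energy A_res(T, V, n)/RT with
respect to mole numbers at fixed (T, V), step 10⁻⁶·n (one-sided for a
component whose mole number is below the step, to stay inside the Wilson
composition domain), minus ln Z. This route is numerically exact partial
differentiation and is validated against the closed-form vdW expressions to
10⁻⁶ and against the Gibbs–Duhem relation.

Solid fugacity uses the subcooled-liquid reference:
ln(f^S/f^L) = ΔH_m/(RT_m)(1 − T_m/T) + (V̄^S − V̄^L)(P − P_atm)/(RT).
f^L and V̄^L are taken from the liquid-like root of the pure-solute PR EoS
at (T, P) (the only root at the studied states, since T/T_c ≈ 0.25).
All fugacity arithmetic is done in logarithms; f^L is of order 10⁻⁶ Pa here
and underflow-safe handling matters.

Equifugacity y₂φ₂P = f^S is solved by successive substitution in ln y from
y₀ = 10⁻⁵, full steps capped at |Δln y| = 2, tolerance |Δln y| < 10⁻¹⁰, with
an acceptance fallback when steps stop contracting below a 10⁻⁸ noise floor
(the finite-difference fugacities for WS/HV carry ~10⁻⁹ numerical noise that
a pure tolerance test cannot beat; the closed-form vdW route reaches the
strict tolerance). The map is a strong contraction because φ₂ barely depends
on a trace solute; 10–40 iterations suffice.

Binary-parameter regression minimises ALD-y. vdW: bounded scalar search for
k₁₂ in [−0.5, 0.5] (Brent, xatol 10⁻⁷). WS/HV with Wilson: multistart
Nelder–Mead over (u₁₂, u₂₁) in [−10⁵, 10⁵] J/mol (default 8 seeded starts
including the origin). Records where the solve fails are excluded from the
objective with a warning, counted, and penalised so optima avoid failure
regions.

## Synthetic data generator

The generator emulates the packaged study design: 4 × 6 (T, P) grid,
triplicate replicates, multiplicative lognormal noise y·exp(ε),
ε ~ N(0, σ²). Default σ = 0.03, chosen once from the mean relative replicate
scatter of the packaged study (mean Std(y)/y ≈ 0.029); replicate means, the
sample standard deviation and U = 2·std/√n are stored per record. Densities
come either from the packaged grid (PCHIP-interpolated off-grid) or from the
pure-CO₂ PR EoS (which carries the known ~5–10% PR density bias). For small
σ the expected AARD of a fit to such data is ≈ 100·√(2/π)·σ/√n_rep, which
the test suite checks over 20 seeds.

What the generator does **not** emulate: apparatus drift, equilibration-time
effects, UV-detection noise structure, density errors correlated across an
isotherm, and any systematic (non-random) measurement bias. Passing
recovery/noise-band tests therefore demonstrates correctness of the
estimation machinery under the stated statistical model, not robustness of
the laboratory procedure.

## Reproducibility and known limitations

* All stochastic elements (multistart draws) are seeded; the semi-empirical
  optima are anchored by the least-squares start and are seed-stable.
* Several quantities derived from these data are weakly identified: the
  Bartle temperature coefficient (above), and the (u₁₂, u₂₁) pair of the
  WS+Wilson rule on this system, whose ALD-y surface is a broad plateau in
  the saturation regime — AARD/ALD at the optimum are stable, the parameter
  pair itself is not unique.
* The PR description of this system is extremely sensitive to the solute's
  estimated critical constants (T_c = 1254.31 K, P_c = 1.6069 MPa means
  T_r ≈ 0.25 at study conditions, far outside the α-function's calibrated
  range); the subcooled-liquid fugacity inherits that entire extrapolation
  uncertainty, and published results computed with other internal
  conventions for this step are not generally recoverable from the
  equations alone.
* Multicomponent (co-solvent) systems, SRK, and σ-profile-based excess-Gibbs
  models are out of scope; the HV rule accepts a user excess-Gibbs callback
  instead.
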