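# Methods

## Scope and model

`freemetal` computes equilibrium speciation of mixtures of metal ions and
chelators: given total (or desired free) concentrations, it reports free,
bound and total amounts per species, plus pX = −log₁₀[free]. The model is
the classical conditional-constant treatment used by the MaxChelator
family of calculators: all pH and condition dependence is folded into one
apparent association constant per metal–ligand pair, after which the
mixture is a system of bilinear mass balances. Only 1:1
metal-to-ligand stoichiometry is modelled (ML and its protonated forms
MHₙL); polynuclear and ternary complexes, kinetics, and activity of the
free metal ion itself are out of scope — results are concentrations.

## Stored constants and conventions

Constant sets are data, not code. Each record stores log₁₀ *association*
constants on a molar basis at a reference temperature (°C) and reference
ionic equivalence (mM), with optional association enthalpies ΔH° (kJ/mol,
exothermic negative). Protonation ladders are *stepwise*: step 1 is the
first proton onto the fully deprotonated ligand, so its log K equals the
highest pKa. A complex with `protons = n` is defined from free metal plus
the ligand form already carrying n protons (`protons = 1` ⇒ M + HL ⇌ MHL);
cumulative constants from the bare ligand are reconstructed internally as
β_MHₙL = K_MHₙL · Π_{j≤n} K_Hj. These conventions are stated in the JSON
schema (`data/constant_set.schema.json`) so custom sets are
self-describing; unknown JSON keys round-trip untouched but never affect
computation.

The four shipped sources (NIST, Chelator, SPECS, Calcium) contain
representative values transcribed from the critical-stability-constant
literature for Ca/Mg(/Zn) with EGTA, EDTA and ATP, quoted at 20 °C and
100 mM. They are replaceable: any set in the interchange format works, and
differences between sources are real and substantial (which is why the
report echoes the source used).

## Corrections to working conditions

Order: temperature first, then ionic strength evaluated at the target
temperature. The order is a convention; because both corrections are
additive shifts on log K and only the Debye–Hückel slope A(T) couples
them, swapping the order moves log K_app by far less than 10⁻⁶ across the
validated ranges for |ΔH°| ≤ 60 kJ/mol (asserted on a grid in the test
suite).

**van't Hoff.** log K(T) = log K(T_ref) − (ΔH°/(ln10·R))·(1/T − 1/T_ref),
R = 8.31446 J/(mol·K), 0 °C = 273.15 K. A missing ΔH° means no correction
— the package does not guess enthalpies.

**Ionic strength.** The activity model is the extended Debye–Hückel form
used by this calculator lineage, log γᵢ = −zᵢ²·f with

    f(I, T) = A(T) · ( √I/(1+√I) − 0.25·I )

where the ionic equivalence Ie = ½ΣCᵢ|zᵢ| (in molar) is substituted
directly for I, and A(T) = 1.824829×10⁶·(ε(T)·T_K)^(−3/2) with the
Malmberg–Maryott polynomial for water's dielectric constant
(A ≈ 0.507 at 20 °C). Combining activity coefficients for an association
reaction gives

    log K(I) = log K(I_ref) − Δz²·(f(I) − f(I_ref)),
    Δz² = Σz²(reactants) − z²(product).

For Ca²⁺ + EGTA⁴⁻ → CaEGTA²⁻, Δz² = 4 + 16 − 4 = 16 > 0, so the apparent
constant falls as salt rises — the physically observed screening of a
charge-neutralizing association. The sign follows directly from
log γ = −z²f; implementations that quote the shift with a plus sign define
Δz² with the opposite orientation. Protonation constants receive the same
two corrections, using Δz² from the charges of the ligand forms; this is
why ligand charges are stored exactly.

Note a property of the chosen f: the −0.25·I tail gives it a stationary
point at I ≈ 0.485 M (where √I(1+√I)² = 2), so f increases strictly up to
~480 mM and is flat (variation < 5×10⁻⁵) over the last 20 mM of the
validated range. This is inherent to the formula, not an artifact. The
formula is isolated in `debye_huckel_term`, so an alternative (e.g., a
Davies 0.3·I term) is a one-line swap.

**Proton competition.** pH is taken as −log₁₀ of proton *concentration*;
no electrode activity conversion is applied (pre-correct the input pH if
needed). With condition-corrected stepwise constants K_Hj,
α = 1/(1 + Σᵢ (Π_{j≤i}K_Hj)[H⁺]ⁱ) is the metal-avid fraction of unbound
ligand, and K_app = α·Σₙ β_MHₙL[H⁺]ⁿ relates free metal to the *total*
unbound ligand pool. At reference conditions with no protonation and a
single ML complex this reduces exactly to K_app = 10^{log K}.

Conditions are validated against closed ranges 0–40 °C, pH 0–14, and
(0, 500] mM ionic equivalence; violations are returned as data (one
message per field) so a front end can show all of them.

## Solver

Unknowns are the free metal and free (unbound-total) ligand
concentrations. The iteration alternates the closed-form updates
L_j ← L_T,j/(1 + Σₘ K·M_m) and M_m ← M_T,m/(1 + Σⱼ K·L_j) from the
starting point M = M_T, L = L_T. Each variable acquires a 0.5 damping
factor the first time its update direction flips (the undamped map
oscillates in strongly buffered regimes). Convergence requires both the
maximum relative change *and* the maximum relative mass-balance residual
below 10⁻¹² (the residual condition is what the conservation guarantee is
stated in terms of); the iteration cap is 10 000, after which a
single-unknown problem falls back to bisection of the monotone residual
and anything else raises with the last residual attached. Typical
mixtures converge in 50–150 iterations.

In free-known mode the prescribed metals are simply never updated; the
required total is read off afterwards as free·(1 + ΣK·L). Multiple
free-known metals are supported by fixing all of them (an extension beyond
single-metal use). Bound amounts are K·M_free·L_free per pair; zero-
concentration species stay in the result with free = total = 0 so the
report shape is stable; pX is omitted (None) for zero free values.

All concentrations convert to molar on ingestion. The conversion is a
decimal exponent shift, so power-of-ten units are exact (250 nM is
exactly 2.5×10⁻⁷). Chelator purity scales the nominal concentration
before solving: effective = nominal × purity/100, purity ∈ (0, 100].

**Precision.** The solver runs in native floats by default or, via
`ArithmeticContext(mode="arbitrary-precision")`, in `decimal.Decimal`
arithmetic at a configurable number of significant digits (default 50,
minimum 15 — the native float capability). The iteration is identical in
both modes. On the standard titration grid the two modes agree to better
than 10⁻¹⁵ relative, which is the package's quantitative restatement of
the observation that these calculations are not limited by double
precision; the decimal mode exists to let users verify that on their own
inputs.

## Synthetic fixtures and the oracle

`fixtures.make_synthetic_constant_set` draws validate-clean sets from
seeded uniform ranges: complex log K in [2, 11] (spanning ATP-weak to
EGTA-strong binding), protonation pK in [1, 10] with ladders sorted so
step 1 is the most basic site, divalent metals, tetravalent anionic
ligands, and an MHL complex 4–8 log units weaker than ML wherever a
ladder exists. Random mixtures draw totals from 0.05–5 mM with purities
90–100 %. All draws use `numpy.random.default_rng(seed)`; the seed is
recorded in the set's citation field.

What the generator does *not* emulate: correlated errors between
constants of one source, temperature-dependent enthalpies, ternary
species, or measurement noise — passing tests show the solver reproduces
the stated model to tight tolerance, not that any constant source matches
a particular lab's reality.

The verification oracle shares no code with the production solver: for
trial free-metal values the ligands are eliminated in closed form, and
each metal's strictly increasing mass-balance residual is bracketed on
[0, M_T] by `scipy.optimize.brentq` (rtol 10⁻¹⁵, absolute tolerance
pushed to 10⁻³⁰ so it never dominates at nanomolar free values), nested
per metal and therefore limited to 3×3 systems. The production solver and
the oracle agree to better than 10⁻¹⁰ relative on hundreds of seeded
instances; 1:1 systems additionally match the numerically stable quadratic
closed form.

## Reporting

Sessions are append-only; export produces one workbook per session with a
`summary` sheet (one row per calculation: source, conditions, headline
free/pX per metal) and long-format `calc_N` sheets (entity, quantity,
value, unit), honouring the per-calculation report selections. Exported
numbers are rounded to a display precision of 10 significant digits
(configurable) — below solver tolerance, above lab needs, and chosen so
that re-reading the workbook reproduces every value exactly (spreadsheet
writers serialize at most 16 significant digits, so raw-double fidelity
is not achievable; explicit rounding makes the round trip exact by
construction). CSV and JSON exports mirror the same content for
pipelines.

## Problem sizes used in the shipped checks

The acceptance script and test suite run a 20-point total-Ca titration of
the 2 mM ATP / 1 mM EGTA / 6 mM Mg buffer at pH 7.0, 20 °C, 100 mM; 100
seeded 2×2 random systems (plus 3×3 spot checks) against the brute-force
oracle; and 3-point free↔total inversions. These sizes give worst-case
discrepancies two to four orders of magnitude below the asserted
tolerances and complete in seconds.

## Known limitations

- No ΔCp: enthalpies are treated as temperature-independent over 0–40 °C.
- Ionic-equivalence substitution for ionic strength is a lineage
  convention, not thermodynamic rigor; at Ie far from the reference the
  correction is an extrapolation.
- Constants without ΔH° are silently left uncorrected for temperature;
  mixing corrected and uncorrected records at T ≠ T_ref is only as
  consistent as the source data.
- pH is concentration-based; electrode readings are activity-based and
  should be pre-corrected by the user.
- The shipped constant values are representative transcriptions; for
  publication-grade work, verify them against the primary literature and
  cite the set used.
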