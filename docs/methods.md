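# Methods

This note documents the models implemented in `fetiron`, the conventions
and defaults they use, the numerical choices behind the solvers, and
what the synthetic-data generators do and do not emulate.

## Speciation model

Species set: free ligand L⁴⁻ and its protonated forms HL, H₂L; free
Fe³⁺; the complexes FeL, FeL₂, FeL₃; and the mixed hydroxo species
FeL₂H₋₁ (≡ [FeL₂(OH)]⁶⁻). Constants (decadic logs, concentration
constants at I = 0.15 M, 25 °C):

| constant | meaning | default |
|---|---|---|
| logK₁ᴴ, logK₂ᴴ | stepwise ligand protonation, Kᵢᴴ = [HᵢL]/([Hᵢ₋₁L][H⁺]) | 12.40, 7.46 |
| logK_FeL, logK_FeL₂, logK_FeL₃ | stepwise stability, K = [FeLₓ]/([FeLₓ₋₁][L]) | 20.32, 14.49, 9.83 |
| logK_FeL₂H₋₁ | protonation constant [FeL₂]/([FeL₂H₋₁][H⁺]) | 7.86 |
| pKw | stoichiometric water ionic product | 13.77 |
| pA | electrode offset, pH_true = pH_read − pA | 0.02 |

The hydroxo species is parameterised as a protonation constant so that
its population grows above pH ≈ 7.9, consistent with the base-consuming
process observed at 1:2 metal-to-ligand ratios. Activity corrections
are deliberately absent: the constants are concentration constants at
fixed ionic strength, and temperature/ionic strength are carried as
metadata only.

**Solver.** At fixed [H⁺] = 10^(−pH) the iron mass balance is *linear*
in free [Fe³⁺] once free [L⁴⁻] is given, so [Fe³⁺] is eliminated
exactly and a single monotone scalar equation in log₁₀[L⁴⁻] remains.
It is bracketed on [−40, 0] and solved with Brent's method
(xtol 1e−15), which guarantees a positive root and machine-precision
mass balances (the tests enforce < 1e−10 relative everywhere on a grid
of totals and pH). This replaces a 2-D damped-Newton iteration: the
exact elimination makes the 1-D problem strictly better conditioned and
removes any dependence on starting guesses.

Full proton bookkeeping (with pKw) is used only when simulating
base-volume titrations: the ligand is delivered as H₂L, so the total
dissociable proton content is `initial_acid + 2·total_L`, and the added
base volume at each pH is found by root-finding on the proton balance
including dilution.

**Constant refinement** (`TitrationFit`) is Levenberg–Marquardt least
squares over any subset of the logK constants and, optionally, molar
absorptivities; 1σ uncertainties come from the SVD-based covariance of
the Jacobian at the optimum, and a rank-deficiency warning is recorded
whenever the Jacobian loses rank (e.g. more free ε+K than informative
data).

## Relaxivity model

Total relaxivity is the sum of inner-sphere (IS), second-sphere (SS)
and outer-sphere (OS) contributions, each per mM of complex.

IS and SS use the exchange-limited dipolar form

    r₁ = P_m / (T₁M + τ_M),  P_m = q·10⁻³/55.6
    1/T₁M = (2/15)(μ₀/4π)² γ_I² g² μ_B² S(S+1) r⁻⁶ ·
            [3τ_c1/(1+ω_I²τ_c1²) + 7τ_c2/(1+ω_S²τ_c2²)]
    1/τ_ci = 1/τ_R + 1/τ_M + 1/T_ie

with the ω_I spectral density paired with τ_c1 (T₁e) and the ω_S
density with τ_c2 (T₂e). The SS term reuses the full form with
(q_SS, r_SS, τ_R^SS, τ_M^SS); τ_M^SS defaults to 1 ns, short enough not
to limit relaxivity — at that value the full form and the fast-exchange
simplification differ by well under 1 %, and the full form is used.
Scalar (contact) ¹H relaxation is omitted (dipole–dipole dominated).

Electron relaxation is the transient-ZFS (Bloembergen–Morgan) model for
S = 5/2:

    1/T₁e = (Δ²τ_v/25)[4S(S+1)−3]·[u₁ + 4u₂]
    1/T₂e = (Δ²τ_v/50)[4S(S+1)−3]·[3 + 5u₁ + 2u₂],  u_n = 1/(1+n²ω_S²τ_v²)

so T₁e = T₂e at zero field and both diverge when Δ² = 0. The OS term is
Freed's hard-sphere translational model,

    r₁^OS = (32π/405)(μ₀/4π)² γ_I² γ_S² ħ² S(S+1) · N_A·1 mol m⁻³/(aD) ·
            [3J(ω_I, T₁e) + 7J(ω_S, T₂e)]
    J(ω, T_je) = Re[(1 + z/4)/(1 + z + 4z²/9 + z³/9)],  z = √(iωτ_D + τ_D/T_je)

with τ_D = a²/D. These closed forms were validated, before any fitting
code existed, against an independent scalar transcription; the tests
keep that transcription as a permanent oracle (1e−10 relative agreement
on random parameter draws).

**Temperature laws.** Correlation times and Δ² follow Arrhenius
behaviour τ(T) = τ²⁹⁸·exp[E/R(1/T − 1/298.15)] (E > 0 ⇒ shorter at
higher T); diffusion follows the inverse (rate-like) form; the exchange
rate 1/τ_M follows Eyring,
k_ex(T) = k_ex²⁹⁸·(T/298.15)·exp[ΔH_M/R(1/298.15 − 1/T)]. "298 K"
reference values mean 298.15 K throughout.

**Units at the API.** Distances in Å, τ_R/τ_v in ps, τ_M in s, energies
in J/mol, Δ² in s⁻², D in m²/s; every field name carries its unit. The
reported ²⁹⁸D of 2.24×10⁵ cm² s⁻¹ in the source table is a typographic
slip for 2.24×10⁻⁵ cm² s⁻¹ (the standard aqueous value); the fixtures
store 2.24×10⁻⁹ m² s⁻¹. Field points are specified as proton Larmor
frequency in MHz with ω_S = 658.21·ω_I.

With the literature parameter bundles the model reproduces the printed
298 K relaxivities of all three Tiron complexes at 60 and 120 MHz
within a few percent (see the test suite and `scripts/acceptance.py`);
component shares are more convention-sensitive: the second-sphere share
of the tris complex evaluates to ≈61–65 % depending on field, at the
lower edge of the 65–70 % quoted from graphical decomposition.

## ¹⁷O model

Reduced quantities are per mole fraction of bound water. The bound-site
shift is Δω_m = g μ_B S(S+1) B₀/(3k_B T)·(A_O/ħ); the bound-site
transverse relaxation is scalar-dominated,
1/T₂m = (S(S+1)/3)(A_O/ħ)²τ_s with 1/τ_s = 1/τ_M + 1/T₁e and T₁e
evaluated at the electron frequency of the spectrometer field
(11.74 T default). The observed reduced rate and shift follow
Swift–Connick:

    R₂r = (1/τ_M)·[T₂m⁻² + (T₂m τ_M)⁻¹ + Δω_m²] / [(T₂m⁻¹+τ_M⁻¹)² + Δω_m²]
    Δω_r = Δω_m/[(1+τ_M/T₂m)² + (τ_M Δω_m)²] + C_os·Δω_m

C_os is the empirical outer-sphere shift coefficient: it scales Δω_m
into the observed shift only and never contributes to R₂r — the
convention that reproduces its role as a small (0.04–0.05) correction.
The ¹⁷O dipolar relaxation pathway is omitted. Exchange-regime labels
compare τ_M with T₂m (slow > 10, fast < 0.1, intermediate between).

Limiting behaviour: τ_M → ∞ gives R₂r → 1/τ_M (slow exchange);
τ_M → 0 gives R₂r → 1/T₂m + τ_M Δω_m² − τ_M/T₂m². Note the middle term
is a *constant fraction* of 1/T₂m when T₂m itself is exchange-limited
(both scale with τ_M), so the naive "R₂r → 1/T₂m" is only an
approximation; the tests assert the exact closed-form limit.

## Global fit

`GlobalRelaxationFit` refines any subset of the union of ¹H and ¹⁷O
parameters against NMRD profiles and ¹⁷O datasets simultaneously.
τ_M, ΔH_M, Δ², E_Δ, τ_v and E_v are shared between branches; Δ²(T)
enters both with the same Arrhenius law.

* **Weighting.** Residuals of each dataset are divided by that
  dataset's mean observed magnitude (or its σ column when present), so
  ¹H and ¹⁷O blocks contribute comparably regardless of units. The
  relative weighting is configurable per dataset label; the
  normalisation choice is a documented default, since nothing in the
  source analysis fixes it.
* **Parameter scaling.** Positive parameters (times, Δ², distances,
  diffusion) are optimised in log₁₀; A_O/ħ is optimised as a log
  magnitude with the sign frozen at its starting sign; energies and
  C_os stay linear. Default bounds: one decade around the start for
  log-scale parameters, ±3·max(|x₀|, 1) for linear ones.
* **Multi-start.** Bounded trust-region least squares from the supplied
  starting vector plus 7 log-uniform draws within bounds (8 starts,
  seeded generator) — the analysis this reimplements is silent on
  initialisation, and a single-start fit would not be reproducible.
  Identical seed and problem give bit-identical results.
* **Uncertainties.** SVD-based covariance of the internal Jacobian at
  the optimum, delta-method transformed to natural units. Rank
  deficiency raises a recorded warning rather than an exception, as
  does the structurally unidentifiable case of a q = 0 complex with no
  ¹⁷O data and free exchange/hyperfine parameters.

On synthetic bis-complex data (4-temperature NMRD, 30 log-spaced
frequencies over 0.01–500 MHz, plus a 278–310 K ¹⁷O set) the fit
recovers Δ², τ_v, τ_R, τ_M and A_O/ħ exactly (≤0.1 %) without noise and
well within 20 % at 1 % relative noise — comparable to the ±21 %
uncertainty quoted for τ_M in the reference analysis.

## Kinetics

Single traces follow A(t) = A_p + (A₀ − A_p)e^(−k_d t); both endpoints
are fitted by default (endpoint drift) and can be frozen. Constant
traces raise a degenerate-trace error; traces spanning < 2 half-lives,
with < 5 points, or with < 20× CDTA excess are flagged with warnings,
not rejected.

The observed rate constant combines spontaneous dissociation of FeL₃
with proton- and CDTA-assisted dissociation of FeL₂:

    k_d = x_FeL₃·k₀ + x_FeL₂·(k₁[H⁺] + k₄[H⁺][CDTA])

The FeL₃/FeL₂ mole fractions come from the speciation solver run with
the *kinetically determined* stability constant (logK_FeL₃ = 9.20
rather than the equilibrium 9.83) and with the hydroxo species
excluded, renormalised over the two species — which dominate under the
experimental conditions (pH 5.0–7.5, 5-fold Tiron excess). This
pathway-weighted form reproduces the reported k_d = 1.1×10⁻⁴ s⁻¹ at
pH 7.4 to ≈2 %. The CDTA dependence is linear: whether k_d saturates at
high CDTA excess cannot be decided from the available information, so
the linear form is used and isolated behind one function for easy
replacement. A separate hydroxide-assisted law
(k₀ + k_OH[OH⁻] + k_OH²[OH⁻]², [OH⁻] from pKw = 13.77) serves the
inertness comparison with the aminopolycarboxylate complexes.

Rate-constant refinement (`RateLawFit`) fits log₁₀k₀, log₁₀k₁, log₁₀k₄
and logK_FeL₃ to a table of (conditions, k_d) with relative residuals
(k_d spans decades); a design without CDTA variation flags k₄ as
unidentifiable.

## Synthetic data

Generators mirror the published measurement designs: NMRD at
283/288/298/310 K over 30 log-spaced frequencies (0.01–500 MHz), ¹⁷O
over 278–310 K at 11.74 T, absorbance titrations at 0.19 mM Fe /
9.1 mM Tiron across pH 0.5–10, and kinetic traces at 0.1 mM Fe,
0.5 mM Tiron with 2–8 mM CDTA over pH 5.0–7.5, each spanning four
half-lives. Noise is Gaussian (relative or absolute) with a mandatory
integer seed whenever σ > 0, applied through one `numpy` Generator so
datasets are bit-reproducible across platforms; the 1 % default for r₁
follows the stated measurement uncertainty. Noiseless generation equals
the forward model exactly, which the round-trip tests exploit:
generate(θ, σ=0) → fit → θ.

What the generators do *not* emulate: baseline drift, field-calibration
error, temperature-gradient artifacts, pH-electrode hysteresis, or any
correlated noise. Passing the recovery tests therefore demonstrates
correctness and identifiability of the estimation chain under the ideal
noise model, not robustness to instrument systematics in real
measurements.

## Numerical choices and degenerate inputs

* Speciation: Brent bracketing on [10⁻⁴⁰, 1] M free ligand; zero totals
  short-circuit analytically (no metal ⇒ ligand distributed by
  protonation alone).
* Titration ε validation: a species carrying > 10⁻⁶ of total Fe without
  a molar absorptivity raises immediately.
* Exponential trace fitting seeds k_d from the 1/e crossing of the
  observed span, then refines with bounded least squares; k_d ≥ 0 is
  enforced by bounds.
* All "298" parameters are exact at T = 298.15 K by construction of the
  temperature laws.
* Electron relaxation with Δ² = 0 returns infinite T₁e/T₂e and the
  correlation times fall back to rotation/exchange — used to isolate
  dispersion behaviour in tests.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full analysis at the
study's own designs (120-point NMRD grids, 9-point ¹⁷O sets, 24-point
kinetic grids, 40-point titrations). Oracle-equivalence checks use 50
random instances per module with a 10⁵–10⁶-point grid oracle for
speciation; replicate studies use 6–12 seeded repetitions, sizes chosen
so the whole suite completes in well under a minute on one core while
keeping every statistical bound comfortably away from its threshold.

## Known limitations

* Static-ZFS electron relaxation, Curie relaxation and r₂ are out of
  scope; at fields ≫ 3 T the transient-ZFS model underestimates
  electron-relaxation anisotropy effects.
* The hydroxo complex FeL₂H₋₁ borrows the bis-complex relaxation
  parameters in pH-profile predictions (its population is < 1 % under
  the 1:50 conditions where those predictions are compared).
* No activity-coefficient model: constants are valid at the ionic
  strength where they were determined.
* The linear-in-[CDTA] rate law extrapolates poorly if the true
  mechanism saturates at high excess.
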