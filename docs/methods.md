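# Methods

## Model

The package couples SIR disease dynamics to a contact-based awareness
process in a well-mixed population of fixed size N. Compartments are
indexed by disease state (S, I, R), behavioural group (trusting T,
distrusting D) and awareness level i ∈ {0, …, K−1, ∞}. Level 0 is
first-hand information (a diagnosed infection); each transmission or
fading step degrades quality by one level; ∞ is complete unawareness.

Events and rates:

- **Infection.** A susceptible at level k meets infected individuals at
  level i and is infected at rate (β/N)(1 − ρ^i)(1 − ρ^k) per pair: both
  parties' precautions reduce transmission. Fully aware infected (level 0)
  transmit nothing — self-isolation upon diagnosis.
- **Recovery** at rate σ, preserving group and level.
- **Refresh.** Infected individuals at any level ≥ 1 (including ∞) move
  to level 0 at rate ω. Including the unaware reservoir in the refresh is
  required for an epidemic seeded in a fully unaware population to
  generate any information at all.
- **Information exchange.** A trusting individual at level j adopts from
  any contact at level i < j, landing at i + 1; a distrusting individual
  adopts from contacts at i > j (the unaware reservoir counts as the
  worst source), landing at i + 1. Encounter rates α_T/N and α_D/N per
  pair. Sources are individuals of every disease state and group.
- **Fading** at rate λ: level k → k + 1, level K−1 → ∞; the reservoir
  does not fade further.

All moves are transfers between compartments, so the right-hand side
conserves N exactly (to floating-point accumulation, tested at 1e−12·N).
Summing over groups and levels yields aggregate SIR dynamics
dS/dt = −β̃SI/N with the awareness-weighted effective rate β̃
(tested at 1e−10·N), and R_e = β̃/σ. R_e is reported exactly as β̃/σ —
without a susceptible-depletion factor — matching its role as a
transmissibility (not growth) measure here; when I or S is zero the
weights are undefined and the fresh-population value β is returned with a
logged note.

## Truncation of the awareness ladder

The awareness index is unbounded in principle. The package retains K
finite levels plus an explicit ∞ reservoir. Boundary semantics: a
trusting receiver lands at min(i+1, K−1) — it stays in the aware chain,
since for the default K its protection there is numerically
indistinguishable anyway; a distrusting receiver adopting from level K−1
or from the reservoir falls into the reservoir ("worse than resolved"
information); fading out of K−1 enters the reservoir. The default depth
is the smallest K with ρ^(K−1) < 1e−6, i.e. the protection factor at the
deepest resolved level differs from the unaware factor by less than 1e−6.
Doubling K changes trajectory summaries by < 1e−6 relative (tested).

In the fast-information regime (α ≳ 10⁴) the population concentrates on
levels {0, 1, ∞} and the occupancy of level 2 is already of order
λN/(α n₀); phase-boundary searches there use a fixed shallow truncation
(K = 6), which reproduces the default-rule results to 8 significant
digits at a fraction of the cost (the deep default truncation at large ρ
makes the stiff solves needlessly expensive).

## Numerical integration

`scipy.integrate.solve_ivp` with LSODA, rtol 1e−8, atol 1e−12·N. LSODA
behaves like an explicit method while the system is non-stiff (moderate
α) and switches to BDF automatically; the fast-information regime
(α = 10⁶) makes the exchange terms extremely stiff and is intractable for
purely explicit methods. Negative values are never clipped inside the
right-hand side; trajectories are clipped at 0 only when evaluating the
effective transmission rate on stored output (solver undershoot is below
atol). Internal dynamics are homogeneous of degree one in the
compartments, so results are invariant to N (tested at 1e−6 relative
between N = 1 and N = 10⁶).

Integration runs as a single adaptive pass to a generous horizon
(16 000 d by default, because near the phase boundary the infection level
plateaus and epidemics extend enormously), terminated early by an event
when the total infection falls below the epidemic-over threshold (default
1e−7·N, i.e. fewer than one case per 10⁷). A single pass matters
numerically: restarting the solver mid-plateau forces LSODA to re-detect
stiffness from a cold start and can stall it in the fast-information
regime. The stored series resamples the dense output on a uniform grid
over the realised interval. The peak is located on dense output with local quadratic
refinement around the discrete argmax (plateaus make the raw argmax
noisy). The epidemic duration is the first post-peak crossing of the
epidemic-over threshold, or the horizon if none.

Initial condition: infected density 5e−6 in the unaware reservoir of
*each* group (so d ≥ 5e−6 and 1 − d ≥ 5e−6 are required), the remainder
susceptible and unaware.

## Regime classification and boundary location

Suppression is declared when the peak prevalence stays strictly below a
threshold, default 1e−4 (ten times the total seed); "very low peak" is
not otherwise quantified, and the threshold is configurable. A trajectory
still rising at the fully extended horizon is labelled undetermined; a
trajectory whose maximum is covered is classified even if its tail has
not yet died out — suppressed epidemics at moderate α decay over many
thousands of days while R_e hovers just below the growth threshold.

Two boundary detectors are implemented. The bisection detector finds the
ρ at which the peak crosses the classification threshold; the
time-to-peak detector finds the ρ maximising t_peak (coarse grid plus
golden-section refinement), exploiting the plateau at the transition
where epidemics are longest. They agree to a few hundredths in ρ in the
fast-information regime (tested); the bisection detector is the default
because near-boundary plateau runs make the argmax search several times
more expensive. Both return "unachievable" (nan) when the whole search
bracket lies in the mitigation regime, which happens for d above the
critical density d_M = σ/β.

## Fast-information limit

With α_T, α_D → ∞ the model reduces to five compartments (trusting S/I at
levels 0–1, distrusting mass at ∞). Assuming the infected sub-groups are
metastable at the transition — dI₀/dt = 0 gives I₀ = ω/(σ+λ)·I₁, and
stationarity of the unaware infected with S_∞/N ≈ d gives
I_∞ = βd(1−ρ)/(σ−βd)·I₁ — the total-infection stationarity condition
becomes a quadratic in x = 1 − ρ with coefficients a = (1−d)(1+dy) > 0,
b = d(1+dy−y/R₀) and c = −(1/R₀)(1+ω/(σ+λ)) < 0, y = β/(σ−βd). The sign
structure guarantees exactly one positive root x₊, and ρ_c(d) = 1 − x₊.
Algebraically 1 + dy = y/R₀, so b vanishes identically and
x₊ = sqrt(−c/a); the general quadratic form is kept as the primary
expression and the root is verified against an independent bisection
solve and by residual substitution (< 1e−12). At d = 0 this gives
ρ_c(0) = 1 − sqrt((σ/β)(1 + ω/(σ+λ))) — note the radical, which a naive
reading of the d = 0 specialisation can drop. Values ρ_c ≤ 0 are
reported as 0 with an "always suppressed" flag (suppression at any ρ);
d = d_M itself is classified unachievable since y is singular there.

The reduced model is only the α → ∞ limit: at α = 10⁶ with the default
seed the residual finite-α correction (level-2 occupancy of order
λ/(αn₀)) is a few percent early in the outbreak and compounds over a full
epidemic, so the consistency test asserts convergence — the projected
full trajectory approaches the reduced one roughly like 1/α, with sup-norm
mismatch below 5% at α = 10⁸ — rather than a fixed tolerance at 10⁶. The
boundary agreement at α = 10⁶ (numeric vs analytic within ±0.03 in ρ) is
unaffected.

## Problem sizes and defaults

Default study conditions follow the headline configuration: σ = 0.133/d,
λ = 0.2/d, ω ≈ 0.33/d, seed 5e−6 per group, β chosen by the target R₀
(0.267–0.667 for R₀ 2–5). Phase scans default to a 41 × 41 grid on
(ρ, d) ∈ [0.02, 0.98] × [0, 0.95]; the test suite and the acceptance
script use reduced grids (boundary checks at d ∈ {0.05, 0.15, 0.25} for
β ∈ {0.333, 0.467}, monotonicity on 4–5-point grids) chosen to exercise
every ordering the full-resolution figures display.

## Limitations

- Deterministic ODE (law of large numbers) only; no demographic noise,
  no stochastic extinction at the seed scale.
- Well-mixed contacts; no network or spatial structure.
- Fixed composition d and fixed ρ; no opinion dynamics, no time-varying
  policy, no vaccination.
- SIR without demography or waning immunity: no reinfection.
- The analytic threshold assumes instantaneous information spread and
  metastability of all infected sub-groups; at moderate α the true
  boundary shifts upward in ρ and the closed form is only indicative.
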