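# awaresir

Coupled awareness–epidemic modelling for heterogeneously trusting
populations.

`awaresir` implements an SIR model whose transmission is modulated by a
contact-based information (awareness) process in a population split into
**trusting** individuals — who adopt better-quality outbreak information
from the people they meet and take protective measures accordingly — and
**distrusting** individuals — who adopt *worse*-quality information,
modelling susceptibility to misinformation. It is aimed at infectious
disease modellers studying behaviour-change feedback and the population
level cost of distrust in public-health messaging.

## The model

Each individual carries an awareness level *i* ∈ {0, 1, 2, …, ∞}: level 0
is fresh first-hand information, larger *i* is staler information, and ∞
is complete unawareness. An individual at level *i* reduces transmission
by the protection factor (1 − ρ^*i*), where ρ ∈ [0, 1) is the
effectiveness of non-pharmaceutical interventions; the factor applies to
both parties of a contact, so the transmission rate between an infected
individual at level *i* and a susceptible at level *k* is
β (1 − ρ^*i*)(1 − ρ^*k*). Information moves by contact: a trusting
individual at level *j* meeting anyone at level *i* < *j* adopts the
information at quality *i* + 1, while a distrusting individual adopts from
sources with *i* > *j*; encounter rates are α_T and α_D. Awareness fades
one level at rate λ, and infected individuals refresh to level 0 at rate ω
(diagnosis). Disease dynamics are SIR with recovery rate σ. Summing over
awareness levels gives aggregate SIR dynamics with the effective rate

    β̃ = β · Σ_{i,j} (1 − ρ^i)(1 − ρ^j) (I_i/I)(S_j/S),    R_e = β̃/σ.

Two regimes emerge: **suppression** (the awareness feedback keeps the
outbreak at the seed scale) and **mitigation** (a large outbreak with a
reduced, delayed peak), separated by a critical curve ρ_c(d) in the
(d, ρ) plane, where d is the density of distrusting individuals. In the
fast-information limit (α_T, α_D → ∞) the model collapses to five
compartments and a metastability argument yields ρ_c(d) = 1 − x₊(d) with
x₊ the positive root of

    x²(1 − d)(1 + dy) + x d(1 + dy − y/R₀) − (1/R₀)(1 + ω/(σ + λ)) = 0,

y = β/(σ − βd), R₀ = β/σ. Suppression is impossible at any ρ < 1 beyond
the critical distrusting density **d_M = σ/β = 1/R₀**.

## Worked example

```python
from awaresir import ModelParams, integrate, summarize, critical_rho_analytic

params = ModelParams(beta=0.667, sigma=0.133,   # R0 ~ 5
                     rho=0.8, d=0.1,            # strong NPIs, 10% distrust
                     alpha_T=5.0, alpha_D=5.0, lam=0.2, omega=0.333)
traj = integrate(params, t_max=1000.0)
s = summarize(traj)
print(f"peak I/N = {s.peak_I:.3g} at day {s.t_peak:.1f}; "
      f"final S/N = {s.final_S:.4f}")

fast = params.with_(beta=0.333, alpha_T=1e6, alpha_D=1e6, omega=0.33)
print(f"rho_c(0.15) = {critical_rho_analytic(0.15, fast).rho_c:.4f}")
```

prints

```
peak I/N = 8.39e-05 at day 16.0; final S/N = 0.9610
rho_c(0.15) = 0.2357
```

The first line says that with 10% distrust and ρ = 0.8 the behavioural
feedback caps the outbreak at a peak prevalence of about 8 per 100 000 —
the suppression regime — and ~96% of the population is never infected.
The second gives the analytic threshold for a slower disease (R₀ ≈ 2.5)
under near-instant information spread: NPI effectiveness above ρ ≈ 0.24
suppresses the outbreak when 15% of the population is distrusting.

The same computations are available from a shell:

```bash
awaresir simulate --beta 0.667 --rho 0.8 --d 0.1 --out-dir out/
awaresir critical-curve --beta 0.333 --omega 0.33 --out-dir out/
awaresir phase --config examples/phase.yaml --out-dir out/
```

`simulate` writes `trajectory.csv` (time, S, I, R, β̃, R_e) and
`summary.json`; `phase` writes a long-format grid CSV plus a boundary
JSON; `critical-curve` writes ρ_c(d) with the achievability flags and d_M.

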