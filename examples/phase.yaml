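# Small suppression/mitigation phase scan in the fast-information regime.
# The analytic fast-limit boundary for these rates crosses the rho grid
# between d = 0 (rho_c ~ 0.11) and the critical density d_M ~ 0.4.
beta: 0.333
sigma: 0.133
alpha_T: 1.0e6
alpha_D: 1.0e6
lam: 0.2
omega: 0.33
K: 6
rho_grid: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
d_grid: [0.05, 0.15, 0.25, 0.35, 0.45]
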