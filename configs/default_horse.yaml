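# Prior hyperparameters and MCMC settings for the Bayesian adjustment.
rho_beta_a: 3.0
rho_beta_b: 1.0
tau_scale: 1.0
phi_scale: 1.0
b_lower: -10.0
b_upper: 10.0
mu_prior_sd: 1.0
sx2_prior_scale: 1.0
prior_family_gy: horseshoe
n_chains: 4
n_iterations: 15000
burn_in_fraction: 0.20
seed: 1
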