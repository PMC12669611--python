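# Main simulated scenario: collider bias in a progression GWAS of a
# 40%-prevalence disease with strongly positively correlated pleiotropy.
n_individuals: 10000
n_snps: 2000
frac_null: 0.95
frac_inc_only: 0.01
frac_prog_only: 0.01
frac_pleio: 0.03
rho: 0.7
r2_inc_only: 0.5
r2_inc_pleio: 0.5
r2_prog_nonpleio: 0.5
r2_prog_pleio: 2.0
h2_liability: 0.40
h2_prog_range: [0.30, 0.40]
confounder_var_range: [0.30, 0.40]
lambda_: 0.1
gamma: 1.5
prevalence: 0.40
maf_range: [0.01, 0.49]
seed: 1
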