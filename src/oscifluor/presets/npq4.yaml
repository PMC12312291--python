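k1_plus: 250.0
k1_minus: 100.0
k3: 0.01
k4: 0.001
k6: 8.0
k9: 5.0e-05
k10: 0.004
KQ_VDE: 1.0
KQ_PsbS: 1.0
n_VDE: 6.0
n_PsbS: 4.0
Zea_max: 0.3
PsbS_max: 0.3
a: 0.09202
k2: 281.25
K_PQ: 0.05
k5: 11.1606045627
sigma_II: 2.8871903751
sigma_I: 6.0
beta_H: 0.0826086956522
n_H: 1.0
k_leak: 1.0
H_0: 0.1
A_tot: 10.0
PQ_tot: 21.0
nu_e: 2.0
phi_II_max: 0.83
genotype: npq4
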