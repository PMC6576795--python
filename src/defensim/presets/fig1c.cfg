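# preset: fig1c
# provenance: uncontested logistic colony growth on a 40x40 habitat
# intended sweep axes: occupancy vs. generation at eps in {1, 0.1, 0.01}
mode = NONE
test = NONE
M = 40
Dt = 0.1
u = 100
eps = 0.01
rho_B0 = 1.0
alpha_B = 0.5
alpha_P = 0.5
beta_P = 0.0
gamma_B = 0.3
gamma_P = 0.4
r_B0 = 0.8
r_P0 = 0.8
a = 1.0
T = 1.0
k = 25.0
n_B0 = 1
n_Pt = 10
f = 0.0
kappa = 1
max_generations = 200000
D = 5.0
phi = 0.5
beta_B = 0.6
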