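# preset: fig3a
# provenance: minimal sustainable colony size map, efflux beta_B=1.0, decay phi=0.2
# intended sweep axes: D x CSI
mode = NONE
test = TEST2
M = 100
Dt = 0.1
u = 100
eps = 0.01
rho_B0 = 1.0
alpha_B = 0.5
alpha_P = 0.5
beta_P = 0.0
gamma_B = 0.4
gamma_P = 0.4
r_B0 = 0.8
r_P0 = 0.8
a = 1.0
T = 1.0
k = 25.0
n_B0 = 100
n_Pt = 10
f = 0.01
kappa = 1
max_generations = 100000
c = 0.4
phi = 0.2
D = 5.0
beta_B = 1.0
tau = 0
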