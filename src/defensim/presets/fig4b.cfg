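# preset: fig4b
# provenance: MSC vs efflux at decay phi=0.9, diffusion D=0.5
# intended sweep axes: beta_B x CSI
mode = NONE
test = TEST2
M = 100
Dt = 0.1
u = 100
eps = 0.01
rho_B0 = 1.0
alpha_B = 0.6
alpha_P = 0.6
beta_P = 0.0
gamma_B = 0.3
gamma_P = 0.3
r_B0 = 0.8
r_P0 = 0.8
a = 1.0
T = 1.0
k = 25.0
n_B0 = 100
n_Pt = 10
f = 0.01
kappa = 300
max_generations = 100000
c = 0.1
phi = 0.9
D = 0.5
beta_B = 0.5
tau = 0
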