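# Default model parameters. Flat mapping: symbol -> value.
# Units and meaning are given in trailing comments.

# --- membrane ---
C_m: 0.08  # [nF] membrane capacitance of the isopotential postsynaptic compartment
g_L: 8.0  # [nS] leak conductance
V_L: -75.0  # [mV] leak reversal potential (MSN resting potential)
g_AMPA: 2.0  # [nS] AMPAR maximal conductance
g_NMDA: 1.5  # [nS] NMDAR maximal conductance
g_VSCC: 0.3  # [nS] L-type (Cav1.3) voltage-sensitive calcium channel maximal conductance
g_TRPV1: 0.4  # [nS] TRPV1 maximal conductance
E_glu: 0.0  # [mV] AMPAR/NMDAR reversal potential
E_Ca: 120.0  # [mV] calcium channel reversal potential
alpha_AMPA: 1.1  # [1/(uM s)] AMPAR two-state binding rate
beta_AMPA: 190.0  # [1/s] AMPAR two-state unbinding rate
alpha_NMDA: 0.2  # [1/(uM s)] NMDAR two-state binding rate
beta_NMDA: 70.0  # [1/s] NMDAR two-state unbinding rate
Mg_out: 1.0  # [mM] extracellular magnesium (voltage-dependent NMDAR block)
Mg_K: 3.57  # [mM] magnesium block concentration constant
Mg_slope: 0.062  # [1/mV] magnesium block voltage slope
V_m_half: -25.0  # [mV] Cav1.3 activation half voltage
k_m_VSCC: 6.7  # [mV] Cav1.3 activation slope
tau_m_VSCC: 0.0005  # [s] Cav1.3 activation time constant
V_h_half: -13.4  # [mV] Cav1.3 inactivation half voltage
k_h_VSCC: 11.9  # [mV] Cav1.3 inactivation slope
tau_h_VSCC: 0.0143  # [s] Cav1.3 inactivation time constant
V_TRPV1_half: 150.0  # [mV] TRPV1 open-probability half voltage without agonist
k_TRPV1: 25.0  # [mV] TRPV1 voltage slope
dV_TRPV1: 210.0  # [mV] leftward shift of TRPV1 half voltage at saturating AEA
K_AEA_TRPV1: 1.0  # [uM] AEA concentration for half-maximal TRPV1 gating shift
xi_NMDA: 18.0  # [uM/(pA s)] NMDAR current to calcium-flux conversion
xi_VSCC: 0.4  # [uM/(pA s)] VSCC current to calcium-flux conversion
xi_TRPV1: 4.0  # [uM/(pA s)] TRPV1 current to calcium-flux conversion

# --- stimuli ---
G_max: 1500.0  # [uM] peak cleft glutamate per presynaptic spike
tau_G: 0.003  # [s] glutamate clearance time constant
DC_max: 330.0  # [pA] amplitude of the somatic depolarizing current step
DC_dur: 0.03  # [s] duration of the depolarizing current step
AP_max: 2400.0  # [pA] amplitude of the spike (bAP) action current
delta: 0.003  # [s] delay between step onset and bAP onset
tau_bAP: 0.002  # [s] bAP action-current decay time constant

# --- calcium ---
B_T: 25.0  # [uM] total endogenous fast calcium buffer
K_dB: 10.0  # [uM] buffer dissociation constant
Ca_b: 0.1  # [uM] basal cytosolic calcium
tau_Cab: 0.02  # [s] cytosolic calcium extrusion time constant
rho_ER: 0.185  # ER-to-cytoplasm volume ratio (scales ER depletion)
r_C: 179.0  # [1/s] maximal IP3R (CICR) release rate
r_L: 0.11  # [1/s] ER leak rate
v_ER: 14.3  # [uM/s] maximal SERCA pump rate
K_ER: 0.2  # [uM] SERCA half-activation calcium
d_1: 0.13  # [uM] IP3R: IP3 dissociation constant
d_2: 1.049  # [uM] IP3R: calcium inactivation dissociation constant
d_3: 0.9434  # [uM] IP3R: IP3 dissociation constant (inactivation coupling)
d_5: 0.08234  # [uM] IP3R: calcium activation dissociation constant
a_2: 0.2  # [1/(uM s)] IP3R inactivation gate rate

# --- ip3 ---
v_beta: 19.0  # [uM/s] maximal mGluR/PLCbeta IP3 (and DAG) production rate
K_R: 50.0  # [uM] glutamate affinity of the mGluR/PLCbeta cascade
n_G: 0.7  # glutamate cooperativity of PLCbeta activation
K_pi: 0.52  # [uM] calcium cofactor affinity of PLCbeta
n_pi: 4.0  # calcium cofactor cooperativity of PLCbeta
v_delta: 0.0096  # [uM/s] maximal PLCdelta production rate
kappa_delta: 1.5  # [uM] IP3 inhibition constant of PLCdelta
K_PLCdelta: 0.1  # [uM] calcium affinity of PLCdelta
r_5P: 0.104  # [1/s] IP3 degradation rate by IP-5P
v_3K: 1.0  # [uM/s] maximal IP3K degradation rate (CaMKII dependent)
K_3: 1.0  # [uM] IP3 affinity of IP3K

# --- ecb ---
r_DGL: 93.4  # [1/s] DAGLalpha maximal turnover rate
DAGL_T: 1.0  # [uM] total DAGLalpha concentration
K_DAGL: 8.8  # [uM] DAGLalpha Michaelis constant for DAG
r_DAGK: 2.0  # [1/s] DAG consumption rate by DAG kinase
r_MAGL: 0.286  # [1/s] 2-AG degradation rate (MAG-lipase + spillover)
r_k: 91.0  # [1/(uM^n_c s)] DAGLalpha calcium-activation on-rate
r_p: 2.63  # [1/s] DAGLalpha deactivation rate
n_c: 4.0  # calcium cooperativity of DAGLalpha activation
nu_AT: 0.2  # [1/s] lumped NAPE-pathway AEA synthesis rate per unit calcium
r_FAAH: 1.0  # [uM/s] maximal AEA degradation rate by FAAH
K_FAAH: 1.0  # [uM] AEA Michaelis constant of FAAH

# --- cb1r ---
alpha_CB1R: 4.39  # [1/(uM s)] CB1R opening rate per unit eCB
beta_CB1R: 0.631  # [1/s] CB1R closing rate
gamma_CB1R: 0.159  # [1/s] CB1R desensitization rate
epsilon_CB1R: 0.0043  # [1/s] CB1R recovery rate from desensitization
A_AEA: 0.1  # partial-agonism factor of AEA at CB1R

# --- plasticity ---
k_CB1R: 1.0  # gain from open-CB1R fraction to plasticity drive y_CB1R
D_1: 0.01  # tonic offset of y_CB1R (e.g. tonic dopamine)
D_2: 0.01  # tonic offset of the tau_Wpre drive
theta_LTD_start: 0.06  # lower edge of the LTD band of y_CB1R
theta_LTD_stop: 0.13  # upper edge of the LTD band of y_CB1R
theta_LTP_start: 0.16  # LTP threshold of y_CB1R
A_LTD: 0.6  # LTD depth (W_pre target 1 - A_LTD)
A_LTP: 1.5  # LTP drive (W_pre target 1 + A_LTP, clipped)
P_1: 0.00022  # [s] tau_Wpre numerator constant
P_2: 0.02  # tau_Wpre half-drive constant
P_3: 4.0  # tau_Wpre drive exponent
P_4: 3.0  # [s] tau_Wpre floor (fast limit)
W_pre_max: 3.0  # hard ceiling of the presynaptic weight
w_post_gain: 3.5  # gain of W_post on the phosphorylated CaMKII fraction
use_smooth_omega: 0.0  # [bool] 0: sharp threshold rule, 1: smooth sigmoidal rule
k_S: 2.0  # steepness of the smooth threshold rule

# --- camkii ---
CaM_T: 10.0  # [uM] total calmodulin
K_CaM1: 2.4  # [uM] calmodulin site-1 calcium dissociation constant
K_CaM2: 2.4  # [uM] calmodulin site-2 calcium dissociation constant
K_CaM3: 0.22  # [uM] calmodulin site-3 calcium dissociation constant
K_CaM4: 0.22  # [uM] calmodulin site-4 calcium dissociation constant
K_5: 25.0  # [uM] (Ca)4CaM affinity of a CaMKII subunit
CaMKII_T: 5.55  # [uM] total CaMKII holoenzyme (6-subunit rings)
k_6: 0.55  # [1/s] initiation autophosphorylation rate (two bound CaM)
k_7: 14.0  # [1/s] propagation autophosphorylation rate (one bound CaM)
k_12: 6.0  # [1/s] PP1 catalytic dephosphorylation rate constant
K_M: 0.4  # [uM] PP1 Michaelis constant for phosphorylated subunits
PP1_T: 0.2  # [uM] total protein phosphatase 1
I1_T: 2.0  # [uM] total inhibitor-1 (DARPP-32 analog)
k_11: 500.0  # [1/(uM s)] PP1 inhibition rate by phosphorylated I1
km_11: 0.3  # [1/s] PP1:I1p complex dissociation rate
k_PKA0: 0.002  # [1/s] basal PKA activity on I1
k_PKA: 0.005  # [1/s] calcium-stimulated PKA activity on I1
K_PKA: 2.0  # [uM] calcium half-activation of PKA (via B72-PP2A/DARPP-32)
n_PKA: 3.0  # Hill exponent of PKA activation by calcium
k_CaN0: 0.005  # [1/s] basal calcineurin activity on I1p
k_CaN: 0.005  # [1/s] calcium-stimulated calcineurin activity on I1p
K_CaN: 0.45  # [uM] calcium half-activation of calcineurin
n_CaN: 3.0  # Hill exponent of calcineurin activation

# --- numerics ---
rtol: 1e-07  # relative integration tolerance
atol: 1e-07  # absolute integration tolerance
blur_sd_ms: 3.0  # [ms] s.d. of the Gaussian spike-timing blur
settle_time: 300.0  # [s] post-protocol settling horizon before weights are read
record_dt: 0.001  # [s] trajectory sampling step during the protocol
settle_record_dt: 0.5  # [s] trajectory sampling step during settling
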