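# Wild-type mouse rod parameter set (schema v1).
#
# Units: concentrations uM, first-order rates s^-1, bimolecular rates
# uM^-1 s^-1 unless marked volumetric (um^3 s^-1), currents pA, volume um^3.
#
# provenance codes:
#   [lit]  published mouse-rod measurement or modeling range
#   [cal]  calibrated within published ranges against measured wild-type /
#          mutant saturation behaviour (Pepperberg slopes, X-intercepts,
#          bend and plateau positions); see docs/methods.md
schema_version: 1

# --- guanylate cyclase: two GCAP-regulated activities -------------------
alpha_min: 2.0        # uM/s, synthesis at high Ca2+            [lit]
alpha_max: 60.0       # uM/s, synthesis at low Ca2+             [cal]
beta: 0.4             # GCAP1-arm weight (GCAP2 KO retains 40%) [lit]
K_cyc1: 0.047         # uM, GCAP1 Ca2+ K_1/2 (46-47 nM)         [lit]
K_cyc2: 0.133         # uM, GCAP2 Ca2+ K_1/2 (133 nM)           [lit]
m_cyc1: 2.0           # Hill exponent                           [lit]
m_cyc2: 2.0           # Hill exponent                           [lit]

# --- cGMP hydrolysis by PDE (volumetric, um^3/s) ------------------------
k_hyd_vol: 5.3e-5     # basal subunit rate; k_hyd*E0 ~ 4.1 s^-1 in darkness [lit]
k_sigma_hyd_vol: 1.08 # activated subunit rate (beta_sub ~ 0.06 s^-1)       [cal]

# --- CNG channel --------------------------------------------------------
j_cg_max: 1200.0      # pA at saturating cGMP (~1.5% open dark) [cal]
K_cG_min: 13.0        # uM, low-Ca2+ channel K_1/2              [lit]
K_cG_max: 32.0        # uM, high-Ca2+ channel K_1/2             [lit]
m_cG: 2.0             # channel Hill exponent                   [lit]
m_CaM: 2.0            # calmodulin Hill exponent                [lit]
K_CaM: 0.06           # uM, Ca2+ K_1/2 of calmodulin effect     [cal]
f_Ca: 0.12            # Ca2+ fraction of CNG current            [lit]

# --- Na+/Ca2+,K+ exchanger ----------------------------------------------
j_ex_sat: 8.0         # pA saturated exchange current           [cal]
K_ex: 2.0             # uM                                      [lit]

# --- calcium bookkeeping ------------------------------------------------
B_Ca: 20.0            # cytosolic buffering power               [lit]
V_cyt: 18.0           # um^3 cytosolic outer-segment volume     [lit]

# --- rhodopsin phosphorylation chain ------------------------------------
n_sites: 6            # max phosphorylations (mouse)            [lit]
lambda_max: 60.0      # s^-1, per-state max phosphorylation     [cal]
mu_max: 30.0          # s^-1, arrestin capture (states >= 4)    [cal]

# --- recoverin / RK equilibrium -----------------------------------------
K1: 0.4               # uM, Ca2+ binding to recoverin           [lit]
K2: 2.0               # uM, membrane association                [cal]
K3: 25.0              # uM, Rec.Ca2--RK (cytosolic)             [cal]
K4: 25.0              # uM, Rec.Ca2--RK (membrane)              [cal]
M_rec: 5.0            # uM, membrane site availability          [cal]
RK_tot: 7.0           # uM total rhodopsin kinase               [lit]
Rec_tot: 34.0         # uM total recoverin                      [lit]

# --- transducin / PDE / RGS9 front end ----------------------------------
nu_RT: 138.0          # s^-1 transducin activations per R*      [lit]
k_TE: 5.0             # uM^-1 s^-1, T* + E association          [cal]
k_f: 0.0475           # uM^-1 s^-1, RGS9 + T*--E association    [cal]
k_b: 0.01             # s^-1, RGS9--T*--E dissociation          [cal]
k_cat: 5.8            # s^-1, GTP hydrolysis in RGS9--T*--E     [cal]
T0: 240.0             # uM total transducin                     [cal]
E0: 130.0             # uM total PDE catalytic subunits         [lit]
RGS9_0: 60.0          # uM total RGS9 complex                   [cal]
k_E: 2.84             # s^-1 first-order E* shutoff (simplified
                      # front-end variant only); ~1/tau_E*      [cal]

# --- closed-form saturation theory --------------------------------------
nu_RE:                # s^-1 lumped R* -> E* gain; empty = derived
epsilon: 0.02         # criterion recovery fraction

# --- geometry -----------------------------------------------------------
collecting_area: 0.45 # um^2, photoisomerizations per photon/um^2 [lit]
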