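# Default parameter set for the pediatric L-serine score model.
# PK block (cl_f/v1_f/q_f/v2_f/d1): PLACEHOLDER values -- substitute the
# published adult population PK estimates when available.  The kinetic
# shape (absorption ~2 h, terminal half-life ~12 h, allometric exponents
# 0.75/1.0) is realistic; the concentration scale is calibrated so that
# deff * (typical high-dose effect-site exposure) lands in the clinically
# reported score-change range.
# PD block and variability: final population estimates.
cl_f_L_per_day: 16000.0
v1_f_L: 1600.0
q_f_L_per_day: 6400.0
v2_f_L: 3200.0
d1_day: 0.08
ref_weight_kg: 70.0
exp_cl: 0.75
exp_v: 1.0
ke0_per_day: 0.0065
e0_score: 48.51
beta_age: -0.21
deff_L_per_ug: 0.0022
kprog_score_per_day: 0.015
age_ref_yr: 5.0
omega_ke0: 0.21
omega_e0: 0.2
omega_deff: 1.4
omega_kprog_score_per_day: 0.018
corr_e0_kprog: 0.48
sigma_add_score: 1.6
rse_percent:
  ke0: 7.92
  e0: 1.66
  beta_age: 18.4
  deff: 37.5
  kprog: 12.0
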