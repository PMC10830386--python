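# vvcsim model parameters (mmHg, mL, s)
la.e_max = 0.25
la.e_min = 0.13
la.v0 = 10.0
la.activation_duration_fraction = 0.16
la.activation_delay = 0.0
la.activation_rise_fraction = 0.5
lv.e_max = 2.5138622578125
lv.e_min = 0.055
lv.v0 = 10.0
lv.activation_duration_fraction = 0.84
lv.activation_delay = 0.04
lv.activation_rise_fraction = 0.9
ra.e_max = 0.22
ra.e_min = 0.1
ra.v0 = 10.0
ra.activation_duration_fraction = 0.16
ra.activation_delay = 0.0
ra.activation_rise_fraction = 0.5
rv.e_max = 0.65
rv.e_min = 0.045
rv.v0 = 10.0
rv.activation_duration_fraction = 0.84
rv.activation_delay = 0.04
rv.activation_rise_fraction = 0.9
aorta.compliance = 0.25
aorta.r_out = 0.06
aorta.v_unstressed = 280.0
systemic_veins.compliance = 43.7050048828125
systemic_veins.r_out = 0.03
systemic_veins.v_unstressed = 2250.0
thoracic_veins.compliance = 15.0
thoracic_veins.r_out = 0.015
thoracic_veins.v_unstressed = 280.0
pulmonary_arteries.compliance = 4.5
pulmonary_arteries.r_out = 0.08
pulmonary_arteries.v_unstressed = 120.0
pulmonary_veins.compliance = 8.0
pulmonary_veins.r_out = 0.01
pulmonary_veins.v_unstressed = 350.0
bed_splanchnic.compliance = 0.15
bed_splanchnic.r_out = 4.076666666666667
bed_splanchnic.v_unstressed = 170.0
bed_extrasplanchnic.compliance = 0.12
bed_extrasplanchnic.r_out = 4.892
bed_extrasplanchnic.v_unstressed = 130.0
bed_skeletal_muscle.compliance = 0.1
bed_skeletal_muscle.r_out = 6.115
bed_skeletal_muscle.v_unstressed = 110.0
bed_brain.compliance = 0.05
bed_brain.r_out = 8.153333333333334
bed_brain.v_unstressed = 65.0
bed_coronary.compliance = 0.03
bed_coronary.r_out = 12.23
bed_coronary.v_unstressed = 35.0
r_mitral = 0.005
r_aortic = 0.015
r_tricuspid = 0.005
r_pulmonic = 0.006
aortic_inertance = 0.0003
heart_rate = 80.0
total_blood_volume = 4663.53759765625
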