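activity_gp_boost: 4.0
atp_capacity_halfpoint: 0.7
atp_cost_per_ap: 0.0008
atp_rest_cost: 0.0008
atp_sensor_k: 3.0
bleach_rate: 2.0e-05
ca_tau_s: 10.0
condition: da_0gluc
cost_jitter_sigma: 0.1
d2r_tone: 1.0
endocytosis_tau: 8.0
exo_pool_fraction_per_round: 0.15
glucose_mM: 0.0
glucose_uptake_gain: 0.0004
glycogen_capacity: 4.1
glycogen_fade_power: 2.0
glycogen_knee: 0.18
glycogen_store_0: 0.5
gp_activity: 1.0
gp_jitter_sigma: 0.15
gp_max_flux: 0.0014
hill_n: 8.0
noise_sd: 0.05
recovery_gain: 0.05
store_jitter_sigma: 0.45
surface_fraction_rest: 0.15
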