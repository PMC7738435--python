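# Experiment-II most aggressive schedule: 32 mL every 0.5 d in 150 mL
# -> SRT 2.34375 d (2.3 d at one decimal).
vc_ml: 150.0
exchange_volume_ml: 32.0
exchange_interval_d: 0.5
cf_g_per_l: 6.2
cc_g_per_l: 6.2
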