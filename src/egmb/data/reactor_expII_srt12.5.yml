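# Experiment-II intermediate schedule: 12 mL every 1 d in 150 mL -> SRT 12.5 d.
vc_ml: 150.0
exchange_volume_ml: 12.0
exchange_interval_d: 1.0
cf_g_per_l: 6.2
cc_g_per_l: 6.2
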