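# Experiment-I control schedule: 150 mL working volume, 3 mL of well-mixed
# liquor discarded and replaced with fresh WAS every 2 days -> SRT 100 d.
# cf: feed (WAS) VSS; cc: reactor VSS, to be overridden by the final-day
# measurement when available (ReactorConfig.with_cc).
vc_ml: 150.0
exchange_volume_ml: 3.0
exchange_interval_d: 2.0
cf_g_per_l: 6.2
cc_g_per_l: 6.2
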