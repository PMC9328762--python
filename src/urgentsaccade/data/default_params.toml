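# Calibrated default parameters of the CAS/CPS race model (high-luminance
# cue).  Activity in arbitrary units, rates in units/ms, accelerations in
# units/ms^2, times in ms.  Calibrated once so that the simulated
# antisaccade tachometric curve drops below 0.2 for rPTs inside 90-140 ms
# and recovers above 0.9 past 220 ms, while the prosaccade curve rises
# early and stays at or above chance everywhere.

[race]
build_mean = 4.5
build_sd = 2.8
build_corr = 0.1
threshold = 1000.0
efferent_delay_ms = 10.0
go_latency_ms = 60.0
go_jitter_sd_ms = 15.0
exo_latency_ms = 80.0
eri_duration_ms = 25.0
halt_ms = 10.0
exo_accel = 1.2
endo_accel = 0.15
endo_decel = 0.4
bias = 0.0
timeout_cap_ms = 2000
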