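# Severe chronic-kidney-disease physiology overlay (CKD stage 4-5 conventions).
# GFR reduced to 20% of healthy (stage-4/5 boundary, ~15-29 mL/min/1.73 m^2),
# renal blood flow to 40%; plasma protein binding left unchanged (fu_scale 1).
# Override any key from the command line or a scenario config.
label: severe_ckd
gfr_fraction: 0.2
renal_flow_fraction: 0.4
fu_scale: 1.0
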