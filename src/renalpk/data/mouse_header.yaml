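# Reference whole-body physiology: adult C57BL/6 mouse, 20 g.
# Cardiac output from Davies & Morris (1993): 8 mL/min.
# GFR from Davies & Morris (1993): 0.28 mL/min.
# Hematocrit: 0.45 (Brown et al. 1997).
species: mouse
body_weight_kg: 0.02
cardiac_output_ml_min: 8.0
gfr_ml_min: 0.28
hematocrit: 0.45
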