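# Reference whole-body physiology: adult Sprague-Dawley rat, 300 g.
# Cardiac output from Davies & Morris (1993): ~296 mL/min/kg -> 89 mL/min at 0.3 kg.
# GFR from Davies & Morris (1993): 1.31 mL/min.
# Hematocrit: 0.46 (Brown et al. 1997, Toxicol Ind Health 13:407).
species: rat
body_weight_kg: 0.3
cardiac_output_ml_min: 89.0
gfr_ml_min: 1.31
hematocrit: 0.46
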