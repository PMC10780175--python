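# Reference whole-body physiology: healthy adult European male, ~30 y, 73 kg.
# Cardiac output after Davies & Morris (1993, Pharm Res 10:1093): 5.6 L/min.
# GFR: standard healthy adult value, ~125 mL/min (ICRP Publication 89).
# Hematocrit: 0.45 (ICRP 89).
species: human
body_weight_kg: 73.0
cardiac_output_ml_min: 5600.0
gfr_ml_min: 125.0
hematocrit: 0.45
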