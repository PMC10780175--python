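# Compound model for 84-B10, a 3-phenylglutaric acid derivative (LONP1 activator)
# in development against acute kidney injury and chronic kidney disease.
# Physicochemical profile from in-silico characterisation (ChemDraw / ADMETlab);
# blood:plasma ratio from platform optimisation.
name: 84-B10
mw_g_mol: 473.15
pka_acid: 4.22
logp: 4.82
permeability_cm_s: 9.30e-6
solubility_ug_ml: 1.75
fu: 0.0061
clh_ml_min_kg: 4.26
clr_ml_min_kg: 4.26
bp_ratio: 1.50
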