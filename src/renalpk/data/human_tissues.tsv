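# Tissue table, healthy adult male, 73 kg reference.
# Volumes: Brown et al. (1997) / ICRP 89 fractional organ weights x 73 kg (density ~1 g/mL);
#   blood 7.9% BW split 1/3 arterial, 2/3 venous; "rest" = perfused remainder of the
#   carcass (bone marrow, glands, lymphatics; excludes bone mineral).
# Flows: fractions of cardiac output (Davies & Morris 1993; ICRP 89): adipose 5%,
#   muscle 17%, skin 5%, hepatic artery 6.5%, gut 16%, spleen 3%, kidney 19%,
#   brain 12%, heart 4%, rest = remainder (12.5%); lung/arterial/venous carry the
#   full cardiac output in series. Liver flow column is the hepatic artery only;
#   portal inflow from gut and spleen is added by the model.
# Composition fractions (water / total lipid / protein): Poulin & Theil (2002)-type
#   compendium values, shared across species.
# Capillary columns: endothelium class and exchange surface density (cm2/g).
#   Sinusoidal/fenestrated/alveolar organs (liver, spleen, gut, kidney, lung) pose
#   no effective transcapillary barrier; continuous-capillary organs exchange across
#   ~70 cm2/g (heart ~500 cm2/g) after Renkin/Crone; brain is tight-junction limited.
name	volume_ml	flow_ml_min	fraction_water	fraction_lipid	fraction_protein	portal_drained	eliminating	capillary_type	cap_surface_cm2_per_g
lung	555.0	5600.0	0.79	0.021	0.15	0	none	fenestrated	3500.0
arterial	1922.0	5600.0	0.82	0.004	0.16	0	none	fenestrated	0.0
venous	3845.0	5600.0	0.82	0.004	0.16	0	none	fenestrated	0.0
heart	343.0	224.0	0.73	0.035	0.16	0	none	continuous	500.0
spleen	190.0	168.0	0.78	0.030	0.17	1	none	fenestrated	70.0
gi	1241.0	896.0	0.75	0.065	0.15	1	none	fenestrated	70.0
liver	1898.0	364.0	0.75	0.049	0.18	0	hepatic	fenestrated	250.0
kidney	321.0	1064.0	0.78	0.050	0.16	0	renal	fenestrated	350.0
brain	1460.0	672.0	0.77	0.110	0.08	0	none	tight	240.0
adipose	13140.0	280.0	0.18	0.790	0.02	0	none	continuous	70.0
muscle	29200.0	952.0	0.76	0.022	0.177	0	none	continuous	70.0
skin	2708.0	280.0	0.65	0.060	0.25	0	none	continuous	70.0
rest	10000.0	700.0	0.70	0.060	0.18	0	none	continuous	70.0
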