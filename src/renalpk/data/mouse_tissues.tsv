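# Tissue table, C57BL/6 mouse, 20 g reference.
# Volumes: Brown et al. (1997) fractional organ weights x 20 g; blood 8% BW
#   (1/3 arterial, 2/3 venous); "rest" = perfused carcass remainder.
# Flows: fractions of cardiac output (Brown et al. 1997): adipose 7.0%, muscle 15.9%,
#   skin 5.8%, hepatic artery 2.0%, gut 14.1%, spleen 1.1%, kidney 9.1%, brain 3.3%,
#   heart 6.6%, rest = remainder (35.1%). Liver column = hepatic artery only.
# Composition fractions shared across species (see human table).
# Capillary columns: endothelium class and exchange surface density (cm2/g).
#   Sinusoidal/fenestrated/alveolar organs (liver, spleen, gut, kidney, lung) pose
#   no effective transcapillary barrier; continuous-capillary organs exchange across
#   ~70 cm2/g (heart ~500 cm2/g) after Renkin/Crone; brain is tight-junction limited.
name	volume_ml	flow_ml_min	fraction_water	fraction_lipid	fraction_protein	portal_drained	eliminating	capillary_type	cap_surface_cm2_per_g
lung	0.146	8.0	0.79	0.021	0.15	0	none	fenestrated	3500.0
arterial	0.53	8.0	0.82	0.004	0.16	0	none	fenestrated	0.0
venous	1.07	8.0	0.82	0.004	0.16	0	none	fenestrated	0.0
heart	0.1	0.528	0.73	0.035	0.16	0	none	continuous	500.0
spleen	0.07	0.088	0.78	0.030	0.17	1	none	fenestrated	70.0
gi	0.84	1.128	0.75	0.065	0.15	1	none	fenestrated	70.0
liver	1.1	0.16	0.75	0.049	0.18	0	hepatic	fenestrated	250.0
kidney	0.334	0.728	0.78	0.050	0.16	0	renal	fenestrated	350.0
brain	0.33	0.264	0.77	0.110	0.08	0	none	tight	240.0
adipose	1.4	0.56	0.18	0.790	0.02	0	none	continuous	70.0
muscle	7.68	1.272	0.76	0.022	0.177	0	none	continuous	70.0
skin	3.3	0.464	0.65	0.060	0.25	0	none	continuous	70.0
rest	2.0	2.808	0.70	0.060	0.18	0	none	continuous	70.0
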