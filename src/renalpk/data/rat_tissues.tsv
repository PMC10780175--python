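# Tissue table, Sprague-Dawley rat, 300 g reference.
# Volumes: Brown et al. (1997) fractional organ weights x 300 g; blood 7.4% BW
#   (1/3 arterial, 2/3 venous); "rest" = perfused carcass remainder.
# Flows: fractions of cardiac output (Brown et al. 1997): adipose 7.0%, muscle 27.8%,
#   skin 5.8%, hepatic artery 2.1%, gut 13.1%, spleen 2.0%, kidney 14.1%, brain 2.0%,
#   heart 4.9%, rest = remainder (21.2%). Liver column = hepatic artery only.
# Composition fractions shared across species (see human table).
# Capillary columns: endothelium class and exchange surface density (cm2/g).
#   Sinusoidal/fenestrated/alveolar organs (liver, spleen, gut, kidney, lung) pose
#   no effective transcapillary barrier; continuous-capillary organs exchange across
#   ~70 cm2/g (heart ~500 cm2/g) after Renkin/Crone; brain is tight-junction limited.
name	volume_ml	flow_ml_min	fraction_water	fraction_lipid	fraction_protein	portal_drained	eliminating	capillary_type	cap_surface_cm2_per_g
lung	1.5	89.0	0.79	0.021	0.15	0	none	fenestrated	3500.0
arterial	7.4	89.0	0.82	0.004	0.16	0	none	fenestrated	0.0
venous	14.8	89.0	0.82	0.004	0.16	0	none	fenestrated	0.0
heart	0.99	4.36	0.73	0.035	0.16	0	none	continuous	500.0
spleen	0.6	1.78	0.78	0.030	0.17	1	none	fenestrated	70.0
gi	8.1	11.66	0.75	0.065	0.15	1	none	fenestrated	70.0
liver	10.98	1.87	0.75	0.049	0.18	0	hepatic	fenestrated	250.0
kidney	2.19	12.55	0.78	0.050	0.16	0	renal	fenestrated	350.0
brain	1.71	1.78	0.77	0.110	0.08	0	none	tight	240.0
adipose	21.0	6.23	0.18	0.790	0.02	0	none	continuous	70.0
muscle	121.2	24.74	0.76	0.022	0.177	0	none	continuous	70.0
skin	57.0	5.16	0.65	0.060	0.25	0	none	continuous	70.0
rest	30.0	18.87	0.70	0.060	0.18	0	none	continuous	70.0
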