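# Methods

`renalpk` models the disposition of 84-B10 — a 3-phenylglutaric acid
derivative and LONP1 activator in development against acute kidney injury
and chronic kidney disease (CKD) — with a whole-body physiologically based
pharmacokinetic (PBPK) model, and reproduces the supporting analyses:
non-compartmental analysis (NCA), absorption/clearance calibration against
observed rat data, extrapolation to healthy and severe-CKD humans, and
fold-error validation.

## Whole-body model

Thirteen compartments: lung, heart, spleen, gastrointestinal tract, liver,
kidney, brain, adipose, muscle, skin, arterial blood, venous blood and rest
of body. Blood runs venous → lung → arterial in series; organs are perfused
in parallel, except spleen and gut, which drain through the portal vein
into the liver. All kinetics are linear (no saturable terms), with amounts
in ng, times in h, volumes in mL.

**Distribution.** Blood equilibrating with tissue *i* leaves at
`C_i·BP/Kp_i` (venous equilibrium), where `BP` is the blood:plasma ratio
(1.50) and `Kp_i` the tissue:plasma partition coefficient. Tissue access is
gated by the capillary endothelium. Sinusoidal/fenestrated/alveolar organs
(liver, spleen, gut, kidney, lung) pass even protein-bound drug and behave
perfusion-limited. Continuous-capillary organs exchange only the extracted
fraction of their perfusing stream, the Renkin–Crone expression
`E_i = 1 − exp(−PS_i·fu/Q_i)` with `PS_i = P·S_i·V_i`: `P` is the
compound's transcellular permeability (9.30×10⁻⁶ cm/s), `S_i` the capillary
exchange surface density (≈70 cm²/g; heart ≈500 cm²/g), and the factor `fu`
implements restrictive (free-drug-only) transport — for a 99.4%-bound acid
this is the dominant barrier. Brain tight junctions attenuate `PS` a
further hundred-fold. The practical consequence is a small, rapidly
accessible distribution space (blood plus splanchnic/renal organs) and a
slow, shallow uptake into muscle, skin and fat, which matches the observed
biphasic rat profile (fast 0.4-h decline, then a low flat tail).

**Partition coefficients.** "Composition-based" Kp follows the
Poulin–Theil/Rodgers–Rowland family: drug in any medium distributes over
water, lipid and protein, `Kp = (fu/f_w,plasma)·(f_w + P_mem·f_l +
K_prot·f_p)`. `P_mem` is a membrane affinity with the ionized species
ten-fold weaker than neutral (Henderson–Hasselbalch weighting at pH 7.4);
`K_prot` is back-calculated from the plasma unbound fraction, so plasma
binding anchors tissue protein binding. For 84-B10 this yields
kidney/liver/lung Kp ≈ 3–5, adipose ≈ 33, muscle ≈ 3 (rat Vss ≈ 5.5 L/kg,
same order as the reported terminal volume ~4.5 L/kg). A cruder
lipid-weighted heuristic is selectable for sensitivity work. Numeric
identity with any proprietary platform's "standard" method is not claimed.

**Elimination.** The printed specific clearances (CLH = CLR =
4.26 mL/min/kg plasma) are converted to whole-body blood clearances via
body weight and `BP`, scaled by the calibrated `cl_scale`, and drawn on the
liver/kidney outflow concentrations. The renal flux first transits a
tubular (urine) sub-compartment with a 3-minute nephron transit time;
measured kidney concentration includes tubule content. This couples kidney
exposure to filtration: severe CKD (GFR at 20%, renal flow at 40%,
clearance scaled with GFR) lowers kidney exposure while raising plasma
exposure — the qualitative pattern reported for CKD patients.

**Dosing.** Intraperitoneal doses fill a peritoneal depot that empties
first-order (`ka`) into the portal inflow with absorbed fraction `f_abs`;
intravenous boluses enter venous blood instantaneously. Reported
concentrations: tissues in ng/mL of tissue, plasma derived from venous
blood via `BP`. At a grid instant that carries a dose the *pre-dose* value
is recorded — the unmixed syringe-in-vein transient of an instantaneous
bolus is a bookkeeping artifact, not a physiological peak, so e.g. the
human Cmax is read from the first grid point (0.05 h) after the bolus.

**Numerics.** The system is linear and time-invariant between dose events,
so states are propagated by a cached matrix exponential per output step
rather than an adaptive ODE solver: mass balance, dose linearity and
superposition hold to machine precision (the tests require ≤10⁻⁶ relative;
the engine delivers ~10⁻¹⁴) and stiffness is moot. Output grids are 0.01 h
for the 8-h animal arms and 0.05 h for the 72-h human arms — fine enough to
resolve an absorption peak near 0.1–0.2 h.

## Physiology tables

Reference physiologies (mouse 20 g, rat 300 g, human 73 kg) are compiled
from standard compendia (Brown et al. 1997; Davies & Morris 1993; ICRP 89)
and ship as commented plain-text files; per-value provenance lives in the
file headers. "Rest of body" is the perfused carcass remainder; flow
fractions are constructed to sum exactly to cardiac output, and volumes,
flows and GFR rescale linearly with body weight within a species
(allometric scaling across species enters only through each species' own
table). The severe-CKD overlay (GFR fraction 0.2, renal flow fraction 0.4,
unchanged protein binding) reflects CKD stage 4–5 conventions and is fully
overridable; cardiac output drops by the kidney-flow decrement without
redistribution.

## Calibration

The in-silico clearances under-predict the observed rat clearance
(8.52 vs ~22 mL/min/kg) and the intraperitoneal absorption rate is
unmeasured, so three parameters — `ka`, `f_abs`, `cl_scale` — are fitted to
the observed rat NCA summary (Cmax 257 ng/mL, tmax 0.17 h, CL
22.15 mL/min/kg, AUC0–t 269 h·ng/mL) by minimizing the equally weighted sum
of squared log-ratios (unit-invariant, symmetric). Optimization is
multi-start Nelder–Mead in log-parameter space from a seeded Latin
hypercube within bounds ka ∈ [0.5, 50] h⁻¹, f_abs ∈ [0.3, 1], cl_scale ∈
[0.25, 4]; the optimum (ka ≈ 15 h⁻¹, f_abs ≈ 0.40, cl_scale ≈ 1.04) is
reproducible across seeds. Mouse and human scenarios reuse `cl_scale`
(clearance per kg body weight) with their own physiology — the central
cross-species extrapolation assumption. Because an essentially exact fit to
the observed rat data is attainable, the calibrated model reproduces the
*observation* rather than the reference platform's rat Cmax over-prediction
(615 ng/mL, itself 2.39-fold above the measurement); comparisons against
that platform value therefore sit below the two-fold band, which we report
rather than re-weight.

## NCA

WinNonlin-style defaults: λz by log-linear regression over the suffix
window (≥3 points, excluding tmax) maximizing adjusted R², ties toward more
points; AUC by linear-up/log-down trapezoid (all-linear selectable);
AUC0–∞ adds `C_last/λz`; CL = dose/AUC0–∞ (CL/F for extravascular routes);
Vz = CL/λz. Concentrations below the assay LLOQ (1 ng/mL, the plasma
linear-range floor) can be censored before analysis with a logged count.

## Synthetic data

The generator emulates the rat study design: sparse sampling at 0.033,
0.083, 0.25, 0.5, 1, 2, 4, 6, 8 h, multiplicative lognormal residual error
with mean-one multipliers (default CV 15%, the assay precision bound), LLOQ
censoring, one explicit seed. It reproduces assay-like *noise*, not
between-animal physiological variability, absorption-time heterogeneity or
correlated residuals — so passing recovery tests demonstrate estimator
correctness under the stated error model, not robustness to real-world
population variability.

## Known limitations

- Quantities that depend on the reference platform's undisclosed internals
  (its Kp/permeability values, its IP absorption handling) are reproduced
  only to order of magnitude/two-fold; the rat and CKD single-dose Cmax
  comparisons against the platform's values sit at ~0.42–0.47-fold (see
  calibration note above).
- Single-dose kidney persistence is shorter here than the reported ~17 h
  above 150 ng/mL (we find ~4 h for CKD after one dose; >24 h under q8h
  dosing): the platform evidently carries slower deep-tissue/kidney
  kinetics than the restrictive-transport model.
- Mouse observed clearance (56.8 mL/min/kg) is 2.6× the rat value per kg;
  reusing the rat `cl_scale` leaves the mouse AUC ~2.8-fold over-predicted,
  shown honestly in the mouse validation table.
- No transporters, metabolites, enterohepatic recycling, oral absorption,
  permeability-limited solubility effects, or population variability.
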