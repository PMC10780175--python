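"""Compound model: ionization, partitioning and blood/plasma conversions.

Houses the physicochemical and biochemical profile of a compound (the drug
half of the PBPK model) and computes tissue:plasma partition coefficients
(Kp) from tissue composition.

The default Kp method is a tissue-composition equation in the
Poulin & Theil (2002) / Rodgers & Rowland family.  Drug in any medium is
assumed to distribute between water (free), lipid and protein::

    C_medium = Cu * (f_water + P_mem * f_lipid + K_prot * f_protein)

with a common unbound aqueous concentration Cu at equilibrium, so that

    Kp_tissue = fu / f_water,plasma * (f_w + P_mem * f_l + K_prot * f_p).

``P_mem`` is a membrane-lipid affinity: the neutral species partitions with
10^logP and the ionized species roughly ten-fold weaker (an Austin-type
correction), weighted by the Henderson-Hasselbalch neutral fraction at
pH 7.4.  ``K_prot`` is the protein association constant back-calculated
from the measured plasma unbound fraction, so plasma binding anchors the
tissue protein-binding term.  Numeric identity with any particular
commercial platform's standard method is not claimed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import yaml

from .physiology import BLOOD_COMPARTMENTS, Physiology

__all__ = [
    "DrugParameters",
    "PartitionSet",
    "PLASMA_COMPOSITION",
    "load_drug",
    "neutral_fraction",
    "membrane_affinity",
    "compute_kps",
    "plasma_to_blood",
    "blood_to_plasma",
    "ng_per_ml_to_umol_per_l",
    "umol_per_l_to_ng_per_ml",
]

#: Plasma composition fractions (water / lipid / protein, w/w); ~93% water,
#: ~7 g/dL protein, ~0.35% lipid.
PLASMA_COMPOSITION = {"water": 0.925, "lipid": 0.0035, "protein": 0.07}

PH_PLASMA = 7.4


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical and biochemical profile of one compound.

    Clearances are specific plasma clearances in mL/min/kg body weight;
    they are converted to whole-body blood clearances at model build time.
    ``permeability`` (transcellular, cm/s) and ``solubility`` (ug/mL at
    pH 7) are carried in the data model but not rate-limiting under the
    default perfusion-limited distribution assumption.
    """

    name: str
    mw: float                # g/mol
    pka_acid: float          # monoprotic acid
    logp: float
    permeability: float      # cm/s
    solubility: float        # ug/mL
    fu_plasma: float         # fraction unbound in plasma, (0, 1]
    cl_hepatic: float        # mL/min/kg
    cl_renal: float          # mL/min/kg
    bp_ratio: float          # blood:plasma concentration ratio

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("molecular weight must be > 0")
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")
        if self.cl_hepatic < 0 or self.cl_renal < 0:
            raise ValueError("clearances must be >= 0")
        if self.bp_ratio <= 0:
            raise ValueError("blood:plasma ratio must be > 0")

    def with_fu_scale(self, fu_scale: float) -> "DrugParameters":
        """Scale the unbound fraction (e.g. uremic binding displacement), capped at 1."""
        return replace(self, fu_plasma=min(1.0, self.fu_plasma * fu_scale))


@dataclass(frozen=True)
class PartitionSet:
    """Tissue:plasma partition coefficients keyed by compartment id."""

    method: str
    kp: dict[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.kp.items() if not v > 0}
        if bad:
            raise ValueError(f"non-positive partition coefficients: {bad}")


def load_drug(source: str | None = None) -> DrugParameters:
    """Load a compound from a key-value YAML file (default: bundled 84-B10)."""
    if source is None:
        text = (importlib.resources.files("renalpk.data") / "84B10.yaml").read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return DrugParameters(
        name=str(raw["name"]),
        mw=float(raw["mw_g_mol"]),
        pka_acid=float(raw["pka_acid"]),
        logp=float(raw["logp"]),
        permeability=float(raw["permeability_cm_s"]),
        solubility=float(raw["solubility_ug_ml"]),
        fu_plasma=float(raw["fu"]),
        cl_hepatic=float(raw["clh_ml_min_kg"]),
        cl_renal=float(raw["clr_ml_min_kg"]),
        bp_ratio=float(raw["bp_ratio"]),
    )


def neutral_fraction(pka_acid: float, ph: float) -> float:
    """Henderson-Hasselbalch neutral (protonated) fraction of a monoprotic acid.

    ``1 / (1 + 10**(ph - pka))``; 0.5 at pH == pKa, strictly decreasing in pH.
    """
    return 1.0 / (1.0 + 10.0 ** (ph - pka_acid))


def membrane_affinity(logp: float, pka_acid: float, ph: float = PH_PLASMA) -> float:
    """Membrane-lipid partition coefficient of the neutral/ionized mixture.

    Neutral species at 10^logP, ionized species at 10^(logP - 1).
    """
    fn = neutral_fraction(pka_acid, ph)
    return fn * 10.0 ** logp + (1.0 - fn) * 10.0 ** (logp - 1.0)


def _protein_association(drug: DrugParameters, p_mem: float) -> float:
    """Protein association constant consistent with the plasma unbound fraction."""
    fw, fl, fp = (PLASMA_COMPOSITION[k] for k in ("water", "lipid", "protein"))
    k = (fw / drug.fu_plasma - fw - p_mem * fl) / fp
    return max(k, 0.0)


def compute_kps(drug: DrugParameters, phys: Physiology,
                method: str = "composition_based") -> PartitionSet:
    """Tissue:plasma partition coefficients for every non-blood compartment.

    ``composition_based`` (default) is the composition equation described in
    the module docstring.  ``logp_fu_heuristic`` is a cruder lipid-weighted
    rule, ``Kp = (f_w + P_mem f_l) / (f_w,p + P_mem f_l,p)`` scaled by the
    bound fraction carried over from plasma — useful as a sensitivity
    alternative, not as the primary method.

    Kp depends on tissue composition only, never on body weight.
    """
    p_mem = membrane_affinity(drug.logp, drug.pka_acid)
    kp: dict[str, float] = {}
    if method == "composition_based":
        k_prot = _protein_association(drug, p_mem)
        fw_p = PLASMA_COMPOSITION["water"]
        for name, t in phys.tissues.items():
            if name in BLOOD_COMPARTMENTS:
                continue
            kp[name] = (drug.fu_plasma / fw_p) * (
                t.fraction_water
                + p_mem * t.fraction_lipid
                + k_prot * t.fraction_protein
            )
    elif method == "logp_fu_heuristic":
        fw_p, fl_p = PLASMA_COMPOSITION["water"], PLASMA_COMPOSITION["lipid"]
        denom = fw_p + p_mem * fl_p
        for name, t in phys.tissues.items():
            if name in BLOOD_COMPARTMENTS:
                continue
            lipid_term = (t.fraction_water + p_mem * t.fraction_lipid) / denom
            kp[name] = drug.fu_plasma * lipid_term + (1.0 - drug.fu_plasma)
    else:
        raise ValueError(f"unknown Kp method {method!r}")
    return PartitionSet(method=method, kp=kp)


def plasma_to_blood(c_plasma: float, bp_ratio: float):
    """Convert a plasma concentration to whole blood: ``C_b = C_p * B:P``."""
    return c_plasma * bp_ratio


def blood_to_plasma(c_blood: float, bp_ratio: float):
    """Inverse of :func:`plasma_to_blood`."""
    return c_blood / bp_ratio


def ng_per_ml_to_umol_per_l(value: float, mw: float) -> float:
    """ng/mL -> umol/L given a molecular weight in g/mol."""
    if mw <= 0:
        raise ValueError("molecular weight must be > 0")
    return value / mw


def umol_per_l_to_ng_per_ml(value: float, mw: float) -> float:
    """umol/L -> ng/mL: ``ng/mL = umol/L * MW (g/mol)``."""
    if mw <= 0:
        raise ValueError("molecular weight must be > 0")
    return value * mw
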