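"""Species physiology: the compound-independent half of the PBPK model.

A :class:`Physiology` holds the 13 anatomical compartments of a whole-body
model — lung, heart, spleen, gastrointestinal tract, liver, kidney, brain,
adipose, muscle, skin, arterial and venous blood, and the rest of body —
with volumes, blood flows, tissue composition and elimination flags.
Reference tables for mouse (20 g), rat (300 g) and human (73 kg) ship as
commented plain-text data files; :func:`get_physiology` rescales them
linearly to an arbitrary body weight, and :func:`apply_ckd` derives a
renal-impairment variant with reduced glomerular filtration and renal
blood flow.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from io import StringIO

import pandas as pd
import yaml

__all__ = [
    "COMPARTMENTS",
    "BLOOD_COMPARTMENTS",
    "TissueSpec",
    "Physiology",
    "CKDAdjustment",
    "get_physiology",
    "apply_ckd",
    "load_ckd_adjustment",
]

#: Canonical compartment ids of the whole-body model.
COMPARTMENTS = (
    "lung", "heart", "spleen", "gi", "liver", "kidney", "brain",
    "adipose", "muscle", "skin", "arterial", "venous", "rest",
)

#: Compartments that are blood, not perfused tissue.
BLOOD_COMPARTMENTS = ("arterial", "venous")

SPECIES = ("mouse", "rat", "human")

#: Generous whole-body density bound used for the volume invariant (mL/kg).
_MAX_ML_PER_KG = 1050.0


class PhysiologyError(ValueError):
    """Raised when a physiology violates its structural invariants."""


@dataclass(frozen=True)
class TissueSpec:
    """One compartment: volume, perfusion, composition and elimination role.

    ``blood_flow`` is the arterial inflow in mL/min; for the liver it is the
    hepatic artery only (portal inflow from spleen/gut is wired by the PBPK
    engine), and for lung/arterial/venous it equals cardiac output.
    Composition fractions (water, total lipid, protein, w/w) drive the
    tissue:plasma partition coefficient calculation.
    """

    name: str
    volume: float            # mL
    blood_flow: float        # mL/min
    fraction_water: float
    fraction_lipid: float
    fraction_protein: float
    is_portal_drained: bool = False
    eliminating: str = "none"   # none | hepatic | renal
    #: Capillary endothelium class governing the distribution barrier:
    #: ``fenestrated`` (sinusoidal/fenestrated organs, no barrier),
    #: ``continuous`` (transcapillary permeability-surface limit), or
    #: ``tight`` (blood-brain-type junctions, strongly restricted).
    capillary_type: str = "fenestrated"
    #: Capillary exchange surface density, cm^2 per g of tissue (Renkin/Crone
    #: compendium values); unused for fenestrated organs.
    cap_surface_cm2_per_g: float = 70.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise PhysiologyError(f"{self.name}: volume must be > 0")
        if self.blood_flow < 0:
            raise PhysiologyError(f"{self.name}: blood flow must be >= 0")
        for frac in (self.fraction_water, self.fraction_lipid, self.fraction_protein):
            if not 0.0 <= frac <= 1.0:
                raise PhysiologyError(f"{self.name}: composition fractions must be in [0, 1]")
        if self.fraction_water + self.fraction_lipid + self.fraction_protein > 1.0 + 1e-9:
            raise PhysiologyError(f"{self.name}: composition fractions sum to > 1")
        if self.eliminating not in ("none", "hepatic", "renal"):
            raise PhysiologyError(f"{self.name}: unknown eliminating flag {self.eliminating!r}")
        if self.capillary_type not in ("fenestrated", "continuous", "tight"):
            raise PhysiologyError(f"{self.name}: unknown capillary type {self.capillary_type!r}")
        if self.cap_surface_cm2_per_g < 0:
            raise PhysiologyError(f"{self.name}: capillary surface must be >= 0")


@dataclass(frozen=True)
class Physiology:
    """A species' compartment volumes, blood flows, cardiac output and GFR."""

    species: str
    body_weight: float       # kg
    tissues: dict[str, TissueSpec]
    cardiac_output: float    # mL/min
    gfr: float               # mL/min
    hematocrit: float

    def __post_init__(self) -> None:
        self.validate()

    # -- structural invariants -------------------------------------------------
    def validate(self) -> None:
        if self.body_weight <= 0:
            raise PhysiologyError("body weight must be > 0")
        if not 0 < self.hematocrit < 1:
            raise PhysiologyError("hematocrit must be in (0, 1)")
        flow_sum = sum(t.blood_flow for t in self.perfused_tissues().values())
        if abs(flow_sum - self.cardiac_output) > 0.01 * self.cardiac_output:
            raise PhysiologyError(
                f"tissue blood flows ({flow_sum:.3g} mL/min) do not match cardiac "
                f"output ({self.cardiac_output:.3g} mL/min) within 1%"
            )
        vol_sum = sum(t.volume for t in self.tissues.values())
        if vol_sum > self.body_weight * _MAX_ML_PER_KG:
            raise PhysiologyError("total compartment volume exceeds body size")
        if "kidney" in self.tissues and self.gfr > self.tissues["kidney"].blood_flow:
            raise PhysiologyError("GFR cannot exceed kidney blood flow")

    def perfused_tissues(self) -> dict[str, TissueSpec]:
        """Tissues receiving arterial blood in parallel (excludes lung and blood)."""
        skip = set(BLOOD_COMPARTMENTS) | {"lung"}
        return {k: v for k, v in self.tissues.items() if k not in skip}

    @property
    def total_blood_volume(self) -> float:
        return sum(self.tissues[c].volume for c in BLOOD_COMPARTMENTS if c in self.tissues)

    # -- derived physiologies --------------------------------------------------
    def scaled_to(self, body_weight: float) -> "Physiology":
        """Rescale all volumes and flows linearly to a new body weight."""
        if body_weight <= 0:
            raise PhysiologyError("body weight must be > 0")
        f = body_weight / self.body_weight
        tissues = {
            k: replace(t, volume=t.volume * f, blood_flow=t.blood_flow * f)
            for k, t in self.tissues.items()
        }
        return Physiology(
            species=self.species,
            body_weight=body_weight,
            tissues=tissues,
            cardiac_output=self.cardiac_output * f,
            gfr=self.gfr * f,
            hematocrit=self.hematocrit,
        )


@dataclass(frozen=True)
class CKDAdjustment:
    """Renal-impairment overlay: fractional GFR and renal-flow reduction.

    Defaults correspond to severe CKD (stage 4-5): GFR at 20% of healthy and
    renal blood flow at 40%. ``fu_scale`` optionally increases the unbound
    plasma fraction (uremic displacement of protein binding); 1.0 leaves the
    compound model untouched.
    """

    gfr_fraction: float = 0.2
    renal_flow_fraction: float = 0.4
    fu_scale: float = 1.0
    label: str = "severe_ckd"

    def __post_init__(self) -> None:
        for name, frac in (("gfr_fraction", self.gfr_fraction),
                           ("renal_flow_fraction", self.renal_flow_fraction)):
            if not 0 < frac <= 1:
                raise PhysiologyError(f"{name} must be in (0, 1]")
        if self.fu_scale < 1:
            raise PhysiologyError("fu_scale must be >= 1")


def _data_text(filename: str) -> str:
    return (importlib.resources.files("renalpk.data") / filename).read_text()


def _load_reference(species: str) -> Physiology:
    header = yaml.safe_load(_data_text(f"{species}_header.yaml"))
    table = pd.read_csv(StringIO(_data_text(f"{species}_tissues.tsv")),
                        sep="\t", comment="#")
    tissues: dict[str, TissueSpec] = {}
    for row in table.itertuples(index=False):
        tissues[row.name] = TissueSpec(
            name=row.name,
            volume=float(row.volume_ml),
            blood_flow=float(row.flow_ml_min),
            fraction_water=float(row.fraction_water),
            fraction_lipid=float(row.fraction_lipid),
            fraction_protein=float(row.fraction_protein),
            is_portal_drained=bool(row.portal_drained),
            eliminating=str(row.eliminating),
            capillary_type=str(row.capillary_type),
            cap_surface_cm2_per_g=float(row.cap_surface_cm2_per_g),
        )
    return Physiology(
        species=species,
        body_weight=float(header["body_weight_kg"]),
        tissues=tissues,
        cardiac_output=float(header["cardiac_output_ml_min"]),
        gfr=float(header["gfr_ml_min"]),
        hematocrit=float(header["hematocrit"]),
    )


def get_physiology(species: str, body_weight: float | None = None) -> Physiology:
    """Return the reference physiology for a species, rescaled to ``body_weight``.

    Volumes and flows scale linearly with body weight within a species;
    composition fractions and hematocrit are weight-independent.

    Parameters
    ----------
    species:
        One of ``mouse``, ``rat``, ``human``.
    body_weight:
        Target body weight in kg; defaults to the species reference weight
        (0.02 / 0.3 / 73 kg).
    """
    if species not in SPECIES:
        raise PhysiologyError(f"unknown species {species!r}; expected one of {SPECIES}")
    ref = _load_reference(species)
    if body_weight is None or body_weight == ref.body_weight:
        return ref
    return ref.scaled_to(body_weight)


def apply_ckd(base: Physiology, adj: CKDAdjustment | None = None) -> Physiology:
    """Derive a chronic-kidney-disease physiology from a healthy one.

    GFR is multiplied by ``gfr_fraction`` and kidney blood flow by
    ``renal_flow_fraction``; cardiac output is reduced by the kidney-flow
    decrement (the flow lost to the kidney is not redistributed to other
    organs), so venous return stays conserved.
    """
    adj = adj or CKDAdjustment()
    kidney = base.tissues["kidney"]
    new_kidney_flow = kidney.blood_flow * adj.renal_flow_fraction
    new_gfr = base.gfr * adj.gfr_fraction
    if new_gfr > new_kidney_flow:
        raise PhysiologyError("adjusted GFR exceeds adjusted kidney blood flow")
    decrement = kidney.blood_flow - new_kidney_flow
    tissues = dict(base.tissues)
    tissues["kidney"] = replace(kidney, blood_flow=new_kidney_flow)
    new_co = base.cardiac_output - decrement
    for name in ("lung", *BLOOD_COMPARTMENTS):
        if name in tissues:
            tissues[name] = replace(tissues[name], blood_flow=new_co)
    return Physiology(
        species=base.species,
        body_weight=base.body_weight,
        tissues=tissues,
        cardiac_output=new_co,
        gfr=new_gfr,
        hematocrit=base.hematocrit,
    )


def load_ckd_adjustment(source: str | None = None) -> CKDAdjustment:
    """Load a CKD overlay from a YAML file, or the bundled severe-CKD default."""
    text = _data_text("ckd_severe.yaml") if source is None else open(source).read()
    raw = yaml.safe_load(text)
    return CKDAdjustment(
        gfr_fraction=float(raw["gfr_fraction"]),
        renal_flow_fraction=float(raw["renal_flow_fraction"]),
        fu_scale=float(raw.get("fu_scale", 1.0)),
        label=str(raw.get("label", "ckd")),
    )
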