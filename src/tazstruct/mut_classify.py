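"""Structural classification of missense mutations.

Each Barth-syndrome missense variant is placed in one of four structural
location classes on the tafazzin model — catalytic site, substrate-binding
cleft, membrane-associated surface, or buried core — and two boolean
flags are derived from the substitution chemistry:

* **electrostatic** — the substitution changes the residue's coarse
  charge class (negative {D,E} / positive {K,R} / histidine {H} /
  neutral).  Histidine is its own class: exchanging His for Gln or Arg
  alters the local electrostatics even though His carries no formal
  charge in net-charge sums.
* **stability** — the substitution plausibly destabilises the fold:
  proline introduction, glycine introduction inside the cleft or core,
  glycine removal, a charge-class change in the buried core, a large
  side-chain volume change (Zamyatnin volumes, default |ΔV| ≥ 20 Å³)
  inside the cleft or core, or a hydrophobic→polar change on the
  membrane-binding surface.

The proposed functional effect is then a deterministic function of the
location class alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .core_io import MutationRecord, SequenceRecord, Structure
from .membrane_charge import DEFAULT_SCHEME, ChargeScheme, PatchSet
from .surface_core import AccessibilityProfile

__all__ = [
    "ZAMYATNIN_VOLUME",
    "MotifHit",
    "SSAssignment",
    "MutationAnnotation",
    "LocationCall",
    "find_hx4d",
    "dihedral",
    "assign_secondary_structure",
    "classify_location",
    "effect_flags",
    "propose_effect",
    "normalize_location",
    "EFFECT_OF_LOCATION",
]

#: Amino-acid side-chain volumes in Å³ (Zamyatnin 1972).
ZAMYATNIN_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

#: Residue classes for the surface hydrophobic→polar stability rule.
RULE_F_HYDROPHOBIC = frozenset("AVLIMFWC")
RULE_F_POLAR = frozenset("STNQYH")

EFFECT_OF_LOCATION = {
    "catalytic": "Catalytic activity",
    "cleft": "Substrate binding",
    "surface": "Membrane association",
    "buried": "Destabilization",
}

_LOCATION_ALIASES = {
    "catalytic": "catalytic", "catalytic site": "catalytic",
    "cleft": "cleft", "surface": "surface", "buried": "buried",
}


def normalize_location(text: str) -> str:
    key = text.strip().lower()
    if key not in _LOCATION_ALIASES:
        raise ValueError(f"unknown location label {text!r}")
    return _LOCATION_ALIASES[key]


class MotifHit(NamedTuple):
    """An HX4D acyltransferase catalytic motif occurrence."""

    his_position: int
    asp_position: int


@dataclass
class SSAssignment:
    """Per-residue secondary-structure label: H (helix), E (strand), C (coil)."""

    labels: dict[tuple, str] = field(default_factory=dict)

    def label_of(self, key) -> str:
        return self.labels.get(key, "C")


class LocationCall(NamedTuple):
    location: str
    distal: bool = False


@dataclass
class MutationAnnotation:
    """One classified variant: location, flags, effect and triggering rules."""

    record: MutationRecord
    location: str
    electrostatic: bool
    stability: bool
    effect: str
    rules: list[str] = field(default_factory=list)
    distal: bool = False


def find_hx4d(seq: SequenceRecord) -> list[MotifHit]:
    """All His positions followed by Asp five residues later (HX4D motif).

    Positions are biological numbers (sequence index + numbering offset).
    """
    hits = []
    s = seq.seq
    for i in range(len(s) - 5):
        if s[i] == "H" and s[i + 5] == "D":
            hits.append(MotifHit(seq.number_of(i), seq.number_of(i + 5)))
    return hits


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = -(p1 - p0)
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone(res) -> Optional[dict[str, np.ndarray]]:
    atoms = {}
    for name in ("N", "CA", "C"):
        a = res.atom(name)
        if a is None:
            return None
        atoms[name] = a.coord
    return atoms


def assign_secondary_structure(structure: Structure) -> SSAssignment:
    """Torsion-window secondary structure: helix and strand by (φ, ψ) ranges.

    Helix requires φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°] sustained over
    runs of ≥ 4 residues; strand requires φ ∈ [−180°, −40°] and
    ψ ∈ [60°, 180°] over runs of ≥ 3.  Chain termini and residues with
    missing backbone atoms are coil.
    """
    residues = structure.residues
    bb = [_backbone(r) for r in residues]
    raw = []
    for i, res in enumerate(residues):
        prev_ok = i > 0 and bb[i - 1] is not None and residues[i - 1].chain_id == res.chain_id
        next_ok = (
            i + 1 < len(residues)
            and bb[i + 1] is not None
            and residues[i + 1].chain_id == res.chain_id
        )
        if bb[i] is None or not prev_ok or not next_ok:
            raw.append("C")
            continue
        phi = dihedral(bb[i - 1]["C"], bb[i]["N"], bb[i]["CA"], bb[i]["C"])
        psi = dihedral(bb[i]["N"], bb[i]["CA"], bb[i]["C"], bb[i + 1]["N"])
        if -100 <= phi <= -30 and -80 <= psi <= -5:
            raw.append("H")
        elif -180 <= phi <= -40 and 60 <= psi <= 180:
            raw.append("E")
        else:
            raw.append("C")
    # enforce minimum run lengths
    labels: dict[tuple, str] = {}
    min_run = {"H": 4, "E": 3}
    i = 0
    while i < len(raw):
        lab = raw[i]
        j = i
        while j < len(raw) and raw[j] == lab:
            j += 1
        final = lab if lab != "C" and (j - i) >= min_run[lab] else "C"
        for k in range(i, j):
            labels[residues[k].key] = final
        i = j
    return SSAssignment(labels=labels)


def classify_location(
    record: MutationRecord,
    catalytic: set[int],
    cleft: set[int],
    patch: PatchSet,
    profile: AccessibilityProfile,
    structure: Structure,
    patch_distance: float = 10.0,
) -> LocationCall:
    """Assign the structural location class of a mutated position.

    Precedence: catalytic > cleft > buried > surface.  A non-buried
    position inside a basic patch, or within ``patch_distance`` Å of a
    patch centroid, is membrane-associated surface; other exposed
    positions are surface with a ``distal`` qualifier.

    ``catalytic`` and ``cleft`` are sets of residue numbers (author /
    full-length numbering).
    """
    pos = record.position
    res = structure.find(pos)
    if res is None:
        raise KeyError(f"position {pos} absent from structure {structure.id!r}")
    if pos in catalytic:
        return LocationCall("catalytic")
    if pos in cleft or res.key in cleft:
        return LocationCall("cleft")
    buried = res.key in profile.buried_keys()
    if buried:
        return LocationCall("buried")
    if res.key in patch.all_members():
        return LocationCall("surface")
    ca = res.atom("CA") or (res.atoms[0] if res.atoms else None)
    if ca is not None and patch.nearest_centroid_distance(ca.coord) <= patch_distance:
        return LocationCall("surface")
    return LocationCall("surface", distal=True)


def effect_flags(
    record: MutationRecord,
    location: str,
    charge_scheme: ChargeScheme = DEFAULT_SCHEME,
    volume_table: dict[str, float] | None = None,
    dv_threshold: float = 20.0,
) -> tuple[bool, bool, list[str]]:
    """Electrostatic and conformational-stability flags for one substitution.

    Returns ``(electrostatic, stability, rules)`` where ``rules`` names
    every rule that fired, so each flag is auditable.
    """
    volumes = ZAMYATNIN_VOLUME if volume_table is None else volume_table
    loc = normalize_location(location)
    ref, alt = record.ref_aa, record.alt_aa
    rules: list[str] = []

    class_change = charge_scheme.class_of(ref) != charge_scheme.class_of(alt)
    if class_change:
        rules.append("charge-class-change")
    electrostatic = class_change

    stability = False
    if alt == "P":
        stability = True
        rules.append("proline-introduction")
    if alt == "G" and loc in ("cleft", "buried"):
        stability = True
        rules.append("glycine-introduction-in-packed-region")
    if ref == "G":
        stability = True
        rules.append("glycine-removal")
    if loc == "buried" and class_change:
        stability = True
        rules.append("buried-charge-change")
    dv = abs(volumes[ref] - volumes[alt])
    if loc in ("cleft", "buried") and dv >= dv_threshold:
        stability = True
        rules.append(f"volume-change-{dv:.1f}A3")
    if loc == "surface" and ref in RULE_F_HYDROPHOBIC and alt in RULE_F_POLAR:
        stability = True
        rules.append("surface-hydrophobic-to-polar")
    return electrostatic, stability, rules


def propose_effect(location: str) -> str:
    """Map a location class to its proposed functional effect."""
    return EFFECT_OF_LOCATION[normalize_location(location)]


def annotate_mutation(
    record: MutationRecord,
    location: str,
    distal: bool = False,
    charge_scheme: ChargeScheme = DEFAULT_SCHEME,
    dv_threshold: float = 20.0,
) -> MutationAnnotation:
    """Bundle flags + proposed effect for one variant at a known location."""
    loc = normalize_location(location)
    elec, stab, rules = effect_flags(
        record, loc, charge_scheme=charge_scheme, dv_threshold=dv_threshold
    )
    return MutationAnnotation(
        record=record,
        location=loc,
        electrostatic=elec,
        stability=stab,
        effect=propose_effect(loc),
        rules=rules,
        distal=distal,
    )
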