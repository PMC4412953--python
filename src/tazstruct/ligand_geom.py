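"""Phosphate-spacing geometry of dimeric phospholipids (cardiolipin-like).

Cardiolipin carries two phosphate groups whose characteristic spacing
(about 8.1 ± 0.4 Å between the oxygen centroids across surveyed CL
instances) constrains which pairs of basic residues in a binding cleft
can simultaneously contact both head groups.  This module measures that
spacing on ligand instances and scores basic-residue pairs for
compatibility with a reference spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core_io import LigandInstance, Structure
from .membrane_charge import TERMINAL_N

__all__ = [
    "PhosphateGroup",
    "SpacingStats",
    "PairMatch",
    "phosphate_groups",
    "phosphate_spacing",
    "aggregate_spacing",
    "match_basic_pairs",
]


@dataclass
class PhosphateGroup:
    p_coord: np.ndarray
    o_coords: np.ndarray     # (k, 3), 3-4 bonded oxygens

    @property
    def oxygen_centroid(self) -> np.ndarray:
        return self.o_coords.mean(axis=0)


@dataclass
class SpacingStats:
    """Per-ligand phosphate spacings with sample mean and SD."""

    spacings: np.ndarray
    mean: float
    sd: float
    n: int


@dataclass
class PairMatch:
    """Basic-residue pairs scored against a reference phosphate spacing."""

    pairs: list[tuple[tuple, tuple, float, bool]]   # (key_a, key_b, distance, compatible)
    reference_mean: float
    tolerance: float

    def compatible_pairs(self) -> list[tuple[tuple, tuple, float]]:
        return [(a, b, d) for a, b, d, ok in self.pairs if ok]

    def __len__(self) -> int:
        return len(self.pairs)


def phosphate_groups(ligand: LigandInstance, bond_cutoff: float = 1.8) -> list[PhosphateGroup]:
    """Group each phosphorus atom with its bonded oxygens (P–O <= cutoff Å)."""
    p_atoms = [a for a in ligand.atoms if a.element.upper() == "P"]
    o_atoms = [a for a in ligand.atoms if a.element.upper() == "O"]
    groups = []
    for p in p_atoms:
        bonded = [
            o.coord for o in o_atoms
            if np.linalg.norm(o.coord - p.coord) <= bond_cutoff
        ]
        groups.append(PhosphateGroup(p_coord=p.coord, o_coords=np.array(bonded)))
    return groups


def phosphate_spacing(ligand: LigandInstance, convention: str = "oxygen_centroid") -> float:
    """Distance in Å between the two phosphate groups of a dimeric lipid.

    Conventions: ``oxygen_centroid`` (default) — distance between the two
    groups' oxygen centroids; ``min_oo`` — closest inter-group O–O pair;
    ``pp`` — P–P distance.
    """
    groups = phosphate_groups(ligand)
    if len(groups) != 2:
        raise ValueError(
            f"ligand {ligand.id!r}: expected 2 phosphate groups, found {len(groups)}"
        )
    a, b = groups
    if convention == "oxygen_centroid":
        return float(np.linalg.norm(a.oxygen_centroid - b.oxygen_centroid))
    if convention == "min_oo":
        d = a.o_coords[:, None, :] - b.o_coords[None, :, :]
        return float(np.sqrt((d ** 2).sum(axis=-1)).min())
    if convention == "pp":
        return float(np.linalg.norm(a.p_coord - b.p_coord))
    raise ValueError(f"unknown spacing convention {convention!r}")


def aggregate_spacing(
    ligands: list[LigandInstance], convention: str = "oxygen_centroid"
) -> SpacingStats:
    """Sample mean and (n−1)-denominator SD of per-ligand phosphate spacings."""
    if not ligands:
        raise ValueError("no ligands supplied")
    spacings = np.array([phosphate_spacing(lg, convention) for lg in ligands])
    n = len(spacings)
    sd = float(spacings.std(ddof=1)) if n > 1 else 0.0
    return SpacingStats(spacings=spacings, mean=float(spacings.mean()), sd=sd, n=n)


def match_basic_pairs(
    basics,
    structure: Structure,
    reference: SpacingStats,
    tolerance: float = 3.0,
) -> PairMatch:
    """Score basic-residue pairs for compatibility with phosphate spacing.

    For every pair of basic residues (identified by residue number or
    key), the minimal distance between their side-chain terminal
    nitrogens (Nζ for Lys, Nη1/Nη2 for Arg) is compared with
    ``reference.mean ± tolerance``.  Residues lacking terminal nitrogens
    are skipped.
    """
    resolved = []
    for b in basics:
        res = structure.find(b) if isinstance(b, int) else next(
            (r for r in structure.residues if r.key == b), None
        )
        if res is None:
            continue
        names = TERMINAL_N.get(res.aa, ())
        pts = [res.atom(n).coord for n in names if res.atom(n)]
        if not pts:
            continue
        resolved.append((res.key, np.array(pts)))
    pairs = []
    for (key_a, pts_a), (key_b, pts_b) in combinations(resolved, 2):
        d = pts_a[:, None, :] - pts_b[None, :, :]
        dist = float(np.sqrt((d ** 2).sum(axis=-1)).min())
        ok = abs(dist - reference.mean) <= tolerance
        pairs.append((key_a, key_b, dist, ok))
    pairs.sort(key=lambda p: p[2])
    return PairMatch(pairs=pairs, reference_mean=reference.mean, tolerance=tolerance)
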