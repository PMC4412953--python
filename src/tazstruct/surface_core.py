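"""Solvent accessibility, burial, residue contacts and structural cores.

The structural core of a globular protein is defined here as the connected
components (size >= 2) of the residue-contact graph restricted to buried
residues, where a residue is buried when its relative solvent
accessibility — Shrake–Rupley SASA divided by a residue-type theoretical
maximum — falls strictly below a threshold (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core_io import Structure

__all__ = [
    "VDW_RADII",
    "MAX_ASA",
    "HYDROPHOBIC_SET",
    "AccessibilityProfile",
    "ContactGraph",
    "CoreSet",
    "sphere_points",
    "compute_sasa",
    "residue_sasa",
    "relative_accessibility",
    "residue_contacts",
    "structural_core",
    "core_hydrophobic_stats",
]

#: Van der Waals radii in Å (Bondi set with common biopolymer elements).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70

#: Theoretical maximum accessible surface area per residue type in Å²
#: (Tien et al. 2013, theoretical values from Gly-X-Gly tripeptides).
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Default hydrophobic residue classes used for core statistics: the
#: aliphatic/sulfur class (C, I, L, M, V), the aromatic class (F, W, Y)
#: and Ala.
HYDROPHOBIC_SET = frozenset("ACFILMVWY")


class UnknownElementError(KeyError):
    """Raised for an element with no tabulated van der Waals radius."""


@dataclass
class AccessibilityProfile:
    """Per-residue absolute SASA, relative accessibility and burial flags."""

    residue_keys: list[tuple[str, int, str]]
    absolute: np.ndarray       # Å² per residue
    relative: np.ndarray       # absolute / max-ASA, dimensionless
    threshold: float = 0.1

    @property
    def buried(self) -> np.ndarray:
        """Boolean mask: relative accessibility strictly below the threshold."""
        return self.relative < self.threshold

    def buried_keys(self) -> set[tuple[str, int, str]]:
        return {k for k, b in zip(self.residue_keys, self.buried) if b}

    def __len__(self) -> int:
        return len(self.residue_keys)


@dataclass
class ContactGraph:
    """Unordered residue pairs whose minimum heavy-atom distance <= cutoff."""

    pairs: set[frozenset]
    cutoff: float

    def neighbors(self, key) -> set:
        out = set()
        for p in self.pairs:
            if key in p:
                (other,) = p - {key}
                out.add(other)
        return out


@dataclass
class CoreSet:
    """Connected components of buried-residue contacts (each of size >= 2)."""

    components: list[set] = field(default_factory=list)

    def all_residues(self) -> set:
        out: set = set()
        for comp in self.components:
            out |= comp
        return out

    def __len__(self) -> int:
        return len(self.components)


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-section spiral)."""
    i = np.arange(n)
    phi = (1 + np.sqrt(5.0)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _atom_radii(elements: list[str], strict: bool = True) -> np.ndarray:
    radii = np.empty(len(elements))
    for i, el in enumerate(elements):
        key = el.upper()
        if key in VDW_RADII:
            radii[i] = VDW_RADII[key]
        elif strict:
            raise UnknownElementError(f"no van der Waals radius for element {el!r}")
        else:
            radii[i] = DEFAULT_RADIUS
    return radii


def _molecular_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed principal-axis frame of a coordinate set.

    Sphere-point sampling directions are expressed in this frame, which
    co-rotates with the molecule, so the computed areas are exactly
    invariant under rigid motion instead of merely converging to
    invariance with the point count.  Axis signs are fixed by the third
    central moment along each axis (largest-component sign as fallback).
    """
    if len(coords) < 3:
        return np.eye(3)
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    axes = []
    for k in (2, 1, 0):
        v = vecs[:, k]
        skew = float(np.sum((centred @ v) ** 3))
        if abs(skew) > 1e-6:
            v = v if skew > 0 else -v
        else:
            j = int(np.argmax(np.abs(v)))
            v = v if v[j] > 0 else -v
        axes.append(v)
    frame = np.column_stack(axes[:2] + [np.cross(axes[0], axes[1])])
    return frame


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    strict_elements: bool = False,
) -> np.ndarray:
    """Shrake–Rupley solvent-accessible surface area per heavy atom (Å²).

    Each atom is inflated by the probe radius and sampled with
    ``n_sphere_points`` quasi-uniform surface points; points not occluded
    by any neighbouring inflated atom are accessible.  Sampling directions
    live in the molecule's principal-axis frame, making the result
    rigid-motion invariant.  Returns one area per heavy atom in the order
    given by ``structure.heavy_atom_table()``.
    """
    coords, owner = structure.heavy_atom_table()
    if coords.shape[0] == 0:
        raise ValueError("structure has no heavy atoms")
    elements = [
        a.element
        for res in structure.residues
        for a in res.atoms
        if a.element.upper() != "H"
    ]
    radii = _atom_radii(elements, strict=strict_elements) + probe_radius
    unit = sphere_points(n_sphere_points) @ _molecular_frame(coords).T

    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(len(coords))
    # neighbour lists: any atom whose inflated sphere can occlude this one
    neighbor_lists = tree.query_ball_point(coords, r=2.0 * max_r)
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + r * unit
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * r * r * accessible.sum() / n_sphere_points
    return areas


def residue_sasa(structure: Structure, atom_areas: np.ndarray) -> np.ndarray:
    """Sum per-atom SASA over each residue."""
    _, owner = structure.heavy_atom_table()
    out = np.zeros(len(structure.residues))
    np.add.at(out, owner, atom_areas)
    return out


def relative_accessibility(
    structure: Structure,
    atom_areas: np.ndarray,
    max_asa_table: dict[str, float] | None = None,
    threshold: float = 0.1,
) -> AccessibilityProfile:
    """Normalise residue SASA by residue-type maxima and flag buried residues.

    A residue is buried iff its relative accessibility is *strictly* below
    ``threshold``.  Residues typed 'X' (nonstandard) fall back to the mean
    of the table, since no reference maximum exists for them.
    """
    table = MAX_ASA if max_asa_table is None else max_asa_table
    fallback = float(np.mean(list(table.values())))
    absolute = residue_sasa(structure, atom_areas)
    relative = np.empty_like(absolute)
    for i, res in enumerate(structure.residues):
        if res.aa == "X":
            ref = fallback
        elif res.aa in table:
            ref = table[res.aa]
        else:
            raise KeyError(f"residue type {res.aa!r} absent from max-ASA table")
        relative[i] = absolute[i] / ref
    return AccessibilityProfile(
        residue_keys=[r.key for r in structure.residues],
        absolute=absolute,
        relative=relative,
        threshold=threshold,
    )


def residue_contacts(structure: Structure, cutoff: float = 4.5) -> ContactGraph:
    """All residue pairs whose minimum heavy-atom distance is <= cutoff (Å)."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    coords, owner = structure.heavy_atom_table()
    pairs: set[frozenset] = set()
    if len(coords) == 0:
        return ContactGraph(pairs=pairs, cutoff=cutoff)
    tree = cKDTree(coords)
    keys = [r.key for r in structure.residues]
    for i, j in tree.query_pairs(r=cutoff):
        if owner[i] != owner[j]:
            pairs.add(frozenset((keys[owner[i]], keys[owner[j]])))
    return ContactGraph(pairs=pairs, cutoff=cutoff)


def structural_core(profile: AccessibilityProfile, contacts: ContactGraph) -> CoreSet:
    """Connected components of the contact graph induced on buried residues.

    Isolated buried residues (no buried contact partner) are discarded:
    a core requires residues in mutual contact.
    """
    buried = profile.buried_keys()
    g = nx.Graph()
    g.add_nodes_from(buried)
    for pair in contacts.pairs:
        a, b = tuple(pair)
        if a in buried and b in buried:
            g.add_edge(a, b)
    components = [set(c) for c in nx.connected_components(g) if len(c) >= 2]
    components.sort(key=len, reverse=True)
    return CoreSet(components=components)


def core_hydrophobic_stats(
    core: CoreSet,
    structure: Structure,
    hydrophobic_set: frozenset[str] | set[str] = HYDROPHOBIC_SET,
) -> tuple[list[int], int]:
    """Count hydrophobic residues per core component and in total."""
    aa_of = {r.key: r.aa for r in structure.residues}
    per_component = [
        sum(1 for key in comp if aa_of.get(key) in hydrophobic_set)
        for comp in core.components
    ]
    return per_component, int(sum(per_component))
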