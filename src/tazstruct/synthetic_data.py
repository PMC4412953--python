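"""Synthetic structures, ligands and packaged reference tables.

Every pipeline stage is testable offline against constructs with known
ground truth:

* ideal polypeptide backbones at chosen (φ, ψ) torsions (NeRF chain
  extension with standard bond geometry), including four-helix bundles
  with a hydrophobic interior whose buried face is known by construction;
* hollow shell/cup/tube atom lattices enclosing cavities with known
  lining atoms and known numbers of openings (0 / 1 / 2 mouths);
* cardiolipin-like ligands: two tetrahedral phosphate groups at a
  parameterised centroid spacing (mean 8.1 Å, SD 0.4 Å by default — the
  spacing surveyed across CL instances in crystal structures);
* the packaged tafazzin reference tables: the 39 curated Barth-syndrome
  missense variants with their location/flag/effect assignments, the
  exon map (exon 5 = residues 125–154), the per-exon cleft-residue
  distribution, and the HX4D catalytic positions {69, 74}.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core_io import (
    AtomRecord,
    ExonMap,
    LigandInstance,
    MutationRecord,
    ResidueView,
    SequenceRecord,
    Structure,
    parse_hgvs_p,
)

__all__ = [
    "GeneratorConfig",
    "FixtureBundle",
    "place_atom",
    "build_helix",
    "build_bundle",
    "build_pocket_construct",
    "make_cl_ligands",
    "make_disordered_sequence",
    "packaged_fixtures",
    "CATALYTIC_POSITIONS",
]

#: HX4D catalytic motif positions in human tafazzin (full-length numbering).
CATALYTIC_POSITIONS = frozenset({69, 74})

# standard backbone geometry (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_OMEGA = 180.0


@dataclass
class GeneratorConfig:
    """Reproducible description of one synthetic construct."""

    seed: int = 0
    construct: str = "helix"
    helix_length: int = 18
    phi: float = -57.0
    psi: float = -47.0
    bundle_radius: float = 6.0
    cavity_radius: float = 8.0
    tube_radius: float = 6.0
    tube_length: float = 24.0
    ligand_count: int = 200
    spacing_mean: float = 8.1
    spacing_sd: float = 0.4
    sequence: Optional[str] = None


@dataclass
class FixtureBundle:
    """The packaged in-literature reference tables."""

    mutations: pd.DataFrame
    mutation_records: list[MutationRecord]
    exon_map: ExonMap
    cleft_exon_counts: dict[str, int]
    cleft_exon_fractions: dict[str, float]
    catalytic_positions: frozenset[int] = CATALYTIC_POSITIONS


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom D so that |CD| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = torsion (natural extension reference frame)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(chi),
         bond * np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    u = (n - ca) / np.linalg.norm(n - ca)
    v = (c - ca) / np.linalg.norm(c - ca)
    bis = -(u + v)
    bis /= np.linalg.norm(bis)
    perp = np.cross(v, u)
    perp /= np.linalg.norm(perp)
    alpha = np.radians(54.0)
    direction = bis * np.cos(alpha) + perp * np.sin(alpha)
    return ca + _B_CA_CB * direction


#: pseudo side-chain terminal atoms: (atom name, distance from CA along the
#: CB direction, lateral offset) — coarse but adequate for patch geometry.
_SIDECHAIN_TIPS = {
    "K": (("NZ", "N", 5.3, 0.0),),
    "R": (("NH1", "N", 6.0, 0.8), ("NH2", "N", 6.0, -0.8)),
    "H": (("ND1", "N", 3.6, 0.7), ("NE2", "N", 3.6, -0.7)),
}


def build_helix(
    seq: str,
    phi: float = -57.0,
    psi: float = -47.0,
    chain_id: str = "A",
    start_number: int = 1,
    structure_id: str = "helix",
    extend_sidechains: bool = True,
) -> Structure:
    """Ideal polypeptide backbone at uniform (φ, ψ) with Cβ (and a Cγ
    extension plus basic-residue terminal nitrogens) placed geometrically.

    Raises on non-finite torsions or sequences shorter than 4 residues.
    """
    if len(seq) < 4:
        raise ValueError("need at least 4 residues")
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValueError("torsions must be finite")
    n_res = len(seq)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi)
    residues = []
    for i, aa in enumerate(seq):
        atoms = [
            AtomRecord("N", "N", N[i]),
            AtomRecord("CA", "C", CA[i]),
            AtomRecord("C", "C", C[i]),
        ]
        if i + 1 < n_res:
            atoms.append(
                AtomRecord("O", "O", place_atom(N[i], CA[i], C[i], _B_C_O,
                                                _A_CA_C_O, psi + 180.0))
            )
        if aa != "G":
            cb = _cb_position(N[i], CA[i], C[i])
            atoms.append(AtomRecord("CB", "C", cb))
            tip_dir = (cb - CA[i]) / np.linalg.norm(cb - CA[i])
            if extend_sidechains and aa not in ("A",):
                atoms.append(AtomRecord("CG", "C", CA[i] + tip_dir * (_B_CA_CB + 1.5)))
            if aa in _SIDECHAIN_TIPS:
                side = np.cross(tip_dir, [0.0, 0.0, 1.0])
                nrm = np.linalg.norm(side)
                side = side / nrm if nrm > 1e-8 else np.array([1.0, 0.0, 0.0])
                for name, element, dist, lateral in _SIDECHAIN_TIPS[aa]:
                    atoms.append(
                        AtomRecord(name, element, CA[i] + tip_dir * dist + side * lateral)
                    )
        residues.append(
            ResidueView(chain_id=chain_id, number=start_number + i, aa=aa, atoms=atoms)
        )
    return Structure(id=structure_id, residues=residues)


def build_bundle(
    n_helices: int = 4,
    length: int = 18,
    radius: float = 6.0,
    seq_aa: str = "L",
) -> tuple[Structure, set]:
    """Parallel helix bundle with a hydrophobic interior.

    Helices are ideal α-helices translated to the corners of a regular
    polygon of the given radius around the z-ish bundle axis.  Returns
    the structure and the ground-truth interior-face residue set: the
    residues of the central turns whose Cβ points toward the bundle axis.
    """
    helices = []
    for h in range(n_helices):
        st = build_helix(seq_aa * length, chain_id=chr(ord("A") + h),
                         structure_id=f"h{h}")
        helices.append(st)
    # orient each helix along z via PCA of its CA trace, then offset radially
    residues = []
    interior: set = set()
    for h, st in enumerate(helices):
        ca = np.array([r.atom("CA").coord for r in st.residues])
        center = ca.mean(axis=0)
        _, _, vt = np.linalg.svd(ca - center)
        axis = vt[0]
        if axis[2] < 0:
            axis = -axis
        # rotation taking helix axis to z
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(axis, z)
        s, cth = np.linalg.norm(v), float(np.dot(axis, z))
        if s < 1e-9:
            rot = np.eye(3)
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx * ((1 - cth) / s ** 2)
        angle = 2 * np.pi * h / n_helices
        offset = np.array([radius * np.cos(angle), radius * np.sin(angle), 0.0])
        for res in st.residues:
            atoms = [
                AtomRecord(a.name, a.element, rot @ (a.coord - center) + offset)
                for a in res.atoms
            ]
            residues.append(
                ResidueView(chain_id=res.chain_id, number=res.number,
                            aa=res.aa, atoms=atoms)
            )
    structure = Structure(id="bundle", residues=residues)
    # ground truth: central-turn residues whose CB points toward the axis
    z_vals = [a.coord[2] for r in residues for a in r.atoms if a.name == "CA"]
    z_lo, z_hi = np.percentile(z_vals, [20, 80])
    for res in residues:
        ca, cb = res.atom("CA"), res.atom("CB")
        if cb is None or not (z_lo <= ca.coord[2] <= z_hi):
            continue
        inward = -np.array([ca.coord[0], ca.coord[1], 0.0])
        nrm = np.linalg.norm(inward)
        if nrm < 1e-8:
            continue
        side = cb.coord - ca.coord
        if np.dot(side / np.linalg.norm(side), inward / nrm) > 0.55:
            interior.add(res.key)
    return structure, interior


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n)
    phi = (1 + np.sqrt(5.0)) / 2
    z = (1 - (2 * i + 1) / n) * radius
    theta = 2 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, radius ** 2 - z ** 2))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _atoms_to_structure(points: np.ndarray, structure_id: str) -> Structure:
    residues = [
        ResidueView(chain_id="A", number=i + 1, aa="A",
                    atoms=[AtomRecord("CA", "C", p)])
        for i, p in enumerate(points)
    ]
    return Structure(id=structure_id, residues=residues)


def build_pocket_construct(
    kind: str,
    cavity_radius: float = 8.0,
    tube_radius: float = 6.0,
    tube_length: float = 24.0,
    lattice_spacing: float = 2.0,
    seed: int = 0,
) -> tuple[Structure, set, int]:
    """Hollow atom-lattice constructs with known cavities.

    ``kind``: ``cavity`` (closed shell, 0 mouths), ``cup`` (shell with a
    45°-half-angle opening, 1 mouth) or ``tube`` (open-ended cylinder,
    2 mouths).  Returns ``(structure, lining residue keys, expected
    mouth count)``; every wall atom lines the enclosed space, so the
    lining ground truth is the full residue set.
    """
    probe_wall = 3.1   # carbon vdW + water probe: minimum usable lumen
    if kind in ("cavity", "cup"):
        if cavity_radius <= probe_wall + 1.0:
            raise ValueError("cavity radius too small to enclose grid points")
        n = max(8, int(np.ceil(4 * np.pi * cavity_radius ** 2 / lattice_spacing ** 2)))
        pts = _fibonacci_sphere(n, cavity_radius)
        if kind == "cup":
            pts = pts[pts[:, 2] <= cavity_radius * np.cos(np.radians(45.0))]
        expected_mouths = 0 if kind == "cavity" else 1
    elif kind == "tube":
        if tube_radius <= probe_wall:
            raise ValueError("tube radius too small to enclose grid points")
        n_ring = max(6, int(np.ceil(2 * np.pi * tube_radius / lattice_spacing)))
        n_z = int(np.ceil(tube_length / lattice_spacing)) + 1
        rows = []
        for k in range(n_z):
            z = -tube_length / 2 + k * lattice_spacing
            stagger = (k % 2) * np.pi / n_ring
            ang = 2 * np.pi * np.arange(n_ring) / n_ring + stagger
            rows.append(np.column_stack(
                [tube_radius * np.cos(ang), tube_radius * np.sin(ang),
                 np.full(n_ring, z)]
            ))
        pts = np.vstack(rows)
        expected_mouths = 2
    else:
        raise ValueError(f"unknown construct kind {kind!r}")
    structure = _atoms_to_structure(pts, f"{kind}_construct")
    lining = {r.key for r in structure.residues}
    return structure, lining, expected_mouths


def _tetrahedral_oxygens(rng: np.random.Generator, bond: float = 1.54) -> np.ndarray:
    base = np.array(
        [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float
    ) / np.sqrt(3.0)
    rot = Rotation.random(rng=rng).as_matrix()
    return bond * base @ rot.T


def make_cl_ligands(
    n: int,
    mean_spacing: float = 8.1,
    jitter_sd: float = 0.4,
    seed: int = 0,
) -> list[LigandInstance]:
    """Cardiolipin-like ligands: two tetrahedral phosphate groups whose
    oxygen-centroid separation is Normal(mean_spacing, jitter_sd),
    randomly oriented and placed.  Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("need n >= 1 ligands")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ligands = []
    for i in range(n):
        spacing = mean_spacing + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        axis = Rotation.random(rng=rng).as_matrix()[:, 0]
        center = rng.uniform(-50, 50, size=3)
        atoms = []
        for sign, tag in ((-0.5, "A"), (0.5, "B")):
            p = center + sign * spacing * axis
            atoms.append(AtomRecord(f"P{tag}", "P", p))
            for k, o in enumerate(_tetrahedral_oxygens(rng)):
                atoms.append(AtomRecord(f"O{tag}{k + 1}", "O", p + o))
        ligands.append(LigandInstance(id=f"CLX_{i}", atoms=atoms))
    return ligands


# composition biased toward hydrophilic/charged residues, emulating the
# exon-5-encoded segment's chemistry
_DISORDER_POOL = "EEKKRDQSSTPPGN"
_ORDER_POOL = "LIVFMAW"


def make_disordered_sequence(length: int = 30, seed: int = 0) -> str:
    """Random hydrophilic/charged-rich sequence (exon-5-like composition)."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_DISORDER_POOL), size=length))


def packaged_fixtures() -> FixtureBundle:
    """Load the packaged tafazzin reference tables.

    39 curated missense variants at 33 distinct positions with their
    location/flag/effect assignments, the 11-exon protein map (exon 5 =
    125–154), and the 57-residue cleft distribution over exons.
    """
    data = resources.files("tazstruct") / "data"
    mutations = pd.read_csv(data / "table2_mutations.tsv", sep="\t", comment="#",
                            dtype=str).fillna("")
    records = []
    for row in mutations.itertuples():
        rec = parse_hgvs_p(row.hgvs_p)
        records.append(
            MutationRecord(rec.ref_aa, rec.position, rec.alt_aa, exon_id=str(row.exon))
        )
    exon_df = pd.read_csv(data / "exon_map.tsv", sep="\t", comment="#",
                          dtype={"exon_id": str})
    exon_map = ExonMap(
        entries=[(str(r.exon_id), int(r.start), int(r.end)) for r in exon_df.itertuples()]
    )
    cleft_df = pd.read_csv(data / "table1_cleft_counts.tsv", sep="\t", comment="#",
                           dtype={"exon_id": str})
    counts = {
        str(e): int(c) for e, c in zip(cleft_df["exon_id"], cleft_df["count"])
    }
    fractions = {
        str(e): float(f) for e, f in zip(cleft_df["exon_id"], cleft_df["fraction_pct"])
    }
    return FixtureBundle(
        mutations=mutations,
        mutation_records=records,
        exon_map=exon_map,
        cleft_exon_counts=counts,
        cleft_exon_fractions=fractions,
    )
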