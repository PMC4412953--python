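"""Domain types and file I/O for the tafazzin structure-analysis pipeline.

Everything downstream (accessibility, cores, clefts, patches, mutation
classification) operates on the lightweight containers defined here:
:class:`Structure` (chains/residues/heavy atoms in author numbering),
:class:`SequenceRecord`, :class:`ExonMap` and :class:`MutationRecord`.
PDB files are parsed and written through :mod:`gemmi`; FASTA through
:mod:`Bio.SeqIO`; tab-separated tables through :mod:`pandas`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AtomRecord",
    "ResidueView",
    "Structure",
    "LigandInstance",
    "SequenceRecord",
    "ExonMap",
    "MutationRecord",
    "UNDEFINED",
    "read_structure",
    "write_structure",
    "read_fasta",
    "read_exon_map",
    "read_mutation_table",
    "map_numbering",
    "parse_hgvs_p",
    "THREE_TO_ONE",
]

#: Standard one-letter amino-acid alphabet; anything else parses as 'X'.
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
_THREE_TO_ONE_UPPER = {k.upper(): v for k, v in THREE_TO_ONE.items()}

#: Sentinel returned by :func:`map_numbering` for positions inside exon 5
#: of the full-length isoform, which simply do not exist in the Δ5 isoform.
UNDEFINED = None


class EmptyStructureError(ValueError):
    """Raised when a PDB file contains no ATOM records."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy (or hydrogen) atom: name, element and Cartesian coordinate in Å."""

    name: str
    element: str
    coord: np.ndarray
    is_hetero: bool = False

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name!r}: coordinate must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element symbol must be non-empty")
        object.__setattr__(self, "coord", coord)


@dataclass
class ResidueView:
    """One residue in author numbering with its atoms.

    ``aa`` is the one-letter code, or ``'X'`` for nonstandard residues,
    which downstream charge/hydrophobicity computations skip.
    """

    chain_id: str
    number: int
    aa: str
    atoms: list[AtomRecord] = field(default_factory=list)
    icode: str = ""
    name: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        """Unique residue identifier (chain, author number, insertion code)."""
        return (self.chain_id, self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.number}{self.icode}"

    def heavy_coords(self) -> np.ndarray:
        """(n, 3) array of non-hydrogen atom coordinates."""
        pts = [a.coord for a in self.atoms if a.element.upper() != "H"]
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class LigandInstance:
    """A hetero molecule (e.g., a cardiolipin-like dimeric phospholipid)."""

    id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Structure:
    """An ordered collection of residues plus hetero ligands."""

    id: str
    residues: list[ResidueView] = field(default_factory=list)
    ligands: list[LigandInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue identifiers (chain, number, icode)")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[ResidueView]:
        return iter(self.residues)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def find(self, number: int, chain_id: Optional[str] = None) -> Optional[ResidueView]:
        """First residue with the given author number (optionally within a chain)."""
        for r in self.residues:
            if r.number == number and (chain_id is None or r.chain_id == chain_id):
                return r
        return None

    def heavy_atom_table(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates with their owning residue indices.

        Returns ``(coords, residue_index)`` where ``coords`` is (n, 3) and
        ``residue_index[i]`` indexes into :attr:`residues`.
        """
        coords: list[np.ndarray] = []
        owner: list[int] = []
        for i, res in enumerate(self.residues):
            for a in res.atoms:
                if a.element.upper() != "H":
                    coords.append(a.coord)
                    owner.append(i)
        if not coords:
            return np.empty((0, 3)), np.empty(0, dtype=int)
        return np.array(coords), np.array(owner, dtype=int)


@dataclass
class SequenceRecord:
    """A protein sequence with a biological-numbering offset.

    Position ``i`` (1-based within ``seq``) corresponds to biological
    residue number ``i + numbering_offset``.
    """

    id: str
    seq: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("sequence must be non-empty")
        bad = set(self.seq) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(f"sequence {self.id!r}: invalid symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def number_of(self, index: int) -> int:
        """Biological residue number of 0-based sequence index."""
        return index + 1 + self.numbering_offset


@dataclass
class ExonMap:
    """Exon → protein-residue ranges, full-length numbering, 1-based inclusive."""

    entries: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for exon_id, start, end in self.entries:
            if start > end:
                raise ValueError(f"exon {exon_id}: start {start} > end {end}")
            if start < 1:
                raise ValueError(f"exon {exon_id}: start must be >= 1")
        self.entries = sorted(self.entries, key=lambda e: e[1])
        for (id_a, _, end_a), (id_b, start_b, _) in zip(self.entries, self.entries[1:]):
            if start_b <= end_a:
                raise ValueError(f"exons {id_a} and {id_b} overlap")

    def __len__(self) -> int:
        return len(self.entries)

    def exon_of(self, position: int) -> Optional[str]:
        for exon_id, start, end in self.entries:
            if start <= position <= end:
                return exon_id
        return None

    def range_of(self, exon_id: str) -> tuple[int, int]:
        for eid, start, end in self.entries:
            if eid == exon_id:
                return (start, end)
        raise KeyError(f"no exon {exon_id!r} in map")

    def exon_ids(self) -> list[str]:
        return [e[0] for e in self.entries]


@dataclass(frozen=True)
class MutationRecord:
    """One missense variant in HGVS-p style, full-length numbering."""

    ref_aa: str
    position: int
    alt_aa: str
    exon_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("reference and alternate residues must differ")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def hgvs_p(self) -> str:
        one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
        return f"p.{one_to_three[self.ref_aa]}{self.position}{one_to_three[self.alt_aa]}"


# ---------------------------------------------------------------------------
# PDB input / output (gemmi-backed)
# ---------------------------------------------------------------------------

def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc letter order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(path: str | Path, model_index: int = 0) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Only the model at ``model_index`` (default: first) is read.  ATOM
    records become residues; HETATM records (excluding waters) become
    ligands.  Alternate locations are resolved to the highest-occupancy
    conformer, ties broken by altloc letter.

    Raises
    ------
    EmptyStructureError
        If the selected model contains no polymer ATOM records.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    if model_index >= len(st):
        raise IndexError(f"model index {model_index} out of range ({len(st)} models)")
    st.setup_entities()
    model = st[model_index]

    residues: list[ResidueView] = []
    ligands: list[LigandInstance] = []
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            het = res.het_flag == "H"
            # group altlocs by atom name, keep one conformer per name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = [
                AtomRecord(
                    name=name,
                    element=(_pick_altloc(group).element.name or "C"),
                    coord=np.array(
                        [_pick_altloc(group).pos.x,
                         _pick_altloc(group).pos.y,
                         _pick_altloc(group).pos.z]
                    ),
                    is_hetero=het,
                )
                for name, group in by_name.items()
            ]
            if het:
                ligands.append(
                    LigandInstance(id=f"{res.name}_{chain.name}{res.seqid.num}", atoms=atoms)
                )
            else:
                one = _THREE_TO_ONE_UPPER.get(res.name.upper(), "X")
                residues.append(
                    ResidueView(
                        chain_id=chain.name,
                        number=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        aa=one,
                        name=res.name,
                        atoms=atoms,
                    )
                )
    if not residues:
        raise EmptyStructureError(f"{path}: no polymer ATOM records in model {model_index}")
    residues.sort(key=lambda r: (r.chain_id, r.number, r.icode))
    return Structure(id=path.stem, residues=residues, ligands=ligands)


_ONE_TO_THREE_UPPER = {v: k.upper() for k, v in THREE_TO_ONE.items()}


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` back to PDB (coordinates at PDB precision)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        chain = chains.setdefault(res.chain_id, gemmi.Chain(res.chain_id))
        gres = gemmi.Residue()
        gres.name = res.name or _ONE_TO_THREE_UPPER.get(res.aa, "UNK")
        gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = 1.0
            gres.add_atom(ga)
        chain.add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# FASTA / TSV input
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, numbering_offset: int = 0) -> list[SequenceRecord]:
    """Read protein FASTA records; unknown symbols are mapped to 'X'."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(c if c in STANDARD_AA else "X" for c in str(rec.seq).upper())
        records.append(SequenceRecord(id=rec.id, seq=seq, numbering_offset=numbering_offset))
    return records


def read_exon_map(path: str | Path) -> ExonMap:
    """Read a TSV with columns ``exon_id``, ``start``, ``end`` into an ExonMap."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"exon_id": str})
    if df.empty:
        return ExonMap(entries=[])
    missing = {"exon_id", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"exon map missing columns: {sorted(missing)}")
    entries = [
        (str(row.exon_id), int(row.start), int(row.end)) for row in df.itertuples()
    ]
    return ExonMap(entries=entries)


def parse_hgvs_p(text: str) -> MutationRecord:
    """Parse ``p.<Ref3><pos><Alt3>`` protein-variant notation.

    >>> parse_hgvs_p("p.Gly197Arg")
    MutationRecord(ref_aa='G', position=197, alt_aa='R', exon_id=None)
    """
    s = text.strip()
    if not s.startswith("p."):
        raise ValueError(f"{text!r}: HGVS protein notation must start with 'p.'")
    body = s[2:]
    if len(body) < 7:
        raise ValueError(f"{text!r}: too short for p.<Ref><pos><Alt>")
    ref3, alt3 = body[:3], body[-3:]
    pos_str = body[3:-3]
    if ref3 not in THREE_TO_ONE:
        raise ValueError(f"{text!r}: unknown residue code {ref3!r}")
    if alt3 not in THREE_TO_ONE:
        raise ValueError(f"{text!r}: unknown residue code {alt3!r}")
    if not pos_str.isdigit():
        raise ValueError(f"{text!r}: position {pos_str!r} is not an integer")
    return MutationRecord(
        ref_aa=THREE_TO_ONE[ref3], position=int(pos_str), alt_aa=THREE_TO_ONE[alt3]
    )


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a TSV of missense mutations (columns ``hgvs_p``, optional ``exon``).

    Raises a ``ValueError`` naming the offending row index on a malformed
    HGVS string.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        return []
    if "hgvs_p" not in df.columns:
        raise ValueError("mutation table must have an 'hgvs_p' column")
    records = []
    for i, row in enumerate(df.itertuples()):
        try:
            rec = parse_hgvs_p(row.hgvs_p)
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        exon = getattr(row, "exon", None)
        if exon is not None and not (isinstance(exon, float) and math.isnan(exon)):
            rec = MutationRecord(rec.ref_aa, rec.position, rec.alt_aa, exon_id=str(exon))
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Isoform numbering
# ---------------------------------------------------------------------------

def map_numbering(
    position: int, direction: str, exon_map: ExonMap, exon5_id: str = "5"
) -> Optional[int]:
    """Convert residue numbers between the full-length and Δ5 isoforms.

    Exon 5 (30 residues, 125–154 in human tafazzin) is absent from the Δ5
    splice variant; Δ5 numbering equals full-length numbering below exon 5
    and full-length minus the exon length above it.

    Parameters
    ----------
    direction:
        ``"FL->D5"`` or ``"D5->FL"``.

    Returns
    -------
    The converted residue number, or :data:`UNDEFINED` (``None``) for
    full-length positions inside exon 5, which do not exist in Δ5.
    """
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    start, end = exon_map.range_of(exon5_id)
    length = end - start + 1
    if direction in ("FL->D5", "FL->d5"):
        if position < start:
            return position
        if position <= end:
            return UNDEFINED
        return position - length
    if direction in ("D5->FL", "d5->FL"):
        if position < start:
            return position
        return position + length
    raise ValueError(f"unknown direction {direction!r}")
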