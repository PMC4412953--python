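"""Grid-based cleft detection, mouth counting and per-exon tabulation.

Pockets are found with a protein–solvent–protein (PSP) scan in the spirit
of LIGSITE: the structure is rasterised onto a cubic grid (atoms occupy
their van der Waals radius plus a probe radius), and each solvent voxel is
scanned along 7 directions (3 axes + 4 cube diagonals).  A voxel enclosed
by protein on both sides in at least ``psp_threshold`` directions is a
pocket candidate; candidates are clustered by 26-connectivity and small
clusters dropped.  A pocket's "mouths" — its openings to bulk solvent —
are the connected patches of pocket voxels adjacent to the solvent
component that touches the bounding box: a fully enclosed cavity has 0
mouths, a cup 1, an open tube 2 (the openness distinction between the
tafazzin and G3PAT substrate clefts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import ExonMap, Structure
from .surface_core import DEFAULT_RADIUS, VDW_RADII

__all__ = [
    "Pocket",
    "ExonTabulation",
    "detect_pockets",
    "count_mouths",
    "cleft_residues",
    "tabulate_by_exon",
]

_SCAN_DIRECTIONS = np.array(
    [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1)],
    dtype=int,
)
_CONN26 = np.ones((3, 3, 3), dtype=bool)
MAX_GRID_VOXELS = 40_000_000


@dataclass
class Pocket:
    """One detected cleft: grid points, volume and (lazily) its mouths."""

    spacing: float
    points: np.ndarray                  # (k, 3) Å coordinates of pocket voxels
    volume: float                       # k * spacing**3, Å³
    mouth_count: int = -1               # -1 until count_mouths has run
    lining_residues: set = field(default_factory=set)
    # grid context needed for mouth counting
    _indices: np.ndarray | None = None  # (k, 3) integer voxel indices
    _occupancy: np.ndarray | None = None
    _origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (len(self.points) > 0) != (self.volume > 0):
            raise ValueError("volume must be positive iff the pocket has points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ExonTabulation:
    """Cleft residues per exon with percentage fractions (one decimal)."""

    rows: list[tuple[str, int, float]]
    total: int
    unassigned: list = field(default_factory=list)

    def as_dict(self) -> dict[str, int]:
        return {exon: count for exon, count, _ in self.rows}


def _shift(mask: np.ndarray, d: np.ndarray) -> np.ndarray:
    """mask translated by -d (out[v] = mask[v + d]), False outside."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, step in enumerate(d):
        if step > 0:
            src[ax] = slice(step, None)
            dst[ax] = slice(None, -step)
        elif step < 0:
            src[ax] = slice(None, step)
            dst[ax] = slice(-step, None)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _protein_beyond(occ: np.ndarray, d: np.ndarray) -> np.ndarray:
    """True where a protein voxel exists strictly along +d from the voxel."""
    reach = np.zeros_like(occ)
    steps = max(
        occ.shape[ax] for ax in range(3) if d[ax] != 0
    )
    for _ in range(steps):
        new = _shift(occ | reach, d)
        if np.array_equal(new, reach):
            break
        reach = new
    return reach


def _rasterize(
    structure: Structure, spacing: float, probe_radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean occupancy grid (atoms inflated by probe) and its origin."""
    coords, _ = structure.heavy_atom_table()
    if coords.shape[0] == 0:
        raise ValueError("structure has no heavy atoms")
    elements = [
        a.element for r in structure.residues for a in r.atoms if a.element.upper() != "H"
    ]
    radii = np.array(
        [VDW_RADII.get(e.upper(), DEFAULT_RADIUS) for e in elements]
    ) + probe_radius
    margin = radii.max() + 2 * spacing
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    if int(np.prod(shape)) > MAX_GRID_VOXELS:
        raise MemoryError(
            f"grid of {np.prod(shape)} voxels exceeds the configured bound; "
            f"increase grid spacing (currently {spacing} Å)"
        )
    occ = np.zeros(tuple(shape), dtype=bool)
    for c, r in zip(coords, radii):
        ilo = np.maximum(np.floor((c - r - lo) / spacing).astype(int), 0)
        ihi = np.minimum(np.ceil((c + r - lo) / spacing).astype(int) + 1, shape)
        ax = [np.arange(ilo[k], ihi[k]) * spacing + lo[k] for k in range(3)]
        dx2 = (ax[0] - c[0])[:, None, None] ** 2
        dy2 = (ax[1] - c[1])[None, :, None] ** 2
        dz2 = (ax[2] - c[2])[None, None, :] ** 2
        occ[ilo[0]:ihi[0], ilo[1]:ihi[1], ilo[2]:ihi[2]] |= (
            dx2 + dy2 + dz2 <= r * r
        )
    return occ, lo


def detect_pockets(
    structure: Structure,
    grid_spacing: float = 1.0,
    psp_threshold: int = 4,
    min_points: int = 30,
    probe_radius: float = 1.4,
) -> list[Pocket]:
    """Detect clefts by the 7-direction protein–solvent–protein scan.

    Returns pockets sorted by volume, largest first.  Decreasing
    ``psp_threshold`` can only grow the candidate voxel set.
    """
    occ, origin = _rasterize(structure, grid_spacing, probe_radius)
    solvent = ~occ
    psp_count = np.zeros(occ.shape, dtype=np.int8)
    for d in _SCAN_DIRECTIONS:
        before = _protein_beyond(occ, -d)
        after = _protein_beyond(occ, d)
        psp_count += (before & after).astype(np.int8)
    candidate = solvent & (psp_count >= psp_threshold)
    labels, n_labels = ndimage.label(candidate, structure=_CONN26)
    pockets: list[Pocket] = []
    for lab in range(1, n_labels + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_points:
            continue
        points = origin + idx * grid_spacing
        pockets.append(
            Pocket(
                spacing=grid_spacing,
                points=points,
                volume=len(idx) * grid_spacing ** 3,
                _indices=idx,
                _occupancy=occ,
                _origin=origin,
            )
        )
    pockets.sort(key=lambda p: p.volume, reverse=True)
    return pockets


def count_mouths(pocket: Pocket) -> int:
    """Number of distinct openings of a pocket to bulk solvent.

    Bulk solvent is the solvent component (pocket voxels excluded) that
    touches the grid bounding box; each 26-connected patch of pocket
    voxels adjacent to bulk is one mouth.
    """
    if pocket._occupancy is None or pocket._indices is None:
        raise ValueError("pocket lacks grid context; obtain it from detect_pockets")
    occ = pocket._occupancy
    pocket_mask = np.zeros(occ.shape, dtype=bool)
    pocket_mask[tuple(pocket._indices.T)] = True
    outside = (~occ) & (~pocket_mask)
    labels, n_labels = ndimage.label(outside, structure=_CONN26)
    if n_labels == 0:
        pocket.mouth_count = 0
        return 0
    border = np.zeros(occ.shape, dtype=bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    bulk_ids = set(np.unique(labels[border & outside])) - {0}
    bulk = np.isin(labels, sorted(bulk_ids))
    near_bulk = ndimage.binary_dilation(bulk, structure=_CONN26)
    mouth_voxels = pocket_mask & near_bulk
    _, n_mouths = ndimage.label(mouth_voxels, structure=_CONN26)
    pocket.mouth_count = int(n_mouths)
    return pocket.mouth_count


def cleft_residues(
    pocket: Pocket, structure: Structure, contact_distance: float = 4.0
) -> set:
    """Residues with any heavy atom within ``contact_distance`` of a pocket voxel."""
    if len(pocket) == 0 or contact_distance <= 0:
        return set()
    coords, owner = structure.heavy_atom_table()
    tree = cKDTree(pocket.points)
    dists, _ = tree.query(coords, k=1)
    keys = [r.key for r in structure.residues]
    lining = {keys[owner[i]] for i in np.nonzero(dists <= contact_distance)[0]}
    pocket.lining_residues = lining
    return lining


def tabulate_by_exon(
    residue_positions, exon_map: ExonMap
) -> ExonTabulation:
    """Count cleft residues per exon with one-decimal percentage fractions.

    ``residue_positions`` may be residue keys ``(chain, number, icode)``
    or plain integer residue numbers (full-length numbering).  Residues
    outside every exon range land in an ``unassigned`` list.
    """
    numbers = [
        p[1] if isinstance(p, tuple) else int(p) for p in residue_positions
    ]
    counts: dict[str, int] = {eid: 0 for eid in exon_map.exon_ids()}
    unassigned = []
    for num in numbers:
        exon = exon_map.exon_of(num)
        if exon is None:
            unassigned.append(num)
        else:
            counts[exon] += 1
    total = sum(counts.values())
    rows = [
        (eid, c, round(100.0 * c / total, 1) if total else 0.0)
        for eid, c in counts.items()
        if c > 0
    ]
    return ExonTabulation(rows=rows, total=total, unassigned=sorted(unassigned))
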