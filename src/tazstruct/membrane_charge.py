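"""Net charge, basic surface patches, hydropathy TM segments and disorder.

Membrane association of the tafazzin acyltransferase domain is assessed
through two sequence/structure surrogates: the net formal charge of the
domain and clusters of solvent-exposed basic residues (positive patches)
on the model surface.  Transmembrane segments are found with a windowed
Kyte–Doolittle hydropathy scan, and intrinsically unstructured segments
with the charge–hydropathy boundary classifier (a window is disordered
when its mean absolute net charge exceeds the linear boundary
``2.785 * <H> - 1.151`` in normalised hydropathy ``<H>``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core_io import SequenceRecord, Structure
from .surface_core import AccessibilityProfile

__all__ = [
    "ChargeScheme",
    "PatchSet",
    "SegmentAnnotation",
    "KYTE_DOOLITTLE",
    "net_formal_charge",
    "basic_patch",
    "tm_segments",
    "disorder_segments",
]

#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Side-chain terminal nitrogen atom names used for patch geometry.
TERMINAL_N = {"K": ("NZ",), "R": ("NH1", "NH2"), "H": ("ND1", "NE2")}


@dataclass(frozen=True)
class ChargeScheme:
    """Formal per-residue charges plus coarse charge classes.

    The sum scheme drives net-charge totals (His contributes 0); the class
    scheme drives electrostatic mutation flags, where His forms its own
    class so that substitutions into or out of histidine count as an
    electrostatic change without His carrying formal charge.
    """

    charges: tuple = (("K", 1.0), ("R", 1.0), ("D", -1.0), ("E", -1.0))

    def charge_of(self, aa: str) -> float:
        return dict(self.charges).get(aa, 0.0)

    def class_of(self, aa: str) -> str:
        if aa in ("D", "E"):
            return "negative"
        if aa in ("K", "R"):
            return "positive"
        if aa == "H":
            return "histidine"
        return "neutral"


DEFAULT_SCHEME = ChargeScheme()


@dataclass
class PatchSet:
    """Clusters of exposed basic residues with their centroid coordinates."""

    patches: list[tuple[set, np.ndarray]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)

    def all_members(self) -> set:
        out: set = set()
        for members, _ in self.patches:
            out |= members
        return out

    def nearest_centroid_distance(self, coord: np.ndarray) -> float:
        if not self.patches:
            return np.inf
        return min(
            float(np.linalg.norm(np.asarray(coord) - centroid))
            for _, centroid in self.patches
        )


@dataclass
class SegmentAnnotation:
    """Labelled residue ranges (inclusive, biological numbering)."""

    segments: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end, _ in self.segments:
            if start > end:
                raise ValueError(f"segment start {start} > end {end}")
        by_label: dict[str, list[tuple[int, int]]] = {}
        for s, e, lab in self.segments:
            by_label.setdefault(lab, []).append((s, e))
        for lab, ranges in by_label.items():
            ranges.sort()
            for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping {lab} segments")

    def __len__(self) -> int:
        return len(self.segments)

    def covering(self, position: int, label: str | None = None):
        for s, e, lab in self.segments:
            if s <= position <= e and (label is None or lab == label):
                return (s, e, lab)
        return None


def net_formal_charge(
    seq_or_structure, scheme: ChargeScheme = DEFAULT_SCHEME
) -> float:
    """Sum of per-residue formal charges (K/R +1, D/E −1, His 0 by default)."""
    if isinstance(seq_or_structure, Structure):
        seq = seq_or_structure.sequence()
    elif isinstance(seq_or_structure, SequenceRecord):
        seq = seq_or_structure.seq
    else:
        seq = str(seq_or_structure)
    if not seq:
        raise ValueError("empty sequence")
    return float(sum(scheme.charge_of(aa) for aa in seq))


def basic_patch(
    structure: Structure,
    profile: AccessibilityProfile,
    link_distance: float = 15.0,
    min_size: int = 3,
    include_his: bool = False,
) -> PatchSet:
    """Single-linkage clusters of solvent-exposed basic residues.

    Exposed (non-buried) Lys/Arg residues are linked when their side-chain
    terminal nitrogens come within ``link_distance`` Å; clusters of at
    least ``min_size`` members are reported with the centroid of their
    terminal-N coordinates.
    """
    buried = profile.buried_keys()
    basic_aas = set("KR") | ({"H"} if include_his else set())
    members: list = []        # residue keys
    n_coords: list[np.ndarray] = []   # (k_i, 3) terminal-N coords per residue
    for res in structure.residues:
        if res.aa not in basic_aas or res.key in buried:
            continue
        pts = [res.atom(n).coord for n in TERMINAL_N[res.aa] if res.atom(n)]
        if not pts:
            continue
        members.append(res.key)
        n_coords.append(np.array(pts))
    if not members:
        return PatchSet()
    # single linkage on minimum terminal-N pair distance
    n = len(members)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if cdist(n_coords[i], n_coords[j]).min() <= link_distance:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    patches = []
    for idxs in clusters.values():
        if len(idxs) < min_size:
            continue
        keys = {members[i] for i in idxs}
        centroid = np.vstack([n_coords[i] for i in idxs]).mean(axis=0)
        patches.append((keys, centroid))
    patches.sort(key=lambda p: -len(p[0]))
    return PatchSet(patches=patches)


def _window_means(values: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def _center_runs(
    flags: np.ndarray, seq: SequenceRecord, window: int, label: str, merge_gap: int = 0
) -> SegmentAnnotation:
    """Turn qualifying window flags into segments over window-center numbering."""
    half = window // 2
    centers = [i + half for i, f in enumerate(flags) if f]
    if not centers:
        return SegmentAnnotation()
    runs: list[list[int]] = [[centers[0], centers[0]]]
    for c in centers[1:]:
        if c - runs[-1][1] <= 1 + merge_gap:
            runs[-1][1] = c
        else:
            runs.append([c, c])
    segments = [
        (seq.number_of(s), seq.number_of(e), label) for s, e in runs
    ]
    return SegmentAnnotation(segments=segments)


def tm_segments(
    seq: SequenceRecord, window: int = 19, threshold: float = 1.6
) -> SegmentAnnotation:
    """Putative transmembrane helices from windowed mean hydropathy.

    Runs of window centers whose Kyte–Doolittle window mean reaches
    ``threshold`` are reported as TM segments; runs separated by at most
    3 residues are merged.
    """
    if len(seq) < window:
        raise ValueError(f"sequence shorter than window ({len(seq)} < {window})")
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq.seq])
    means = _window_means(values, window)
    return _center_runs(means >= threshold, seq, window, "TM", merge_gap=3)


def ch_boundary(mean_hydropathy: float) -> float:
    """Charge–hydropathy boundary: the mean absolute net charge above which
    a window of the given normalised mean hydropathy is called disordered."""
    return 2.785 * mean_hydropathy - 1.151


def is_disordered_window(mean_charge: float, mean_hydropathy: float) -> bool:
    """Strictly above the boundary: equality classifies as ordered."""
    return mean_charge > ch_boundary(mean_hydropathy)


def disorder_segments(seq: SequenceRecord, window: int = 21) -> SegmentAnnotation:
    """Intrinsically unstructured segments by the charge–hydropathy boundary.

    A window is disordered iff its mean absolute net charge strictly
    exceeds ``2.785 * <H> - 1.151``, where ``<H>`` is the window-mean
    Kyte–Doolittle hydropathy rescaled to [0, 1]; boundary equality
    classifies as ordered.
    """
    if len(seq) < window:
        raise ValueError(f"sequence shorter than window ({len(seq)} < {window})")
    hyd = np.array([(KYTE_DOOLITTLE.get(aa, 0.0) + 4.5) / 9.0 for aa in seq.seq])
    chg = np.array([DEFAULT_SCHEME.charge_of(aa) for aa in seq.seq])
    mean_h = _window_means(hyd, window)
    mean_r = np.abs(_window_means(chg, window))
    flags = np.array(
        [is_disordered_window(r, h) for r, h in zip(mean_r, mean_h)]
    )
    return _center_runs(flags, seq, window, "disordered")
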