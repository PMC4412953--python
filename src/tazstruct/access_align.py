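"""Pairwise global alignment with accessibility-dependent gap penalties.

Template-based modelling of remote homologs (< 20% identity) fails when
indels are placed inside the template's packed interior.  The aligner here
makes gaps cheap where the template is solvent-exposed and expensive where
it is buried: the per-position gap-open penalty is a linear function of
the template residue's relative solvent accessibility.  With a uniform
profile the method reduces exactly to textbook global affine-gap (Gotoh)
alignment, which is how it is validated.

Scoring convention: a gap run of length L opened at template position j
costs ``open(j) + extend * (L - 1)``; substitution scores come from a
standard matrix (BLOSUM62 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .core_io import SequenceRecord
from .surface_core import AccessibilityProfile, CoreSet, HYDROPHOBIC_SET

__all__ = [
    "GapProfile",
    "PairAlignment",
    "AlignmentStats",
    "gap_profile",
    "uniform_gap_profile",
    "align_pair",
    "alignment_stats",
    "core_conservation",
    "load_matrix",
]

NEG_INF = -1e30


def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


@dataclass
class GapProfile:
    """Per-template-position gap-open penalties plus one extend penalty."""

    open_penalties: np.ndarray   # length n, open_penalties[j-1] for template pos j
    extend: float
    g_max: float
    g_min: float

    def __post_init__(self) -> None:
        self.open_penalties = np.asarray(self.open_penalties, dtype=float)
        if not (self.g_max >= self.g_min > self.extend >= 0):
            raise ValueError(
                f"require g_max >= g_min > extend >= 0, got "
                f"g_max={self.g_max}, g_min={self.g_min}, extend={self.extend}"
            )
        lo, hi = self.open_penalties.min(), self.open_penalties.max()
        if lo < self.g_min - 1e-9 or hi > self.g_max + 1e-9:
            raise ValueError("open penalties fall outside [g_min, g_max]")

    def __len__(self) -> int:
        return len(self.open_penalties)


def gap_profile(
    template_profile: AccessibilityProfile | Sequence[float],
    g_max: float = 12.0,
    g_min: float = 4.0,
    extend: float = 1.0,
) -> GapProfile:
    """Linear accessibility-to-penalty map: exposed positions gap cheapest.

    ``open(i) = g_min + (g_max - g_min) * (1 - min(rel_acc_i, 1))`` —
    a fully exposed template residue costs ``g_min`` to gap, a fully
    buried one ``g_max``.
    """
    if isinstance(template_profile, AccessibilityProfile):
        rel = template_profile.relative
    else:
        rel = np.asarray(template_profile, dtype=float)
    if rel.size == 0:
        raise ValueError("template accessibility profile is empty")
    opens = g_min + (g_max - g_min) * (1.0 - np.minimum(rel, 1.0))
    return GapProfile(open_penalties=opens, extend=extend, g_max=g_max, g_min=g_min)


def uniform_gap_profile(n: int, open_penalty: float = 10.0, extend: float = 1.0) -> GapProfile:
    """Constant-penalty profile: the plain affine-gap special case."""
    return GapProfile(
        open_penalties=np.full(n, float(open_penalty)),
        extend=extend,
        g_max=open_penalty,
        g_min=open_penalty,
    )


@dataclass
class PairAlignment:
    """A global target/template alignment as a list of index columns.

    Each column is ``(i, j)`` of 0-based indices into target and template
    sequences, with ``None`` marking a gap on that side.
    """

    target: SequenceRecord
    template: SequenceRecord
    columns: list[tuple[Optional[int], Optional[int]]]
    score: float
    matrix_id: str = "BLOSUM62"

    def __post_init__(self) -> None:
        ti = [c[0] for c in self.columns if c[0] is not None]
        tj = [c[1] for c in self.columns if c[1] is not None]
        if ti != sorted(set(ti)) or tj != sorted(set(tj)):
            raise ValueError("alignment indices must be strictly increasing")
        if any(c == (None, None) for c in self.columns):
            raise ValueError("column with gaps on both sides")

    def n_gap_columns(self) -> int:
        return sum(1 for c in self.columns if c[0] is None or c[1] is None)

    def template_to_target(self) -> dict[int, Optional[int]]:
        """Map template biological number -> target biological number (None for gaps)."""
        out: dict[int, Optional[int]] = {}
        for i, j in self.columns:
            if j is not None:
                out[self.template.number_of(j)] = (
                    self.target.number_of(i) if i is not None else None
                )
        return out

    def pretty(self, width: int = 60) -> str:
        top = "".join(self.target.seq[i] if i is not None else "-" for i, _ in self.columns)
        bot = "".join(self.template.seq[j] if j is not None else "-" for _, j in self.columns)
        lines = []
        for k in range(0, len(top), width):
            lines.append(top[k:k + width])
            lines.append(bot[k:k + width])
            lines.append("")
        return "\n".join(lines).rstrip()


@dataclass
class AlignmentStats:
    percent_identity: float
    n_aligned: int
    n_identical: int
    n_similar: int


def _score_lookup(matrix, a: str, b: str) -> float:
    try:
        return float(matrix[a, b])
    except (KeyError, IndexError) as exc:
        raise KeyError(f"substitution matrix lacks pair ({a!r}, {b!r})") from exc


def align_pair(
    target: SequenceRecord,
    template: SequenceRecord,
    profile: GapProfile,
    matrix=None,
) -> PairAlignment:
    """Optimal global alignment under position-specific template gap opens.

    Gotoh dynamic programming over three states (match, gap-in-template,
    gap-in-target).  Deleting template residue ``j`` opens at cost
    ``open(j)``; inserting target residues between template positions
    ``j`` and ``j+1`` opens at the penalty of the next template position
    (the position the gap pushes against), terminal insertions at the
    last position's penalty.  Terminal gaps are penalized like internal
    ones.  Traceback ties prefer diagonal over up (target-consuming) over
    left (template-consuming), making the output deterministic.
    """
    if matrix is None:
        matrix = load_matrix()
    x, y = target.seq, template.seq
    m, n = len(x), len(y)
    if len(profile) != n:
        raise ValueError(f"gap profile length {len(profile)} != template length {n}")
    opens = profile.open_penalties
    ext = profile.extend

    def open_ins(j: int) -> float:
        # insertion (gap in template) sitting after template position j (0=before start)
        return opens[j] if j < n else opens[n - 1]

    M = np.full((m + 1, n + 1), NEG_INF)
    Ix = np.full((m + 1, n + 1), NEG_INF)   # ends consuming target (gap in template)
    Iy = np.full((m + 1, n + 1), NEG_INF)   # ends consuming template (gap in target)
    # pointers: state entered from (0=M, 1=Ix, 2=Iy), -1 = origin
    Pm = np.full((m + 1, n + 1), -1, dtype=np.int8)
    Px = np.full((m + 1, n + 1), -1, dtype=np.int8)
    Py = np.full((m + 1, n + 1), -1, dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, m + 1):
        if i == 1:
            Ix[i, 0] = -open_ins(0)
            Px[i, 0] = 0
        else:
            Ix[i, 0] = Ix[i - 1, 0] - ext
            Px[i, 0] = 1
    for j in range(1, n + 1):
        if j == 1:
            Iy[0, j] = -opens[0]
            Py[0, j] = 0
        else:
            Iy[0, j] = Iy[0, j - 1] - ext
            Py[0, j] = 2

    for i in range(1, m + 1):
        xi = x[i - 1]
        row_scores = [_score_lookup(matrix, xi, y[j]) for j in range(n)]
        for j in range(1, n + 1):
            # match state: tie-break M > Ix > Iy
            cands = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            k = int(np.argmax(cands))
            M[i, j] = row_scores[j - 1] + cands[k]
            Pm[i, j] = k
            # gap in template (consume x_i)
            oi = open_ins(j)
            cands = (M[i - 1, j] - oi, Ix[i - 1, j] - ext, Iy[i - 1, j] - oi)
            k = int(np.argmax(cands))
            Ix[i, j] = cands[k]
            Px[i, j] = k
            # gap in target (consume y_j, deleting template residue j)
            oj = opens[j - 1]
            cands = (M[i, j - 1] - oj, Ix[i, j - 1] - oj, Iy[i, j - 1] - ext)
            k = int(np.argmax(cands))
            Iy[i, j] = cands[k]
            Py[i, j] = k

    finals = (M[m, n], Ix[m, n], Iy[m, n])
    state = int(np.argmax(finals))
    score = float(finals[state])

    columns: list[tuple[Optional[int], Optional[int]]] = []
    i, j = m, n
    while i > 0 or j > 0:
        if state == 0:
            prev = int(Pm[i, j])
            columns.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == 1:
            prev = int(Px[i, j])
            columns.append((i - 1, None))
            i -= 1
        else:
            prev = int(Py[i, j])
            columns.append((None, j - 1))
            j -= 1
        state = prev
    columns.reverse()
    return PairAlignment(
        target=target,
        template=template,
        columns=columns,
        score=score,
        matrix_id=getattr(matrix, "name", "custom") or "custom",
    )


def alignment_stats(
    aln: PairAlignment,
    target_range: Optional[tuple[int, int]] = None,
    template_range: Optional[tuple[int, int]] = None,
    matrix=None,
) -> AlignmentStats:
    """Percent identity over aligned (both-non-gap) columns, optionally
    restricted to biological-number ranges on either sequence.

    Similar pairs are those with a positive substitution score.
    """
    if matrix is None:
        matrix = load_matrix(aln.matrix_id if aln.matrix_id != "custom" else "BLOSUM62")
    n_aligned = n_ident = n_sim = 0
    for i, j in aln.columns:
        if i is None or j is None:
            continue
        pos_t = aln.target.number_of(i)
        pos_p = aln.template.number_of(j)
        if target_range and not (target_range[0] <= pos_t <= target_range[1]):
            continue
        if template_range and not (template_range[0] <= pos_p <= template_range[1]):
            continue
        a, b = aln.target.seq[i], aln.template.seq[j]
        n_aligned += 1
        if a == b:
            n_ident += 1
        if _score_lookup(matrix, a, b) > 0:
            n_sim += 1
    if n_aligned == 0:
        raise ValueError("no aligned columns in the requested region")
    return AlignmentStats(
        percent_identity=100.0 * n_ident / n_aligned,
        n_aligned=n_aligned,
        n_identical=n_ident,
        n_similar=n_sim,
    )


def core_conservation(
    aln: PairAlignment,
    template_core: CoreSet | set[int],
    hydrophobic_set: frozenset[str] | set[str] = HYDROPHOBIC_SET,
) -> tuple[int, int]:
    """Count template structural-core positions aligned to hydrophobic
    target residues.

    Returns ``(n_core, n_hydrophobic_aligned)``; core positions aligned
    to a gap contribute to ``n_core`` only.  ``template_core`` may be a
    :class:`CoreSet` (residue keys carry biological numbers) or a plain
    set of template residue numbers.
    """
    if isinstance(template_core, CoreSet):
        core_numbers = {key[1] for key in template_core.all_residues()}
    else:
        core_numbers = set(template_core)
    mapping = aln.template_to_target()
    target_aa = {
        aln.target.number_of(i): aln.target.seq[i] for i in range(len(aln.target.seq))
    }
    n_core = n_hydro = 0
    for num in core_numbers:
        if num not in mapping:
            continue  # core residue outside the aligned template range
        n_core += 1
        partner = mapping[num]
        if partner is not None and target_aa.get(partner) in hydrophobic_set:
            n_hydro += 1
    return n_core, n_hydro
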