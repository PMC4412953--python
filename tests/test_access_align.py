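import numpy as np
import pytest
from Bio import Align

from tazstruct import (
    SequenceRecord,
    align_pair,
    alignment_stats,
    core_conservation,
    gap_profile,
    uniform_gap_profile,
)
from tazstruct.access_align import GapProfile, load_matrix

AAS = list("ACDEFGHIKLMNPQRSTVWY")
MATRIX = load_matrix()


def brute_force_score(x, y, opens, extend):
    """Independent oracle: enumerate every global alignment recursively."""
    best = [-np.inf]

    def rec(i, j, score, state):
        if i == len(x) and j == len(y):
            best[0] = max(best[0], score)
            return
        if i < len(x) and j < len(y):
            rec(i + 1, j + 1, score + MATRIX[x[i], y[j]], "M")
        if i < len(x):
            o = opens[j] if j < len(y) else opens[-1]
            rec(i + 1, j, score - (extend if state == "X" else o), "X")
        if j < len(y):
            rec(i, j + 1, score - (extend if state == "Y" else opens[j]), "Y")

    rec(0, 0, 0.0, "start")
    return best[0]


def biopython_affine_score(x, y, open_penalty, extend):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = MATRIX
    aligner.open_gap_score = -open_penalty
    aligner.extend_gap_score = -extend
    return aligner.score(x, y)


def random_seq(rng, lo, hi):
    return "".join(rng.choice(AAS, rng.integers(lo, hi + 1)))


class TestGapProfile:
    @pytest.mark.parametrize(
        "rel,expected", [(1.0, 4.0), (0.0, 12.0), (0.5, 8.0), (1.7, 4.0)]
    )
    def test_linear_in_accessibility(self, rel, expected):
        gp = gap_profile([rel], g_max=12, g_min=4, extend=1)
        assert gp.open_penalties[0] == pytest.approx(expected)

    def test_parameter_ordering_enforced(self):
        with pytest.raises(ValueError):
            gap_profile([0.5], g_max=4, g_min=12, extend=1)
        with pytest.raises(ValueError):
            gap_profile([0.5], g_max=12, g_min=1, extend=2)


class TestAlignPair:
    def test_identical_sequences_align_without_gaps(self):
        seq = SequenceRecord(id="s", seq="MKTAYIAKQR")
        gp = uniform_gap_profile(len(seq.seq))
        aln = align_pair(seq, SequenceRecord(id="t", seq=seq.seq), gp)
        assert aln.n_gap_columns() == 0
        assert alignment_stats(aln).percent_identity == 100.0

    def test_position_specific_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            x, y = random_seq(rng, 1, 6), random_seq(rng, 1, 6)
            opens = rng.uniform(4, 12, size=len(y))
            gp = GapProfile(open_penalties=opens, extend=1.0, g_max=12, g_min=4)
            aln = align_pair(
                SequenceRecord(id="x", seq=x), SequenceRecord(id="y", seq=y), gp
            )
            assert aln.score == pytest.approx(
                brute_force_score(x, y, list(opens), 1.0)
            )

    def test_uniform_profile_matches_textbook_affine(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            x, y = random_seq(rng, 5, 30), random_seq(rng, 5, 30)
            gp = uniform_gap_profile(len(y), 10.0, 1.0)
            aln = align_pair(
                SequenceRecord(id="x", seq=x), SequenceRecord(id="y", seq=y), gp
            )
            assert aln.score == pytest.approx(biopython_affine_score(x, y, 10.0, 1.0))

    def test_score_symmetric_under_swap_with_uniform_profile(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x, y = random_seq(rng, 8, 20), random_seq(rng, 8, 20)
            a = align_pair(
                SequenceRecord(id="x", seq=x), SequenceRecord(id="y", seq=y),
                uniform_gap_profile(len(y)),
            )
            b = align_pair(
                SequenceRecord(id="y", seq=y), SequenceRecord(id="x", seq=x),
                uniform_gap_profile(len(x)),
            )
            assert a.score == pytest.approx(b.score)

    def test_raising_open_penalty_never_adds_gaps(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            x, y = random_seq(rng, 10, 25), random_seq(rng, 10, 25)
            gaps = [
                align_pair(
                    SequenceRecord(id="x", seq=x), SequenceRecord(id="y", seq=y),
                    uniform_gap_profile(len(y), open_penalty, 1.0),
                ).n_gap_columns()
                for open_penalty in (4.0, 8.0, 14.0)
            ]
            assert gaps[0] >= gaps[1] >= gaps[2]

    def test_exposed_template_region_attracts_gaps(self):
        # identical scoring context, but one template half exposed:
        # an unalignable target insertion should be placed there
        target = SequenceRecord(id="t", seq="MKTAYIWWWWIAKQRQ")
        template = SequenceRecord(id="p", seq="MKTAYIIAKQRQ")
        buried_first = gap_profile([0.0] * 6 + [1.0] * 6, g_max=14, g_min=2)
        aln = align_pair(target, template, buried_first)
        insert_cols = [k for k, (i, j) in enumerate(aln.columns) if j is None]
        assert insert_cols, "expected an insertion"
        # template position after the insertion must be in the exposed half
        nxt = next(
            j for i, j in aln.columns[insert_cols[-1]:] if j is not None
        )
        assert nxt >= 6


class TestAlignmentStats:
    def test_half_identity_without_gaps(self):
        a = SequenceRecord(id="a", seq="AAAA")
        b = SequenceRecord(id="b", seq="AATT")
        aln = align_pair(a, b, uniform_gap_profile(4))
        assert alignment_stats(aln).percent_identity == pytest.approx(50.0)

    def test_region_restriction(self):
        a = SequenceRecord(id="a", seq="AAAATTTT")
        b = SequenceRecord(id="b", seq="AAAAGGGG")
        aln = align_pair(a, b, uniform_gap_profile(8))
        full = alignment_stats(aln)
        head = alignment_stats(aln, target_range=(1, 4))
        assert full.percent_identity == pytest.approx(50.0)
        assert head.percent_identity == pytest.approx(100.0)

    def test_empty_region_raises(self):
        a = SequenceRecord(id="a", seq="AAAA")
        aln = align_pair(a, a, uniform_gap_profile(4))
        with pytest.raises(ValueError):
            alignment_stats(aln, target_range=(100, 200))


class TestCoreConservation:
    def test_all_core_aligned_to_leucine(self):
        target = SequenceRecord(id="t", seq="LLLL")
        template = SequenceRecord(id="p", seq="VVVV")
        aln = align_pair(target, template, uniform_gap_profile(4))
        n_core, n_hydro = core_conservation(aln, {1, 2, 3, 4})
        assert (n_core, n_hydro) == (4, 4)

    def test_gap_aligned_core_counts_in_denominator_only(self):
        target = SequenceRecord(id="t", seq="LLLL")
        template = SequenceRecord(id="p", seq="LLLLVVVV")
        aln = align_pair(target, template, uniform_gap_profile(8, 4.0, 1.0))
        n_core, n_hydro = core_conservation(aln, {5, 6, 7, 8})
        assert n_core == 4
        assert n_hydro == 0

    def test_polar_partners_not_counted(self):
        target = SequenceRecord(id="t", seq="SSSS")
        template = SequenceRecord(id="p", seq="LLLL")
        aln = align_pair(target, template, uniform_gap_profile(4))
        assert core_conservation(aln, {1, 2, 3, 4}) == (4, 0)
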