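"""Length-variant heterozygote deconvolution from superposed traces."""

from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploweb.deconvolution import (
    DeconvolutionError,
    MixedTrace,
    NoLengthVariance,
    Orientation,
    deconvolve,
    read_trace,
    score_shifts,
    simulate_superposition,
    write_trace,
)
from haploweb.seq_core import Sequence


def trace(sets, orientation=Orientation.FORWARD, tid="t"):
    return MixedTrace(
        id=tid,
        positions=tuple(frozenset(s) for s in sets),
        orientation=orientation,
    )


def enumerate_consistent_pairs(fwd, rev, delta):
    """Exhaustive oracle: all (long, short) pairs satisfying both traces."""
    L = len(fwd)
    LY = L - delta
    solutions = set()
    choices = [sorted(s) for s in fwd.positions]
    # enumerate X over forward sets, derive Y from forward, verify reverse
    for xs in product(*choices):
        x = "".join(xs)
        ok = True
        y = []
        for i in range(LY):
            f = set(fwd.positions[i])
            if x[i] not in f:
                ok = False
                break
            rest = f - {x[i]}
            y.append(next(iter(rest)) if rest else x[i])
        if not ok:
            continue
        y = "".join(y)
        for i in range(L):
            fset = {x[i]} | ({y[i]} if i < LY else set())
            rset = {x[i]} | ({y[i - delta]} if i >= delta else set())
            if fset != set(fwd.positions[i]) or rset != set(rev.positions[i]):
                ok = False
                break
        if ok:
            solutions.add((x, y))
    return solutions


class TestSimulateSuperposition:
    def test_known_pair_produces_expected_traces(self):
        f, r = simulate_superposition(
            Sequence("x", "ACGTACGT"), Sequence("y", "ACGACGT")
        )
        assert [sorted(s) for s in f.positions] == [
            ["A"], ["C"], ["G"], ["A", "T"], ["A", "C"], ["C", "G"],
            ["G", "T"], ["T"],
        ]
        assert [sorted(s) for s in r.positions] == [
            ["A"], ["A", "C"], ["C", "G"], ["G", "T"], ["A"], ["C"],
            ["G"], ["T"],
        ]

    def test_terminal_extra_base_gives_singleton_prefix(self):
        f, _ = simulate_superposition(
            Sequence("x", "ACGTT"), Sequence("y", "ACGT")
        )
        assert all(len(s) == 1 for s in f.positions)

    def test_equal_lengths_rejected(self):
        with pytest.raises(ValueError, match="phasing"):
            simulate_superposition(Sequence("x", "ACGT"), Sequence("y", "TGCA"))


class TestScoreShifts:
    def test_true_shift_is_unique_top_scorer(self):
        f, r = simulate_superposition(
            Sequence("x", "ACGTACGT"), Sequence("y", "ACGACGT")
        )
        scores = score_shifts(f, r, max_delta=3)
        assert scores[0].delta == 1
        assert scores[0].score == 8
        assert scores[0].score > scores[1].score

    def test_all_singleton_equal_length_reports_no_length_variance(self):
        t = [["A"], ["C"], ["G"], ["T"]]
        with pytest.raises(NoLengthVariance):
            score_shifts(trace(t), trace(t, Orientation.REVERSE), 2)

    def test_incompatible_traces_score_below_trace_length(self):
        # reverse trace from an unrelated pair: no shift explains both
        f, _ = simulate_superposition(
            Sequence("x", "ACGTACGTACGT"), Sequence("y", "ACGACGTACGT")
        )
        _, r = simulate_superposition(
            Sequence("x", "TTGAGCTCAGCT"), Sequence("y", "TGAGCTCAGCT")
        )
        scores = score_shifts(f, r, max_delta=3)
        assert all(s.score < len(f) for s in scores)

    def test_length_mismatch_beyond_max_delta_rejected(self):
        f = trace([["A", "C"]] * 8)
        r = trace([["A", "C"]] * 3, Orientation.REVERSE)
        with pytest.raises(ValueError, match="max_delta"):
            score_shifts(f, r, max_delta=3)


class TestDeconvolve:
    def test_recovers_known_pair_uniquely(self):
        x, y = Sequence("x", "ACGTACGT"), Sequence("y", "ACGACGT")
        f, r = simulate_superposition(x, y)
        oracle = enumerate_consistent_pairs(f, r, 1)
        assert oracle == {("ACGTACGT", "ACGACGT")}
        res = deconvolve(f, r, 1)
        assert res.pair == frozenset({"ACGTACGT", "ACGACGT"})
        assert res.unique

    def test_homozygous_trace_delta_zero(self):
        t = [["A"], ["C"], ["G"], ["T"]]
        res = deconvolve(trace(t), trace(t, Orientation.REVERSE), 0)
        assert res.haplotype_long.residues == "ACGT"
        assert res.haplotype_short.residues == "ACGT"
        assert res.unique

    def test_fully_symmetric_trace_flagged_not_unique(self):
        # double peaks everywhere: the two solutions are mirror images
        t = [["A", "C"]] * 6
        res = deconvolve(trace(t), trace(t, Orientation.REVERSE), 0)
        assert not res.unique
        assert {res.haplotype_long.residues, res.haplotype_short.residues} == {
            "AAAAAA", "CCCCCC",
        }
        # with a genuine length difference the tail would have to be a
        # singleton, so no consistent pair exists
        with pytest.raises(DeconvolutionError):
            deconvolve(trace(t), trace(t, Orientation.REVERSE), 2)
        assert enumerate_consistent_pairs(
            trace(t), trace(t, Orientation.REVERSE), 2
        ) == set()

    def test_contradiction_reports_first_bad_position(self):
        f, r = simulate_superposition(
            Sequence("x", "ACGTACGT"), Sequence("y", "ACGACGT")
        )
        with pytest.raises(DeconvolutionError) as err:
            deconvolve(f, r, 3)  # wrong shift
        assert err.value.position >= 1

    @given(
        x=st.text(alphabet="ACGT", min_size=5, max_size=12),
        delta=st.integers(min_value=1, max_value=3),
        cut=st.integers(min_value=0, max_value=11),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_round_trip_matches_exhaustive_oracle(self, x, delta, cut, data):
        if delta >= len(x):
            return
        cut = min(cut, len(x) - delta)
        y = x[:cut] + x[cut + delta:]
        if len(y) == len(x):
            return
        f, r = simulate_superposition(Sequence("x", x), Sequence("y", y))
        oracle = enumerate_consistent_pairs(f, r, delta)
        assert (x, y) in oracle
        res = deconvolve(f, r, delta)
        if len(oracle) == 1:
            assert res.unique
            assert res.pair == frozenset({x, y})
        else:
            assert not res.unique
            assert (
                res.haplotype_long.residues,
                res.haplotype_short.residues,
            ) in oracle


class TestTraceIO:
    def test_forward_round_trip(self, tmp_path):
        f, _ = simulate_superposition(
            Sequence("ind1", "ACGTACGT"), Sequence("ind1", "ACGACGT")
        )
        p = tmp_path / "f.trace"
        write_trace(f, p)
        assert read_trace(p) == f

    def test_reverse_written_as_read_off_the_machine(self, tmp_path):
        _, r = simulate_superposition(
            Sequence("ind1", "ACGTACGT"), Sequence("ind1", "ACGACGT")
        )
        p = tmp_path / "r.trace"
        write_trace(r, p)
        # on disk the reverse read is 5'->3' on the opposite strand:
        # first data line is the complement of the last stored base-set
        lines = p.read_text().splitlines()
        assert lines[0] == "#id=ind1 orientation=reverse"
        assert lines[1] == "A"  # complement of 3'-terminal T
        assert read_trace(p) == r

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.trace"
        p.write_text("A,C\nG\n")
        with pytest.raises(ValueError, match="header"):
            read_trace(p)
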