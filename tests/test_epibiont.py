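"""Primer/probe matching, clade assignment, mixtures and rarefaction."""

from itertools import combinations

import numpy as np
import pytest

from haploweb.deconvolution import MixedTrace, Orientation
from haploweb.epibiont import (
    AssignmentStatus,
    Oligo,
    OligoRole,
    ReferenceSet,
    assign_clade,
    expected_richness,
    match_oligo,
    packaged_oligos,
    pairwise_identity,
    predict_amplicon,
    rarefaction_curve,
    resolve_mixture_by_reference,
)
from haploweb.seq_core import Marker, Sequence


def seq16(sid, s):
    return Sequence(sid, s, Marker.RRNA_16S)


def revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture(scope="module")
def oligos():
    return packaged_oligos()


class TestMatchOligo:
    def test_probe_vs_competitor_differ_by_one_base(self, oligos):
        # the FISH probe and its competitor are one substitution apart
        g123t, comp = oligos["G123T"], oligos["G123T-C"]
        hits = match_oligo(g123t, seq16("tpl", comp.bases), max_mismatch=2)
        assert hits == [(1, "+", 1)]

    def test_verbatim_site_yields_zero_mismatch_hit(self, oligos):
        fwd = oligos["THIO714F"]
        tpl = seq16("tpl", "ACGT" * 5 + fwd.bases + "ACGT" * 5)
        assert match_oligo(fwd, tpl, 0) == [(21, "+", 0)]

    def test_reverse_primer_scans_opposite_strand(self, oligos):
        rev = oligos["THIO1492R"]
        site = revcomp(rev.bases)
        tpl = seq16("tpl", "AAAA" + site + "CCCC")
        hits = match_oligo(rev, tpl, 0)
        assert hits == [(5, "-", 0)]
        # strand symmetry: the same oligo as a forward primer finds the
        # same site on the reverse-complemented template, coordinates
        # re-mapped by position = L - end + 1
        as_fwd = Oligo("x", rev.bases, OligoRole.FORWARD_PRIMER)
        rc_tpl = seq16("rc", revcomp(tpl.residues))
        (pos, strand, mm), = match_oligo(as_fwd, rc_tpl, 0)
        L, k = len(tpl.residues), len(rev)
        assert (L - (pos + k - 1) + 1, mm) == (5, 0)

    def test_oligo_longer_than_template_gives_empty_list(self, oligos):
        assert match_oligo(oligos["G123T"], seq16("t", "ACGT"), 2) == []

    def test_zero_mismatch_equals_substring_search(self, oligos):
        rng = np.random.default_rng(4)
        tpl = "".join(rng.choice(list("ACGT"), 300))
        probe = oligos["THIO718Fseq"]
        tpl = tpl[:100] + probe.bases + tpl[100:]
        hits = match_oligo(probe, seq16("t", tpl), 0)
        expect = [
            i + 1
            for i in range(len(tpl) - len(probe) + 1)
            if tpl[i:i + len(probe)] == probe.bases
        ]
        assert [h[0] for h in hits] == expect


class TestPredictAmplicon:
    def _template(self, oligos, gap=741):
        fwd, rev = oligos["THIO714F"], oligos["THIO1492R"]
        rng = np.random.default_rng(0)
        mid = "".join(rng.choice(list("ACGT"), gap))
        s = "GGGG" + fwd.bases + mid + revcomp(rev.bases) + "GGGG"
        return seq16("tpl", s), fwd, rev

    def test_planted_sites_give_expected_product_length(self, oligos):
        # 19 + 741 + 18 missing? amplicon = fwd site + gap + rev site
        tpl, fwd, rev = self._template(oligos, gap=778 - len(oligos["THIO714F"]) - len(oligos["THIO1492R"]))
        (amp,) = predict_amplicon(fwd, rev, tpl, 0)
        assert amp.length == 778

    def test_template_without_reverse_site_gives_none(self, oligos):
        fwd, rev = oligos["THIO714F"], oligos["THIO1492R"]
        tpl = seq16("t", "AAAA" + fwd.bases + "AAAA" * 20)
        assert predict_amplicon(fwd, rev, tpl, 0) == []

    def test_reverse_site_upstream_of_forward_is_rejected(self, oligos):
        fwd, rev = oligos["THIO714F"], oligos["THIO1492R"]
        tpl = seq16("t", "AA" + revcomp(rev.bases) + "TTTT" + fwd.bases + "AA")
        assert predict_amplicon(fwd, rev, tpl, 0) == []

    def test_length_equals_coordinate_bookkeeping(self, oligos):
        rng = np.random.default_rng(1)
        for gap in rng.integers(50, 900, size=5):
            tpl, fwd, rev = self._template(oligos, gap=int(gap))
            (amp,) = predict_amplicon(fwd, rev, tpl, 0)
            assert amp.length == amp.end - amp.start + 1
            assert amp.length == len(fwd) + int(gap) + len(rev)


class TestAssignClade:
    def _refs(self, rng, n_clades=3, div=0.10, length=300):
        root = "".join(rng.choice(list("ACGT"), length))
        seqs, clades = [], {}
        names = ["T3", "T4", "mat"][:n_clades]
        for c in names:
            anc = list(root)
            for pos in rng.choice(length, size=int(div * length), replace=False):
                anc[pos] = rng.choice([b for b in "ACGT" if b != anc[pos]])
            rid = f"{c}_ref"
            seqs.append(seq16(rid, "".join(anc)))
            clades[rid] = c
        return ReferenceSet(sequences=seqs, clades=clades)

    def test_identical_query_assigned_at_full_identity(self):
        refs = self._refs(np.random.default_rng(0))
        q = seq16("q", refs.of_clade("T4")[0].residues)
        a = assign_clade(q, refs)
        assert (a.best_clade, a.identity, a.status) == (
            "T4", 100.0, AssignmentStatus.ASSIGNED,
        )

    def test_equidistant_query_is_ambiguous(self):
        r3 = seq16("T3_ref", "AAAAACCCCC")
        r4 = seq16("T4_ref", "AAAAAGGGGG")
        refs = ReferenceSet([r3, r4], {"T3_ref": "T3", "T4_ref": "T4"})
        q = seq16("q", "AAAAATTTTT")  # 50% to both
        a = assign_clade(q, refs, assign_threshold=40.0)
        assert a.margin == 0.0
        assert a.status is AssignmentStatus.AMBIGUOUS

    def test_nearby_clade_wins_over_distant_one(self):
        rng = np.random.default_rng(2)
        refs = self._refs(rng, n_clades=2, div=0.15)
        base = refs.of_clade("T3")[0].residues
        q = list(base)
        for pos in rng.choice(len(q), size=int(0.03 * len(q)), replace=False):
            q[pos] = rng.choice([b for b in "ACGT" if b != q[pos]])
        a = assign_clade(seq16("q", "".join(q)), refs, 90.0, 2.0)
        assert a.best_clade == "T3"
        assert a.status is AssignmentStatus.ASSIGNED

    def test_distant_query_is_non_thiothrix(self):
        rng = np.random.default_rng(3)
        refs = self._refs(rng)
        q = "".join(rng.choice(list("ACGT"), 300))
        a = assign_clade(seq16("q", q), refs, assign_threshold=90.0)
        assert a.status is AssignmentStatus.NON_THIOTHRIX

    def test_identity_of_unaligned_sequences_ignores_end_gaps(self):
        a = seq16("a", "ACGTACGTACGTACGTACGT")
        b = seq16("b", "CGTACGTACGTACGTAC")  # a truncated at both ends
        assert pairwise_identity(a, b) == pytest.approx(100.0)


class TestResolveMixture:
    def _refs(self, rng):
        root = "".join(rng.choice(list("ACGT"), 60))
        seqs = {}
        for name in ("r1", "r2", "r3"):
            s = list(root)
            for pos in rng.choice(60, size=6, replace=False):
                s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
            seqs[name] = "".join(s)
        return ReferenceSet(
            [seq16(k, v) for k, v in seqs.items()],
            {"r1": "T3", "r2": "T4", "r3": "mat"},
        )

    def test_superposed_pair_recovered_exactly(self):
        rng = np.random.default_rng(5)
        refs = self._refs(rng)
        s1 = refs.sequences[0].residues
        s2 = refs.sequences[1].residues
        tr = MixedTrace(
            id="mix",
            positions=tuple(frozenset({a, b}) for a, b in zip(s1, s2)),
            orientation=Orientation.FORWARD,
        )
        # exhaustive oracle over all reference pairs
        fits = [
            {i, j}
            for i, j in combinations(range(3), 2)
            if all(
                frozenset({x, y}) == p
                for x, y, p in zip(
                    refs.sequences[i].residues,
                    refs.sequences[j].residues,
                    tr.positions,
                )
            )
        ]
        assert fits == [{0, 1}]
        pair = resolve_mixture_by_reference(tr, refs)
        assert pair is not None
        assert {pair[0].id, pair[1].id} == {"r1", "r2"}

    def test_single_sequence_short_circuit(self):
        rng = np.random.default_rng(6)
        refs = self._refs(rng)
        s1 = refs.sequences[0].residues
        tr = MixedTrace(
            id="pure",
            positions=tuple(frozenset({c}) for c in s1),
            orientation=Orientation.FORWARD,
        )
        pair = resolve_mixture_by_reference(tr, refs)
        assert pair[0].id == pair[1].id == "r1"

    def test_incompatible_trace_fails_with_near_miss_count(self):
        rng = np.random.default_rng(7)
        refs = self._refs(rng)
        tr = MixedTrace(
            id="bad",
            positions=tuple(
                frozenset({"A", "C"}) for _ in range(60)
            ),
            orientation=Orientation.FORWARD,
        )
        assert resolve_mixture_by_reference(tr, refs) is None
        assert resolve_mixture_by_reference.last_near_miss > 0


class TestRarefaction:
    def test_two_singletons_subsample_of_one(self):
        assert expected_richness([1, 1], 1) == pytest.approx(1.0)

    def test_three_one_subsample_of_two_matches_enumeration(self):
        # exhaustive: C(4,2)=6 subsamples, 3 contain both OTUs
        assert expected_richness([3, 1], 2) == pytest.approx(1.5)

    def test_complete_sampling_returns_all_otus(self):
        assert expected_richness([1] * 7, 7) == pytest.approx(7.0)

    def test_subsample_larger_than_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            expected_richness([2, 2], 5)

    def test_curve_endpoints_and_monotonicity(self):
        pts = rarefaction_curve([5, 3, 2, 1, 1], step=2)
        assert pts[-1].n == 12
        assert pts[-1].expected_otus == pytest.approx(5.0)
        values = [p.expected_otus for p in pts]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_matches_exhaustive_enumeration_small_n(self):
        from itertools import combinations as comb

        rng = np.random.default_rng(8)
        for _ in range(5):
            k = int(rng.integers(2, 4))
            counts = [int(c) for c in rng.integers(1, 4, size=k)]
            N = sum(counts)
            if N > 8:
                continue
            labels = [i for i, c in enumerate(counts) for _ in range(c)]
            for n in range(1, N + 1):
                exact = np.mean(
                    [len(set(sub)) for sub in comb(labels, n)]
                )
                assert expected_richness(counts, n) == pytest.approx(exact)

    def test_matches_monte_carlo_within_three_se(self):
        rng = np.random.default_rng(9)
        counts = [int(c) for c in rng.integers(1, 20, size=6)]
        N = sum(counts)
        labels = np.repeat(np.arange(6), counts)
        n = N // 2
        draws = np.array([
            len(np.unique(rng.choice(labels, size=n, replace=False)))
            for _ in range(10_000)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert expected_richness(counts, n) == pytest.approx(
            draws.mean(), abs=3 * se
        )
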