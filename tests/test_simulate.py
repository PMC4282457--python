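"""Synthetic data generator: determinism and planted structure."""

import numpy as np
import pytest

from haploweb.deconvolution import deconvolve, score_shifts
from haploweb.ecology import fit_eh_h2s, screening_tally
from haploweb.seq_core import Marker, Sequence, k2p_distance
from haploweb.simulate import (
    SimulationConfig,
    build_reference_set,
    mutate,
    simulate_dataset,
    simulate_individuals,
    simulate_sites,
    simulate_species_pools,
    simulate_study_screening,
)


class TestConfig:
    def test_divergence_ordering_enforced(self):
        with pytest.raises(ValueError, match="divergence"):
            SimulationConfig(inter_divergence=0.01, intra_divergence=0.05)

    def test_probability_domains_enforced(self):
        with pytest.raises(ValueError, match="probabilit"):
            SimulationConfig(p_heterozygote=1.5)


class TestPools:
    def test_zero_intra_divergence_gives_identical_alleles(self):
        cfg = SimulationConfig(intra_divergence=0.0, p_length_variant=0.0)
        pools = simulate_species_pools(cfg, np.random.default_rng(0))
        for p in pools.values():
            assert len(set(p["ITS"])) == 1
            assert len(set(p["COI"])) == 1

    def test_between_species_distance_reflects_planted_divergence(self):
        cfg = SimulationConfig(p_length_variant=0.0)
        pools = simulate_species_pools(cfg, np.random.default_rng(1))
        names = sorted(pools)
        for a in names:
            for b in names:
                if a >= b:
                    continue
                d = k2p_distance(
                    Sequence("a", pools[a]["ITS"][0], Marker.ITS),
                    Sequence("b", pools[b]["ITS"][0], Marker.ITS),
                )
                assert d >= cfg.inter_divergence / 2

    def test_same_seed_reproduces_dataset_exactly(self):
        d1 = simulate_dataset(seed=5)
        d2 = simulate_dataset(seed=5)
        assert [s.residues for s in d1.its_genotypes.sequences] == [
            s.residues for s in d2.its_genotypes.sequences
        ]
        assert [s.residues for s in d1.queries] == [s.residues for s in d2.queries]
        assert [(s.location, s.eh_mv, s.h2s_um) for s in d1.sites] == [
            (s.location, s.eh_mv, s.h2s_um) for s in d2.sites
        ]


class TestIndividuals:
    def test_no_heterozygotes_when_probability_zero(self):
        cfg = SimulationConfig(p_heterozygote=0.0, p_length_variant=0.0)
        pools = simulate_species_pools(cfg, np.random.default_rng(2))
        inds, its, traces, coi = simulate_individuals(
            pools, cfg, np.random.default_rng(2)
        )
        assert traces == {}
        assert all(i.its_pair[0] == i.its_pair[1] for i in inds)

    def test_alleles_drawn_from_own_species_pool_only(self):
        ds = simulate_dataset(seed=3)
        pools = simulate_species_pools(ds.config, np.random.default_rng(3))
        for ind in ds.individuals:
            for allele in ind.its_pair:
                assert allele in pools[ind.species]["ITS"]

    def test_length_variant_traces_round_trip(self):
        cfg = SimulationConfig(p_length_variant=1.0, seed=4)
        ds = simulate_dataset(cfg)
        assert ds.traces, "expected at least one length-variant heterozygote"
        for ind_id, (fwd, rev) in ds.traces.items():
            ind = next(i for i in ds.individuals if i.id == ind_id)
            true_pair = {a.replace("-", "") for a in ind.its_pair}
            best = score_shifts(fwd, rev, max_delta=cfg.indel_length)[0]
            res = deconvolve(fwd, rev, best.delta)
            assert res.pair == frozenset(true_pair)


class TestSites:
    def test_noiseless_sites_recover_planted_line_exactly(self):
        cfg = SimulationConfig(h2s_noise_sd=0.0, p_h2s_inferred=0.0, n_sites=10)
        sites = simulate_sites(cfg, np.random.default_rng(5))
        m = fit_eh_h2s(sites)
        assert m.slope == pytest.approx(cfg.eh_h2s_slope)
        assert m.intercept == pytest.approx(cfg.eh_h2s_intercept)

    def test_nonsulphidic_sites_have_zero_h2s(self):
        sites = simulate_sites(SimulationConfig(), np.random.default_rng(6))
        for s in sites:
            if s.eh_mv > 0:
                assert s.h2s_um == 0.0

    def test_planted_slope_recovered_within_three_se_under_noise(self):
        cfg = SimulationConfig(
            h2s_noise_sd=5.0, p_h2s_inferred=0.0, n_sites=40, p_sulphidic=0.9
        )
        slopes = []
        for seed in range(30):
            sites = simulate_sites(cfg, np.random.default_rng(seed))
            slopes.append(fit_eh_h2s(sites).slope)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert np.mean(slopes) == pytest.approx(cfg.eh_h2s_slope, abs=3 * se)


class TestEpibiontGeneration:
    def test_t4_never_appears_at_nonsulphidic_sites(self):
        for seed in range(5):
            ds = simulate_dataset(seed=seed)
            sulphidic = {s.location: s.h2s_um > 0 for s in ds.sites}
            for rec in ds.screening:
                if "T4" in rec.clade:
                    assert sulphidic[rec.site_id]

    def test_reference_set_contains_expected_clades(self):
        refs = build_reference_set(SimulationConfig(), np.random.default_rng(7))
        assert refs.clade_labels == {"T1", "T2", "T3", "T4", "mat"}

    def test_amplifiable_by_packaged_primers(self):
        from haploweb.epibiont import packaged_oligos, predict_amplicon

        refs = build_reference_set(SimulationConfig(), np.random.default_rng(8))
        ol = packaged_oligos()
        for ref in refs.sequences:
            amps = predict_amplicon(ol["THIO714F"], ol["THIO1492R"], ref, 0)
            assert amps and amps[0].length == 778

    def test_screening_tally_matches_planted_outcomes(self):
        ds = simulate_dataset(seed=9)
        tally = screening_tally(ds.screening)
        planted = {
            "thiothrix": sum(1 for r in ds.screening if r.outcome == "thiothrix"),
            "other": sum(1 for r in ds.screening if r.outcome == "other_bacteria"),
        }
        assert tally.thiothrix_positive == planted["thiothrix"]
        assert tally.other_bacteria == planted["other"]
        assert tally.total == len(ds.individuals)


class TestStudyScreening:
    def test_default_counts_match_the_survey(self):
        records = simulate_study_screening(seed=0)
        t = screening_tally(records)
        assert (t.thiothrix_positive, t.other_bacteria, t.negative, t.total) == (
            21, 11, 39, 71,
        )

    def test_custom_planted_counts_recovered(self):
        records = simulate_study_screening(
            seed=1, n_thiothrix=5, n_other=2, n_negative=3
        )
        t = screening_tally(records)
        assert (t.thiothrix_positive, t.other_bacteria, t.negative, t.total) == (
            5, 2, 3, 10,
        )


class TestMutate:
    def test_transition_bias_is_two_to_one(self):
        rng = np.random.default_rng(10)
        base = "A" * 30000
        out = mutate(base, 0.5, rng)
        ts = out.count("G")
        tv = out.count("C") + out.count("T")
        assert ts / tv == pytest.approx(2.0, rel=0.15)

    def test_protected_windows_untouched(self):
        rng = np.random.default_rng(11)
        base = "ACGT" * 25
        out = mutate(base, 1.0, rng, protected=((10, 20),))
        assert out[10:20] == base[10:20]

    def test_gaps_preserved(self):
        rng = np.random.default_rng(12)
        out = mutate("AC--GT", 1.0, rng)
        assert out[2:4] == "--"
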