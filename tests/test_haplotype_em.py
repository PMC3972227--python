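import numpy as np
import pytest

from hla_popgen import (
    GenotypeDataset,
    HaplotypeFrequencyModel,
    HaplotypeFrequencyTable,
    LOCI,
    allele_frequencies,
    em_haplotype_frequencies,
    enumerate_diplotypes,
    filter_and_rank,
    frequency_band_summary,
    han_truth_table,
    sample_genotypes,
    SimulationSpec,
)
from hla_popgen.errors import HlaPopgenError

from conftest import hap, record, total_variation


class TestEnumerateDiplotypes:
    def test_fully_homozygous_has_one_pair(self):
        rec = record("s", "P", ("A*02", "A*02"), ("B*07", "B*07"), ("DRB1*09", "DRB1*09"))
        pairs = enumerate_diplotypes(rec)
        assert pairs == [(hap("A*02", "B*07", "DRB1*09"), hap("A*02", "B*07", "DRB1*09"))]

    def test_triple_heterozygote_has_four_pairs(self):
        rec = record("s", "P", ("A*01", "A*02"), ("B*07", "B*08"), ("DRB1*01", "DRB1*04"))
        pairs = enumerate_diplotypes(rec)
        assert len(pairs) == 4
        for h1, h2 in pairs:
            for locus in LOCI:
                assert {h1.allele(locus), h2.allele(locus)} == set(rec.pair(locus))

    def test_single_heterozygous_locus_has_one_pair(self):
        rec = record("s", "P", ("A*01", "A*02"), ("B*07", "B*07"), ("DRB1*09", "DRB1*09"))
        pairs = enumerate_diplotypes(rec)
        assert len(pairs) == 1
        h1, h2 = pairs[0]
        assert h1.b == h2.b and h1.drb1 == h2.drb1 and h1.a != h2.a

    @pytest.mark.parametrize("n_het,expected", [(0, 1), (1, 1), (2, 2), (3, 4)])
    def test_count_is_two_to_het_minus_one(self, n_het, expected):
        pairs_by_locus = [("A*01", "A*02"), ("B*07", "B*08"), ("DRB1*01", "DRB1*04")]
        homs = [("A*01", "A*01"), ("B*07", "B*07"), ("DRB1*01", "DRB1*01")]
        slots = [pairs_by_locus[i] if i < n_het else homs[i] for i in range(3)]
        rec = record("s", "P", *slots)
        assert len(enumerate_diplotypes(rec)) == expected


class TestEMFit:
    def test_homozygous_dataset_equals_direct_counting(self):
        ds = GenotypeDataset(
            [
                record("s1", "P", ("A*02", "A*02"), ("B*07", "B*07"), ("DRB1*09", "DRB1*09")),
                record("s2", "P", ("A*11", "A*11"), ("B*13", "B*13"), ("DRB1*12", "DRB1*12")),
                record("s3", "P", ("A*02", "A*02"), ("B*07", "B*07"), ("DRB1*09", "DRB1*09")),
            ]
        )
        res = em_haplotype_frequencies(ds, "P")
        # no phase ambiguity: the first M-step already lands on the count
        # estimate, the next pass only certifies the fixed point
        assert res.converged and res.iterations <= 2
        assert res.table.get(hap("A*02", "B*07", "DRB1*09")) == pytest.approx(2 / 3)
        assert res.table.get(hap("A*11", "B*13", "DRB1*12")) == pytest.approx(1 / 3)

    def test_double_heterozygote_symmetric_fixed_point(self):
        # het at A and B, homozygous at DRB1: two diplotype resolutions.
        # From a uniform start both are weighted 1/2 and all four haplotypes
        # sit at 1/4 - a stationary point of the EM map.
        ds = GenotypeDataset(
            [record("s", "P", ("A*01", "A*02"), ("B*07", "B*08"), ("DRB1*09", "DRB1*09"))]
        )
        res = em_haplotype_frequencies(ds, "P", init="uniform")
        assert len(res.table) == 4
        for h in res.table:
            assert res.table.get(h) == pytest.approx(0.25, abs=1e-12)

    def test_recovery_from_simulated_registry_sample(self):
        truth = han_truth_table(20)
        ds = sample_genotypes(SimulationSpec(truth, 2000, population_label="Han", seed=20140401))
        res = em_haplotype_frequencies(ds, "Han", tol=1e-7)
        assert res.converged
        assert total_variation(res.table, truth) < 0.04
        # every common generating haplotype is found
        for h, v in truth.items():
            if v >= 0.01:
                assert res.table.get(h) > 0

    def test_em_matches_phase_known_oracle(self):
        # The information loss from discarding phase is nearly zero for
        # strongly linked haplotypes: the unphased MLE must sit within a
        # whisker of direct counting of the true simulated haplotypes.
        truth = han_truth_table(20)
        haps = sorted(truth, key=lambda h: h.key)
        p = np.array([truth.get(h) for h in haps])
        for seed in (1, 2, 3):
            ds = sample_genotypes(SimulationSpec(truth, 2000, population_label="Han", seed=seed))
            # reconstruct the actual drawn haplotypes (same rng protocol)
            rng = np.random.default_rng(seed)
            cdf = np.cumsum(p / p.sum())
            cdf[-1] = 1.0
            draws = np.searchsorted(cdf, rng.random(4000), side="right")
            phased = np.bincount(draws, minlength=len(p)) / 4000
            oracle = HaplotypeFrequencyTable(
                {h: float(v) for h, v in zip(haps, phased)}, population="Han"
            )
            res = em_haplotype_frequencies(ds, "Han")
            assert total_variation(res.table, truth) <= total_variation(oracle, truth) + 0.005

    def test_log_likelihood_monotone_and_total_mass(self):
        truth = han_truth_table(10)
        ds = sample_genotypes(SimulationSpec(truth, 500, population_label="Han", seed=2))
        res = em_haplotype_frequencies(ds, "Han")
        trace = res.log_likelihood_trace
        assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))
        assert res.table.total() == pytest.approx(1.0, abs=1e-9)

    def test_marginals_match_direct_counting(self):
        truth = han_truth_table(15)
        ds = sample_genotypes(SimulationSpec(truth, 800, population_label="Han", seed=9))
        res = em_haplotype_frequencies(ds, "Han")
        af = allele_frequencies(ds, "Han")
        for locus in LOCI:
            marg = res.table.marginal(locus)
            for c, v in af.freqs[locus].items():
                assert marg.get(c, 0.0) == pytest.approx(v, abs=1e-6)

    def test_record_order_invariance(self):
        truth = han_truth_table(8)
        ds = sample_genotypes(SimulationSpec(truth, 200, population_label="Han", seed=4))
        rev = GenotypeDataset(list(ds)[::-1])
        a = em_haplotype_frequencies(ds, "Han").table
        b = em_haplotype_frequencies(rev, "Han").table
        for h in set(a) | set(b):
            assert a.get(h) == pytest.approx(b.get(h), abs=1e-9)

    def test_restarts_keep_best_likelihood(self):
        truth = han_truth_table(10)
        ds = sample_genotypes(SimulationSpec(truth, 300, population_label="Han", seed=6))
        single = em_haplotype_frequencies(ds, "Han", restarts=1)
        multi = em_haplotype_frequencies(ds, "Han", restarts=3, seed=6)
        assert multi.log_likelihood >= single.log_likelihood - 1e-6

    def test_invalid_settings_error(self, tiny_dataset):
        with pytest.raises(HlaPopgenError):
            em_haplotype_frequencies(tiny_dataset, "P1", tol=0)
        with pytest.raises(HlaPopgenError):
            em_haplotype_frequencies(tiny_dataset, "P1", max_iter=0)

    def test_summary_mentions_convergence(self):
        truth = han_truth_table(5)
        ds = sample_genotypes(SimulationSpec(truth, 100, population_label="Han", seed=8))
        text = em_haplotype_frequencies(ds, "Han").summary()
        assert "converged" in text and "log-likelihood" in text


class TestFilterAndRank:
    def test_threshold_on_fixture(self, paper_fixtures):
        kept = filter_and_rank(paper_fixtures.han_haplotypes, min_freq=0.005)
        assert len(kept) == 25

    def test_zero_threshold_is_identity_up_to_order(self, paper_fixtures):
        kept = filter_and_rank(paper_fixtures.han_haplotypes, min_freq=0.0)
        assert set(kept) == set(paper_fixtures.han_haplotypes)

    def test_top_one(self, paper_fixtures):
        kept = filter_and_rank(paper_fixtures.han_haplotypes, top_n=1)
        ((h, v),) = list(kept.items())
        assert h == hap("A*30", "B*13", "DRB1*07")
        assert v == pytest.approx(0.0488)

    def test_descending_with_lexicographic_ties(self):
        t = HaplotypeFrequencyTable(
            {
                hap("A*02", "B*07", "DRB1*01"): 0.2,
                hap("A*01", "B*07", "DRB1*01"): 0.2,
                hap("A*03", "B*07", "DRB1*01"): 0.5,
            }
        )
        ranked = list(filter_and_rank(t))
        assert [h.a.code for h in ranked] == ["A*03", "A*01", "A*02"]

    def test_negative_threshold_errors(self, paper_fixtures):
        with pytest.raises(HlaPopgenError):
            filter_and_rank(paper_fixtures.han_haplotypes, min_freq=-0.1)


class TestFrequencyBands:
    def test_fixture_band_counts(self, paper_fixtures):
        df = frequency_band_summary(paper_fixtures.han_haplotypes)
        top = df[df["band"] == ">0.01"].iloc[0]
        assert top["count"] == 7
        assert top["percent_of_total"] == pytest.approx(13.62, abs=0.02)

    def test_empty_table_zero_counts(self):
        df = frequency_band_summary(HaplotypeFrequencyTable({}))
        assert df["count"].sum() == 0

    def test_bands_partition_the_table(self, paper_fixtures):
        df = frequency_band_summary(paper_fixtures.han_haplotypes)
        assert df["count"].sum() == len(paper_fixtures.han_haplotypes)

    def test_unsorted_edges_error(self, paper_fixtures):
        with pytest.raises(HlaPopgenError):
            frequency_band_summary(paper_fixtures.han_haplotypes, band_edges=[0.001, 0.01])
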