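import numpy as np
import pytest

import rilforge as rf
from rilforge.genotype_core import GenotypeCall as GC
from rilforge.ril_simulator import simulate_gamete, translocation_demo_genome


class TestSimulateGamete:
    def test_zero_length_group_copies_one_homolog(self):
        rng = np.random.default_rng(0)
        pair = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
        for _ in range(20):
            gam = simulate_gamete(pair, [5.0, 5.0, 5.0], rng)
            assert gam.tolist() in ([0, 0, 0], [1, 1, 1])

    def test_recombinant_frequency_matches_haldane(self):
        """Two markers 100 cM apart: recombinant gametes at r = (1-e^-2)/2."""
        rng = np.random.default_rng(1)
        pair = np.array([[0, 0], [1, 1]], dtype=np.int8)
        n = 20_000
        rec = sum(
            g[0] != g[1] for g in (simulate_gamete(pair, [0.0, 100.0], rng) for _ in range(n))
        )
        r_expected = 0.5 * (1 - np.exp(-2.0))
        se = np.sqrt(r_expected * (1 - r_expected) / n)
        assert abs(rec / n - r_expected) < 3 * se

    def test_unsorted_positions_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="sorted"):
            simulate_gamete(np.zeros((2, 2), dtype=np.int8), [2.0, 1.0], rng)

    def test_crossover_count_is_poisson_of_map_length(self):
        """Mean switches along a dense 240 cM group ~ Poisson(2.4) mean."""
        rng = np.random.default_rng(2)
        m = 241
        pair = np.stack([np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8)])
        pos = np.linspace(0, 240.0, m)
        n = 20_000
        switches = np.empty(n)
        for i in range(n):
            gam = simulate_gamete(pair, pos, rng)
            switches[i] = (np.diff(gam) != 0).sum()
        lam = 2.4
        # switch count undercounts crossovers landing in the same interval
        assert abs(switches.mean() - lam) < 3 * np.sqrt(lam / n) + 0.05
        assert switches.var() / switches.mean() == pytest.approx(1.0, abs=0.1)


class TestSimulateSSD:
    def test_f2_single_line_half_heterozygous(self):
        genome = rf.unlinked_loci_genome(4000)
        pop = rf.simulate_ssd(rf.SimConfig(genome=genome, n_lines=1, final_generation=2, seed=5))
        h = rf.het_fraction(pop.genotypes)
        assert abs(h - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_haldane_waddington_limit_at_large_g(self):
        """Two-locus recombinant-line fraction tends to R = 2r/(1+2r)."""
        r = 0.1
        genome = rf.GenomeSpec(
            (rf.LinkageGroupSpec("LG1", ("a", "b"), (0.0, rf.haldane_cM(r))),)
        )
        pop = rf.simulate_ssd(rf.SimConfig(genome=genome, n_lines=8000, final_generation=20, seed=6))
        pr = rf.pairwise_R(pop.genotypes)
        R_exp = 2 * r / (1 + 2 * r)
        se = np.sqrt(R_exp * (1 - R_exp) / pr.n_informative[0, 1])
        assert abs(pr.R[0, 1] - R_exp) < 3 * se

    def test_same_seed_bit_identical(self):
        genome = rf.uniform_genome(2, 20, 80.0)
        cfg = rf.SimConfig(genome=genome, n_lines=30, final_generation=6,
                           error_rate=0.01, missing_rate=0.02, seed=11)
        a, b = rf.simulate_ssd(cfg), rf.simulate_ssd(cfg)
        assert np.array_equal(a.genotypes.calls, b.genotypes.calls)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_truth_counts_match_genotype_counts_noiseless(self, f6_population, truth_map):
        from rilforge.recombination import crossover_table

        ct = crossover_table(f6_population.genotypes, truth_map)
        truth = f6_population.visible_crossover_counts()
        assert np.allclose(ct.per_line.to_numpy()[:, 0], truth[:, 0])

    def test_distortion_skews_allele_frequency(self):
        genome = rf.uniform_genome(1, 21, 50.0)
        locus = genome.linkage_groups[0].marker_ids[10]
        pop = rf.simulate_ssd(
            rf.SimConfig(genome=genome, n_lines=400, final_generation=6,
                         distortion={locus: (0.5, 1.0, 1.0)}, seed=8)
        )
        calls = pop.genotypes.marker_calls(locus)
        n1 = (calls == GC.A).sum()
        n2 = (calls == GC.B).sum()
        assert n2 > n1  # parent-1 homozygotes selected against

    def test_invalid_config_rejected(self):
        genome = rf.uniform_genome(1, 5, 10.0)
        with pytest.raises(ValueError):
            rf.SimConfig(genome=genome, n_lines=0, final_generation=6)
        with pytest.raises(ValueError):
            rf.SimConfig(genome=genome, n_lines=5, final_generation=1)
        with pytest.raises(ValueError):
            rf.SimConfig(genome=genome, n_lines=5, final_generation=6, error_rate=1.5)


class TestApplyNoise:
    def test_zero_rates_identity(self, f6_population):
        rng = np.random.default_rng(0)
        out = rf.apply_noise(f6_population, 0.0, 0.0, rng)
        assert np.array_equal(out.genotypes.calls, f6_population.genotypes.calls)

    def test_all_missing_boundary(self, f6_population):
        rng = np.random.default_rng(0)
        out = rf.apply_noise(f6_population, 0.0, 1.0, rng)
        assert (out.genotypes.calls == GC.MISSING).all()
        assert np.array_equal(out.haplotypes, f6_population.haplotypes)

    def test_observed_rates_match_nominal(self):
        genome = rf.unlinked_loci_genome(2500)
        pop = rf.simulate_ssd(rf.SimConfig(genome=genome, n_lines=400, final_generation=7, seed=1))
        rng = np.random.default_rng(2)
        noisy = rf.apply_noise(pop, 0.01, 0.02, rng)
        n = pop.genotypes.calls.size
        miss = (noisy.genotypes.calls == GC.MISSING).mean()
        assert abs(miss - 0.02) < 3 * np.sqrt(0.02 * 0.98 / n)
        surviving = noisy.genotypes.calls != GC.MISSING
        err = (noisy.genotypes.calls != pop.genotypes.calls)[surviving].mean()
        assert abs(err - 0.01) < 3 * np.sqrt(0.01 * 0.99 / n)


class TestInjectTranslocation:
    def test_zero_length_segment_changes_nothing(self):
        genome = rf.uniform_genome(2, 11, 100.0)
        out = rf.inject_translocation(genome, "LG1", "LG2", 100.0 + 1.0)
        assert out.lg_by_name("LG1").chrom_labels == genome.lg_by_name("LG1").chrom_labels

    def test_distal_segment_relabeled_linkage_untouched(self):
        genome = rf.uniform_genome(2, 11, 100.0)
        out = rf.inject_translocation(genome, "LG1", "LG2", 70.0)
        lg1 = out.lg_by_name("LG1")
        swapped = [lab for p, lab in zip(lg1.positions_cM, lg1.chrom_labels) if p >= 70.0]
        kept = [lab for p, lab in zip(lg1.positions_cM, lg1.chrom_labels) if p < 70.0]
        assert set(swapped) == {"LG2"} and set(kept) == {"LG1"}
        assert lg1.positions_cM == genome.lg_by_name("LG1").positions_cM

    def test_unknown_group_rejected(self):
        genome = rf.uniform_genome(1, 5, 10.0)
        with pytest.raises(ValueError, match="unknown"):
            rf.inject_translocation(genome, "LGx", "LG1", 5.0)

    def test_demo_genome_labels_match_declared_truth(self):
        demo = translocation_demo_genome()
        chrom = {m.marker_id: m.sequence_name for m in demo.genome.marker_info()}
        assert all(chrom[m] == "chr1" for m in demo.swapped_markers)
        assert all(chrom[m] == "chr5" for m in demo.partner_markers)


class TestSimulateTrait:
    def test_noiseless_trait_equals_genotype_classes(self, f6_population):
        from rilforge.trait_mapping import P1, P2

        locus = f6_population.genotypes.markers[30]
        rng = np.random.default_rng(0)
        t = rf.simulate_trait(f6_population, locus, 0.0, rng)
        calls = f6_population.genotypes.marker_calls(locus)
        for line, call in zip(f6_population.genotypes.lines, calls):
            if call == GC.A:
                assert t.states[line] == P1
            elif call == GC.B:
                assert t.states[line] == P2

    def test_full_misscore_inverts(self, f6_population):
        locus = f6_population.genotypes.markers[30]
        t0 = rf.simulate_trait(f6_population, locus, 0.0, np.random.default_rng(0))
        t1 = rf.simulate_trait(f6_population, locus, 1.0, np.random.default_rng(0))
        for line in f6_population.genotypes.lines:
            if t0.states[line] != "unknown":
                assert t1.states[line] != t0.states[line]
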