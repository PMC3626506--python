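"""Heterozygosity landscape: windows, rates, purging, pedigree expectation."""

import numpy as np
import pandas as pd
import pytest

from inbredscape import het
from inbredscape.io import Assembly, AnnotationSet, VariantSet
from inbredscape.simulate import SimulationConfig, random_sequence, simulate_genome


def make_variants(chrom, positions, vtype="SNP"):
    return VariantSet.from_records([(chrom, p, "A", "G", vtype) for p in positions])


class TestWindowHeterozygosity:
    def test_no_variants_all_zero(self, rng):
        asm = Assembly({"s": random_sequence(200_000, rng)})
        prof = het.window_heterozygosity(VariantSet.empty(), asm)
        assert len(prof) == 4
        assert (prof.windows.het_rate == 0).all()

    def test_single_window_direct_ratio(self, rng):
        asm = Assembly({"s": random_sequence(50_000, rng)})
        prof = het.window_heterozygosity(make_variants("s", range(65)), asm)
        assert len(prof) == 1
        assert prof.windows.het_rate.iloc[0] == pytest.approx(0.0013)

    def test_counts_match_bruteforce(self, rng):
        L, width = 1_000_000, 50_000
        asm = Assembly({"s": random_sequence(L, rng)})
        pos = np.sort(rng.choice(L, size=800, replace=False))
        prof = het.window_heterozygosity(make_variants("s", pos), asm, width=width)
        for w in prof.windows.itertuples(index=False):
            brute = sum(1 for p in pos if w.start <= p < w.end)
            assert w.het_sites == brute

    def test_short_tail_window_dropped(self, rng):
        asm = Assembly({"s": random_sequence(120_000, rng)})
        prof = het.window_heterozygosity(VariantSet.empty(), asm)
        # 120 kb = 2 full windows + a 20 kb tail (< half width: dropped)
        assert len(prof) == 2
        asm2 = Assembly({"s": random_sequence(130_000, rng)})
        prof2 = het.window_heterozygosity(VariantSet.empty(), asm2)
        assert len(prof2) == 3  # 30 kb tail >= half width: kept

    def test_variant_beyond_scaffold_end_rejected(self, rng):
        asm = Assembly({"s": random_sequence(10_000, rng)})
        with pytest.raises(ValueError, match="beyond"):
            het.window_heterozygosity(make_variants("s", [20_000]), asm)

    def test_window_sites_bounded_by_total_variants(self, bundle):
        prof = het.window_heterozygosity(bundle.variants, bundle.assembly)
        assert prof.windows.het_sites.sum() <= len(bundle.variants)


class TestGenomeRates:
    def test_paper_scale_worked_example(self):
        v = VariantSet.from_records(
            [("s", i, "A", "G", "SNP") for i in range(118)]
            + [("s", 1000 + 2 * i, "A", "AT", "INDEL") for i in range(17)])
        s = het.genome_rates(v, 100_000)
        assert 100 * s.snp_rate == pytest.approx(0.118)
        assert 100 * s.indel_rate == pytest.approx(0.017)
        assert 100 * s.combined_rate == pytest.approx(0.135)

    def test_empty_variant_set(self):
        s = het.genome_rates(VariantSet.empty(), 1_000)
        assert s.snp_rate == s.indel_rate == s.combined_rate == 0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            het.genome_rates(VariantSet.empty(), 0)


class TestFractionBelow:
    def make_profile(self, rates):
        df = pd.DataFrame({
            "chrom": "s", "start": np.arange(len(rates)) * 50_000,
            "end": (np.arange(len(rates)) + 1) * 50_000,
            "callable_bases": 50_000, "het_sites": 0, "het_rate": rates})
        return het.WindowProfile(windows=df, width=50_000)

    def test_threshold_above_max_is_100(self):
        prof = self.make_profile([1e-5, 2e-5, 3e-5])
        assert het.fraction_below(prof, 1.0) == 100.0

    def test_threshold_zero_is_0(self):
        prof = self.make_profile([1e-5, 2e-5, 0.0])
        assert het.fraction_below(prof, 0.0) == 0.0

    def test_monotone_in_threshold(self, rng):
        prof = self.make_profile(rng.random(200) * 0.01)
        vals = [het.fraction_below(prof, t) for t in np.linspace(0, 0.011, 30)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            het.fraction_below(het.WindowProfile(pd.DataFrame(
                columns=["chrom", "start", "end", "callable_bases",
                         "het_sites", "het_rate"]), 50_000), 1e-4)

    def test_two_state_simulation_recovers_purged_fraction(self):
        # bimodal window histogram; the fraction below the midpoint of the
        # two configured rates recovers the purged fraction
        cfg = SimulationConfig(genome_length=20_000_000, window_purged_fraction=0.6,
                               het_rate_retained=0.0033, het_rate_purged=0.00005,
                               mean_block_length=500_000, gene_count=0, te_bursts=[],
                               provirus_count=0, fragment_count=0, seed=9)
        out = simulate_genome(cfg)
        prof = het.window_heterozygosity(out.variants, out.assembly)
        midpoint = (0.0033 + 0.00005) / 2
        measured = het.fraction_below(prof, midpoint)
        blocks = out.truth.state_blocks
        realized = (blocks[blocks.state == "purged"].end
                    - blocks[blocks.state == "purged"].start).sum() / cfg.genome_length
        assert measured / 100 == pytest.approx(realized, abs=0.02)


class TestTopDivergentRegions:
    def test_equal_rates_pick_first_five_by_coordinate(self, rng):
        df = pd.DataFrame({"chrom": "s", "start": np.arange(100) * 50_000,
                           "end": (np.arange(100) + 1) * 50_000,
                           "callable_bases": 50_000, "het_sites": 5,
                           "het_rate": 1e-4})
        prof = het.WindowProfile(df, 50_000)
        regions = het.top_divergent_regions(prof, 0.05)
        assert regions.n_windows.sum() == 5
        assert regions.start.min() == 0  # ties broken by coordinate order

    def test_planted_high_windows_selected_exactly(self, rng):
        rates = np.full(200, 1e-4)
        high = rng.choice(200, size=10, replace=False)
        rates[high] = 0.006
        df = pd.DataFrame({"chrom": "s", "start": np.arange(200) * 50_000,
                           "end": (np.arange(200) + 1) * 50_000,
                           "callable_bases": 50_000, "het_sites": 0,
                           "het_rate": rates})
        regions = het.top_divergent_regions(het.WindowProfile(df, 50_000), 0.05)
        assert regions.n_windows.sum() == 10
        assert regions.min_rate.min() == pytest.approx(0.006)

    def test_selection_equals_sort_oracle(self, rng):
        rates = rng.random(137) * 0.01
        df = pd.DataFrame({"chrom": "s", "start": np.arange(137) * 50_000,
                           "end": (np.arange(137) + 1) * 50_000,
                           "callable_bases": 50_000, "het_sites": 0,
                           "het_rate": rates})
        regions = het.top_divergent_regions(het.WindowProfile(df, 50_000), 0.05)
        n_top = int(np.ceil(137 * 0.05))
        expected_starts = set(df.sort_values("het_rate", ascending=False)
                              .head(n_top).start)
        got = set()
        for r in regions.itertuples(index=False):
            got.update(range(r.start, r.end, 50_000))
        assert got == expected_starts


class TestGeneHeterozygosity:
    def test_direct_ratio(self):
        ann = AnnotationSet(genes=pd.DataFrame(
            [("g1", "s", 0, 10_000, "+")],
            columns=["gene_id", "chrom", "start", "end", "strand"]))
        v = make_variants("s", range(48))
        tab = het.gene_heterozygosity(v, ann)
        assert tab.het_rate.iloc[0] == pytest.approx(0.0048)

    def test_gene_without_variants_zero(self):
        ann = AnnotationSet(genes=pd.DataFrame(
            [("g1", "s", 0, 1_000, "+")],
            columns=["gene_id", "chrom", "start", "end", "strand"]))
        tab = het.gene_heterozygosity(VariantSet.empty(), ann)
        assert tab.het_rate.iloc[0] == 0.0

    def test_counts_equal_bruteforce_with_overlapping_genes(self, rng):
        genes = [(f"g{i}", "s", int(s), int(s) + 5_000, "+")
                 for i, s in enumerate(rng.integers(0, 95_000, size=30))]
        ann = AnnotationSet(genes=pd.DataFrame(
            genes, columns=["gene_id", "chrom", "start", "end", "strand"]))
        pos = rng.integers(0, 100_000, size=500)
        v = make_variants("s", pos)
        tab = het.gene_heterozygosity(v, ann).set_index("gene_id")
        for gid, _, s, e, _ in genes:
            brute = int(((pos >= s) & (pos < e)).sum())
            assert tab.loc[gid, "het_sites"] == brute


class TestInbreeding:
    def test_base_cases(self):
        assert het.inbreeding_coefficient(0) == 0.0
        assert het.inbreeding_coefficient(1) == 0.25

    def test_negative_generations_rejected(self):
        with pytest.raises(ValueError):
            het.inbreeding_coefficient(-1)

    def test_monotone_and_geometric_approach_to_one(self):
        fs = [het.inbreeding_coefficient(t) for t in range(30)]
        assert all(b > a for a, b in zip(fs, fs[1:]))
        ratios = [(1 - fs[t + 1]) / (1 - fs[t]) for t in range(20, 29)]
        # (1-F) shrinks geometrically at the golden-ratio rate ~0.809
        assert np.allclose(ratios, 0.809, atol=0.01)

    def test_recurrence_matches_gene_dropping_monte_carlo(self):
        # gene-dropping oracle: follow allele copies through t generations
        # of full-sib mating; F_t = P(the two alleles of an offspring are
        # identical by descent from the founder pair)
        rng = np.random.default_rng(77)
        t, n_rep = 20, 200_000
        founders = np.array([0, 1, 2, 3])
        sire = np.tile(founders[:2], (n_rep, 1))
        dam = np.tile(founders[2:], (n_rep, 1))
        for _ in range(t):
            pick = rng.integers(2, size=(n_rep, 4))
            child1 = np.stack([sire[np.arange(n_rep), pick[:, 0]],
                               dam[np.arange(n_rep), pick[:, 1]]], axis=1)
            child2 = np.stack([sire[np.arange(n_rep), pick[:, 2]],
                               dam[np.arange(n_rep), pick[:, 3]]], axis=1)
            sire, dam = child1, child2
        pick = rng.integers(2, size=(n_rep, 2))
        a = sire[np.arange(n_rep), pick[:, 0]]
        b = dam[np.arange(n_rep), pick[:, 1]]
        f_mc = float(np.mean(a == b))
        # t loop iterations + the final mating = t full-sib matings (the
        # founder cross itself is between unrelated animals)
        f_exact = het.inbreeding_coefficient(t)
        se = np.sqrt(f_exact * (1 - f_exact) / n_rep)
        assert abs(f_mc - f_exact) < 3 * se

    def test_expected_het_decreases(self):
        hs = [het.expected_heterozygosity(0.001, t) for t in range(10)]
        assert all(b < a for a, b in zip(hs, hs[1:]))


class TestExpectedVsObserved:
    def test_identical_vectors(self):
        v = [0.1, 0.2, 0.3, 0.4]
        assert het.expected_vs_observed(v, v) == pytest.approx(1.0)

    def test_antiproportional_vectors(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        assert het.expected_vs_observed(v, -2 * v) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning):
            r = het.expected_vs_observed([1, 1, 1], [0.1, 0.2, 0.3])
        assert np.isnan(r)

    def test_independent_vectors_near_zero_vs_permutation(self, rng):
        # 17 strains as in the inbred-mouse comparison: independent
        # expected/observed vectors give |r| within the permutation null
        x, y = rng.random(17), rng.random(17)
        r = het.expected_vs_observed(x, y)
        perm = np.array([het.expected_vs_observed(x, rng.permutation(y))
                         for _ in range(500)])
        assert abs(r) <= np.quantile(np.abs(perm), 0.99)
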