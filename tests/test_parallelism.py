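"""Parallel-evolution statistics: filters, multiplicities, nulls, FDR."""

import numpy as np
import pytest
from scipy import stats

from coevo.parallelism import (
    fdr_critical_p,
    filter_variants,
    gene_multiplicity,
    gene_pvalues,
    identical_site_parallelism,
    nucleotide_null,
    parallel_evolution_scan,
    simulate_null_pvalues,
)
from coevo.types import Gene, GeneCatalog, MutationTable
from conftest import make_record


class TestFilterVariants:
    def test_below_detection_frequency_removed(self):
        tab = MutationTable([make_record(freq=0.19), make_record(pos=60, freq=0.2)])
        out = filter_variants(tab, None, min_freq=0.2)
        assert [r.position for r in out.records] == [60]

    def test_ancestor_fixed_site_removed_everywhere(self):
        anc = MutationTable([make_record(pop="anc", pos=50, freq=0.99)])
        tab = MutationTable([
            make_record(pop=f"pop_{i}", pos=50, freq=0.9) for i in (1, 2, 3)
        ] + [make_record(pop="pop_1", pos=70, freq=0.9)])
        out = filter_variants(tab, anc, min_freq=0.2)
        assert [r.position for r in out.records] == [70]

    def test_segregating_ancestor_site_kept(self):
        anc = MutationTable([make_record(pop="anc", pos=50, freq=0.5)])
        tab = MutationTable([make_record(pos=50, freq=0.9)])
        assert len(filter_variants(tab, anc)) == 1

    def test_no_filtering_is_identity(self):
        tab = MutationTable([make_record(freq=0.01, pos=p) for p in (5, 6)])
        out = filter_variants(tab, None, min_freq=0.0)
        assert len(out) == 2

    def test_invalid_min_freq_rejected(self):
        with pytest.raises(ValueError):
            filter_variants(MutationTable([]), None, min_freq=1.5)


class TestSiteParallelism:
    def test_shared_substitution_has_full_multiplicity(self):
        tab = MutationTable([
            make_record(pop=f"pop_{i}", pos=50, alt="T") for i in (1, 2, 3)
        ])
        sp = identical_site_parallelism(tab, 3)
        assert sp.sites["multiplicity"].tolist() == [3]
        assert sp.n_k == {1: 1, 2: 1, 3: 1}

    def test_different_alt_alleles_split_sites(self):
        tab = MutationTable([
            make_record(pop="pop_1", pos=50, alt="T"),
            make_record(pop="pop_2", pos=50, alt="G"),
        ])
        sp = identical_site_parallelism(tab, 2)
        # brute-force grouping oracle on (contig, position, alt)
        groups = {}
        for r in tab.records:
            groups.setdefault((r.contig, r.position, r.alt_allele),
                              set()).add(r.population_id)
        assert sorted(len(v) for v in groups.values()) == [1, 1]
        assert sp.sites["multiplicity"].tolist() == [1, 1]
        # position-only mode merges them
        sp2 = identical_site_parallelism(tab, 2, match_alt=False)
        assert sp2.sites["multiplicity"].tolist() == [2]

    def test_empty_table_all_zero(self):
        sp = identical_site_parallelism(MutationTable([]), 3)
        assert sp.n_k == {1: 0, 2: 0, 3: 0}

    def test_more_populations_than_declared_rejected(self):
        tab = MutationTable([
            make_record(pop=f"pop_{i}", pos=10 + i) for i in range(4)
        ])
        with pytest.raises(ValueError):
            identical_site_parallelism(tab, 3)


class TestNucleotideNull:
    def test_expected_n1_approaches_total_mutations(self):
        r = nucleotide_null(10**7, [10, 10, 10], k=1, B=1000, seed=1)
        assert r.expected_n_k == pytest.approx(30, rel=1e-3)

    def test_expected_n2_closed_form_and_mc_agree(self):
        # frozen closed-form value for L=1000, n=(10,10,10)
        r = nucleotide_null(1000, [10, 10, 10], k=2, B=20_000, seed=2)
        assert r.expected_n_k == pytest.approx(0.2953, abs=2e-4)
        mc_se = r.simulated_n_k.std(ddof=1) / np.sqrt(r.n_simulations)
        assert abs(r.simulated_n_k.mean() - r.expected_n_k) < 3 * mc_se

    def test_observed_zero_gives_p_one(self):
        r = nucleotide_null(1000, [10, 10, 10], k=2, B=1000, seed=3,
                            observed_n_k=0)
        assert r.p_value == 1.0

    def test_k_larger_than_populations_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_null(1000, [10, 10], k=3)


class TestGeneMultiplicity:
    def test_length_ratio_scaling(self, toy_catalog):
        # all genes equal length: m_i = n_i
        tab = MutationTable([
            make_record(pos=p, genes=("g0",)) for p in (10, 20, 30, 40)
        ])
        gm = gene_multiplicity(tab, toy_catalog)
        row = gm.table.set_index("gene_id").loc["g0"]
        assert row["multiplicity"] == pytest.approx(4.0)

    def test_double_length_gene_halves_multiplicity(self):
        cat = GeneCatalog("t", 300, [Gene("long", "chr1", 1, 200),
                                     Gene("short", "chr1", 201, 300)])
        # Lbar = 150; long gene has L = 2 * 150 * (2/3)... direct: m = n * Lbar/L
        tab = MutationTable([
            make_record(pos=p, genes=("long",)) for p in (10, 20, 30)
        ])
        gm = gene_multiplicity(tab, cat)
        row = gm.table.set_index("gene_id").loc["long"]
        assert row["multiplicity"] == pytest.approx(3 * 150 / 200)

    def test_even_spread_on_equal_genes_has_zero_excess(self, toy_catalog):
        tab = MutationTable([
            make_record(pos=g.start + 5, genes=(g.gene_id,))
            for g in toy_catalog
        ])
        gm = gene_multiplicity(tab, toy_catalog)
        assert gm.delta_ll_total == pytest.approx(0.0, abs=1e-12)

    def test_excess_equals_scaled_kl_divergence(self, toy_catalog):
        rng = np.random.default_rng(5)
        records, pos = [], 1
        counts = rng.integers(0, 6, size=10)
        for g, c in zip(toy_catalog, counts):
            for j in range(c):
                records.append(make_record(pos=g.start + j,
                                           genes=(g.gene_id,)))
        gm = gene_multiplicity(MutationTable(records), toy_catalog)
        n = counts.astype(float)
        p_hat = n / n.sum()
        p0 = toy_catalog.lengths / toy_catalog.lengths.sum()
        kl = np.sum(p_hat[n > 0] * np.log(p_hat[n > 0] / p0[n > 0]))
        assert gm.delta_ll_total == pytest.approx(n.sum() * kl)
        assert gm.delta_ll_total >= 0

    def test_intergenic_records_excluded(self, toy_catalog):
        tab = MutationTable([make_record(pos=10, genes=()),
                             make_record(pos=20, genes=("g0",))])
        gm = gene_multiplicity(tab, toy_catalog)
        assert gm.n_tot == 1

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            gene_multiplicity(MutationTable([]), GeneCatalog("e", 100, []))


class TestGenePvalues:
    @pytest.fixture
    def gm_toy(self, toy_catalog):
        tab = MutationTable([
            make_record(pos=5 + j, genes=("g0",)) for j in range(2)
        ])
        return gene_multiplicity(tab, toy_catalog)

    def test_zero_count_gene_has_p_one(self, gm_toy):
        out = gene_pvalues(gm_toy, method="poisson")
        t = out.table.set_index("gene_id")
        assert t.loc["g5", "p_value"] == pytest.approx(1.0)

    def test_poisson_tail_value(self, toy_catalog):
        # 5 mutations over 10 equal genes: lambda_i = 0.5;
        # P(N >= 2) = 1 - e^-0.5 (1 + 0.5) = 0.09020, frozen from the
        # direct tail sum 1 - pmf(0) - pmf(1)
        records = [make_record(pos=5 + j, genes=("g0",)) for j in range(2)]
        records += [make_record(pos=101 + j, genes=("g1",)) for j in range(3)]
        gm = gene_multiplicity(MutationTable(records), toy_catalog)
        out = gene_pvalues(gm, method="poisson")
        t = out.table.set_index("gene_id")
        direct = 1 - stats.poisson.pmf(0, 0.5) - stats.poisson.pmf(1, 0.5)
        assert t.loc["g0", "p_value"] == pytest.approx(0.090204, abs=1e-6)
        assert t.loc["g0", "p_value"] == pytest.approx(direct)

    def test_montecarlo_matches_poisson_on_toy(self):
        # mutations concentrated in short genes (the parallel-evolution
        # signal): their placement probability is small, the regime where
        # the Poisson tail approximates the fixed-total placement null
        genes, pos = [], 1
        for i in range(50):
            L = 40 if i < 10 else 1000
            genes.append(Gene(f"g{i:02d}", "chr1", pos, pos + L - 1))
            pos += L + 10
        cat = GeneCatalog("toy50", pos, genes)
        counts = [3, 2, 2, 1, 1, 1, 1, 1, 0, 0] + [0] * 40
        records = []
        for g, c in zip(cat, counts):
            for j in range(c):
                records.append(make_record(pos=g.start + j,
                                           genes=(g.gene_id,)))
        gm = gene_multiplicity(MutationTable(records), cat)
        pois = gene_pvalues(gm, method="poisson").table["p_value"].to_numpy()
        B = 100_000
        mc = gene_pvalues(gm, method="montecarlo", B=B,
                          seed=1).table["p_value"].to_numpy()
        se = np.sqrt(np.maximum(mc * (1 - mc), 1e-12) / B) + 1.0 / B
        assert np.all(np.abs(mc - pois) < 3 * se)

    def test_unknown_method_rejected(self, gm_toy):
        with pytest.raises(ValueError):
            gene_pvalues(gm_toy, method="bootstrap")


class TestFdrCriticalP:
    def test_all_p_one_flags_nothing(self):
        null = np.ones((50, 5))
        p_star, mask = fdr_critical_p(np.ones(5), null, fdr=0.05)
        assert p_star == 0.0 and not mask.any()

    def test_planted_small_p_values_recovered(self):
        rng = np.random.default_rng(11)
        observed = np.array([1e-6, 1e-6, 0.3, 0.6, 0.9])
        # null ensemble whose smallest p-values hover around 0.02
        null = 0.02 + 0.98 * rng.random((200, 5))
        p_star, mask = fdr_critical_p(observed, null, fdr=0.05)
        # brute-force threshold scan oracle
        best = 0.0
        for t in np.unique(observed):
            est = (null <= t).sum(axis=1).mean() / max(
                1, (observed <= t).sum())
            if est < 0.05:
                best = max(best, t)
        assert p_star == pytest.approx(best)
        assert mask.tolist() == [True, True, False, False, False]

    def test_permissive_fdr_flags_everything_below_one(self):
        rng = np.random.default_rng(13)
        observed = rng.random(20)
        null = rng.random((100, 20))
        _, mask = fdr_critical_p(observed, null, fdr=1 - 1e-9)
        assert mask.sum() == (observed < 1).sum()

    def test_invalid_fdr_rejected(self):
        with pytest.raises(ValueError):
            fdr_critical_p(np.array([0.5]), np.ones((10, 1)), fdr=0.0)


class TestScanRecovery:
    def test_enriched_genes_detected_null_genes_spared(self):
        from coevo.simulate import MutationSimSpec, simulate_genome, simulate_mutations

        spec = MutationSimSpec(
            genome_length=1_000_000, n_genes=1000, gene_length_mean=900,
            n_mut_per_pop=100, seed=17, enrichment=50.0,
            target_genes=tuple(f"gene_{i:04d}" for i in range(1, 11)),
        )
        cat = simulate_genome(spec)
        tab = simulate_mutations(cat, spec)
        scan = parallel_evolution_scan(tab, cat, fdr=0.05, B_null=500, seed=1)
        t = scan.table.set_index("gene_id")
        targets = list(spec.target_genes)
        assert t.loc[targets, "significant"].mean() >= 0.8
        assert t.drop(targets)["significant"].sum() <= 5
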