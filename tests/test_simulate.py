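"""Generators: determinism, null uniformity, planted-effect construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coevo.simulate import (
    CommunitySimSpec,
    EffectSpec,
    MutationSimSpec,
    simulate_community,
    simulate_genome,
    simulate_mutations,
)


class TestGenome:
    def test_equal_lengths_give_mean(self):
        spec = MutationSimSpec(genome_length=2000, n_genes=10,
                               gene_length_mean=100, gene_length_shape=1e9,
                               seed=1)
        cat = simulate_genome(spec)
        assert len(cat) == 10
        assert cat.mean_length == pytest.approx(100)
        # non-overlapping, ordered placement
        genes = sorted(cat.genes, key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            assert a.end < b.start

    def test_deterministic_under_seed(self):
        spec = MutationSimSpec(genome_length=50_000, n_genes=30, seed=9)
        a = simulate_genome(spec).to_frame()
        b = simulate_genome(spec).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_genes_that_do_not_fit_error(self):
        spec = MutationSimSpec(genome_length=500, n_genes=10,
                               gene_length_mean=100, gene_length_shape=1e9,
                               seed=1)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_genome(spec)


class TestMutations:
    def test_uniform_null_is_length_proportional(self):
        spec = MutationSimSpec(genome_length=10_000, n_genes=10,
                               gene_length_mean=500, n_mut_per_pop=4000,
                               n_populations=1, seed=3)
        cat = simulate_genome(spec)
        # sample positions directly (no per-population collapse) at large n
        from coevo.simulate import _mutation_site_sampler

        draw = _mutation_site_sampler(cat, spec)
        pos = draw(200_000, np.random.default_rng(4))
        for g in list(cat)[:5]:
            frac = np.mean((pos >= g.start) & (pos <= g.end))
            assert frac == pytest.approx(g.length / cat.genome_length,
                                         rel=0.08)

    def test_enrichment_matches_closed_form_and_mc_oracle(self, toy_catalog):
        # one of ten equal genes covering the genome, weighted x20:
        # expected target share = 20 / (20 + 9)
        spec = MutationSimSpec(genome_length=1000, n_genes=10,
                               target_genes=("g0",), enrichment=20.0, seed=5)
        from coevo.simulate import _mutation_site_sampler

        draw = _mutation_site_sampler(toy_catalog, spec)
        pos = draw(100_000, np.random.default_rng(6))
        share = np.mean(pos <= 100)
        expected = 20.0 / 29.0
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(share - expected) < 4 * se

    def test_zero_mutations_gives_empty_table(self, toy_catalog):
        spec = MutationSimSpec(n_mut_per_pop=0, genome_length=1000,
                               n_genes=10, seed=1)
        assert len(simulate_mutations(toy_catalog, spec)) == 0

    def test_same_site_hits_collapse_within_population(self):
        spec = MutationSimSpec(genome_length=40, n_genes=1,
                               gene_length_mean=30, n_mut_per_pop=200,
                               n_populations=1, seed=2)
        cat = simulate_genome(spec)
        tab = simulate_mutations(cat, spec)
        keys = [(r.population_id, r.position) for r in tab.records]
        assert len(keys) == len(set(keys))
        assert len(tab) <= 40

    def test_deterministic_under_seed(self, toy_catalog):
        spec = MutationSimSpec(genome_length=1000, n_genes=10,
                               n_mut_per_pop=30, seed=11)
        a = simulate_mutations(toy_catalog, spec).to_frame()
        b = simulate_mutations(toy_catalog, spec).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_null_passes_chisq_goodness_of_fit(self):
        """Under theta=1, per-gene counts fit length-proportional
        expectations in nearly all seeds (alpha=0.01)."""
        spec0 = MutationSimSpec(genome_length=100_000, n_genes=20,
                                gene_length_mean=4000, n_mut_per_pop=400,
                                n_populations=1, seed=0)
        cat = simulate_genome(spec0)
        from coevo.simulate import _mutation_site_sampler

        probs = np.append(
            cat.lengths / cat.genome_length,
            1 - cat.lengths.sum() / cat.genome_length,
        )
        starts = np.array([g.start for g in cat])
        ends = np.array([g.end for g in cat])
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            draw = _mutation_site_sampler(cat, spec0)
            pos = draw(2000, np.random.default_rng(1000 + seed))
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
            gene_counts = np.bincount(idx[inside], minlength=20)
            obs = np.append(gene_counts, (~inside).sum())
            p = stats.chisquare(obs, 2000 * probs).pvalue
            rejections += p < 0.01
        assert rejections <= 2  # >= 98/100 seeds pass


class TestCommunity:
    def test_no_effects_means_equal_across_treatments(self):
        spec = CommunitySimSpec(n_taxa=2, genes_per_taxon=200,
                                libsize_sdlog=0.0, dispersion_mean=0.02,
                                seed=21)
        em = simulate_community(spec)
        pred = em.sample_meta["predation"]
        a = em.counts.loc[:, pred[pred].index].to_numpy().mean()
        b = em.counts.loc[:, pred[~pred].index].to_numpy().mean()
        assert a == pytest.approx(b, rel=0.05)

    def test_abundance_shift_scales_only_that_taxon(self):
        spec = CommunitySimSpec(
            n_taxa=2, genes_per_taxon=300, libsize_sdlog=0.0,
            dispersion_mean=1e-12, seed=22,
            abundance_shift={"taxon_1": ("predation", 2.0)},
        )
        em = simulate_community(spec)
        pred = em.sample_meta["predation"]
        totals = em.taxon_totals()
        on = totals.loc[:, pred[pred].index].mean(axis=1)
        off = totals.loc[:, pred[~pred].index].mean(axis=1)
        # taxon_1 doubles relative to taxon_2: shares go 1/2 -> 2/3 vs 1/3
        ratio = (on / off)
        assert (ratio["taxon_1"] / ratio["taxon_2"]) == pytest.approx(
            2.0, rel=0.05)

    def test_interaction_effect_reaches_planted_fold_change(self):
        genes = tuple(f"taxon_1:g{i + 1:04d}" for i in range(50))
        means = []
        for seed in range(30):
            spec = CommunitySimSpec(
                n_taxa=2, genes_per_taxon=60, libsize_sdlog=0.0,
                dispersion_mean=0.05, seed=seed,
                effects=(EffectSpec(genes, "interaction", 3.0),),
            )
            em = simulate_community(spec)
            meta = em.sample_meta
            cell = meta.index[meta["predation"] & meta["coevolved_prey"]]
            rest = meta.index.difference(cell)
            sub = em.counts.loc[list(genes)]
            means.append(
                sub[cell].to_numpy().mean() / sub[rest].to_numpy().mean()
            )
        assert np.mean(means) == pytest.approx(8.0, rel=0.1)

    def test_nb_mean_variance_relation(self):
        spec = CommunitySimSpec(n_taxa=1, genes_per_taxon=2000,
                                n_replicates=100, libsize_sdlog=0.0,
                                dispersion_shape=1e9, dispersion_mean=0.1,
                                seed=23)
        em = simulate_community(spec)
        mu = em.counts.mean(axis=1)
        var = em.counts.var(axis=1, ddof=1)
        high = mu > 200
        ratio = (var[high] / (mu[high] + 0.1 * mu[high] ** 2)).median()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_relabund_tracks_abundance_and_is_compositional(self):
        spec = CommunitySimSpec(n_taxa=3, genes_per_taxon=50, seed=24,
                                abundance_shift={"taxon_2": ("coevolution", 4.0)})
        em = simulate_community(spec)
        np.testing.assert_allclose(em.taxon_relabund.sum(axis=0), 1.0,
                                   atol=1e-9)
        coev = em.sample_meta["coevolved_prey"]
        on = em.taxon_relabund.loc["taxon_2", coev[coev].index].mean()
        off = em.taxon_relabund.loc["taxon_2", coev[~coev].index].mean()
        assert on > 2 * off

    def test_deterministic_under_seed(self):
        spec = CommunitySimSpec(n_taxa=2, genes_per_taxon=40, seed=31)
        a = simulate_community(spec)
        b = simulate_community(spec)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.taxon_relabund, b.taxon_relabund)

    def test_bad_abundance_shift_rejected(self):
        with pytest.raises(ValueError):
            CommunitySimSpec(abundance_shift={"taxon_1": ("weather", 2.0)})
        with pytest.raises(ValueError):
            CommunitySimSpec(abundance_shift={"taxon_1": ("predation", -1.0)})
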