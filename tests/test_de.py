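"""NB differential expression: dispersions, GLM, shrinkage, rlog, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coevo.de import (
    NegativeBinomialDE,
    _posterior_mode,
    estimate_dispersions,
    hypergeom_enrichment,
    library_size_factors,
    rlog_transform,
    select_top_variable,
    shrink_lfc,
)
from coevo.normalization import within_taxon_size_factors
from coevo.simulate import CommunitySimSpec, EffectSpec, simulate_community
from coevo.types import PathwayMap


@pytest.fixture(scope="module")
def null_community():
    spec = CommunitySimSpec(n_taxa=2, genes_per_taxon=300, seed=101)
    return simulate_community(spec)


class TestDispersions:
    def test_poisson_genes_stay_at_or_below_trend(self):
        spec = CommunitySimSpec(n_taxa=1, genes_per_taxon=500,
                                dispersion_shape=1e12, dispersion_mean=1e-12,
                                libsize_sdlog=0.0, seed=5)
        em = simulate_community(spec)
        sf = within_taxon_size_factors(em)
        phi = estimate_dispersions(em, sf)
        # Poisson data: dispersion estimates collapse toward ~0 trend
        assert phi.median() < 0.02

    def test_constant_gene_has_zero_raw_dispersion(self, toy_expression):
        sf = within_taxon_size_factors(toy_expression)
        norm = sf.normalize(toy_expression)
        # the equal-totals taxon-B gene is constant after normalization
        phi = estimate_dispersions(toy_expression, sf,
                                   group_by=())
        assert norm.loc["tB:g1"].nunique() == 1
        # final value equals the trend (no upward pull from the data)
        assert phi.loc["tB:g1"] > 0  # trend floor, not a raw estimate

    def test_nb_dispersion_recovered_at_high_counts(self):
        spec = CommunitySimSpec(n_taxa=2, genes_per_taxon=1000,
                                dispersion_shape=1e12, dispersion_mean=0.1,
                                baseline_sdlog=0.3, seed=6)
        em = simulate_community(spec)
        sf = within_taxon_size_factors(em)
        phi = estimate_dispersions(em, sf)
        high = em.counts.mean(axis=1) > 50
        assert 0.05 <= phi[high].median() <= 0.2

    def test_too_few_samples_instructs_pooling(self):
        spec = CommunitySimSpec(n_taxa=1, genes_per_taxon=20,
                                n_replicates=1, seed=7)
        em = simulate_community(spec)
        sf = within_taxon_size_factors(em)
        with pytest.raises(ValueError, match="pool"):
            estimate_dispersions(em, sf)


class TestNBFit:
    def test_null_wald_pvalues_are_uniform(self, null_community):
        est = NegativeBinomialDE(shrink=False).fit(null_community)
        p = est.results_["p_value"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").statistic < 0.05

    def test_interaction_lfc_recovered(self):
        # planted genes kept a small share of each taxon's reads: sum
        # scaling assumes most of the taxon's transcriptome is unchanged
        planted = tuple(f"taxon_{t}:g{i + 1:04d}"
                        for t in (1, 2) for i in range(10))
        spec = CommunitySimSpec(
            n_taxa=2, genes_per_taxon=500, seed=15,
            effects=(EffectSpec(planted, "interaction", 3.0),),
        )
        em = simulate_community(spec)
        est = NegativeBinomialDE().fit(em)
        res = est.results_.set_index("gene_id").loc[list(planted)]
        assert res["lfc_mle"].median() == pytest.approx(3.0, abs=0.5)
        # heavy-tailed prior keeps strong signals nearly unshrunk
        assert res["lfc_shrunk"].median() > 2.0

    def test_abundance_confound_not_flagged_with_wtss(self):
        spec = CommunitySimSpec(
            n_taxa=2, genes_per_taxon=150, seed=16,
            abundance_shift={"taxon_1": ("predation", 4.0)},
        )
        em = simulate_community(spec)
        wtss = NegativeBinomialDE(contrast="predation").fit(em)
        t1 = wtss.results_[wtss.results_["taxon"] == "taxon_1"]
        assert (t1["padj"] < 0.1).sum() == 0
        naive = NegativeBinomialDE(contrast="predation",
                                   normalization="library",
                                   abundance_covariate=False).fit(em)
        n1 = naive.results_[naive.results_["taxon"] == "taxon_1"]
        assert (n1["padj"] < 0.1).sum() >= 1

    def test_bh_adjustment_is_monotone(self, null_community):
        est = NegativeBinomialDE(shrink=False).fit(null_community)
        res = est.results_.dropna(subset=["p_value"]).sort_values("p_value")
        assert res["padj"].is_monotonic_increasing
        assert (res["padj"] >= res["p_value"] - 1e-12).all()

    def test_rank_deficient_design_names_aliased_column(self, null_community):
        # "day" is constant within this design, aliasing the intercept
        est = NegativeBinomialDE(design=("predation", "day"),
                                 contrast="predation")
        with pytest.raises(ValueError, match="aliased.*day"):
            est.fit(null_community)

    def test_unknown_contrast_rejected(self, null_community):
        with pytest.raises(ValueError, match="contrast"):
            NegativeBinomialDE(contrast="moon_phase").fit(null_community)

    def test_sklearn_param_interface(self):
        est = NegativeBinomialDE()
        params = est.get_params()
        assert params["alpha"] == 0.1 and params["lfc_threshold"] == 2.0
        est.set_params(alpha=0.05)
        assert est.alpha == 0.05
        with pytest.raises(ValueError):
            est.set_params(bogus=1)


class TestShrinkage:
    def test_strong_signal_nearly_unshrunk(self):
        assert _posterior_mode(5.0, 0.2, 0.5) == pytest.approx(5.0, abs=0.05)

    def test_zero_estimate_stays_zero(self):
        assert _posterior_mode(0.0, 0.5, 0.5) == 0.0

    def test_mode_matches_grid_search_oracle(self):
        for lfc, se, scale in [(2.0, 0.7, 0.3), (-1.5, 0.4, 0.2),
                               (0.8, 0.8, 1.0)]:
            grid = np.linspace(min(0, lfc), max(0, lfc), 2_000_001)
            nlp = 0.5 * (grid - lfc) ** 2 / se**2 + np.log1p(
                (grid / scale) ** 2)
            oracle = grid[np.argmin(nlp)]
            assert _posterior_mode(lfc, se, scale) == pytest.approx(
                oracle, abs=1e-6)

    def test_all_null_lfcs_floor_the_prior_scale(self, caplog):
        from coevo.de import DEResult

        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(20)],
             "taxon": "t", "baseMean": 50.0,
             "lfc_mle": np.zeros(20), "lfc_se": np.full(20, 0.5),
             "p_value": np.ones(20), "tested": True, "padj": np.ones(20),
             "lfc_shrunk": np.zeros(20), "de": False}
        )
        de = DEResult(results=df, design=("predation",), contrast="predation")
        out = shrink_lfc(de)
        assert np.allclose(out.results["lfc_shrunk"], 0.0)


class TestRlog:
    def test_zero_dispersion_is_identity_on_shifted_log(self, toy_expression):
        sf = within_taxon_size_factors(toy_expression)
        phi = pd.Series(0.0, index=toy_expression.counts.index)
        rlog = rlog_transform(toy_expression, sf, phi)
        y = np.log2((toy_expression.counts + 0.5) /
                    sf.for_genes(toy_expression.gene_taxon))
        pd.testing.assert_frame_equal(rlog, y)

    def test_constant_gene_is_constant(self, toy_expression):
        sf = within_taxon_size_factors(toy_expression)
        phi = pd.Series(0.5, index=toy_expression.counts.index)
        rlog = rlog_transform(toy_expression, sf, phi)
        # taxon B: equal counts, unit factors -> rlog == log2(100.5)
        np.testing.assert_allclose(rlog.loc["tB:g1"],
                                   np.log2(100.5), atol=1e-12)

    def test_shrinkage_never_inflates_variance(self):
        spec = CommunitySimSpec(n_taxa=2, genes_per_taxon=200, seed=18)
        em = simulate_community(spec)
        sf = within_taxon_size_factors(em)
        phi = estimate_dispersions(em, sf)
        rlog = rlog_transform(em, sf, phi)
        y = np.log2((em.counts + 0.5) / sf.for_genes(em.gene_taxon))
        assert (rlog.var(axis=1) <= y.var(axis=1) + 1e-12).all()

    def test_low_dispersion_genes_keep_their_signal(self, toy_expression):
        sf = within_taxon_size_factors(toy_expression)
        phi = pd.Series(0.01, index=toy_expression.counts.index)
        rlog = rlog_transform(toy_expression, sf, phi)
        y = np.log2((toy_expression.counts + 0.5) /
                    sf.for_genes(toy_expression.gene_taxon))
        dev = (rlog - y).abs().to_numpy().max()
        spread = (y.sub(y.mean(axis=1), axis=0)).abs().to_numpy().max()
        assert dev <= 0.06 * spread


class TestTopVariable:
    def test_exact_count_selected(self):
        rng = np.random.default_rng(21)
        rlog = pd.DataFrame(rng.normal(size=(200, 6)),
                            index=[f"t:g{i:03d}" for i in range(200)])
        gt = pd.Series("t", index=rlog.index)
        top = select_top_variable(rlog, gt, n=50)
        assert len(top["t"]) == 50
        var = rlog.var(axis=1)
        assert set(top["t"]) == set(var.nlargest(50).index)

    def test_constant_genes_rank_last(self):
        rlog = pd.DataFrame(
            {"s1": [1.0, 5.0], "s2": [2.0, 5.0]}, index=["t:g1", "t:g2"]
        )
        gt = pd.Series("t", index=rlog.index)
        assert select_top_variable(rlog, gt, n=1)["t"] == ["t:g1"]

    def test_sample_order_does_not_matter(self):
        rng = np.random.default_rng(22)
        rlog = pd.DataFrame(rng.normal(size=(50, 8)),
                            index=[f"t:g{i:02d}" for i in range(50)])
        gt = pd.Series("t", index=rlog.index)
        a = select_top_variable(rlog, gt, n=10)
        b = select_top_variable(rlog[rlog.columns[::-1]], gt, n=10)
        assert a == b

    def test_small_taxon_selects_all_with_warning(self, caplog):
        rlog = pd.DataFrame(np.ones((3, 4)),
                            index=["t:g1", "t:g2", "t:g3"])
        gt = pd.Series("t", index=rlog.index)
        with caplog.at_level("WARNING"):
            top = select_top_variable(rlog, gt, n=500)
        assert len(top["t"]) == 3
        assert any("500" in r.message for r in caplog.records)


class TestEnrichment:
    def test_exact_tail_probability(self):
        # N=10, K=5, n=4, x=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        pathway = PathwayMap({"p1": {f"g{i}" for i in range(5)}})
        de = {"g0", "g1", "g2", "g3"}
        out = hypergeom_enrichment(de, universe, pathway)
        assert out.loc[0, "p_value"] == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_hits_give_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        pathway = PathwayMap({"p1": {"g8", "g9"}})
        out = hypergeom_enrichment({"g0", "g1"}, universe, pathway)
        assert out.loc[0, "hits"] == 0
        # survival at 0 covers the whole distribution
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_pathway_equal_to_universe_is_never_enriched(self):
        universe = {f"g{i}" for i in range(10)}
        pathway = PathwayMap({"p1": set(universe)})
        out = hypergeom_enrichment({"g0", "g1", "g2"}, universe, pathway)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(set(), set(), PathwayMap({}))
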