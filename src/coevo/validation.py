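"""Reproducible validation experiments for the pipeline's statistics.

Each function runs a self-contained simulation experiment at the study's
default conditions and returns the measured quantities.  They are used by
the acceptance checks and by ``scripts/acceptance.py``; problem sizes are
chosen so the whole battery runs in a few minutes on one CPU (see
docs/methods.md for the rationale behind each condition).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .simulate import (
    CommunitySimSpec,
    EffectSpec,
    MutationSimSpec,
    simulate_community,
    simulate_genome,
    simulate_mutations,
)

__all__ = [
    "parallelism_null_fdp",
    "parallelism_power",
    "poisson_mc_agreement",
    "expected_nk_agreement",
    "likelihood_excess",
    "confound_cancellation",
    "de_null_calibration",
    "de_interaction_recovery",
    "distatis_exactness",
    "permanova_toy",
    "hypergeom_toy",
    "kl_selection_rate",
    "pipeline_determinism",
]


# ---------------------------------------------------------------------------
# Parallel evolution
# ---------------------------------------------------------------------------

def parallelism_null_fdp(n_datasets: int = 200, n_genes: int = 1000,
                         n_populations: int = 3, n_per_pop: int = 50,
                         fdr: float = 0.05, B_null: int = 400,
                         seed: int = 0) -> dict:
    """Realized false-discovery proportion of the critical-p procedure on
    null datasets (uniform mutation placement; every discovery is false)."""
    from .parallelism import (
        fdr_critical_p,
        gene_multiplicity,
        gene_pvalues,
        simulate_null_pvalues,
    )

    spec0 = MutationSimSpec(
        genome_length=1_000_000, n_genes=n_genes, gene_length_mean=900,
        n_populations=n_populations, n_mut_per_pop=n_per_pop, seed=seed,
    )
    catalog = simulate_genome(spec0)
    fdp = []
    for i in range(n_datasets):
        spec = MutationSimSpec(**{**spec0.__dict__, "seed": seed + 1 + i})
        table = simulate_mutations(catalog, spec)
        gm = gene_pvalues(gene_multiplicity(table, catalog))
        null_p = simulate_null_pvalues(catalog, gm.n_tot, B=B_null,
                                       seed=seed + 10_000 + i)
        _, mask = fdr_critical_p(gm.table["p_value"].to_numpy(), null_p,
                                 fdr=fdr)
        n_disc = int(mask.sum())
        fdp.append(n_disc / max(1, n_disc))  # all discoveries are false
    fdp = np.asarray(fdp, dtype=float)
    mc_se = fdp.std(ddof=1) / np.sqrt(n_datasets) if n_datasets > 1 else 0.0
    return {"mean_fdp": float(fdp.mean()), "mc_se": float(mc_se),
            "bound": fdr + 2 * mc_se, "n_datasets": n_datasets}


def parallelism_power(n_seeds: int = 50, enrichment: float = 20.0,
                      n_targets: int = 10, n_genes: int = 1000,
                      n_per_pop: int = 100, fdr: float = 0.05,
                      B_null: int = 400, seed: int = 0) -> dict:
    """Fraction of mutation-enriched target genes flagged by the scan."""
    from .parallelism import parallel_evolution_scan

    rng = np.random.default_rng(seed)
    powers = []
    for i in range(n_seeds):
        targets = tuple(
            f"gene_{j:04d}"
            for j in rng.choice(np.arange(1, n_genes + 1), n_targets,
                                replace=False)
        )
        spec = MutationSimSpec(
            genome_length=1_000_000, n_genes=n_genes, gene_length_mean=900,
            n_mut_per_pop=n_per_pop, enrichment=enrichment,
            target_genes=targets, seed=seed + 1 + i,
        )
        catalog = simulate_genome(spec)
        table = simulate_mutations(catalog, spec)
        scan = parallel_evolution_scan(table, catalog, fdr=fdr,
                                       B_null=B_null, seed=seed + 5000 + i)
        t = scan.table.set_index("gene_id")
        powers.append(float(t.loc[list(targets), "significant"].mean()))
    return {"mean_power": float(np.mean(powers)), "n_seeds": n_seeds}


def _sparse_fifty_gene_toy():
    """Fixed 50-gene toy with mutations concentrated in short genes, the
    regime where the Poisson tail approximates the placement null."""
    from .types import Gene, GeneCatalog, MutationRecord, MutationTable

    genes, pos = [], 1
    for i in range(50):
        L = 40 if i < 10 else 1000
        genes.append(Gene(f"g{i:02d}", "chr1", pos, pos + L - 1))
        pos += L + 10
    catalog = GeneCatalog("toy50", pos, genes)
    counts = [3, 2, 2, 1, 1, 1, 1, 1, 0, 0] + [0] * 40
    records = [
        MutationRecord("pop_1", "chr1", g.start + j, "A", "T", 0.5,
                       "substitution", (g.gene_id,))
        for g, c in zip(catalog, counts) for j in range(c)
    ]
    return catalog, MutationTable(records)


def poisson_mc_agreement(B: int = 100_000, seed: int = 0) -> dict:
    """Poisson-tail vs Monte-Carlo gene p-values on the 50-gene toy."""
    from .parallelism import gene_multiplicity, gene_pvalues

    catalog, table = _sparse_fifty_gene_toy()
    gm = gene_multiplicity(table, catalog)
    pois = gene_pvalues(gm, method="poisson").table["p_value"].to_numpy()
    mc = gene_pvalues(gm, method="montecarlo", B=B,
                      seed=seed).table["p_value"].to_numpy()
    se = np.sqrt(np.maximum(mc * (1 - mc), 1e-12) / B) + 1.0 / B
    excess = np.abs(mc - pois) / (3 * se)
    return {"max_diff": float(np.abs(mc - pois).max()),
            "max_diff_over_3se": float(excess.max()), "B": B}


def expected_nk_agreement(B: int = 100_000, seed: int = 0) -> dict:
    """Closed-form E[N_2] for L=1000, n=(10,10,10) vs Monte-Carlo."""
    from .parallelism import nucleotide_null

    res = nucleotide_null(1000, [10, 10, 10], k=2, B=B, seed=seed)
    mc_mean = float(res.simulated_n_k.mean())
    mc_se = float(res.simulated_n_k.std(ddof=1) / np.sqrt(B))
    return {"closed_form": float(res.expected_n_k), "mc_mean": mc_mean,
            "mc_se": mc_se,
            "diff_over_3se": abs(mc_mean - res.expected_n_k) / (3 * mc_se)}


def likelihood_excess(n_instances: int = 1000, seed: int = 0) -> dict:
    """Delta-ll = n_tot * KL(p_hat || p0) over random instances (always >= 0)
    and on a perfectly length-proportional instance (exactly 0)."""
    from .parallelism import gene_multiplicity
    from .types import Gene, GeneCatalog, MutationRecord, MutationTable

    rng = np.random.default_rng(seed)
    min_excess = np.inf
    genes = [Gene(f"g{i}", "chr1", i * 100 + 1, (i + 1) * 100)
             for i in range(20)]
    catalog = GeneCatalog("toy", 2000, genes)
    for _ in range(n_instances):
        counts = rng.integers(0, 5, size=20)
        if counts.sum() == 0:
            counts[0] = 1
        records = [
            MutationRecord("pop_1", "chr1", g.start + j, "A", "T", 0.5,
                           "substitution", (g.gene_id,))
            for g, c in zip(catalog, counts) for j in range(c)
        ]
        gm = gene_multiplicity(MutationTable(records), catalog)
        min_excess = min(min_excess, gm.delta_ll_total)
    # proportional instance: equal lengths, equal counts
    records = [
        MutationRecord("pop_1", "chr1", g.start + j, "A", "T", 0.5,
                       "substitution", (g.gene_id,))
        for g in catalog for j in range(3)
    ]
    gm0 = gene_multiplicity(MutationTable(records), catalog)
    return {"min_excess": float(min_excess),
            "proportional_excess": float(abs(gm0.delta_ll_total)),
            "n_instances": n_instances}


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def confound_cancellation(n_seeds: int = 20, fold: float = 4.0,
                          seed: int = 0) -> dict:
    """A taxon's abundance shifts ``fold``-x with predation while relative
    expression is constant: WTSS + abundance covariate should flag none of
    its genes at padj < 0.1; naive library-size normalization flags some."""
    from .de import NegativeBinomialDE

    wtss_flags, naive_flags = [], []
    for i in range(n_seeds):
        spec = CommunitySimSpec(
            n_taxa=2, genes_per_taxon=100, seed=seed + i,
            abundance_shift={"taxon_1": ("predation", fold)},
        )
        em = simulate_community(spec)
        wtss = NegativeBinomialDE(contrast="predation", shrink=False).fit(em)
        t = wtss.results_
        wtss_flags.append(
            int(((t["taxon"] == "taxon_1") & (t["padj"] < 0.1)).sum()))
        naive = NegativeBinomialDE(contrast="predation", shrink=False,
                                   normalization="library",
                                   abundance_covariate=False).fit(em)
        t = naive.results_
        naive_flags.append(
            int(((t["taxon"] == "taxon_1") & (t["padj"] < 0.1)).sum()))
    return {"wtss_max_flags": int(max(wtss_flags)),
            "wtss_total_flags": int(sum(wtss_flags)),
            "naive_min_flags": int(min(naive_flags)),
            "n_seeds": n_seeds}


def de_null_calibration(n_genes: int = 2000, seed: int = 0) -> dict:
    """Kolmogorov distance of null Wald p-values from uniform."""
    from .de import NegativeBinomialDE

    spec = CommunitySimSpec(n_taxa=4, genes_per_taxon=n_genes // 4, seed=seed)
    em = simulate_community(spec)
    est = NegativeBinomialDE(shrink=False).fit(em)
    p = est.results_["p_value"].dropna().to_numpy()
    return {"ks_distance": float(stats.kstest(p, "uniform").statistic),
            "n_genes": len(p)}


def de_interaction_recovery(lfc: float = 3.0, n_planted: int = 200,
                            seed: int = 0) -> dict:
    """Median estimated LFC over planted interaction-effect genes.

    Planted genes are a small share (~2.5 %) of each taxon's reads: sum
    scaling assumes the bulk of a taxon's transcriptome is unchanged.
    """
    from .de import NegativeBinomialDE

    n_taxa = 8
    per_taxon = n_planted // n_taxa
    planted = tuple(f"taxon_{t}:g{i + 1:04d}"
                    for t in range(1, n_taxa + 1) for i in range(per_taxon))
    spec = CommunitySimSpec(
        n_taxa=n_taxa, genes_per_taxon=1000, seed=seed,
        effects=(EffectSpec(planted, "interaction", lfc),),
    )
    em = simulate_community(spec)
    est = NegativeBinomialDE(shrink=False).fit(em)
    res = est.results_.set_index("gene_id").loc[list(planted)]
    return {"median_lfc": float(res["lfc_mle"].median()),
            "planted_lfc": lfc, "n_planted": len(planted)}


# ---------------------------------------------------------------------------
# DiSTATIS and downstream tests
# ---------------------------------------------------------------------------

def distatis_exactness(n_samples: int = 10, K: int = 5, seed: int = 0) -> dict:
    """Identical tables: reduction to classical MDS, equal weights, and the
    barycentric identity on perturbed tables."""
    from scipy.spatial.distance import pdist, squareform

    from .distatis import Distatis, cross_product

    rng = np.random.default_rng(seed)
    D = squareform(pdist(rng.normal(size=(n_samples, 6))))
    model = Distatis().fit([D] * K)
    # classical MDS of the normalized table: eigendecomposition oracle
    S = cross_product(D)
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-9
    F_mds = vecs[:, keep] * np.sqrt(vals[keep])
    k = model.factor_scores_.shape[1]
    mds_dev = float(np.abs(np.abs(model.factor_scores_)
                           - np.abs(F_mds[:, :k])).max())
    alpha_dev = float(np.abs(model.alpha_ - 1.0 / K).max())

    tables = [D + 0.1 * squareform(pdist(rng.normal(size=(n_samples, 6))))
              for _ in range(K)]
    m2 = Distatis().fit(tables)
    bar = sum(a * P for a, P in zip(m2.alpha_, m2.partial_scores_))
    bary_dev = float(np.abs(bar - m2.factor_scores_).max())
    return {"mds_max_dev": mds_dev, "alpha_max_dev": alpha_dev,
            "barycentric_max_dev": bary_dev}


def permanova_toy() -> dict:
    """Exhaustive-enumeration p on the 6-sample, 2-group toy (2/20)."""
    from .permtests import permanova

    pts = np.array([[0, 0], [0.3, 0], [0, 0.3],
                    [10, 10], [10.3, 10], [10, 10.3]], dtype=float)
    res = permanova(pts, ["a"] * 3 + ["b"] * 3, permutations="exhaustive")
    return {"p_value": res.p_value, "n_permutations": res.n_permutations,
            "pseudo_F": res.statistic}


def hypergeom_toy() -> dict:
    """N=10, K=5, n=4, x=4 over-representation p against exact pmf sums."""
    from .de import hypergeom_enrichment
    from .types import PathwayMap

    universe = {f"g{i}" for i in range(10)}
    pm = PathwayMap({"p1": {f"g{i}" for i in range(5)}})
    out = hypergeom_enrichment({"g0", "g1", "g2", "g3"}, universe, pm)
    # independent oracle: direct pmf summation
    from math import comb

    exact = sum(comb(5, x) * comb(5, 4 - x) for x in (4,)) / comb(10, 4)
    return {"p_value": float(out.loc[0, "p_value"]), "exact": exact,
            "abs_error": float(abs(out.loc[0, "p_value"] - exact))}


def kl_selection_rate(n_seeds: int = 100, seed: int = 0) -> dict:
    """Fraction of seeds where the KL index picks k=3 on 3 separated blobs."""
    from .cluster import KLKMeans

    hits = 0
    centers = np.array([[0, 0], [12, 0], [0, 12]], dtype=float)
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        X = np.vstack([rng.normal(c, 0.3, size=(10, 2)) for c in centers])
        model = KLKMeans(k_range=(2, 6), random_state=seed + i).fit(X)
        hits += model.k_ == 3
    return {"selection_rate": hits / n_seeds, "n_seeds": n_seeds}


def pipeline_determinism(workdir: str, seed: int = 0) -> dict:
    """Run the full synthetic pipeline twice; outputs must be byte-identical."""
    import filecmp
    import os
    import time

    from .pipeline import RunConfig, run_all

    small = dict(
        mutation_sim=dict(genome_length=200_000, n_genes=200,
                          gene_length_mean=800, n_mut_per_pop=40),
        community_sim=dict(n_taxa=3, genes_per_taxon=120),
        null_ensemble_size=400, nucleotide_null_B=1000, permutations=199,
    )
    t0 = time.time()
    run_all(RunConfig(seed=seed, outdir=os.path.join(workdir, "a"), **small))
    elapsed = time.time() - t0
    run_all(RunConfig(seed=seed, outdir=os.path.join(workdir, "b"), **small))
    names = [n for n in os.listdir(os.path.join(workdir, "a"))
             if n.endswith((".tsv", ".json"))]
    _, mismatch, errors = filecmp.cmpfiles(
        os.path.join(workdir, "a"), os.path.join(workdir, "b"), names,
        shallow=False)
    return {"identical": not mismatch and not errors,
            "n_files": len(names), "runtime_s": elapsed}
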