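"""Statistics for detecting parallel molecular evolution across replicates.

Two levels of parallelism are quantified against uniform nulls:

* **Nucleotide multiplicity** — the number of replicate populations carrying
  a mutation at the same genomic site.  The null assumes mutations land
  uniformly over all sites; the expected number of sites hit in >= k
  populations has a closed form, and a Monte-Carlo p-value is attached to
  the observed count.

* **Gene multiplicity** — the mutation count of gene *i* across all
  replicates, rescaled by the ratio of the mean gene length to the gene's
  length, ``m_i = n_i * (Lbar / L_i)``, so every gene has the same expected
  multiplicity ``m_bar = n_tot / G`` under uniform length-proportional
  mutation.  The aggregate log-likelihood excess over the null is
  ``sum_i n_i * log(m_i / m_bar) = n_tot * KL(p_hat || p0)``, and per-gene
  p-values (Poisson tail or Monte-Carlo) feed an empirical-null critical-p
  procedure that controls the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .types import GeneCatalog, MutationTable

__all__ = [
    "filter_variants",
    "identical_site_parallelism",
    "nucleotide_null",
    "gene_multiplicity",
    "gene_pvalues",
    "simulate_null_pvalues",
    "fdr_critical_p",
    "parallel_evolution_scan",
    "SiteParallelism",
    "GeneMultiplicityTable",
    "NucleotideNullResult",
]


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------

def filter_variants(table: MutationTable, ancestor: MutationTable | None,
                    min_freq: float = 0.2,
                    ancestor_fixed_threshold: float = 0.95) -> MutationTable:
    """Remove ancestral fixed variants and low-frequency calls.

    A variant present in the ancestor at frequency >=
    ``ancestor_fixed_threshold`` (default 0.95; "fixed") is removed from
    every population at the same (contig, position, alt).  Records below
    ``min_freq`` (default 0.2, i.e. calls are kept at or greater than 20 %
    frequency) are then dropped.
    """
    if not (0.0 <= min_freq <= 1.0):
        raise ValueError(f"min_freq {min_freq} outside [0, 1]")
    fixed = set()
    if ancestor is not None:
        fixed = {
            (r.contig, r.position, r.alt_allele)
            for r in ancestor.records
            if r.frequency >= ancestor_fixed_threshold
        }
    kept, n_anc, n_freq = [], 0, 0
    for r in table.records:
        if (r.contig, r.position, r.alt_allele) in fixed:
            n_anc += 1
            continue
        if r.frequency < min_freq:
            n_freq += 1
            continue
        kept.append(r)
    import logging

    logging.getLogger(__name__).info(
        "filter_variants: removed %d ancestor-fixed and %d low-frequency "
        "records; %d kept", n_anc, n_freq, len(kept),
    )
    return MutationTable(kept)


# ---------------------------------------------------------------------------
# Nucleotide multiplicity
# ---------------------------------------------------------------------------


@dataclass
class SiteParallelism:
    """Per-site multiplicities and their N_k summaries.

    ``sites`` has one row per distinct mutated site (matching alt allele by
    default) with its multiplicity ``k``; ``n_k[k]`` counts sites with
    multiplicity >= k, for k = 1..R.
    """

    sites: pd.DataFrame
    n_populations: int
    match_alt: bool = True

    @property
    def n_k(self) -> dict[int, int]:
        mult = self.sites["multiplicity"].to_numpy() if len(self.sites) else np.array([])
        return {
            k: int((mult >= k).sum()) for k in range(1, self.n_populations + 1)
        }


def identical_site_parallelism(table: MutationTable, n_populations: int,
                               match_alt: bool = True) -> SiteParallelism:
    """Count, per site, the number of populations carrying a mutation there.

    With ``match_alt`` (default) two populations only share a site if they
    carry the same alternative allele ("identical mutations"); set False to
    group on position alone.
    """
    pops = table.populations
    if len(pops) > n_populations:
        raise ValueError(
            f"table has {len(pops)} populations but n_populations="
            f"{n_populations}"
        )
    groups: dict[tuple, set[str]] = {}
    for r in table.records:
        key = (r.contig, r.position, r.alt_allele) if match_alt else (
            r.contig, r.position)
        groups.setdefault(key, set()).add(r.population_id)
    rows = [
        {"contig": key[0], "position": key[1],
         "alt_allele": key[2] if match_alt else "*",
         "multiplicity": len(pops_at)}
        for key, pops_at in sorted(groups.items())
    ]
    sites = pd.DataFrame(
        rows, columns=["contig", "position", "alt_allele", "multiplicity"]
    )
    return SiteParallelism(sites=sites, n_populations=n_populations,
                           match_alt=match_alt)


@dataclass
class NucleotideNullResult:
    k: int
    expected_n_k: float
    observed_n_k: int | None
    p_value: float | None
    n_simulations: int
    simulated_n_k: np.ndarray = field(repr=False, default=None)


def _multiplicity_tail(p_hit: np.ndarray, k: int) -> float:
    """P(at least k of the independent Bernoulli(p_r) hit) by DP."""
    dist = np.zeros(len(p_hit) + 1)
    dist[0] = 1.0
    for p in p_hit:
        dist[1:] = dist[1:] * (1 - p) + dist[:-1] * p
        dist[0] *= 1 - p
    return float(dist[k:].sum())


def nucleotide_null(genome_length: int, n_per_pop: list[int], k: int,
                    B: int = 10_000, seed: int = 0,
                    observed_n_k: int | None = None) -> NucleotideNullResult:
    """Uniform-placement null for the number of sites hit in >= k populations.

    Closed form: a given site is hit by population r with probability
    ``1 - (1 - 1/L)**n_r`` (n_r uniform draws with replacement, repeated
    hits collapsing); ``E[N_k] = L * P(multiplicity >= k)``.  The
    Monte-Carlo p-value for an observed N_k uses the +1-corrected tail
    ``(1 + #{sims with N_k >= observed}) / (B + 1)``.
    """
    R = len(n_per_pop)
    if k > R:
        raise ValueError(f"k={k} exceeds number of populations {R}")
    if B < 1000:
        raise ValueError("B must be >= 1000 for a stable Monte-Carlo tail")
    L = int(genome_length)
    p_hit = 1.0 - (1.0 - 1.0 / L) ** np.asarray(n_per_pop, dtype=float)
    expected = L * _multiplicity_tail(p_hit, k)

    rng = np.random.default_rng(seed)
    sim_nk = np.empty(B, dtype=np.int64)
    for b in range(B):
        sites = np.concatenate(
            [np.unique(rng.integers(0, L, size=n)) for n in n_per_pop]
        )
        _, counts = np.unique(sites, return_counts=True)
        sim_nk[b] = int((counts >= k).sum())

    p_value = None
    if observed_n_k is not None:
        p_value = (1 + int((sim_nk >= observed_n_k).sum())) / (B + 1)
    return NucleotideNullResult(
        k=k, expected_n_k=expected, observed_n_k=observed_n_k,
        p_value=p_value, n_simulations=B, simulated_n_k=sim_nk,
    )


# ---------------------------------------------------------------------------
# Gene multiplicity
# ---------------------------------------------------------------------------


@dataclass
class GeneMultiplicityTable:
    """Per-gene multiplicities with the global likelihood excess.

    ``table`` columns: gene_id, length, n (mutation count across replicates),
    multiplicity ``m = n * Lbar / L``, delta_ll ``= n * log(m / m_bar)``, and
    after :func:`gene_pvalues` / :func:`fdr_critical_p` also p_value and
    significant.  ``n_tot`` counts unique genic variants; a variant
    overlapping several genes increments each gene's n (with non-overlapping
    gene models, as in the synthetic genomes, sum(n) == n_tot and
    ``delta_ll_total == n_tot * KL(p_hat || p0) >= 0`` exactly).
    """

    table: pd.DataFrame
    n_tot: int
    mean_length: float
    m_bar: float
    delta_ll_total: float
    p_star: float | None = None
    fdr_level: float | None = None

    @property
    def n_genes(self) -> int:
        return len(self.table)


def gene_multiplicity(table: MutationTable,
                      catalog: GeneCatalog) -> GeneMultiplicityTable:
    """Compute per-gene mutation counts, multiplicities and the likelihood
    excess over the uniform length-proportional null.

    Only records assigned to at least one gene contribute; the null places
    mutations over genic space, so intergenic records are excluded from
    ``n_tot``.
    """
    if len(catalog) == 0:
        raise ValueError("empty gene catalog")
    gene_ids = catalog.gene_ids
    lengths = catalog.lengths
    counts = pd.Series(0, index=gene_ids, dtype=int)
    n_tot = 0
    for r in table.records:
        if not r.gene_ids:
            continue
        n_tot += 1
        for g in r.gene_ids:
            counts[g] += 1
    G = len(gene_ids)
    lbar = catalog.mean_length
    m_bar = n_tot / G if G else 0.0
    n = counts.to_numpy(dtype=float)
    m = n * (lbar / lengths)
    with np.errstate(divide="ignore", invalid="ignore"):
        dll = np.where(n > 0, n * np.log(np.where(n > 0, m, 1.0) / m_bar)
                       if m_bar > 0 else 0.0, 0.0)
    df = pd.DataFrame(
        {"gene_id": gene_ids, "length": lengths.astype(int), "n": n.astype(int),
         "multiplicity": m, "delta_ll": dll}
    )
    return GeneMultiplicityTable(
        table=df, n_tot=n_tot, mean_length=lbar, m_bar=m_bar,
        delta_ll_total=float(dll.sum()),
    )


def _null_gene_counts(lengths: np.ndarray, n_tot: int, B: int,
                      rng: np.random.Generator) -> np.ndarray:
    """B draws of per-gene counts under uniform placement over genic bp."""
    G = len(lengths)
    cum = np.cumsum(lengths / lengths.sum())
    u = rng.random((B, n_tot))
    idx = np.searchsorted(cum, u, side="right")
    counts = np.zeros((B, G), dtype=np.int64)
    for b in range(B):
        counts[b] = np.bincount(idx[b], minlength=G)
    return counts


def _poisson_sf_lookup(lengths: np.ndarray, n_tot: int,
                       max_count: int) -> np.ndarray:
    """sf_table[g, c] = P(Poisson(lambda_g) >= c) for c = 0..max_count."""
    from scipy import stats

    lam = n_tot * lengths / lengths.sum()
    cs = np.arange(max_count + 1)
    return stats.poisson.sf(cs[None, :] - 1, lam[:, None])


def gene_pvalues(gm: GeneMultiplicityTable, method: str = "poisson",
                 B: int = 10_000, seed: int = 0) -> GeneMultiplicityTable:
    """Attach per-gene p-values for excess mutation counts.

    ``poisson``: p_i = P(N >= n_i) for N ~ Poisson(n_tot * L_i / sum(L)).
    ``montecarlo``: +1-corrected tail over ``B`` uniform re-placements of
    the n_tot mutations across genes with length weights.
    """
    lengths = gm.table["length"].to_numpy(dtype=float)
    n = gm.table["n"].to_numpy()
    if method == "poisson":
        sf = _poisson_sf_lookup(lengths, gm.n_tot, int(n.max(initial=0)))
        p = sf[np.arange(len(n)), n]
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        null = _null_gene_counts(lengths, gm.n_tot, B, rng)
        p = (1 + (null >= n[None, :]).sum(axis=0)) / (B + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    table = gm.table.copy()
    table["p_value"] = p
    return GeneMultiplicityTable(
        table=table, n_tot=gm.n_tot, mean_length=gm.mean_length,
        m_bar=gm.m_bar, delta_ll_total=gm.delta_ll_total,
    )


def simulate_null_pvalues(catalog: GeneCatalog, n_tot: int, B: int = 1000,
                          seed: int = 0) -> np.ndarray:
    """B simulated Poisson-tail p-vectors under the uniform genic null.

    Used by :func:`fdr_critical_p` as the empirical null ensemble; the
    catalog and n_tot must match the observed dataset.
    """
    rng = np.random.default_rng(seed)
    lengths = catalog.lengths
    counts = _null_gene_counts(lengths, n_tot, B, rng)
    sf = _poisson_sf_lookup(lengths, n_tot, int(counts.max(initial=0)))
    return sf[np.arange(len(lengths))[None, :], counts]


def fdr_critical_p(observed_p: np.ndarray, null_p: np.ndarray,
                   fdr: float = 0.05) -> tuple[float, np.ndarray]:
    """Empirical-null critical p-value controlling the FDR.

    For each candidate threshold t among the unique observed p-values (in
    increasing order), ``FDR(t)`` is the mean null discovery count at t
    divided by the observed discovery count at t; the critical value ``p*``
    is the largest t with ``FDR(t) < fdr``.  Returns ``(p_star, mask)``
    where ``mask`` flags genes with p <= p*; if no threshold qualifies,
    ``p_star = 0`` and nothing is flagged.
    """
    if not (0.0 < fdr < 1.0):
        raise ValueError(f"fdr {fdr} outside (0, 1)")
    observed_p = np.asarray(observed_p, dtype=float)
    null_p = np.asarray(null_p, dtype=float)
    B = null_p.shape[0]
    null_sorted = np.sort(null_p.ravel())
    thresholds = np.unique(observed_p)
    obs_sorted = np.sort(observed_p)
    n_obs = np.searchsorted(obs_sorted, thresholds, side="right")
    n_null = np.searchsorted(null_sorted, thresholds, side="right") / B
    est_fdr = n_null / np.maximum(1, n_obs)
    ok = est_fdr < fdr
    p_star = float(thresholds[ok].max()) if ok.any() else 0.0
    return p_star, observed_p <= p_star


def parallel_evolution_scan(table: MutationTable, catalog: GeneCatalog,
                            method: str = "poisson", fdr: float = 0.05,
                            B_pvalue: int = 10_000, B_null: int = 1000,
                            seed: int = 0) -> GeneMultiplicityTable:
    """Full gene-level scan: multiplicities, p-values, critical-p FDR flags."""
    gm = gene_multiplicity(table, catalog)
    gm = gene_pvalues(gm, method=method, B=B_pvalue, seed=seed)
    null_p = simulate_null_pvalues(catalog, gm.n_tot, B=B_null,
                                   seed=seed + 1)
    p_star, mask = fdr_critical_p(
        gm.table["p_value"].to_numpy(), null_p, fdr=fdr
    )
    table_out = gm.table.copy()
    table_out["significant"] = mask
    return GeneMultiplicityTable(
        table=table_out, n_tot=gm.n_tot, mean_length=gm.mean_length,
        m_bar=gm.m_bar, delta_ll_total=gm.delta_ll_total, p_star=p_star,
        fdr_level=fdr,
    )
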