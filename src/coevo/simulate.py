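"""Synthetic data generators with the statistical structure the pipeline assumes.

Three generators: a single-contig genome with non-overlapping genes, mutation
tables under a uniform per-bp null (optionally enriched in target genes), and
multi-taxon negative-binomial count matrices with taxon-abundance confounding
and factorial treatment effects.  All randomness flows from one
``numpy.random.default_rng(seed)`` per call, so fixed seeds give bit-identical
outputs across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, Gene, GeneCatalog, MutationRecord, MutationTable, PathwayMap

__all__ = [
    "MutationSimSpec",
    "CommunitySimSpec",
    "EffectSpec",
    "simulate_genome",
    "simulate_mutations",
    "simulate_community",
    "simulate_pathways",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class MutationSimSpec:
    """Conditions for the mutation / parallel-evolution simulator.

    ``enrichment`` multiplies the per-bp mutation rate inside
    ``target_genes``; ``enrichment == 1`` recovers the uniform null.
    Frequencies are uniform on (freq_lo, freq_hi]; the default lower bound
    0.05 sits below the 20 % detection filter so the filter is exercised.
    """

    n_populations: int = 3
    genome_length: int = 1_000_000
    n_genes: int = 1000
    gene_length_mean: float = 900.0
    gene_length_shape: float = 4.0
    n_mut_per_pop: int = 50
    target_genes: tuple[str, ...] = ()
    enrichment: float = 1.0
    freq_lo: float = 0.05
    freq_hi: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")
        if not (0 <= self.freq_lo < self.freq_hi <= 1):
            raise ValueError("need 0 <= freq_lo < freq_hi <= 1")
        if self.n_populations < 1:
            raise ValueError("need at least one population")


def simulate_genome(spec: MutationSimSpec) -> GeneCatalog:
    """Place ``n_genes`` non-overlapping genes left-to-right on one contig.

    Lengths are gamma(shape, mean/shape) rounded to >= 30 bp; the remaining
    genome is distributed as random intergenic gaps (including the flanks).
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.gene_length_shape
    lengths = rng.gamma(shape, spec.gene_length_mean / shape, spec.n_genes)
    lengths = np.maximum(np.round(lengths).astype(int), 30)
    total = int(lengths.sum())
    if total > spec.genome_length:
        raise ValueError(
            f"total gene length {total} exceeds genome_length "
            f"{spec.genome_length}"
        )
    slack = spec.genome_length - total
    # random non-negative gaps before each gene and after the last
    gap_w = rng.dirichlet(np.ones(spec.n_genes + 1))
    gaps = np.floor(gap_w * slack).astype(int)
    gaps[-1] += slack - gaps.sum()

    genes = []
    pos = 1
    width = len(str(spec.n_genes))
    for i, (gap, L) in enumerate(zip(gaps[:-1], lengths)):
        start = pos + int(gap)
        genes.append(
            Gene(
                gene_id=f"gene_{i + 1:0{width}d}",
                contig="chr1",
                start=start,
                end=start + int(L) - 1,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
        pos = start + int(L)
    return GeneCatalog("synthetic_genome", spec.genome_length, genes)


def _mutation_site_sampler(catalog: GeneCatalog, spec: MutationSimSpec):
    """Return ``draw(n, rng)`` sampling sites with target-gene weighting.

    The genome is cut into maximal segments of constant per-bp weight
    (``enrichment`` inside target genes, 1 elsewhere); a site is drawn by
    inverse-transform sampling on the cumulative segment weights.
    """
    L = catalog.genome_length
    missing = set(spec.target_genes) - set(catalog.gene_ids)
    if missing:
        raise ValueError(f"target genes absent from catalog: {sorted(missing)}")
    targets = sorted(
        (catalog[g].start, catalog[g].end) for g in spec.target_genes
    )
    # merge overlapping target intervals
    merged: list[list[int]] = []
    for s, e in targets:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    seg_start, seg_len, seg_w = [], [], []
    pos = 1
    for s, e in merged:
        if s > pos:
            seg_start.append(pos)
            seg_len.append(s - pos)
            seg_w.append(1.0)
        seg_start.append(s)
        seg_len.append(e - s + 1)
        seg_w.append(spec.enrichment)
        pos = e + 1
    if pos <= L:
        seg_start.append(pos)
        seg_len.append(L - pos + 1)
        seg_w.append(1.0)

    starts = np.asarray(seg_start, dtype=np.int64)
    lens = np.asarray(seg_len, dtype=np.int64)
    weights = np.asarray(seg_w, dtype=float) * lens
    cumw = np.concatenate([[0.0], np.cumsum(weights)])

    def draw(n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(0.0, cumw[-1], size=n)
        seg = np.searchsorted(cumw, u, side="right") - 1
        seg = np.clip(seg, 0, len(lens) - 1)
        frac = (u - cumw[seg]) / (cumw[seg + 1] - cumw[seg])
        offset = np.minimum((frac * lens[seg]).astype(np.int64), lens[seg] - 1)
        return starts[seg] + offset

    return draw


def simulate_mutations(catalog: GeneCatalog, spec: MutationSimSpec) -> MutationTable:
    """Draw ``n_mut_per_pop`` mutations per population.

    Each site is drawn with probability proportional to 1 per bp, except
    sites inside ``target_genes`` which are weighted by ``enrichment``.
    Repeated hits at the same site within a population collapse to one
    record, so realized per-population counts can fall slightly below
    ``n_mut_per_pop`` when the genome is short.
    """
    rng = np.random.default_rng(spec.seed)
    draw = _mutation_site_sampler(catalog, spec)
    records: list[MutationRecord] = []
    for r in range(spec.n_populations):
        pop = f"pop_{r + 1}"
        if spec.n_mut_per_pop == 0:
            continue
        pos = draw(spec.n_mut_per_pop, rng)
        _, first = np.unique(pos, return_index=True)
        pos = pos[np.sort(first)]  # collapse repeated hits, keep draw order
        n = len(pos)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        cls_draw = rng.random(n)
        freqs = rng.uniform(spec.freq_lo, spec.freq_hi, size=n)
        for j in range(n):
            ref, alt = _BASES[ref_idx[j]], _BASES[alt_idx[j]]
            if cls_draw[j] < 0.8:
                mclass = "substitution"
            elif cls_draw[j] < 0.9:
                mclass, ref, alt = "deletion", ref + alt, ref
            else:
                mclass, alt = "insertion", ref + alt
            records.append(
                MutationRecord(
                    population_id=pop, contig="chr1", position=int(pos[j]),
                    ref_allele=str(ref), alt_allele=str(alt),
                    frequency=float(freqs[j]), mutation_class=mclass,
                    gene_ids=tuple(catalog.genes_at("chr1", int(pos[j]))),
                )
            )
    return MutationTable(records)


# ---------------------------------------------------------------------------
# Community expression simulator
# ---------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """A planted differential-expression effect.

    ``coefficient`` is one of ``predation``, ``coevolution`` or
    ``interaction``; ``lfc`` is the planted log2 fold change applied to the
    listed genes whenever the coefficient's indicator is 1 for a sample.
    """

    genes: tuple[str, ...]
    coefficient: str
    lfc: float

    def __post_init__(self) -> None:
        if self.coefficient not in {"predation", "coevolution", "interaction"}:
            raise ValueError(f"unknown coefficient {self.coefficient!r}")


@dataclass
class CommunitySimSpec:
    """Conditions for the multi-taxon count simulator.

    The design mirrors a 2 x 2 factorial (predation x coevolved focal prey)
    with ``n_replicates`` microcosms per cell sampled on each of ``days``.
    Expected counts follow
    ``libsize_s * A[t(g), s] * q_g * 2**(planted effects)`` with
    NB(mean, phi_g) sampling noise; ``q`` sums to 1 within each taxon so
    ``A`` is the taxon's expected library share.  ``abundance_shift`` maps
    taxon -> (coefficient, fold) and multiplies that taxon's abundance (DNA
    and expected counts alike) when the coefficient's indicator is 1 —
    the confounding that within-taxon scaling plus the abundance covariate
    must remove.
    """

    n_taxa: int = 4
    genes_per_taxon: int = 250
    n_replicates: int = 3
    days: tuple[int, ...] = (4,)
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 1.0
    dispersion_shape: float = 4.0
    dispersion_mean: float = 0.1
    libsize_mean: float = 2e5
    libsize_sdlog: float = 0.1
    abundance_shift: dict = field(default_factory=dict)
    effects: tuple[EffectSpec, ...] = ()
    relabund_concentration: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        for taxon, (coef, fold) in self.abundance_shift.items():
            if coef not in {"predation", "coevolution", "interaction"}:
                raise ValueError(f"unknown abundance-shift coefficient {coef!r}")
            if fold <= 0:
                raise ValueError("abundance-shift fold must be positive")


def _design_table(spec: CommunitySimSpec) -> pd.DataFrame:
    rows = []
    for day in spec.days:
        for pred in (False, True):
            for coev in (False, True):
                for rep in range(1, spec.n_replicates + 1):
                    sid = (
                        f"d{day}_P{int(pred)}C{int(coev)}_r{rep}"
                    )
                    rows.append(
                        {"sample_id": sid, "predation": pred,
                         "coevolved_prey": coev, "day": day, "replicate": rep}
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def _indicator(meta: pd.DataFrame, coefficient: str) -> np.ndarray:
    pred = meta["predation"].to_numpy(dtype=float)
    coev = meta["coevolved_prey"].to_numpy(dtype=float)
    if coefficient == "predation":
        return pred
    if coefficient == "coevolution":
        return coev
    return pred * coev  # interaction


def simulate_community(spec: CommunitySimSpec) -> ExpressionMatrix:
    """Draw a gene x sample NB count matrix with metadata and abundances."""
    rng = np.random.default_rng(spec.seed)
    meta = _design_table(spec)
    samples = list(meta.index)
    n_s = len(samples)

    taxa = [f"taxon_{t + 1}" for t in range(spec.n_taxa)]
    gene_ids, gene_tax = [], []
    for t, taxon in enumerate(taxa):
        for g in range(spec.genes_per_taxon):
            gene_ids.append(f"{taxon}:g{g + 1:04d}")
            gene_tax.append(taxon)
    gene_taxon = pd.Series(gene_tax, index=gene_ids, name="taxon_id")
    n_g = len(gene_ids)

    # baseline relative expression q, normalized within taxon
    q = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, n_g)
    qs = pd.Series(q, index=gene_ids)
    q = (qs / qs.groupby(gene_taxon).transform("sum")).to_numpy()

    # per-gene dispersions
    phi = rng.gamma(
        spec.dispersion_shape, spec.dispersion_mean / spec.dispersion_shape, n_g
    )

    # taxon abundance A (taxa x samples): uniform baseline, optional shifts
    A = np.ones((spec.n_taxa, n_s))
    for taxon, (coef, fold) in spec.abundance_shift.items():
        ti = taxa.index(taxon)
        A[ti] *= np.where(_indicator(meta, coef) > 0, fold, 1.0)
    A /= A.sum(axis=0, keepdims=True)

    # planted expression effects on the log2 scale
    log2fc = np.zeros((n_g, n_s))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for eff in spec.effects:
        idx = [gene_pos[g] for g in eff.genes]
        log2fc[np.ix_(idx, range(n_s))] += np.outer(
            np.full(len(idx), eff.lfc), _indicator(meta, eff.coefficient)
        )

    libsize = rng.lognormal(np.log(spec.libsize_mean), spec.libsize_sdlog, n_s)
    tax_idx = np.array([taxa.index(t) for t in gene_tax])
    mu = libsize[None, :] * A[tax_idx, :] * q[:, None] * 2.0 ** log2fc

    # NB draws: variance mu + phi mu^2 (phi == 0 -> Poisson)
    counts = np.empty((n_g, n_s), dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r[:, None] / (r[:, None] + mu[nb])
        counts[nb] = rng.negative_binomial(r[:, None], p)

    # amplicon relative abundances: Dirichlet noise around A
    relabund = np.empty_like(A)
    for s in range(n_s):
        relabund[:, s] = rng.dirichlet(spec.relabund_concentration * A[:, s])

    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        gene_taxon=gene_taxon,
        sample_meta=meta,
        taxon_relabund=pd.DataFrame(relabund, index=taxa, columns=samples),
    )


def simulate_pathways(gene_ids: Sequence[str], n_pathways: int = 20,
                      genes_per_pathway: int = 25, seed: int = 0) -> PathwayMap:
    """Random disjoint pathway grouping over ``gene_ids`` (plumbing for the
    enrichment stage; no biological structure)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(gene_ids))
    pathways = {}
    for p in range(n_pathways):
        lo = p * genes_per_pathway
        members = [gene_ids[i] for i in perm[lo:lo + genes_per_pathway]]
        if not members:
            break
        pathways[f"map{p + 1:05d}"] = members
    return PathwayMap(pathways, universe=gene_ids)
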