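"""End-to-end orchestration: simulate -> parallelism -> DE -> DiSTATIS.

A single :class:`RunConfig` (usually from YAML) drives the whole run.  One
global seed is declared; each stage derives its own seed deterministically
from a hash of the stage name, so stages are individually reproducible and
the full run is byte-identical across repeats of the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__, io
from .cluster import kmeans_kl
from .de import (
    NegativeBinomialDE,
    hypergeom_enrichment,
    rlog_transform,
    select_top_variable,
)
from .distatis import Distatis, expression_distances
from .normalization import taxon_inclusion
from .parallelism import (
    filter_variants,
    identical_site_parallelism,
    nucleotide_null,
    parallel_evolution_scan,
)
from .permtests import permanova_compromise, permdisp
from .simulate import (
    CommunitySimSpec,
    EffectSpec,
    MutationSimSpec,
    simulate_community,
    simulate_genome,
    simulate_mutations,
    simulate_pathways,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "load_config", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class Thresholds:
    min_freq: float = 0.2
    ancestor_fixed: float = 0.95
    fdr: float = 0.05
    de_padj: float = 0.1
    lfc: float = 2.0
    enrichment_padj: float = 0.05
    top_n: int = 500
    taxon_inclusion: float = 0.005
    variance_cutoff: float = 0.99

    def __post_init__(self) -> None:
        for name in ("min_freq", "ancestor_fixed", "taxon_inclusion"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"threshold {name}={v} outside [0, 1]")
        for name in ("fdr", "de_padj", "enrichment_padj", "variance_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"threshold {name}={v} outside (0, 1)")
        if self.lfc < 0 or self.top_n < 1:
            raise ValueError("lfc must be >= 0 and top_n >= 1")


@dataclass
class RunConfig:
    """Inputs, thresholds and seed for a full pipeline run."""

    seed: int = 0
    outdir: str = "coevo_out"
    mutation_sim: dict = field(default_factory=dict)
    community_sim: dict = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    # optional external inputs; when set, the matching simulator is skipped
    gff_path: str | None = None
    vcf_paths: dict | None = None
    ancestor_vcf: str | None = None
    counts_paths: dict | None = None   # counts/taxon_map/meta/relabund
    pathway_path: str | None = None
    null_ensemble_size: int = 1000
    nucleotide_null_B: int = 2000
    permutations: int = 999

    def validate_inputs(self) -> list[str]:
        """Check declared input files exist; returns list of problems."""
        problems = []
        paths: list[str] = []
        if self.gff_path:
            paths.append(self.gff_path)
        if self.vcf_paths:
            paths.extend(self.vcf_paths.values())
        if self.ancestor_vcf:
            paths.append(self.ancestor_vcf)
        if self.counts_paths:
            paths.extend(self.counts_paths.values())
        if self.pathway_path:
            paths.append(self.pathway_path)
        for p in paths:
            if not os.path.exists(p):
                problems.append(f"missing input: {p}")
        return problems

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    thresholds = Thresholds(**raw.pop("thresholds", {}))
    return RunConfig(thresholds=thresholds, **raw)


def _write(df: pd.DataFrame, outdir: str, name: str, seed: int,
           index: bool = False) -> int:
    io._write_tsv(df, os.path.join(outdir, name), seed=seed, index=index)
    return len(df)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, outdir: str) -> dict:
    seed = stage_seed(cfg.seed, "simulate")
    info: dict = {"seed": seed}
    simdir = os.path.join(outdir, "inputs")
    os.makedirs(simdir, exist_ok=True)

    if cfg.gff_path is None:
        mspec = MutationSimSpec(**{**cfg.mutation_sim, "seed": seed})
        catalog = simulate_genome(mspec)
        io.write_gene_models(catalog, os.path.join(simdir, "genes.gff3"))
        table = simulate_mutations(catalog, mspec)
        io.write_variant_tables(table, os.path.join(simdir, "vcf"),
                                genome_length=mspec.genome_length)
        info["n_genes"] = len(catalog)
        info["n_mutations"] = len(table)
        cfg.gff_path = os.path.join(simdir, "genes.gff3")
        cfg.vcf_paths = {
            p: os.path.join(simdir, "vcf", f"{p}.vcf")
            for p in table.populations
        }

    if cfg.counts_paths is None:
        sim_kw = dict(cfg.community_sim)
        raw_effects = sim_kw.pop("effects", None)
        cspec = CommunitySimSpec(**{**sim_kw, "seed": seed + 1})
        if raw_effects:
            cspec.effects = tuple(
                EffectSpec(tuple(e["genes"]), e["coefficient"], e["lfc"])
                for e in raw_effects
            )
        em = simulate_community(cspec)
        paths = io.write_count_matrix(em, simdir, seed=seed)
        cfg.counts_paths = paths
        info["n_expression_genes"] = len(em.genes)
        if cfg.pathway_path is None:
            pm = simulate_pathways(em.genes, seed=seed + 2)
            cfg.pathway_path = os.path.join(simdir, "pathways.tsv")
            io.write_pathway_map(pm, cfg.pathway_path, seed=seed)
    return info


def _stage_parallelism(cfg: RunConfig, outdir: str) -> dict:
    seed = stage_seed(cfg.seed, "parallelism")
    catalog = io.read_gene_models(cfg.gff_path)
    table = io.read_variant_table(cfg.vcf_paths, catalog)
    ancestor = (io.read_variant_table({"ancestor": cfg.ancestor_vcf}, catalog)
                if cfg.ancestor_vcf else None)
    filtered = filter_variants(table, ancestor,
                               min_freq=cfg.thresholds.min_freq,
                               ancestor_fixed_threshold=cfg.thresholds.ancestor_fixed)
    R = len(cfg.vcf_paths)
    sp = identical_site_parallelism(filtered, R)
    n_per_pop = [
        sum(1 for r in filtered.records if r.population_id == p)
        for p in filtered.populations
    ]
    k = min(2, R)
    null = nucleotide_null(
        catalog.genome_length, n_per_pop, k=k, B=cfg.nucleotide_null_B,
        seed=seed, observed_n_k=sp.n_k.get(k, 0),
    )
    scan = parallel_evolution_scan(
        filtered, catalog, fdr=cfg.thresholds.fdr,
        B_null=cfg.null_ensemble_size, seed=seed + 1,
    )
    _write(sp.sites, outdir, "site_parallelism.tsv", seed)
    _write(scan.table, outdir, "gene_multiplicity.tsv", seed)
    summary = {
        "n_populations": R,
        "n_records": len(filtered),
        "n_tot_genic": scan.n_tot,
        "delta_ll_total": round(scan.delta_ll_total, 6),
        "p_star": scan.p_star,
        "n_significant_genes": int(scan.table["significant"].sum()),
        "site_n_k": sp.n_k,
        "nucleotide_null": {
            "k": null.k, "expected_n_k": round(null.expected_n_k, 6),
            "observed_n_k": null.observed_n_k, "p_value": null.p_value,
        },
        "seed": seed,
    }
    with open(os.path.join(outdir, "parallelism_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return {"seed": seed, "rows": len(scan.table),
            "n_significant": summary["n_significant_genes"]}


def _stage_de(cfg: RunConfig, outdir: str) -> tuple[dict, dict]:
    seed = stage_seed(cfg.seed, "de")
    em = io.read_count_matrix(
        cfg.counts_paths["counts"], cfg.counts_paths["taxon_map"],
        cfg.counts_paths["meta"], cfg.counts_paths["relabund"],
    )
    keep = taxon_inclusion(em, cfg.thresholds.taxon_inclusion)
    genes = [g for g in em.genes if em.gene_taxon[g] in keep]
    pm = io.read_pathway_map(cfg.pathway_path) if cfg.pathway_path else None

    de_frames, rlog_by_day = [], {}
    sf_frames, enr_frames = [], []
    for day in sorted(em.sample_meta["day"].unique()):
        day_samples = list(em.sample_meta.index[em.sample_meta["day"] == day])
        sub = em.subset_samples(day_samples)
        sub = type(em)(
            sub.counts.loc[genes], sub.gene_taxon.loc[genes],
            sub.sample_meta,
            sub.taxon_relabund.loc[sorted(set(sub.gene_taxon.loc[genes]))]
            / sub.taxon_relabund.loc[
                sorted(set(sub.gene_taxon.loc[genes]))].sum(axis=0),
        )
        est = NegativeBinomialDE(
            alpha=cfg.thresholds.de_padj, lfc_threshold=cfg.thresholds.lfc,
        ).fit(sub)
        res = est.results_.copy()
        res.insert(0, "day", day)
        de_frames.append(res)
        sfdf = est.size_factors_.factors.rename_axis("taxon_id").copy()
        sfdf.insert(0, "day", day)
        sf_frames.append(sfdf.reset_index())
        rlog_by_day[day] = rlog_transform(sub, est.size_factors_,
                                          est.dispersions_)
        if pm is not None:
            enr = hypergeom_enrichment(
                set(est.result_.de_genes), set(sub.genes), pm,
                alpha=cfg.thresholds.enrichment_padj,
            )
            enr.insert(0, "day", day)
            enr_frames.append(enr)

    de_all = pd.concat(de_frames, ignore_index=True)
    _write(de_all, outdir, "de_results.tsv", seed)
    _write(pd.concat(sf_frames, ignore_index=True), outdir,
           "size_factors.tsv", seed)
    rlog_all = pd.concat(
        [df for df in rlog_by_day.values()], axis=1
    ).rename_axis("gene_id")
    _write(rlog_all, outdir, "rlog.tsv", seed, index=True)
    if enr_frames:
        _write(pd.concat(enr_frames, ignore_index=True), outdir,
               "enrichment.tsv", seed)
    info = {"seed": seed, "rows": len(de_all),
            "n_de": int(de_all["de"].sum()), "taxa_included": keep}
    return info, {"em": em, "rlog_by_day": rlog_by_day, "genes": genes}


def _stage_distatis(cfg: RunConfig, outdir: str, state: dict) -> dict:
    seed = stage_seed(cfg.seed, "distatis")
    em = state["em"]
    rows_scores, rows_partial, rows_alpha = [], [], []
    rows_clusters, rows_perm = [], []
    for day, rlog in state["rlog_by_day"].items():
        gene_taxon = em.gene_taxon.loc[state["genes"]]
        top = select_top_variable(rlog, gene_taxon, n=cfg.thresholds.top_n)
        dists = expression_distances(rlog, top)
        model = Distatis().fit(dists)
        res = model.result_
        samples = list(rlog.columns)
        meta = em.sample_meta.loc[samples]
        treatment = [
            f"P{int(p)}C{int(c)}"
            for p, c in zip(meta["predation"], meta["coevolved_prey"])
        ]
        for i, s in enumerate(samples):
            rows_scores.append(
                {"day": day, "sample_id": s, "treatment": treatment[i],
                 "axis1": res.factor_scores[i, 0],
                 "axis2": res.factor_scores[i, 1]
                 if res.factor_scores.shape[1] > 1 else 0.0}
            )
        for t, tid in enumerate(res.table_ids):
            for i, s in enumerate(samples):
                rows_partial.append(
                    {"day": day, "table": tid, "sample_id": s,
                     "axis1": res.partial_scores[t][i, 0],
                     "axis2": res.partial_scores[t][i, 1]
                     if res.partial_scores[t].shape[1] > 1 else 0.0}
                )
            rows_alpha.append({"day": day, "table": tid,
                               "alpha": res.alpha[t]})
        d_keep = res.n_components_for(cfg.thresholds.variance_cutoff)
        cl = kmeans_kl(res.factor_scores[:, :max(d_keep, 2)],
                       k_range=(2, min(6, len(samples) - 2)), seed=seed)
        for i, s in enumerate(samples):
            rows_clusters.append(
                {"day": day, "sample_id": s, "cluster": int(cl.labels[i]),
                 "chosen_k": cl.k}
            )
        pa = permanova_compromise(
            res, treatment, variance_cutoff=cfg.thresholds.variance_cutoff,
            permutations=cfg.permutations, seed=seed,
        )
        pd_ = permdisp(res.factor_scores[:, :d_keep], treatment,
                       permutations=cfg.permutations, seed=seed)
        for r in (pa, pd_):
            rows_perm.append(
                {"day": day, "method": r.method, "pseudo_F": r.statistic,
                 "r_squared": r.r_squared, "p_value": r.p_value,
                 "n_permutations": r.n_permutations}
            )
        rows_perm.append(
            {"day": day, "method": "variance_axis1",
             "pseudo_F": float(res.explained_variance_ratio[0]),
             "r_squared": np.nan, "p_value": np.nan, "n_permutations": 0}
        )
    _write(pd.DataFrame(rows_scores), outdir, "compromise_scores.tsv", seed)
    _write(pd.DataFrame(rows_partial), outdir, "partial_scores.tsv", seed)
    _write(pd.DataFrame(rows_alpha), outdir, "alpha.tsv", seed)
    _write(pd.DataFrame(rows_clusters), outdir, "clusters.tsv", seed)
    _write(pd.DataFrame(rows_perm), outdir, "permtests.tsv", seed)
    return {"seed": seed, "rows": len(rows_scores)}


def run_all(cfg: RunConfig) -> dict:
    """Run every stage in dependency order; returns the provenance manifest."""
    problems = cfg.validate_inputs()
    if problems:
        raise FileNotFoundError("; ".join(problems))
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "global_seed": cfg.seed,
        "stages": {},
    }
    stages = [("simulate", lambda: _stage_simulate(cfg, outdir)),
              ("parallelism", lambda: _stage_parallelism(cfg, outdir))]
    state: dict = {}

    def de_stage():
        info, st = _stage_de(cfg, outdir)
        state.update(st)
        return info

    stages += [("de", de_stage),
               ("distatis", lambda: _stage_distatis(cfg, outdir, state))]
    for name, fn in stages:
        logger.info("running stage %s", name)
        try:
            manifest["stages"][name] = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest["stages"]["manifest"] = {"n_stages": len(stages) + 1}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
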