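"""Readers and writers for the standard formats the pipeline touches.

GFF3 is read through :mod:`gffutils`, VCF through :mod:`cyvcf2`, tabular
files through pandas.  Every TSV written here carries a leading ``#`` comment
line recording the package version and, when supplied, the seed, so that
outputs are self-describing; readers skip such lines.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    Gene,
    GeneCatalog,
    MutationRecord,
    MutationTable,
    PathwayMap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_models",
    "write_gene_models",
    "read_variant_table",
    "write_variant_tables",
    "read_count_matrix",
    "write_count_matrix",
    "read_pathway_map",
    "write_pathway_map",
    "read_mutation_table_tsv",
    "write_mutation_table_tsv",
]


def _comment_header(seed: int | None = None) -> str:
    from . import __version__

    line = f"# coevo v{__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def _write_tsv(df: pd.DataFrame, path: str, seed: int | None = None,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g",
                  lineterminator="\n")


def _read_tsv(path: str, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str, genome_length: int | None = None,
                     genome_id: str | None = None) -> GeneCatalog:
    """Read gene (or CDS) features from a GFF3 file into a :class:`GeneCatalog`.

    ``gene`` features are preferred; if the file has none, CDS features are
    used instead.  ``genome_length`` defaults to the maximum of the
    ``##sequence-region`` directives, or the maximum feature end coordinate.
    """
    import gffutils

    with open(path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        logger.warning("no gene features found in %s", path)
        length = genome_length or 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    length = max(length, int(line.split()[3]))
        return GeneCatalog(
            genome_id or os.path.splitext(os.path.basename(path))[0],
            length, [],
        )

    try:
        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ValueError(f"failed to parse GFF3 {path!r}: {exc}") from exc

    featuretype = "gene"
    if not any(True for _ in db.features_of_type("gene")):
        featuretype = "CDS"

    genes: list[Gene] = []
    max_end = 0
    for feat in db.features_of_type(featuretype, order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(Gene(gene_id=gid, contig=feat.seqid, start=feat.start,
                          end=feat.end, strand=feat.strand or "."))
        max_end = max(max_end, feat.end)

    if genome_length is None:
        genome_length = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    genome_length = max(genome_length, int(parts[3]))
        if genome_length == 0:
            genome_length = max_end
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(path))[0]

    if not genes:
        logger.warning("no %s features found in %s", featuretype, path)
    return GeneCatalog(genome_id=genome_id, genome_length=genome_length,
                       genes=genes)


def write_gene_models(catalog: GeneCatalog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in sorted(catalog.contigs()) or [catalog.genome_id]:
            fh.write(f"##sequence-region {contig} 1 {catalog.genome_length}\n")
        for g in catalog.genes:
            fh.write(
                f"{g.contig}\tcoevo\tgene\t{g.start}\t{g.end}\t.\t{g.strand}"
                f"\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# VCF variant tables
# ---------------------------------------------------------------------------

def _classify(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "substitution"
    return "deletion" if len(ref) > len(alt) else "insertion"


def read_variant_table(paths: dict[str, str] | Sequence[str],
                       catalog: GeneCatalog) -> MutationTable:
    """Read one VCF per population into a single :class:`MutationTable`.

    ``paths`` maps population_id -> VCF path (a bare sequence of paths uses
    file basenames as population ids).  Allele frequency is taken from the
    ``AF`` INFO field, falling back to alt-depth / total-depth from ``AD``;
    a record with neither is an error.  Gene assignment is by coordinate
    overlap against ``catalog``; records on contigs absent from the catalog
    are kept with empty gene_ids and a warning.
    """
    from cyvcf2 import VCF

    if not isinstance(paths, dict):
        paths = {
            os.path.splitext(os.path.basename(p))[0]: p for p in paths
        }
    contigs = catalog.contigs()
    records: list[MutationRecord] = []
    for pop, path in paths.items():
        for var in VCF(path):
            alts = var.ALT or []
            af = var.INFO.get("AF")
            if af is not None:
                freqs = [af] if isinstance(af, float) else list(af)
            else:
                ad = var.format("AD")
                if ad is None:
                    raise ValueError(
                        f"{path}: record {var.CHROM}:{var.POS} has no AF info "
                        "field and no AD format field"
                    )
                depths = np.asarray(ad, dtype=float).ravel()
                total = depths.sum()
                if total <= 0:
                    raise ValueError(
                        f"{path}: record {var.CHROM}:{var.POS} has zero depth"
                    )
                freqs = [depths[i + 1] / total for i in range(len(alts))]
            if var.CHROM not in contigs:
                logger.warning(
                    "%s: contig %s absent from catalog; record kept without "
                    "gene assignment", path, var.CHROM,
                )
                gene_ids: tuple[str, ...] = ()
            else:
                gene_ids = tuple(catalog.genes_at(var.CHROM, var.POS))
            for alt, freq in zip(alts, freqs):
                records.append(
                    MutationRecord(
                        population_id=pop, contig=var.CHROM, position=var.POS,
                        ref_allele=var.REF, alt_allele=alt,
                        frequency=float(freq),
                        mutation_class=_classify(var.REF, alt),
                        gene_ids=gene_ids,
                    )
                )
    return MutationTable(records)


def write_variant_tables(table: MutationTable, outdir: str,
                         genome_id: str = "genome",
                         genome_length: int | None = None) -> dict[str, str]:
    """Write one plain-text VCF 4.2 per population; returns pop -> path."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    for pop in table.populations:
        path = os.path.join(outdir, f"{pop}.vcf")
        recs = sorted(
            (r for r in table.records if r.population_id == pop),
            key=lambda r: (r.contig, r.position, r.alt_allele),
        )
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                     'Description="Allele Frequency">\n')
            if genome_length is not None:
                contigs = sorted({r.contig for r in recs}) or [genome_id]
                for c in contigs:
                    fh.write(f"##contig=<ID={c},length={genome_length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in recs:
                fh.write(
                    f"{r.contig}\t{r.position}\t.\t{r.ref_allele}\t"
                    f"{r.alt_allele}\t.\tPASS\tAF={r.frequency:.6g}\n"
                )
        paths[pop] = path
    return paths


def write_mutation_table_tsv(table: MutationTable, path: str,
                             seed: int | None = None) -> None:
    _write_tsv(table.to_frame(), path, seed=seed)


def read_mutation_table_tsv(path: str) -> MutationTable:
    df = _read_tsv(path, dtype={"gene_ids": str}, keep_default_na=False)
    return MutationTable.from_frame(df)


# ---------------------------------------------------------------------------
# Count matrices / metadata / abundances
# ---------------------------------------------------------------------------

def read_count_matrix(counts_path: str, taxon_map_path: str, meta_path: str,
                      relabund_path: str) -> ExpressionMatrix:
    """Assemble a validated :class:`ExpressionMatrix` from four TSV files.

    ``counts``: gene_id column then one column per sample (integers).
    ``taxon map``: columns gene_id, taxon_id.  ``meta``: sample_id,
    predation, coevolved_prey, day, replicate.  ``relabund``: taxon_id then
    one column per sample, columns summing to 1.
    """
    counts = _read_tsv(counts_path, index_col=0).rename_axis(None)
    float_cols = counts.select_dtypes(include=[float]).columns
    if len(float_cols):
        arr = counts[float_cols].to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(
                f"{counts_path}: non-integer counts in columns "
                f"{list(float_cols)[:3]}"
            )
    tmap = _read_tsv(taxon_map_path)
    gene_taxon = pd.Series(
        tmap["taxon_id"].to_numpy(), index=tmap["gene_id"], name="taxon_id"
    )
    meta = _read_tsv(meta_path, index_col=0).rename_axis(None)
    meta["predation"] = meta["predation"].astype(bool)
    meta["coevolved_prey"] = meta["coevolved_prey"].astype(bool)
    relabund = _read_tsv(relabund_path, index_col=0).rename_axis(None)
    return ExpressionMatrix(counts, gene_taxon, meta, relabund)


def write_count_matrix(em: ExpressionMatrix, outdir: str,
                       seed: int | None = None) -> dict[str, str]:
    """Write the four TSVs read back by :func:`read_count_matrix`."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts": os.path.join(outdir, "counts.tsv"),
        "taxon_map": os.path.join(outdir, "gene_taxon.tsv"),
        "meta": os.path.join(outdir, "sample_meta.tsv"),
        "relabund": os.path.join(outdir, "taxon_relabund.tsv"),
    }
    _write_tsv(em.counts.rename_axis("gene_id"), paths["counts"], seed, index=True)
    tmap = pd.DataFrame(
        {"gene_id": em.gene_taxon.index, "taxon_id": em.gene_taxon.to_numpy()}
    )
    _write_tsv(tmap, paths["taxon_map"], seed)
    meta = em.sample_meta.rename_axis("sample_id").copy()
    meta["predation"] = meta["predation"].astype(bool)
    meta["coevolved_prey"] = meta["coevolved_prey"].astype(bool)
    _write_tsv(meta, paths["meta"], seed, index=True)
    _write_tsv(em.taxon_relabund.rename_axis("taxon_id"), paths["relabund"],
               seed, index=True)
    return paths


# ---------------------------------------------------------------------------
# Pathway maps
# ---------------------------------------------------------------------------

def read_pathway_map(path: str,
                     universe: Iterable[str] | None = None) -> PathwayMap:
    """TSV with columns pathway_id, gene_id and optionally pathway_name."""
    df = _read_tsv(path)
    groups: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        groups.setdefault(row.pathway_id, set()).add(row.gene_id)
        if hasattr(row, "pathway_name"):
            names[row.pathway_id] = row.pathway_name
    return PathwayMap(groups, names=names, universe=universe)


def write_pathway_map(pm: PathwayMap, path: str, seed: int | None = None) -> None:
    rows = [
        {"pathway_id": pid, "gene_id": gid,
         "pathway_name": pm.names.get(pid, pid)}
        for pid, genes in sorted(pm.pathways.items())
        for gid in sorted(genes)
    ]
    _write_tsv(pd.DataFrame(rows), path, seed=seed)
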