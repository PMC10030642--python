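"""Core in-memory containers shared by all pipeline stages.

Coordinates are 1-based inclusive throughout (GFF3/VCF convention); gene
length is ``end - start + 1``.  Strand is stored for completeness but no
statistic in the package is strand-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "GeneCatalog",
    "MutationRecord",
    "MutationTable",
    "ExpressionMatrix",
    "PathwayMap",
]


@dataclass(frozen=True)
class Gene:
    """A single gene model on the reference genome (1-based inclusive)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneCatalog:
    """Gene coordinates and lengths on a (single- or multi-contig) genome.

    Parameters
    ----------
    genome_id:
        Identifier of the reference assembly.
    genome_length:
        Total genome length in bp (for a multi-contig genome, the sum).
    genes:
        Iterable of :class:`Gene`; gene_ids must be unique and coordinates
        must lie within ``genome_length``.
    """

    def __init__(self, genome_id: str, genome_length: int, genes: Iterable[Gene]):
        self.genome_id = genome_id
        self.genome_length = int(genome_length)
        self.genes: list[Gene] = list(genes)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.end > self.genome_length:
                raise ValueError(
                    f"gene {g.gene_id} extends past genome_length "
                    f"({g.end} > {self.genome_length})"
                )
        if not self.genes:
            logger.warning("gene catalog for %s is empty", genome_id)
        self._by_id = {g.gene_id: g for g in self.genes}
        # per-contig lookup index sorted by start, for fast genes_at
        self._index: dict[str, tuple[np.ndarray, np.ndarray, list[str], int]] = {}
        by_contig: dict[str, list[Gene]] = {}
        for g in self.genes:
            by_contig.setdefault(g.contig, []).append(g)
        for contig, gs in by_contig.items():
            gs = sorted(gs, key=lambda g: (g.start, g.gene_id))
            self._index[contig] = (
                np.array([g.start for g in gs]),
                np.array([g.end for g in gs]),
                [g.gene_id for g in gs],
                max(g.length for g in gs),
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def lengths(self) -> np.ndarray:
        """Gene lengths in bp, aligned with :attr:`gene_ids`."""
        return np.array([g.length for g in self.genes], dtype=float)

    @property
    def mean_length(self) -> float:
        """Mean gene length L-bar, the scale factor of gene multiplicity."""
        if not self.genes:
            raise ValueError("empty catalog has no mean gene length")
        return float(self.lengths.mean())

    def contigs(self) -> set[str]:
        return {g.contig for g in self.genes}

    def genes_at(self, contig: str, position: int) -> list[str]:
        """All gene_ids whose interval contains ``position`` on ``contig``.

        Result is sorted so it is invariant to gene order in the source file.
        """
        if contig not in self._index:
            return []
        starts, ends, ids, max_len = self._index[contig]
        hi = int(np.searchsorted(starts, position, side="right"))
        lo = int(np.searchsorted(starts, position - max_len, side="left"))
        return sorted(
            ids[i] for i in range(lo, hi) if ends[i] >= position
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "contig": [g.contig for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "length": [g.length for g in self.genes],
            }
        )


MUTATION_CLASSES = ("substitution", "deletion", "insertion")


@dataclass(frozen=True)
class MutationRecord:
    population_id: str
    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    frequency: float
    mutation_class: str = "substitution"
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError(
                f"{self.population_id}:{self.contig}:{self.position} frequency "
                f"{self.frequency} outside (0, 1]"
            )
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation_class {self.mutation_class!r}")

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.population_id, self.contig, self.position, self.alt_allele)


class MutationTable:
    """Per-population variant records after (or before) filtering."""

    def __init__(self, records: Iterable[MutationRecord]):
        self.records: list[MutationRecord] = list(records)
        keys = [r.key for r in self.records]
        if len(keys) != len(set(keys)):
            from collections import Counter

            dup = [k for k, c in Counter(keys).items() if c > 1][0]
            raise ValueError(f"duplicate mutation record {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def populations(self) -> list[str]:
        return sorted({r.population_id for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population_id": [r.population_id for r in self.records],
                "contig": [r.contig for r in self.records],
                "position": [r.position for r in self.records],
                "ref_allele": [r.ref_allele for r in self.records],
                "alt_allele": [r.alt_allele for r in self.records],
                "frequency": [r.frequency for r in self.records],
                "mutation_class": [r.mutation_class for r in self.records],
                "gene_ids": [",".join(r.gene_ids) for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationTable":
        records = [
            MutationRecord(
                population_id=str(row.population_id),
                contig=str(row.contig),
                position=int(row.position),
                ref_allele=str(row.ref_allele),
                alt_allele=str(row.alt_allele),
                frequency=float(row.frequency),
                mutation_class=str(row.mutation_class),
                gene_ids=tuple(
                    s for s in str(row.gene_ids).split(",") if s and s != "nan"
                ),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records)


class ExpressionMatrix:
    """Gene x sample counts with taxon map, sample metadata and abundances.

    Attributes
    ----------
    counts:
        DataFrame, genes x samples, non-negative integers.
    gene_taxon:
        Series mapping gene_id -> taxon_id; every counted gene must map to
        exactly one taxon.
    sample_meta:
        DataFrame indexed by sample id with columns ``predation`` (bool),
        ``coevolved_prey`` (bool), ``day`` (int), ``replicate`` (int).
    taxon_relabund:
        DataFrame, taxa x samples, columns summing to 1 (amplicon-derived
        relative abundances).
    """

    META_COLUMNS = ("predation", "coevolved_prey", "day", "replicate")

    def __init__(
        self,
        counts: pd.DataFrame,
        gene_taxon: Mapping[str, str] | pd.Series,
        sample_meta: pd.DataFrame,
        taxon_relabund: pd.DataFrame,
    ):
        counts = counts.copy()
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = counts.columns[np.argmax((arr != np.round(arr)).any(axis=0))]
                raise ValueError(f"non-integer counts (e.g. in sample {bad!r})")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = counts

        gene_taxon = pd.Series(dict(gene_taxon)) if not isinstance(
            gene_taxon, pd.Series
        ) else gene_taxon.copy()
        missing = set(counts.index) - set(gene_taxon.index)
        if missing:
            raise ValueError(
                f"genes absent from taxon map: {sorted(missing)[:5]}"
            )
        self.gene_taxon = gene_taxon.loc[counts.index]

        for col in self.META_COLUMNS:
            if col not in sample_meta.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        self.sample_meta = sample_meta.copy()

        samples = list(counts.columns)
        for name, other in (
            ("metadata", list(sample_meta.index)),
            ("relative abundance", list(taxon_relabund.columns)),
        ):
            if set(other) != set(samples):
                off = sorted(set(other) ^ set(samples))
                raise ValueError(f"sample ids mismatch counts vs {name}: {off}")
        self.sample_meta = self.sample_meta.loc[samples]
        taxon_relabund = taxon_relabund[samples]
        colsums = taxon_relabund.sum(axis=0).to_numpy()
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = taxon_relabund.columns[int(np.argmax(np.abs(colsums - 1.0)))]
            raise ValueError(
                f"relative abundance column {bad!r} sums to "
                f"{colsums[np.argmax(np.abs(colsums - 1.0))]:.6f}, not 1"
            )
        self.taxon_relabund = taxon_relabund

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.gene_taxon.unique())

    def genes_of(self, taxon: str) -> list[str]:
        return list(self.gene_taxon.index[self.gene_taxon == taxon])

    def taxon_totals(self) -> pd.DataFrame:
        """Per-(taxon, sample) count totals T_{t,s} (taxa x samples)."""
        return self.counts.groupby(self.gene_taxon).sum()

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        relabund = self.taxon_relabund[samples]
        relabund = relabund / relabund.sum(axis=0)
        return ExpressionMatrix(
            self.counts[samples], self.gene_taxon, self.sample_meta.loc[samples],
            relabund,
        )


class PathwayMap:
    """KEGG-style pathway -> gene-set grouping over a gene universe."""

    def __init__(
        self,
        pathways: Mapping[str, Iterable[str]],
        names: Mapping[str, str] | None = None,
        universe: Iterable[str] | None = None,
    ):
        self.pathways: dict[str, frozenset[str]] = {
            pid: frozenset(genes) for pid, genes in pathways.items()
        }
        self.names = dict(names or {})
        if universe is not None:
            uni = set(universe)
            for pid, genes in self.pathways.items():
                stray = genes - uni
                if stray:
                    raise ValueError(
                        f"pathway {pid!r} references genes outside the "
                        f"universe: {sorted(stray)[:5]}"
                    )

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())
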