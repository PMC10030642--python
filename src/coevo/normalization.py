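"""Within-taxon sum scaling (WTSS) for community transcriptomes.

In a metatranscriptome, a gene's raw counts confound its expression with the
abundance of its source taxon.  WTSS normalizes each gene by its taxon's
total counts in the sample: the size factor of taxon *t* in sample *s* is
``s_{t,s} = T_{t,s} / gmean_s'(T_{t,s'})`` where ``T`` is the taxon-sample
count total, so size factors have geometric mean 1 across samples within
each taxon.  Residual abundance signal (e.g. measurement error in the taxon
totals) is handled downstream by the amplicon relative-abundance covariate
in the NB GLM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

__all__ = ["SizeFactorSet", "within_taxon_size_factors", "taxon_inclusion"]


@dataclass
class SizeFactorSet:
    """Per-(taxon, sample) size factors; NaN marks excluded taxon-samples."""

    factors: pd.DataFrame  # taxa x samples

    def for_genes(self, gene_taxon: pd.Series) -> pd.DataFrame:
        """Expand to a genes x samples factor matrix."""
        return self.factors.loc[gene_taxon.to_numpy()].set_axis(
            gene_taxon.index, axis=0
        )

    def normalize(self, em: ExpressionMatrix) -> pd.DataFrame:
        """Counts divided by their taxon-sample size factor."""
        return em.counts / self.for_genes(em.gene_taxon)


def within_taxon_size_factors(em: ExpressionMatrix) -> SizeFactorSet:
    """Size factors from taxon-sample totals, geometric-mean centred.

    Taxon-samples with a zero total get a NaN factor (their genes cannot be
    tested in that sample); a taxon with zero totals in *every* sample is an
    error.
    """
    totals = em.taxon_totals().astype(float)
    factors = totals.copy()
    for taxon, row in totals.iterrows():
        t = row.to_numpy()
        pos = t > 0
        if not pos.any():
            raise ValueError(f"taxon {taxon!r} has zero counts in all samples")
        gmean = np.exp(np.mean(np.log(t[pos])))
        f = t / gmean
        f[~pos] = np.nan
        factors.loc[taxon] = f
    return SizeFactorSet(factors=factors)


def taxon_inclusion(em: ExpressionMatrix, threshold: float = 0.005) -> list[str]:
    """Taxa whose share of total counts is strictly greater than
    ``threshold`` in every sample (default 0.5 %)."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1)")
    totals = em.taxon_totals()
    share = totals / totals.sum(axis=0)
    keep = (share > threshold).all(axis=1)
    if threshold == 0.0:
        keep = (totals.sum(axis=1) > 0)
    return sorted(share.index[keep])
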