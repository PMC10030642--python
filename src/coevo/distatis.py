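"""DiSTATIS: three-way metric MDS over multiple distance matrices.

Given K distance tables on the same samples (here, per-taxon Euclidean
distances between rlog expression profiles), each table is converted to a
double-centred cross-product matrix, normalized by its first eigenvalue,
and weighted by the first eigenvector of the RV-coefficient congruence
matrix.  The alpha-weighted sum is the *compromise*; its eigendecomposition
yields consensus factor scores, and each table's projection onto the
compromise axes gives its partial factor scores.  Bootstrap resampling of
the tables yields 95 % prediction ellipses for the sample positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "expression_distances",
    "cross_product",
    "table_weights",
    "compromise",
    "bootstrap_compromise",
    "Distatis",
    "DistatisResult",
    "BootstrapEllipses",
]

_EIG_TOL = 1e-9


def expression_distances(rlog: pd.DataFrame,
                         gene_sets: dict[str, list[str]]) -> dict[str, np.ndarray]:
    """Per-taxon Euclidean distance matrices between sample columns."""
    out = {}
    samples = list(rlog.columns)
    for taxon, genes in gene_sets.items():
        missing = set(genes) - set(rlog.index)
        if missing:
            raise ValueError(
                f"genes absent from rlog matrix for {taxon}: "
                f"{sorted(missing)[:5]}"
            )
        X = rlog.loc[genes, samples].to_numpy().T  # samples x genes
        out[taxon] = squareform(pdist(X, metric="euclidean"))
    return out


def _check_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have zero diagonal")
    if (D < -1e-12).any():
        raise ValueError("distance matrix must be nonnegative")
    return D


def cross_product(D: np.ndarray) -> np.ndarray:
    """Normalized double-centred cross-product S~ of a distance matrix.

    ``S = -1/2 C D^(2) C'`` with uniform masses (C = I - 1 m'); S~ = S
    divided by its largest eigenvalue, so lambda_1(S~) = 1 exactly.
    """
    D = _check_distance(D)
    n = D.shape[0]
    C = np.eye(n) - np.ones((n, n)) / n
    S = -0.5 * C @ (D**2) @ C.T
    lam1 = float(np.linalg.eigvalsh(S)[-1])
    if lam1 <= _EIG_TOL:
        raise ValueError("degenerate table: first eigenvalue is not positive")
    return S / lam1


def table_weights(S_list: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """RV-coefficient congruence matrix and the table weights alpha.

    ``C[j,k]`` is the cosine between tables in the Frobenius inner product;
    alpha is the first eigenvector of C (sign-fixed nonnegative) rescaled
    to sum to 1.
    """
    K = len(S_list)
    if K < 2:
        raise ValueError("need at least two tables")
    norms = np.array([np.linalg.norm(S, "fro") for S in S_list])
    C = np.empty((K, K))
    for j in range(K):
        for k in range(j, K):
            C[j, k] = C[k, j] = (
                np.sum(S_list[j] * S_list[k]) / (norms[j] * norms[k])
            )
    vals, vecs = np.linalg.eigh(C)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    alpha = v / v.sum()
    return C, alpha


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude loading positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


@dataclass
class DistatisResult:
    """Compromise decomposition: weights, scores, eigenvalues."""

    congruence: np.ndarray
    alpha: np.ndarray
    compromise_matrix: np.ndarray
    eigenvalues: np.ndarray
    factor_scores: np.ndarray          # samples x dims
    partial_scores: list[np.ndarray]   # per table, samples x dims
    sample_ids: list[str] | None = None
    table_ids: list[str] | None = None

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues

    def n_components_for(self, variance_cutoff: float) -> int:
        """Leading dimensions whose cumulative variance reaches the cutoff."""
        cum = np.cumsum(self.explained_variance_ratio)
        return int(np.searchsorted(cum, variance_cutoff - 1e-12) + 1)


def compromise(S_list: Sequence[np.ndarray],
               alpha: np.ndarray,
               congruence: np.ndarray | None = None,
               sample_ids: list[str] | None = None,
               table_ids: list[str] | None = None) -> DistatisResult:
    """Eigendecompose the alpha-weighted compromise S+ = sum alpha_k S~_k.

    Factor scores are ``F = V Lambda^(1/2)`` (eigenvalues descending, signs
    fixed so the largest loading of each axis is positive); partial scores
    are ``F_k = S~_k V Lambda^(-1/2)``, so ``sum_k alpha_k F_k = F``.
    """
    alpha = np.asarray(alpha, dtype=float)
    S_plus = sum(a * S for a, S in zip(alpha, S_list))
    vals, vecs = np.linalg.eigh(S_plus)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals.min() < -_EIG_TOL * max(1.0, vals.max()):
        raise ValueError(
            f"compromise has a negative eigenvalue ({vals.min():.3g}); "
            "input tables are not positive semi-definite"
        )
    keep = vals > _EIG_TOL * max(1.0, float(vals.max()))
    vals = np.clip(vals[keep], 0.0, None)
    vecs = _fix_signs(vecs[:, keep])
    F = vecs * np.sqrt(vals)
    inv_sqrt = 1.0 / np.sqrt(vals)
    partial = [S @ vecs * inv_sqrt for S in S_list]
    return DistatisResult(
        congruence=congruence if congruence is not None else np.eye(len(S_list)),
        alpha=alpha, compromise_matrix=S_plus, eigenvalues=vals,
        factor_scores=F, partial_scores=partial, sample_ids=sample_ids,
        table_ids=table_ids,
    )


@dataclass
class BootstrapEllipses:
    """95 % prediction ellipses for sample positions in compromise space."""

    centers: np.ndarray        # samples x 2
    covariances: np.ndarray    # samples x 2 x 2
    n_bootstrap: int
    confidence: float = 0.95

    def ellipse_points(self, i: int, n_points: int = 100) -> np.ndarray:
        from scipy import stats

        r2 = stats.chi2.ppf(self.confidence, df=2)
        theta = np.linspace(0, 2 * np.pi, n_points)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        vals, vecs = np.linalg.eigh(self.covariances[i])
        vals = np.clip(vals, 0.0, None)
        return self.centers[i] + circle * np.sqrt(vals * r2) @ vecs.T

    @property
    def areas(self) -> np.ndarray:
        from scipy import stats

        r2 = stats.chi2.ppf(self.confidence, df=2)
        dets = np.linalg.det(self.covariances)
        return np.pi * r2 * np.sqrt(np.clip(dets, 0.0, None))


def bootstrap_compromise(S_list: Sequence[np.ndarray],
                         reference: DistatisResult, B: int = 1000,
                         seed: int = 0,
                         confidence: float = 0.95) -> BootstrapEllipses:
    """Table-level bootstrap of the compromise, projected on reference axes.

    Each replicate resamples the K tables with replacement, recomputes the
    RV weights and compromise matrix, and projects it onto the reference
    eigenvectors; ellipses are 2-D normal approximations to each sample's
    bootstrap cloud in the first two compromise dimensions.
    """
    import logging

    K = len(S_list)
    if K < 3:
        raise ValueError("table bootstrap needs at least 3 tables")
    if B < 100:
        logging.getLogger(__name__).warning(
            "B=%d bootstrap replicates is small; ellipses will be unstable", B
        )
    rng = np.random.default_rng(seed)
    vecs = reference.factor_scores[:, :2] / np.sqrt(reference.eigenvalues[:2])
    inv_sqrt = 1.0 / np.sqrt(reference.eigenvalues[:2])
    n = S_list[0].shape[0]
    cloud = np.empty((B, n, 2))
    for b in range(B):
        idx = rng.integers(0, K, size=K)
        sub = [S_list[i] for i in idx]
        _, alpha_b = table_weights(sub)
        S_plus = sum(a * S for a, S in zip(alpha_b, sub))
        cloud[b] = S_plus @ vecs * inv_sqrt
    centers = cloud.mean(axis=0)
    covs = np.empty((n, 2, 2))
    for i in range(n):
        covs[i] = np.cov(cloud[:, i, :].T)
    return BootstrapEllipses(centers=centers, covariances=covs,
                             n_bootstrap=B, confidence=confidence)


class Distatis:
    """DiSTATIS estimator with sklearn conventions.

    ``fit`` takes a sequence of distance matrices (or a dict name -> matrix)
    on the same samples; ``fit_transform`` returns the compromise factor
    scores.  Fitted attributes: ``alpha_``, ``congruence_``,
    ``eigenvalues_``, ``explained_variance_ratio_``, ``factor_scores_``,
    ``partial_scores_``, ``result_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "Distatis":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "Distatis":
        if isinstance(X, dict):
            table_ids = list(X.keys())
            tables = [X[t] for t in table_ids]
        else:
            tables = list(X)
            table_ids = [f"table_{i + 1}" for i in range(len(tables))]
        sample_ids = None
        if len(tables) and isinstance(tables[0], pd.DataFrame):
            sample_ids = list(tables[0].index)
            tables = [np.asarray(t, dtype=float) for t in tables]
        shapes = {t.shape for t in map(np.asarray, tables)}
        if len(shapes) > 1:
            raise ValueError(f"tables have mismatched shapes: {shapes}")
        self.normalized_tables_ = [cross_product(D) for D in tables]
        self.congruence_, self.alpha_ = table_weights(self.normalized_tables_)
        res = compromise(self.normalized_tables_, self.alpha_,
                         congruence=self.congruence_, sample_ids=sample_ids,
                         table_ids=table_ids)
        if self.n_components is not None:
            res = DistatisResult(
                congruence=res.congruence, alpha=res.alpha,
                compromise_matrix=res.compromise_matrix,
                eigenvalues=res.eigenvalues[: self.n_components],
                factor_scores=res.factor_scores[:, : self.n_components],
                partial_scores=[P[:, : self.n_components]
                                for P in res.partial_scores],
                sample_ids=res.sample_ids, table_ids=res.table_ids,
            )
        self.result_ = res
        self.eigenvalues_ = res.eigenvalues
        self.explained_variance_ratio_ = res.explained_variance_ratio
        self.factor_scores_ = res.factor_scores
        self.partial_scores_ = res.partial_scores
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).factor_scores_
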