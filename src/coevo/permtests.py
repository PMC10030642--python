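"""Permutational MANOVA (PERMANOVA) and dispersion tests (PERMDISP).

PERMANOVA partitions the total sum of squared distances (via the
Gower-centred decomposition) into between- and within-group components and
compares the pseudo-F ratio to its permutation distribution over group
labels.  PERMDISP tests homogeneity of multivariate dispersions: each
sample's distance to its group centroid in principal-coordinate space is
computed, and the ANOVA F on those distances is compared to label
permutations of the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iterperm

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .distatis import DistatisResult

__all__ = ["permanova", "permdisp", "permanova_compromise", "PermTestResult"]


@dataclass
class PermTestResult:
    statistic: float           # pseudo-F
    r_squared: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    method: str = "permanova"
    group_dispersion: dict[str, float] | None = None


def _as_distance(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[0] == X.shape[1] and np.allclose(
            X, X.T) and np.allclose(np.diag(X), 0):
        return X
    return squareform(pdist(X, metric="euclidean"))


def _encode_groups(groups) -> tuple[np.ndarray, list]:
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    codes = np.array([levels.index(g) for g in groups])
    return codes, levels


def _pseudo_f(D2: np.ndarray, codes: np.ndarray, a: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group codes."""
    N = len(codes)
    ss_total = D2[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    for g in range(a):
        idx = np.where(codes == g)[0]
        n_g = len(idx)
        if n_g > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(n_g, 1)].sum() / n_g
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (N - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(X, groups, permutations: int | str = 999,
              seed: int = 0) -> PermTestResult:
    """Permutational multivariate ANOVA on a distance matrix or coordinates.

    ``X`` is either a square distance matrix or a samples x features
    coordinate array (Euclidean distances are taken).  ``permutations`` is
    the number of random label permutations (+1-corrected p), or
    ``"exhaustive"`` to enumerate every distinct assignment of labels to
    samples (p is then the exact fraction of assignments, observed
    included, with F >= F_observed).
    """
    D = _as_distance(X)
    codes, levels = _encode_groups(groups)
    a = len(levels)
    sizes = {str(lv): int((codes == i).sum()) for i, lv in enumerate(levels)}
    if a < 2:
        raise ValueError("need at least two groups")
    if min(sizes.values()) < 2:
        raise ValueError(f"singleton group among {sizes}")
    D2 = D**2
    f_obs, r2 = _pseudo_f(D2, codes, a)

    if permutations == "exhaustive":
        seen = set()
        count = hits = 0
        for perm in _iterperm(codes.tolist()):
            if perm in seen:
                continue
            seen.add(perm)
            count += 1
            f_p, _ = _pseudo_f(D2, np.asarray(perm), a)
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = hits / count
        n_perm = count
    else:
        rng = np.random.default_rng(seed)
        n_perm = int(permutations)
        hits = 0
        for _ in range(n_perm):
            f_p, _ = _pseudo_f(D2, rng.permutation(codes), a)
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
    return PermTestResult(statistic=f_obs, r_squared=r2, p_value=p,
                          n_permutations=n_perm, group_sizes=sizes,
                          method="permanova")


def permanova_compromise(result: DistatisResult, groups,
                         variance_cutoff: float = 0.99,
                         permutations: int | str = 999,
                         seed: int = 0) -> PermTestResult:
    """PERMANOVA on the leading compromise dimensions.

    Dimensions are retained until their cumulative explained variance
    reaches ``variance_cutoff`` (default 99 %); Euclidean distances between
    the truncated factor scores are then tested.
    """
    d = result.n_components_for(variance_cutoff)
    return permanova(result.factor_scores[:, :d], groups,
                     permutations=permutations, seed=seed)


def permdisp(X, groups, permutations: int = 999, seed: int = 0) -> PermTestResult:
    """Permutational test of multivariate dispersion homogeneity.

    Distances to group centroids are computed in the principal-coordinate
    embedding of the distance matrix (negative-eigenvalue axes contribute
    with negative squared distance, following the standard correction);
    the ANOVA F on those distances is compared to permutations of group
    labels.
    """
    D = _as_distance(X)
    codes, levels = _encode_groups(groups)
    a = len(levels)
    sizes = {str(lv): int((codes == i).sum()) for i, lv in enumerate(levels)}
    if a < 2:
        raise ValueError("need at least two groups")
    if min(sizes.values()) < 2:
        raise ValueError(f"singleton group among {sizes}")
    N = len(codes)
    # PCoA embedding
    C = np.eye(N) - np.ones((N, N)) / N
    G = -0.5 * C @ (D**2) @ C.T
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    neg = vals < -1e-10
    Ypos = vecs[:, pos] * np.sqrt(vals[pos])
    Yneg = vecs[:, neg] * np.sqrt(-vals[neg])

    z = np.empty(N)
    for g in range(a):
        idx = np.where(codes == g)[0]
        cp = Ypos[idx].mean(axis=0)
        cn = Yneg[idx].mean(axis=0) if Yneg.shape[1] else np.zeros(0)
        d2 = ((Ypos[idx] - cp) ** 2).sum(axis=1)
        if Yneg.shape[1]:
            d2 = d2 - ((Yneg[idx] - cn) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.clip(d2, 0.0, None))

    def anova_f(zv: np.ndarray, cd: np.ndarray) -> float:
        grand = zv.mean()
        ssb = sum(
            (cd == g).sum() * (zv[cd == g].mean() - grand) ** 2
            for g in range(a)
        )
        ssw = sum(((zv[cd == g] - zv[cd == g].mean()) ** 2).sum()
                  for g in range(a))
        if ssw == 0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / (a - 1)) / (ssw / (N - a))

    f_obs = anova_f(z, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if anova_f(z, rng.permutation(codes)) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (permutations + 1)
    disp = {str(lv): float(z[codes == i].mean()) for i, lv in enumerate(levels)}
    grand = z.mean()
    ssb = sum((codes == g).sum() * (z[codes == g].mean() - grand) ** 2
              for g in range(a))
    sst = ((z - grand) ** 2).sum()
    return PermTestResult(statistic=f_obs,
                          r_squared=float(ssb / sst) if sst > 0 else 0.0,
                          p_value=p, n_permutations=permutations,
                          group_sizes=sizes, method="permdisp",
                          group_dispersion=disp)
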