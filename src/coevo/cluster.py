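"""K-means with Krzanowski-Lai selection of the number of clusters.

The KL index compares successive differences of dimension-scaled
within-cluster sums of squares, ``DIFF(k) = (k-1)^(2/p) W_{k-1} -
k^(2/p) W_k``; the chosen k maximizes ``KL(k) = |DIFF(k) / DIFF(k+1)|``
over the candidate range.  A pronounced elbow at the true cluster count
makes DIFF(k+1) collapse and KL(k) spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["KLKMeans", "ClusterResult", "kmeans_kl"]


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    kl_index: dict[int, float]
    inertia: dict[int, float]


class KLKMeans:
    """K-means clustering with KL-index model selection (sklearn style).

    Parameters
    ----------
    k_range:
        Inclusive (min, max) candidate cluster counts; the default upper
        bound is capped at n - 2 at fit time.
    n_restarts:
        Seeded k-means restarts per candidate k.
    random_state:
        Seed for all restarts.
    """

    def __init__(self, k_range: tuple[int, int] = (2, 8),
                 n_restarts: int = 25, random_state: int | None = 0):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"k_range": self.k_range, "n_restarts": self.n_restarts,
                "random_state": self.random_state}

    def set_params(self, **params) -> "KLKMeans":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "KLKMeans":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        k_lo, k_hi = self.k_range
        k_hi = min(k_hi, n - 2)
        if k_lo < 2 or k_hi < k_lo:
            raise ValueError(
                f"candidate range [{k_lo}, {k_hi}] invalid for n={n} samples"
            )
        # W_k needed for k_lo-1 .. k_hi+1
        W: dict[int, float] = {}
        labels: dict[int, np.ndarray] = {}
        for k in range(max(1, k_lo - 1), k_hi + 2):
            if k == 1:
                W[1] = float(((X - X.mean(axis=0)) ** 2).sum())
                labels[1] = np.zeros(n, dtype=int)
                continue
            km = KMeans(n_clusters=k, n_init=self.n_restarts,
                        random_state=self.random_state).fit(X)
            W[k] = float(km.inertia_)
            labels[k] = km.labels_

        def diff(k: int) -> float:
            return (k - 1) ** (2.0 / p) * W[k - 1] - k ** (2.0 / p) * W[k]

        kl: dict[int, float] = {}
        for k in range(k_lo, k_hi + 1):
            d_next = diff(k + 1)
            if d_next == 0.0:
                kl[k] = np.inf if diff(k) != 0 else 0.0
            else:
                kl[k] = abs(diff(k) / d_next)
        best = max(kl, key=lambda k: (kl[k], -k))
        self.k_ = best
        self.labels_ = labels[best] + 1  # 1-based cluster ids
        self.kl_index_ = kl
        self.inertia_per_k_ = W
        self.result_ = ClusterResult(labels=self.labels_, k=best,
                                     kl_index=kl, inertia=W)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def kmeans_kl(X, k_range: tuple[int, int] = (2, 8), n_restarts: int = 25,
              seed: int | None = 0) -> ClusterResult:
    """Functional wrapper over :class:`KLKMeans`."""
    return KLKMeans(k_range=k_range, n_restarts=n_restarts,
                    random_state=seed).fit(X).result_
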