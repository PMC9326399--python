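"""Sample-to-sample similarity via a self-tuning, density-aware kernel.

Each modality's samples x features matrix is turned into an n x n affinity

    W_ij = exp( - d_ij^2 / ( sigma_i sigma_j (CNN_ij + 1) ) )

where d is Euclidean distance, sigma_i is the distance from sample i to its
k-th nearest neighbor (the Zelnik-Manor / Perona local scale), and CNN_ij
counts the common members of the two samples' k-nearest-neighbor sets.  The
CNN factor amplifies similarity inside locally dense neighborhoods —
samples whose neighborhoods agree are pulled together — and can be switched
off, which reduces the kernel to the plain self-tuning form
exp(-d_ij^2 / sigma_i sigma_j).

``tune_kernel`` scans a grid of k values and keeps the kernel whose
spectrum shows the sharpest multimodality drop (see
:func:`omicsfuse.cluster.select_k_multimodality`), the same criterion that
later picks the cluster number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .omics_io import OmicsMatrix

logger = logging.getLogger("omicsfuse")

Provenance = Literal["single_view", "combined", "diffused"]


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean distance matrix with a zero diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite distances")
        if (self.values < 0).any():
            raise ValueError("negative distances")
        # exact symmetry enforced by averaging with the transpose
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class SimilarityMatrix:
    """Symmetric nonnegative n x n sample-sample affinity."""

    values: np.ndarray
    sample_ids: list[str]
    provenance: Provenance = "single_view"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match sample_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite similarities")
        if (self.values < 0).any():
            raise ValueError("negative similarities")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("similarity matrix not symmetric within 1e-10")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class KernelConfig:
    """Parameters of the adaptive kernel.

    k_nn : local-scale neighbor index (sigma_i = distance to the k_nn-th
        nearest neighbor, self excluded).  Default 10, a mid-density choice
        for cohorts of a few hundred samples.
    use_density : include the common-nearest-neighbor density factor.
    k_grid : candidate k values for ``tune_kernel``.
    """

    k_nn: int = 10
    use_density: bool = True
    k_grid: list[int] = field(default_factory=lambda: [3, 5, 7, 10, 15, 20])

    def __post_init__(self) -> None:
        if self.k_nn < 1:
            raise ValueError("k_nn must be positive")


def pairwise_distance(m: OmicsMatrix) -> DistanceMatrix:
    """Euclidean distances between sample rows."""
    if m.n_samples < 2:
        raise ValueError("pairwise_distance needs at least two samples")
    d = squareform(pdist(m.values, metric="euclidean"))
    return DistanceMatrix(d, list(m.sample_ids))


def _knn_sets(d: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (sigma, membership) for k-nearest neighbors, self excluded.

    sigma[i] is the distance to the k-th nearest neighbor.  membership is a
    boolean n x n matrix with membership[i, j] True when j is among i's k
    nearest neighbors.  Ties are broken by sample order (stable argsort).
    """
    n = d.shape[0]
    if k >= n:
        raise ValueError(f"k_nn={k} must be smaller than n={n}")
    d_noself = d.copy()
    np.fill_diagonal(d_noself, np.inf)
    order = np.argsort(d_noself, axis=1, kind="stable")
    nn = order[:, :k]
    sigma = d_noself[np.arange(n)[:, None], nn][:, -1]
    membership = np.zeros((n, n), dtype=bool)
    membership[np.arange(n)[:, None], nn] = True
    return sigma, membership


def adaptive_kernel(d: DistanceMatrix, cfg: KernelConfig) -> SimilarityMatrix:
    """Self-tuning density-aware kernel on a distance matrix.

    Duplicate points make sigma_i = 0; such scales are replaced by the
    smallest positive scale observed (logged), keeping the kernel finite.
    """
    sigma, member = _knn_sets(d.values, cfg.k_nn)
    if (sigma == 0).any():
        positive = sigma[sigma > 0]
        if positive.size == 0:
            raise ValueError("all local scales are zero (all points identical)")
        floor = positive.min()
        logger.warning(
            "adaptive_kernel: %d zero local scales floored to %.3g",
            int((sigma == 0).sum()), floor,
        )
        sigma = np.where(sigma == 0, floor, sigma)
    scale = np.outer(sigma, sigma)
    if cfg.use_density:
        cnn = (member.astype(np.float64) @ member.T.astype(np.float64))
        scale = scale * (cnn + 1.0)
    w = np.exp(-(d.values**2) / scale)
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 1.0)
    return SimilarityMatrix(w, list(d.sample_ids), provenance="single_view")


def tune_kernel(
    d: DistanceMatrix, cfg: KernelConfig, eigen_budget: int = 11
) -> tuple[int, SimilarityMatrix]:
    """Pick the neighborhood size whose kernel has the sharpest dip drop.

    For every k in ``cfg.k_grid`` the kernel is built and the multimodality
    gap score — the maximal drop between consecutive per-eigenvector dip
    statistics of the normalized kernel spectrum — is evaluated.  The k with
    the largest score wins; ties go to the smallest k.
    """
    from .cluster import multimodality_drops, spectral_eigen

    if not cfg.k_grid:
        raise ValueError("k_grid must be nonempty")
    best: tuple[float, int, SimilarityMatrix] | None = None
    for k in sorted(cfg.k_grid):
        sub = KernelConfig(k_nn=k, use_density=cfg.use_density, k_grid=cfg.k_grid)
        w = adaptive_kernel(d, sub)
        m = min(eigen_budget, w.n)
        es = spectral_eigen(w, m)
        drops = multimodality_drops(es, m - 1)
        score = float(drops[1:].max()) if len(drops) > 1 else float(drops.max())
        logger.info("tune_kernel: k=%d score=%.5f", k, score)
        if best is None or score > best[0] + 1e-12:
            best = (score, k, w)
    assert best is not None
    logger.info("tune_kernel: selected k=%d", best[1])
    return best[1], best[2]


def combine_ids_match(views: Sequence[SimilarityMatrix]) -> None:
    ids = views[0].sample_ids
    for v in views[1:]:
        if v.sample_ids != ids:
            raise ValueError("similarity matrices have mismatched sample ids/order")


def write_similarity(w: SimilarityMatrix, path) -> None:
    """Write a square, headered similarity TSV (audit / precomputed input)."""
    import pandas as pd

    pd.DataFrame(w.values, index=w.sample_ids, columns=w.sample_ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def read_similarity(path, provenance: Provenance = "diffused") -> SimilarityMatrix:
    """Read a square similarity TSV written by :func:`write_similarity`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("similarity TSV must be square with matching row/column ids")
    return SimilarityMatrix(df.to_numpy(float), [str(s) for s in df.index], provenance)
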