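"""Multi-view integration: kernel addition and tensor-product-graph diffusion.

The per-modality affinities are combined by plain elementwise addition
(equal view weights), then denoised by diffusion on the tensor-product
graph — the graph whose nodes are ordered sample pairs and whose adjacency
is the Kronecker product S (x) S.  Materializing that n^2 x n^2 operator is
infeasible beyond toy sizes, but the diffusion iterate

    Q_1 = S,   Q_{t+1} = S Q_t S^T + I

computes exactly the same series implicitly: vec(Q_t) follows
q_{t+1} = (S (x) S) q_t + vec(I).  With spectral radius rho(S) < 1 the
iteration converges to Q* = sum_m S^m (S^m)^T, a smoothed affinity in which
similarity flows along consistent paths in all views.  Convergence is
guaranteed here by row-normalizing a kNN-sparsified graph with the DENSE
row sums of the combined affinity: every row sheds the mass of its dropped
entries, making S strictly substochastic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kernel import SimilarityMatrix, combine_ids_match

logger = logging.getLogger("omicsfuse")


@dataclass
class DiffusionConfig:
    """Controls for TPG diffusion.

    knn_sparsify : number of strongest off-diagonal entries kept per row
        before normalization (kept symmetric by union).  Every row must
        shed affinity mass — through the excluded diagonal and/or dropped
        neighbors — for the series to converge; the spectral-radius guard
        in :func:`tpg_diffuse` enforces this and suggests lowering
        knn_sparsify when it fails.
    max_iter, tol : stopping rule on the Frobenius norm of successive
        iterates.
    """

    knn_sparsify: int = 10
    max_iter: int = 30
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.knn_sparsify < 1 or self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid DiffusionConfig")


def combine_kernels(views: Sequence[SimilarityMatrix]) -> SimilarityMatrix:
    """Elementwise sum of per-view similarity matrices (kernel addition)."""
    if not views:
        raise ValueError("no views to combine")
    combine_ids_match(views)
    total = np.zeros_like(views[0].values)
    for v in views:
        total = total + v.values
    return SimilarityMatrix(total, list(views[0].sample_ids), provenance="combined")


def _sparsify_knn(a: np.ndarray, k: int) -> np.ndarray:
    """Keep each row's k strongest off-diagonal entries, symmetrized by union."""
    n = a.shape[0]
    if k >= n - 1:
        return a.copy()
    off = a.copy()
    np.fill_diagonal(off, -np.inf)
    # stable selection: sort descending by value, ties by column index
    order = np.argsort(-off, axis=1, kind="stable")
    keep = np.zeros((n, n), dtype=bool)
    keep[np.arange(n)[:, None], order[:, :k]] = True
    keep |= keep.T  # union symmetrization
    out = np.where(keep, a, 0.0)
    np.fill_diagonal(out, np.diag(a))
    return out


def _diffuse_iterations(
    s: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, int]:
    """Iterate Q_1 = S, Q_{t+1} = S Q_t S^T + I until the Frobenius change
    falls below ``tol``.  Returns (Q, iterations used).  Exposed separately
    so the fixed-point algebra can be exercised on injected operators."""
    eye = np.eye(s.shape[0])
    q = s.copy()
    for it in range(1, max_iter + 1):
        q_next = s @ q @ s.T + eye
        delta = float(np.linalg.norm(q_next - q, "fro"))
        q = q_next
        if delta < tol:
            logger.info("tpg_diffuse: converged after %d iterations (|dQ|=%.3g)", it, delta)
            return q, it
    logger.info("tpg_diffuse: stopped at max_iter=%d (|dQ|=%.3g)", max_iter, delta)
    return q, max_iter


def tpg_diffuse(a: SimilarityMatrix, cfg: DiffusionConfig | None = None) -> SimilarityMatrix:
    """Diffuse an affinity matrix on its tensor-product graph.

    Steps: (1) kNN-sparsify ``a`` (union-symmetric); (2) row-normalize the
    sparsified matrix by the dense row sums of ``a`` (diagonal excluded from
    kNN selection, reinstated by the +I term); (3) iterate
    Q <- S Q S^T + I to convergence; (4) return the symmetrized Q.

    Raises on an all-zero row (disconnected sample) or when rho(S) >= 1.
    """
    cfg = cfg or DiffusionConfig()
    row_sums = a.values.sum(axis=1)
    if (row_sums <= 0).any():
        bad = [a.sample_ids[i] for i in np.flatnonzero(row_sums <= 0)]
        raise ValueError(f"zero row sum for samples {bad}")
    sparsified = _sparsify_knn(a.values, cfg.knn_sparsify)
    np.fill_diagonal(sparsified, 0.0)
    s = sparsified / row_sums[:, None]
    # S = D^-1 A_sp is similar to D^-1/2 A_sp D^-1/2, so its spectrum is real;
    # strict substochasticity must give rho < 1 for the series to converge.
    conj = sparsified / np.sqrt(np.outer(row_sums, row_sums))
    rho = float(np.abs(np.linalg.eigvalsh(conj)).max())
    if rho >= 1.0 - 1e-12:
        raise ValueError(
            f"spectral radius {rho:.6f} >= 1; lower knn_sparsify so each row "
            "drops affinity mass"
        )
    q, _ = _diffuse_iterations(s, cfg.tol, cfg.max_iter)
    q = 0.5 * (q + q.T)
    return SimilarityMatrix(q, list(a.sample_ids), provenance="diffused")
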