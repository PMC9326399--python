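"""Diffusion-potential (PHATE-style) two-dimensional embedding.

The chain: an alpha-decay kernel (or a precomputed integrated similarity)
is row-normalized into a diffusion operator P, powered t steps so that
probability mass spreads along the data manifold, converted to potential
coordinates U_i = -log(P^t_i. + eps), and the pairwise Euclidean distances
between potentials are embedded in 2-D by metric MDS (classical solution
as initialization, SMACOF stress majorization to refine).  Powering with
t large denoises and reveals global trajectory structure; t can be chosen
automatically at the knee of the von Neumann entropy of the diffusion
spectrum.  Axes are conventionally named PHATE1/PHATE2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform

from .kernel import DistanceMatrix, SimilarityMatrix, pairwise_distance
from .omics_io import OmicsMatrix

logger = logging.getLogger("omicsfuse")


@dataclass
class PhateConfig:
    """Embedding parameters.

    knn : neighbor index for the local bandwidth sigma_i (default 5).
    decay_alpha : exponent of the alpha-decay kernel (default 40); larger
        values sharpen the kernel toward a hard kNN graph.
    t : diffusion time; "auto" picks the von Neumann entropy knee.  The
        integrated-similarity pipeline uses t = 200.
    epsilon_floor : additive floor inside the log potential (default 1e-12)
        keeping potential distances finite.
    mds_max_iter : SMACOF iteration cap.
    seed : reserved for stochastic MDS variants; the default path is
        deterministic.
    """

    knn: int = 5
    decay_alpha: float = 40.0
    t: int | str = "auto"
    epsilon_floor: float = 1e-12
    mds_max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knn < 1 or self.decay_alpha <= 0 or self.epsilon_floor <= 0:
            raise ValueError("invalid PhateConfig")
        if self.t != "auto" and (not isinstance(self.t, int) or self.t < 1):
            raise ValueError("t must be a positive integer or 'auto'")


@dataclass
class DiffusionOperator:
    """Row-stochastic transition matrix with the applied power recorded."""

    values: np.ndarray
    sample_ids: list[str]
    t_applied: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("operator shape does not match sample_ids")
        if (self.values < 0).any():
            raise ValueError("negative transition probabilities")
        rows = self.values.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-10:
            raise ValueError("rows must sum to 1 within 1e-10")


@dataclass
class Embedding:
    """n x 2 coordinates (PHATE1, PHATE2) with the final MDS stress."""

    coords: np.ndarray
    sample_ids: list[str]
    stress: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sample_ids), 2):
            raise ValueError("coords must be n x 2")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if np.abs(self.coords.mean(axis=0)).max() > 1e-8:
            raise ValueError("coordinates must be mean-centered")


def alpha_decay_kernel(d: DistanceMatrix, cfg: PhateConfig) -> SimilarityMatrix:
    """Symmetric alpha-decay kernel
    K_ij = 1/2 exp(-(d_ij/sigma_i)^a) + 1/2 exp(-(d_ij/sigma_j)^a)."""
    n = d.n
    if cfg.knn >= n:
        raise ValueError("knn must be smaller than n")
    dv = d.values.copy()
    np.fill_diagonal(dv, np.inf)
    part = np.partition(dv, cfg.knn - 1, axis=1)
    sigma = part[:, cfg.knn - 1]
    if (sigma == 0).any():
        positive = sigma[sigma > 0]
        if positive.size == 0:
            raise ValueError("all local bandwidths are zero")
        floor = positive.min()
        logger.warning(
            "alpha_decay_kernel: %d zero bandwidths floored to %.3g",
            int((sigma == 0).sum()), floor,
        )
        sigma = np.where(sigma == 0, floor, sigma)
    np.fill_diagonal(dv, 0.0)
    with np.errstate(over="ignore"):
        ki = np.exp(-((dv / sigma[:, None]) ** cfg.decay_alpha))
    w = 0.5 * (ki + ki.T)
    return SimilarityMatrix(w, list(d.sample_ids), provenance="single_view")


def diffusion_operator(w: SimilarityMatrix) -> DiffusionOperator:
    """Row-normalize an affinity into a Markov transition matrix P = D^-1 W."""
    rows = w.values.sum(axis=1)
    if (rows <= 0).any():
        bad = [w.sample_ids[i] for i in np.flatnonzero(rows <= 0)]
        raise ValueError(f"zero affinity row for samples {bad}")
    return DiffusionOperator(w.values / rows[:, None], list(w.sample_ids), t_applied=1)


def diffuse_power(p: DiffusionOperator, t: int) -> DiffusionOperator:
    """P^t by repeated squaring; stochasticity is re-asserted and restored
    against float drift after each multiply."""
    if t < 1:
        raise ValueError("t must be >= 1")
    result = None
    base = p.values.copy()
    e = t
    while e:
        if e & 1:
            result = base.copy() if result is None else _stochastic_mult(result, base)
        e >>= 1
        if e:
            base = _stochastic_mult(base, base)
    assert result is not None
    return DiffusionOperator(result, list(p.sample_ids), t_applied=p.t_applied * t)


def _stochastic_mult(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = a @ b
    rows = out.sum(axis=1)
    if np.abs(rows - 1.0).max() > 1e-10:
        raise AssertionError("row-stochasticity lost during powering")
    return out / rows[:, None]


def von_neumann_entropy(
    p: DiffusionOperator, t_range: Sequence[int]
) -> tuple[list[float], int]:
    """Spectral entropy H(t) of P^t over a grid of diffusion times.

    Eigenvalues of the symmetric conjugate of P are powered, floored at 0
    and renormalized to a distribution; H(t) = -sum eta log eta.  The knee
    t is the grid point farthest from the chord joining the end points
    (the "kneedle" rule) and serves as the automatic diffusion time.
    """
    t_range = list(t_range)
    if any(np.diff(t_range) <= 0) or not t_range:
        raise ValueError("t_range must be increasing and nonempty")
    lam = np.real(scipy.linalg.eigvals(p.values))
    entropies = []
    for t in t_range:
        eta = np.where(lam > 0, lam, 0.0) ** t
        total = eta.sum()
        if total <= 0:
            entropies.append(0.0)
            continue
        eta = eta / total
        nz = eta[eta > 0]
        entropies.append(float(-(nz * np.log(nz)).sum()))
    h = np.asarray(entropies)
    t_arr = np.asarray(t_range, dtype=float)
    if len(t_range) < 3 or h[0] == h[-1]:
        return entropies, t_range[0]
    # distance from the chord (t0, h0) -- (t1, h1)
    dt, dh = t_arr[-1] - t_arr[0], h[-1] - h[0]
    dist = np.abs(dh * (t_arr - t_arr[0]) - dt * (h - h[0])) / np.hypot(dt, dh)
    return entropies, int(t_range[int(np.argmax(dist))])


def potential_distance(p: DiffusionOperator, eps: float = 1e-12) -> DistanceMatrix:
    """Euclidean distances between log-potential rows -log(P_i. + eps)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    u = -np.log(p.values + eps)
    d = squareform(pdist(u, metric="euclidean"))
    return DistanceMatrix(d, list(p.sample_ids))


def _classical_mds(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * j @ d2 @ j
    vals, vecs = scipy.linalg.eigh(bmat)
    order = np.argsort(-vals)[:2]
    vals2 = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals2)
    for jj in range(2):  # reproducible axis orientation
        col = coords[:, jj]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, jj] = -col
    return coords


def mds_embed(d: DistanceMatrix, cfg: PhateConfig | None = None) -> Embedding:
    """Metric MDS of a distance matrix into 2-D.

    Classical (double-centering) MDS initializes; SMACOF stress
    majorization refines until the relative stress change drops below
    1e-8 or ``mds_max_iter`` is reached.  Output is mean-centered.
    """
    cfg = cfg or PhateConfig()
    dv = d.values
    n = dv.shape[0]
    if not np.any(dv > 0):
        logger.warning("mds_embed: all distances zero; returning origin")
        return Embedding(np.zeros((n, 2)), list(d.sample_ids), 0.0)
    x = _classical_mds(dv**2)
    stress_prev = np.inf
    stress = _stress(dv, x)
    it = 0
    while it < cfg.mds_max_iter and (stress_prev - stress) > 1e-8 * max(stress_prev, 1e-30):
        x = _guttman(dv, x)
        stress_prev, stress = stress, _stress(dv, x)
        it += 1
    x = x - x.mean(axis=0)
    logger.info("mds_embed: %d SMACOF iterations, stress %.6g", it, stress)
    return Embedding(x, list(d.sample_ids), float(stress))


def _stress(d: np.ndarray, x: np.ndarray) -> float:
    dz = squareform(pdist(x))
    return float(((d - dz) ** 2).sum() / 2.0)


def _guttman(d: np.ndarray, x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    dz = squareform(pdist(x))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dz > 0, d / np.where(dz > 0, dz, 1.0), 0.0)
    bmat = -ratio
    np.fill_diagonal(bmat, 0.0)
    np.fill_diagonal(bmat, -bmat.sum(axis=1))
    return bmat @ x / n


def phate(
    data: Union[OmicsMatrix, SimilarityMatrix], cfg: PhateConfig | None = None
) -> Embedding:
    """Full diffusion-potential embedding.

    Raw-feature mode (an OmicsMatrix) builds the alpha-decay kernel from
    Euclidean distances with t defaulting to the entropy knee;
    precomputed mode (a SimilarityMatrix, e.g. the diffused multimodal
    affinity) uses the given matrix directly as the kernel.
    """
    cfg = cfg or PhateConfig()
    if isinstance(data, OmicsMatrix):
        w = alpha_decay_kernel(pairwise_distance(data), cfg)
    elif isinstance(data, SimilarityMatrix):
        w = data
    else:
        raise TypeError("phate expects an OmicsMatrix or SimilarityMatrix")
    p = diffusion_operator(w)
    if cfg.t == "auto":
        _, t = von_neumann_entropy(p, range(1, 101))
        logger.info("phate: auto diffusion time t=%d", t)
    else:
        t = int(cfg.t)
    pt = diffuse_power(p, t) if t > 1 else p
    dist = potential_distance(pt, cfg.epsilon_floor)
    return mds_embed(dist, cfg)


def write_embedding(e: Embedding, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"sample_id": e.sample_ids, "PHATE1": e.coords[:, 0], "PHATE2": e.coords[:, 1]}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def plot_embedding(e: Embedding, color=None, path=None, title: str | None = None):
    """Simple scatter of the embedding with an optional categorical or
    continuous overlay; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if color is None:
        ax.scatter(e.coords[:, 0], e.coords[:, 1], s=14)
    else:
        color = np.asarray(color)
        if color.dtype.kind in "OUS":
            for lab in np.unique(color):
                m = color == lab
                ax.scatter(e.coords[m, 0], e.coords[m, 1], s=14, label=str(lab))
            ax.legend(fontsize=7, markerscale=1.2)
        else:
            sc = ax.scatter(e.coords[:, 0], e.coords[:, 1], s=14, c=color, cmap="viridis")
            fig.colorbar(sc, ax=ax)
    ax.set_xlabel("PHATE1")
    ax.set_ylabel("PHATE2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
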