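"""Diffusion-map embedding of connectomes and manifold summaries.

The embedding follows the standard connectome-gradient recipe: a cosine
similarity affinity between connectivity profiles, density normalisation of
the affinity by row sums to the power ``alpha``, row-normalisation to a
random-walk transition matrix, and an eigendecomposition whose nontrivial
eigenvectors give the manifold coordinates M1..Mk.  ``alpha`` controls the
influence of the sampling density (``alpha=0`` maximal, ``alpha=1`` none) and
the diffusion time ``t`` the eigenvalue scaling; the defaults ``alpha=0.5``,
``t=0`` retain global relations between parcels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from .connectome import Connectome


class ManifoldError(ValueError):
    """Invalid manifold input."""


@dataclass
class Embedding:
    """Parcel-by-k manifold coordinates with spectrum metadata.

    ``coords[:, i]`` is coordinate M(i+1).  ``eigenvalues`` are the
    nontrivial transition-matrix eigenvalues, descending; each
    ``variance_explained[i]`` is that eigenvalue's share of the full
    nontrivial (positive) spectrum, so the fractions sum to at most one.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    alpha_diffusion: float = 0.5
    diffusion_time: float = 0.0

    @property
    def n_parcels(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass
class WeightedManifold:
    """Seed-weighted manifold coordinates wM1–wM3 for one seed structure."""

    wcoords: np.ndarray


def cosine_affinity(c) -> np.ndarray:
    """Cosine similarity between connectivity profiles (rows).

    The diagonal of the input is zero, so self-connections do not inflate
    similarity.  Output is symmetric with unit diagonal; for nonnegative
    connectomes entries are nonnegative, and any negative value arising from
    signed inputs is clipped to zero as a guard for the nonnegative-affinity
    requirement of the embedding.
    """
    w = c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    norms = np.linalg.norm(w, axis=1)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        raise ManifoldError(f"all-zero connectivity row for parcel(s) {zero.tolist()}")
    aff = (w @ w.T) / np.outer(norms, norms)
    aff = np.clip(aff, 0.0, 1.0)
    return (aff + aff.T) / 2


def diffusion_embedding(
    affinity: np.ndarray,
    k: int = 3,
    alpha: float = 0.5,
    t: float = 0.0,
) -> Embedding:
    """Diffusion-map embedding of a symmetric nonnegative affinity matrix.

    Steps: density-normalise ``W' = D^-a W D^-a``; row-normalise to the
    transition matrix ``P = D'^-1 W'``; eigendecompose via the conjugate
    symmetric matrix; drop the trivial constant eigenvector (eigenvalue 1);
    scale coordinate ``i`` by ``lam_i / (1 - lam_i)`` when ``t == 0`` and by
    ``lam_i ** t`` otherwise.  Eigenvector signs are fixed so each column's
    largest-magnitude entry is positive.
    """
    w = np.asarray(affinity, dtype=float)
    n = w.shape[0]
    if w.ndim != 2 or w.shape[1] != n:
        raise ManifoldError("affinity must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ManifoldError("affinity must be symmetric")
    if np.any(w < 0):
        raise ManifoldError("affinity must be nonnegative")
    if k >= n:
        raise ManifoldError(f"k={k} must be smaller than matrix size {n}")
    n_comp, _ = connected_components((w > 0).astype(int), directed=False)
    if n_comp > 1:
        raise ManifoldError("affinity graph is disconnected")

    d = w.sum(axis=1)
    w1 = w / np.outer(d**alpha, d**alpha)
    d1 = w1.sum(axis=1)
    # symmetric conjugate of the transition matrix D1^-1 W1
    s = w1 / np.sqrt(np.outer(d1, d1))
    s = (s + s.T) / 2
    lam, u = scipy.linalg.eigh(s)
    order = np.argsort(lam)[::-1]
    lam, u = lam[order], u[:, order]
    # eigenvectors of P
    psi = u / np.sqrt(d1)[:, None]
    # drop trivial eigenvector (lambda ~ 1, constant psi); normalise by phi0
    lam_nt = lam[1:]
    psi_nt = psi[:, 1:] / psi[0, 0]

    if t == 0:
        with np.errstate(divide="ignore"):
            scale = lam_nt / (1.0 - lam_nt)
    else:
        scale = np.sign(lam_nt) * np.abs(lam_nt) ** t
    coords = psi_nt[:, :k] * scale[:k]
    # deterministic sign: largest-magnitude entry of each column positive
    for j in range(coords.shape[1]):
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    pos = np.clip(lam_nt, 0.0, None)
    total = pos.sum()
    var_exp = (pos[:k] / total) if total > 0 else np.zeros(k)
    return Embedding(
        coords=coords,
        eigenvalues=lam_nt[:k],
        variance_explained=var_exp,
        alpha_diffusion=alpha,
        diffusion_time=t,
    )


def procrustes_align(source: Embedding, target: Embedding) -> Embedding:
    """Align ``source`` to ``target`` by an orthogonal rotation/reflection.

    Right-multiplies the source coordinates by the orthogonal matrix that
    minimises the Frobenius distance to the target (no scaling, no
    translation), so per-parcel vector norms are preserved.
    """
    if source.coords.shape != target.coords.shape:
        raise ManifoldError("source and target must share parcel set and k")
    r, _ = scipy.linalg.orthogonal_procrustes(source.coords, target.coords)
    return replace(source, coords=source.coords @ r)


def manifold_eccentricity(e: Embedding, center: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-parcel Euclidean distance from the manifold center in M1–M3.

    ``center`` defaults to the embedding's own per-dimension mean; pass the
    template centroid to measure individual eccentricity in template space.
    """
    if e.k < 3:
        raise ManifoldError("eccentricity requires at least 3 manifold dimensions")
    coords = e.coords[:, :3]
    if center is None:
        center = coords.mean(axis=0)
    center = np.asarray(center, dtype=float)[:3]
    return np.linalg.norm(coords - center[None, :], axis=1)


def weighted_manifold(e: Embedding, seed_weights: np.ndarray) -> WeightedManifold:
    """Weight cortical manifold coordinates by seed-to-parcel streamline values.

    ``wM_d(p) = M_d(p) * seed_weights(p)`` for d in {1,2,3}; rows with zero
    streamline weight are exactly zero.
    """
    sw = np.asarray(seed_weights, dtype=float)
    if sw.shape != (e.n_parcels,):
        raise ManifoldError("seed_weights length must equal parcel count")
    if np.any(sw < 0):
        raise ManifoldError("seed_weights must be nonnegative")
    return WeightedManifold(wcoords=e.coords[:, :3] * sw[:, None])


# ---------------------------------------------------------------------------
# embedding of a subject pipeline helper

def embed_connectome(c: Connectome, k: int = 3, alpha: float = 0.5, t: float = 0.0) -> Embedding:
    """Cosine affinity followed by diffusion-map embedding."""
    return diffusion_embedding(cosine_affinity(c), k=k, alpha=alpha, t=t)


__all__ = [
    "Embedding",
    "WeightedManifold",
    "ManifoldError",
    "cosine_affinity",
    "diffusion_embedding",
    "procrustes_align",
    "manifold_eccentricity",
    "weighted_manifold",
    "embed_connectome",
]
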