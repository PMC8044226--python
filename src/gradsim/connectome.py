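"""Connectome matrices: transforms, group aggregation, and reductions.

A connectome is a symmetric nonnegative parcel-by-parcel weight matrix with a
zero diagonal.  Subject-level matrices carry raw streamline cross-section
weights (``weight_kind="raw_streamline"``); the analysis pipeline
log-transforms them and aggregates subjects into a group-representative
matrix via distance-dependent, consistency-based thresholding that preserves
long-range connections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

WEIGHT_KINDS = ("raw_streamline", "log", "binary")


class ConnectomeError(ValueError):
    """Invalid connectome input."""


@dataclass
class Connectome:
    """Square symmetric nonnegative weight matrix tied to an atlas.

    Parameters
    ----------
    weights:
        ``(P, P)`` symmetric matrix, zero diagonal, finite nonnegative entries.
    atlas:
        Optional reference to the parcel atlas the rows/columns index.
    weight_kind:
        One of ``raw_streamline`` (tractography cross-section weights),
        ``log`` (``ln(1 + w)`` transformed), or ``binary``.
    """

    weights: np.ndarray
    atlas: Optional[object] = None
    weight_kind: str = "raw_streamline"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError("weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ConnectomeError("weights must be finite")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ConnectomeError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        if np.any(w < 0):
            raise ConnectomeError("weights must be nonnegative")
        if self.weight_kind not in WEIGHT_KINDS:
            raise ConnectomeError(f"unknown weight_kind {self.weight_kind!r}")
        self.weights = w

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]


def _as_weights(c) -> np.ndarray:
    return c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)


def log_transform(c: Connectome) -> Connectome:
    """Log-transform raw streamline weights, ``w -> ln(1 + w)``.

    Zeros map to zero and the weight order is preserved.  Guarded by
    ``weight_kind`` so the transform is applied exactly once.
    """
    if c.weight_kind != "raw_streamline":
        raise ConnectomeError(
            f"log_transform expects raw_streamline weights, got {c.weight_kind!r}"
        )
    return Connectome(np.log1p(c.weights), atlas=c.atlas, weight_kind="log")


def density(c) -> float:
    """Connection density in percent: nonzero upper-triangle edges over P(P-1)/2."""
    w = _as_weights(c)
    p = w.shape[0]
    iu = np.triu_indices(p, k=1)
    return 100.0 * float(np.count_nonzero(w[iu])) / (p * (p - 1) / 2)


def consistency_mask(scs: Sequence[Connectome], fraction: float) -> Connectome:
    """Binary mask of edges nonzero in at least ``fraction`` of subjects.

    ``fraction=0`` keeps the union of subject supports (plain group-average
    support).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConnectomeError("fraction must be in [0, 1]")
    stack = np.stack([_as_weights(s) for s in scs])
    frac_nonzero = (stack > 0).mean(axis=0)
    if fraction == 0.0:
        mask = frac_nonzero > 0
    else:
        mask = frac_nonzero >= fraction
    mask = mask.astype(float)
    np.fill_diagonal(mask, 0.0)
    atlas = scs[0].atlas if isinstance(scs[0], Connectome) else None
    return Connectome(mask, atlas=atlas, weight_kind="binary")


def group_representative(
    scs: Sequence[Connectome],
    distances: np.ndarray,
    n_bins: int = 10,
) -> Connectome:
    """Distance-binned, consistency-ranked group-representative connectome.

    Candidate edges (union of subject supports) are partitioned into
    ``n_bins`` equal-count bins of inter-parcel distance.  Within each bin,
    edges are ranked by across-subject consistency (fraction of subjects with
    a nonzero weight; ties broken by mean weight, then by edge index) and the
    top ``m_b`` retained, where ``m_b`` is the average per-subject edge count
    in that bin.  Binning by distance keeps long-range connections that a
    plain consistency threshold would discard.  Retained edge weights are the
    across-subject mean of log weights (``ln(1+w)`` applied when subjects are
    raw; already-log weights averaged as given).
    """
    if len(scs) < 1:
        raise ConnectomeError("need at least one subject")
    p = _as_weights(scs[0]).shape[0]
    stacks = []
    for s in scs:
        w = _as_weights(s)
        if w.shape[0] != p:
            raise ConnectomeError("subjects must share one atlas/parcellation")
        kind = s.weight_kind if isinstance(s, Connectome) else "log"
        stacks.append(np.log1p(w) if kind == "raw_streamline" else w)
    stack = np.stack(stacks)
    distances = np.asarray(distances, dtype=float)
    if distances.shape != (p, p):
        raise ConnectomeError("distance matrix shape must match parcellation")

    iu = np.triu_indices(p, k=1)
    edge_dist = distances[iu]
    nonzero = stack[:, iu[0], iu[1]] > 0  # subjects x edges
    consistency = nonzero.mean(axis=0)
    mean_w = stack[:, iu[0], iu[1]].mean(axis=0)
    candidate = consistency > 0

    # equal-count distance bins over candidate edges
    order = np.argsort(edge_dist[candidate], kind="stable")
    cand_idx = np.flatnonzero(candidate)[order]
    bins = np.array_split(cand_idx, n_bins)

    keep = np.zeros(len(edge_dist), dtype=bool)
    for b in bins:
        if len(b) == 0:
            warnings.warn("empty distance bin skipped", stacklevel=2)
            continue
        m_b = int(round(nonzero[:, b].sum(axis=1).mean()))
        if m_b == 0:
            continue
        # rank: consistency desc, mean weight desc, edge index asc
        rank = np.lexsort((b, -mean_w[b], -consistency[b]))
        keep[b[rank[:m_b]]] = True

    out = np.zeros((p, p))
    out[iu[0][keep], iu[1][keep]] = mean_w[keep]
    out = out + out.T
    atlas = scs[0].atlas if isinstance(scs[0], Connectome) else None
    return Connectome(out, atlas=atlas, weight_kind="log")


def community_reduce(m: np.ndarray, communities: Sequence) -> pd.DataFrame:
    """Reduce a parcel matrix to community-block means.

    Off-diagonal block ``(i, j)`` is the mean of all entries between
    communities *i* and *j*; diagonal blocks are the mean of within-community
    off-diagonal entries (a single-parcel community contributes a 0 diagonal
    block by convention).  Returns a symmetric labelled DataFrame.
    """
    m = _as_weights(m)
    communities = np.asarray(communities)
    if len(communities) != m.shape[0]:
        raise ConnectomeError("labels must cover all parcels")
    labels = pd.unique(communities)
    k = len(labels)
    out = np.zeros((k, k))
    idx = {lab: np.flatnonzero(communities == lab) for lab in labels}
    for a, la in enumerate(labels):
        for b, lb in enumerate(labels):
            ia, ib = idx[la], idx[lb]
            if len(ia) == 0 or len(ib) == 0:
                raise ConnectomeError(f"empty community {la!r}/{lb!r}")
            block = m[np.ix_(ia, ib)]
            if a == b:
                n = len(ia)
                out[a, b] = 0.0 if n == 1 else (block.sum() - np.trace(block)) / (n * (n - 1))
            else:
                out[a, b] = block.mean()
    out = (out + out.T) / 2
    return pd.DataFrame(out, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# square matrix CSV I/O (header row and column of parcel ids)

def write_matrix_csv(path, c, parcel_ids: Optional[Sequence] = None) -> None:
    w = _as_weights(c)
    if parcel_ids is None:
        parcel_ids = list(range(w.shape[0]))
    pd.DataFrame(w, index=parcel_ids, columns=parcel_ids).to_csv(path)


def read_matrix_csv(path, weight_kind: str = "raw_streamline") -> Connectome:
    df = pd.read_csv(path, index_col=0)
    return Connectome(df.to_numpy(dtype=float), weight_kind=weight_kind)


__all__ = [
    "Connectome",
    "ConnectomeError",
    "log_transform",
    "density",
    "consistency_mask",
    "group_representative",
    "community_reduce",
    "write_matrix_csv",
    "read_matrix_csv",
]
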