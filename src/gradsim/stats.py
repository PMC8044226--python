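"""Permutation-based group inference for parcellated brain maps.

Implements the inference layer of the cohort analysis: covariate
residualisation, two-sample Hotelling T² in manifold space, group-label
permutation tests with +1-smoothed one-sided p-values, Benjamini–Hochberg
FDR, spherical spin tests for spatial maps, hierarchy/community
stratification summaries, edge-wise streamline comparisons, tract-length
contrasts, and the cell-type overlap-ratio enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import special_ortho_group
from statsmodels.stats.multitest import multipletests

from .connectome import Connectome, group_representative


class StatsError(ValueError):
    """Invalid statistical input."""


@dataclass
class RegionTestResult:
    """Per-region multivariate test: statistic, permutation p, FDR q."""

    region: np.ndarray
    t2: np.ndarray
    p_perm: np.ndarray
    q_fdr: np.ndarray
    signed_summary: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"region": self.region, "t2": self.t2, "p": self.p_perm, "q": self.q_fdr}
        )
        if self.signed_summary is not None:
            df["signed_summary"] = self.signed_summary
        return df


# ---------------------------------------------------------------------------
# covariates and basic statistics


def residualize(y: np.ndarray, covariates: np.ndarray, add_intercept: bool = True) -> np.ndarray:
    """Least-squares residuals of each column of ``y`` on the covariates."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatsError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def hotelling_t2(group_a: np.ndarray, group_b: np.ndarray, ridge: float = 1e-8) -> float:
    """Two-sample Hotelling T² with pooled covariance.

    A small ridge is added to the pooled covariance if it is singular; a
    covariance degenerate even after the ridge raises.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise StatsError("need at least two subjects per group")
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = ((na - 1) * np.cov(a, rowvar=False) + (nb - 1) * np.cov(b, rowvar=False)) / (
        na + nb - 2
    )
    pooled = np.atleast_2d(pooled)
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError:
        pooled = pooled + ridge * np.eye(pooled.shape[0])
        try:
            sol = np.linalg.solve(pooled, diff)
        except np.linalg.LinAlgError as err:
            raise StatsError("degenerate pooled covariance") from err
    return float(na * nb / (na + nb) * diff @ sol)


def hotelling_t2_map(data: np.ndarray, labels: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Vectorised per-unit Hotelling T² for stacked data (subject, unit, k)."""
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise StatsError("labels must have exactly two levels")
    a = data[labels == levels[0]]
    b = data[labels == levels[1]]
    na, nb = len(a), len(b)
    diff = a.mean(axis=0) - b.mean(axis=0)  # (units, k)
    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    cov = (np.einsum("sui,suj->uij", ca, ca) + np.einsum("sui,suj->uij", cb, cb)) / (
        na + nb - 2
    )
    cov = cov + ridge * np.eye(cov.shape[-1])
    sol = np.linalg.solve(cov, diff[..., None])[..., 0]
    return na * nb / (na + nb) * np.einsum("uk,uk->u", diff, sol)


# ---------------------------------------------------------------------------
# permutation machinery


def permutation_group_test(
    statistic_fn: Callable[[np.ndarray], np.ndarray],
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Group-label permutation p-values for an arbitrary per-unit statistic.

    ``statistic_fn(labels)`` must return the statistic per unit for a label
    assignment; the null shuffles labels, preserving group sizes.  One-sided
    on the statistic's magnitude: p = (1 + #{null >= observed}) / (n_perm+1),
    so p can never be zero.
    """
    labels = np.asarray(labels)
    observed = np.atleast_1d(np.asarray(statistic_fn(labels), dtype=float))
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        null = np.atleast_1d(np.asarray(statistic_fn(perm), dtype=float))
        exceed += null >= observed
    p = (1 + exceed) / (n_perm + 1)
    return observed, p


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotonicity enforced)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def compare_manifolds(
    coords: np.ndarray,
    groups: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    n_perm: int = 1000,
    seed: int = 0,
    signed_summary: Optional[np.ndarray] = None,
) -> RegionTestResult:
    """Per-parcel multivariate group comparison in manifold space.

    ``coords`` is (subject, parcel, k) aligned manifold coordinates.
    Covariates are residualised out before permutation; per-parcel Hotelling
    T² is compared against a group-label permutation null and BH-corrected
    across parcels.
    """
    coords = np.asarray(coords, dtype=float)
    n_subj, n_parcel, k = coords.shape
    if covariates is not None:
        flat = residualize(coords.reshape(n_subj, -1), covariates)
        coords = flat.reshape(n_subj, n_parcel, k)

    def stat(labels):
        return hotelling_t2_map(coords, labels)

    t2, p = permutation_group_test(stat, np.asarray(groups), n_perm=n_perm, seed=seed)
    q = fdr_bh(p)
    return RegionTestResult(
        region=np.arange(n_parcel), t2=t2, p_perm=p, q_fdr=q,
        signed_summary=signed_summary,
    )


# ---------------------------------------------------------------------------
# spin test


@dataclass
class SpinNull:
    """Spatial-permutation null built from random sphere rotations."""

    n_rotations: int
    reassignment: np.ndarray  # (n_rot, n_parcels) source index per parcel
    null_values: Optional[np.ndarray] = None


def spin_rotations(atlas, n_rot: int = 1000, seed: int = 0) -> SpinNull:
    """Random-rotation parcel reassignments preserving hemispheric symmetry.

    Uniform random rotations are applied to left-hemisphere spherical
    centroids and mirrored (x -> -x conjugation) to the right hemisphere;
    each parcel is reassigned to the parcel whose rotated centroid lands
    nearest (duplicate sources allowed).
    """
    hemi = np.asarray(atlas.table["hemisphere"])
    cent = atlas.table[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.allclose(np.linalg.norm(cent, axis=1), 1.0, atol=1e-6):
        raise StatsError("atlas centroids must be unit-norm spherical coordinates")
    left = np.flatnonzero(hemi == "L")
    right = np.flatnonzero(hemi == "R")
    mirror = np.diag([-1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    n = len(hemi)
    reassign = np.empty((n_rot, n), dtype=int)
    tree_l = cKDTree(cent[left])
    tree_r = cKDTree(cent[right])
    for it in range(n_rot):
        rot_l = special_ortho_group.rvs(3, random_state=rng)
        rot_r = mirror @ rot_l @ mirror
        rotated_l = cent[left] @ rot_l.T
        rotated_r = cent[right] @ rot_r.T
        # parcel i takes the value of the parcel whose rotated centroid is nearest
        _, jl = cKDTree(rotated_l).query(cent[left])
        _, jr = cKDTree(rotated_r).query(cent[right])
        row = np.empty(n, dtype=int)
        row[left] = left[jl]
        row[right] = right[jr]
        reassign[it] = row
    del tree_l, tree_r
    return SpinNull(n_rotations=n_rot, reassignment=reassign)


def spin_test(
    map1: np.ndarray,
    map2: np.ndarray,
    atlas,
    n_rot: int = 1000,
    seed: int = 0,
    precomputed: Optional[SpinNull] = None,
) -> tuple[float, float]:
    """Spatial correlation with a rotation-based permutation null.

    Returns the observed Pearson correlation of the two parcel maps and a
    p-value from the null of correlations between ``map1`` and rotated
    versions of ``map2``.  The tail is evaluated in the direction of the
    observed correlation and doubled (capped at 1): conditioning the tail on
    the observed sign alone would squash null p-values into [0, 0.5] and
    break calibration, while the doubled value is uniform under the null.
    Floor 2/(n_rot + 1).
    """
    map1 = np.asarray(map1, dtype=float)
    map2 = np.asarray(map2, dtype=float)
    spin = precomputed or spin_rotations(atlas, n_rot=n_rot, seed=seed)
    r_obs = float(np.corrcoef(map1, map2)[0, 1])
    rotated = map2[spin.reassignment]  # (n_rot, n_parcels)
    m1c = map1 - map1.mean()
    rc = rotated - rotated.mean(axis=1, keepdims=True)
    denom = np.sqrt((m1c**2).sum() * (rc**2).sum(axis=1))
    null = (rc @ m1c) / denom
    if r_obs >= 0:
        count = int(np.sum(null >= r_obs))
    else:
        count = int(np.sum(null <= r_obs))
    p = min(1.0, 2 * (1 + count) / (spin.n_rotations + 1))
    return r_obs, p


# ---------------------------------------------------------------------------
# stratification summaries


def stratify_by_labels(values: np.ndarray, labels: Sequence) -> pd.DataFrame:
    """Class-wise mean and count of a parcel map (radar-plot summary)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != len(values):
        raise StatsError("labels must cover all parcels")
    df = pd.DataFrame({"label": labels, "value": values})
    out = df.groupby("label", sort=False)["value"].agg(["mean", "count"])
    return out


def hemispheric_asymmetry(values: np.ndarray, atlas, labels: Optional[Sequence] = None) -> pd.Series:
    """Right-vs-left percent difference of mean absolute values per class.

    Convention: 100 * (mean|v|_R - mean|v|_L) / mean|v|_L, computed per
    class (default classes: the atlas hierarchy levels).  A zero left-hemisphere
    denominator yields NaN (reported as missing).
    """
    values = np.asarray(values, dtype=float)
    hemi = np.asarray(atlas.table["hemisphere"])
    labels = np.asarray(labels if labels is not None else atlas.table["hierarchy"])
    out = {}
    for lab in pd.unique(labels):
        sel = labels == lab
        left = np.abs(values[sel & (hemi == "L")])
        right = np.abs(values[sel & (hemi == "R")])
        if len(left) == 0 or len(right) == 0:
            raise StatsError(f"class {lab!r} missing a hemisphere")
        ml = left.mean()
        out[lab] = np.nan if ml == 0 else 100.0 * (right.mean() - ml) / ml
    return pd.Series(out)


# ---------------------------------------------------------------------------
# edge-wise comparison


@dataclass
class EdgeTestResult:
    edges: np.ndarray  # (n_edges, 2) parcel index pairs
    t: np.ndarray
    p_perm: np.ndarray
    q_fdr: np.ndarray
    increased: np.ndarray  # edge indices with t > 0, q < 0.05
    decreased: np.ndarray


def _edge_matrix(scs, mask_iu) -> np.ndarray:
    rows = []
    for s in scs:
        w = s.weights if isinstance(s, Connectome) else np.asarray(s, dtype=float)
        kind = s.weight_kind if isinstance(s, Connectome) else "log"
        w = np.log1p(w) if kind == "raw_streamline" else w
        rows.append(w[mask_iu])
    return np.stack(rows)


def edge_group_test(
    scs_a: Sequence,
    scs_b: Sequence,
    distances: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> EdgeTestResult:
    """Edge-wise two-sample t-test on log streamline weights.

    The test runs over the common support: edges retained by the
    group-representative connectome of all subjects (or an explicit boolean
    ``mask``).  Two-sided permutation p-values with BH correction; edges are
    partitioned into increased (t > 0, group A above B) and decreased sets
    at q < ``alpha``.
    """
    all_subj = list(scs_a) + list(scs_b)
    p = (all_subj[0].weights if isinstance(all_subj[0], Connectome)
         else np.asarray(all_subj[0])).shape[0]
    if mask is None:
        if distances is None:
            raise StatsError("provide distances (for group-representative support) or a mask")
        rep = group_representative(all_subj, distances)
        mask = rep.weights > 0
    iu = np.triu_indices(p, k=1)
    edge_sel = mask[iu]
    edges = np.column_stack([iu[0][edge_sel], iu[1][edge_sel]])
    mask_iu = (iu[0][edge_sel], iu[1][edge_sel])
    xa = _edge_matrix(scs_a, mask_iu)
    xb = _edge_matrix(scs_b, mask_iu)
    x = np.vstack([xa, xb])
    labels = np.array([0] * len(xa) + [1] * len(xb))

    def tstat(lab):
        a, b = x[lab == 0], x[lab == 1]
        na, nb = len(a), len(b)
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        sp = np.where(sp == 0, np.inf, sp)
        return (a.mean(axis=0) - b.mean(axis=0)) / (sp * np.sqrt(1 / na + 1 / nb))

    t_obs = tstat(labels)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(t_obs))
    for _ in range(n_perm):
        null = tstat(rng.permutation(labels))
        exceed += np.abs(null) >= np.abs(t_obs)
    p_perm = (1 + exceed) / (n_perm + 1)
    q = fdr_bh(p_perm)
    sig = q < alpha
    return EdgeTestResult(
        edges=edges, t=t_obs, p_perm=p_perm, q_fdr=q,
        increased=np.flatnonzero(sig & (t_obs > 0)),
        decreased=np.flatnonzero(sig & (t_obs < 0)),
    )


def tract_length_contrast(
    decreased_lengths: np.ndarray,
    increased_lengths: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Are decreased-connectivity tracts longer than increased ones?

    Returns the two set means and a one-sided permutation p-value for
    mean(decreased) - mean(increased), shuffling set membership.
    """
    dec = np.asarray(decreased_lengths, dtype=float)
    inc = np.asarray(increased_lengths, dtype=float)
    if len(dec) == 0 or len(inc) == 0:
        raise StatsError("both edge sets must be nonempty")
    observed = dec.mean() - inc.mean()
    pooled = np.concatenate([dec, inc])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if perm[: len(dec)].mean() - perm[len(dec):].mean() >= observed:
            count += 1
    return float(dec.mean()), float(inc.mean()), (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# enrichment overlap


def overlap_ratio_test(
    gene_list: Sequence,
    celltype_sets: dict,
    universe: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-type overlap-ratio enrichment with a random-set permutation null.

    ratio = 100 * |gene_list ∩ set| / |set ∩ universe| per cell type.  The
    null draws random sets of the same size from the union of all cell-type
    genes; p is one-sided (observed or larger), BH-corrected across types.
    """
    genes = set(gene_list)
    universe = set(universe)
    pool = sorted(set().union(*celltype_sets.values()))
    rng = np.random.default_rng(seed)
    names, ratios, pvals = [], [], []
    for name, members in celltype_sets.items():
        members = set(members)
        if not members:
            raise StatsError(f"empty cell-type set {name!r}")
        denom = len(members & universe)
        if denom == 0:
            raise StatsError(f"cell-type set {name!r} disjoint from universe")
        ratio = 100.0 * len(genes & members) / denom
        count = 0
        size = len(members)
        for _ in range(n_perm):
            draw = rng.choice(pool, size=size, replace=False)
            d = len(set(draw) & universe)
            null_ratio = 100.0 * len(genes & set(draw)) / d if d else 0.0
            if null_ratio >= ratio:
                count += 1
        names.append(name)
        ratios.append(ratio)
        pvals.append((1 + count) / (n_perm + 1))
    q = fdr_bh(np.array(pvals))
    return pd.DataFrame({"celltype": names, "overlap_ratio": ratios, "p": pvals, "q": q})


# ---------------------------------------------------------------------------
# weighted-manifold comparison


def weighted_manifold_group_test(
    wms_a: dict,
    wms_b: dict,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Multivariate group test of seed-weighted manifolds, per seed structure.

    ``wms_a[seed_name]`` is an (n_subjects, n_parcels, 3) stack of wM1–wM3.
    Each subject's weighted manifold is summarised to a 3-vector by the
    parcel mean of each dimension; groups are compared with Hotelling T² and
    a group-label permutation null, BH-corrected across seed structures.
    """
    seeds = list(wms_a)
    if set(seeds) != set(wms_b):
        raise StatsError("both groups must provide the same seed structures")
    rows = []
    for si, name in enumerate(seeds):
        a = np.asarray(wms_a[name]).mean(axis=1)  # (n_subj, 3)
        b = np.asarray(wms_b[name]).mean(axis=1)
        data = np.vstack([a, b])[:, None, :]
        labels = np.array([0] * len(a) + [1] * len(b))

        def stat(lab):
            return hotelling_t2_map(data, lab)

        t2, p = permutation_group_test(stat, labels, n_perm=n_perm, seed=seed + si)
        rows.append({"seed": name, "t2": t2[0], "p": p[0]})
    df = pd.DataFrame(rows)
    df["q"] = fdr_bh(df["p"].to_numpy())
    return df


__all__ = [
    "RegionTestResult",
    "EdgeTestResult",
    "SpinNull",
    "StatsError",
    "residualize",
    "hotelling_t2",
    "hotelling_t2_map",
    "permutation_group_test",
    "fdr_bh",
    "compare_manifolds",
    "spin_rotations",
    "spin_test",
    "stratify_by_labels",
    "hemispheric_asymmetry",
    "edge_group_test",
    "tract_length_contrast",
    "overlap_ratio_test",
    "weighted_manifold_group_test",
]
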