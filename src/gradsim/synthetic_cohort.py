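"""Seeded synthetic atlases and two-group cohorts with known ground truth.

The generator emulates the statistical structure a case-control structural
connectome analysis assumes: a parcellated cortical atlas with spherical
centroids, seven spatially contiguous functional communities and four
cortical hierarchy levels; subject structural connectomes whose connection
probability decays with distance and rises within communities, with
log-normal streamline-cross-section-like weights; a planted multiplicative
group effect on a chosen set of parcels; functional connectivity optionally
generated by the mean-field BOLD forward model from known region-wise
parameters; and symptom scores linearly dependent on manifold features plus
noise.  Every generator is deterministic for a fixed seed, and with a zero
effect size the two groups are exchangeable in distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from . import manifold as mf
from .connectome import Connectome, group_representative, log_transform
from .meanfield import MeanFieldParams, normalize_sc, simulate_fc

COMMUNITIES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)
HIERARCHY_LEVELS = ("idiotypic", "unimodal", "heteromodal", "paralimbic")

ADOS_SCORES = ("total", "social_cognition", "communication", "repeated_behavior")
_ADOS_FACTORS = {"total": 1.0, "social_cognition": 0.55, "communication": 0.3,
                 "repeated_behavior": 0.25}
_ADOS_INTERCEPTS = {"total": 8.0, "social_cognition": 5.0, "communication": 4.0,
                    "repeated_behavior": 3.0}


class GenerationError(RuntimeError):
    """Synthetic data could not be generated under the requested settings."""


@dataclass
class ParcelAtlas:
    """Parcel table with unit-sphere centroids, communities and hierarchy.

    ``table`` columns: parcel_id, name, hemisphere (L/R), x, y, z (unit-norm
    per-hemisphere spherical centroid), community (one of seven networks),
    hierarchy (idiotypic/unimodal/heteromodal/paralimbic).  Distances are
    Euclidean between centroids scaled to ``radius`` millimetres.
    """

    table: pd.DataFrame
    radius: float = 70.0
    hemisphere_gap: float = 0.5  # centre offset along x, in units of radius

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        """Unit-sphere centroids, one full sphere per hemisphere."""
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def physical_centroids(self) -> np.ndarray:
        """Millimetre coordinates: per-hemisphere spheres scaled to ``radius``
        and offset left/right along x so the hemispheres sit side by side."""
        c = self.centroids * self.radius
        hemi = self.table["hemisphere"].to_numpy()
        shift = np.where(hemi == "L", -1.0, 1.0) * self.hemisphere_gap * self.radius
        c = c.copy()
        c[:, 0] += shift
        return c

    @property
    def distances(self) -> np.ndarray:
        c = self.physical_centroids
        diff = c[:, None, :] - c[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    @property
    def communities(self) -> np.ndarray:
        return self.table["community"].to_numpy()

    @property
    def hierarchy(self) -> np.ndarray:
        return self.table["hierarchy"].to_numpy()

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def make_atlas(n_parcels: int, seed: int, radius: float = 70.0) -> ParcelAtlas:
    """Generate a mirror-symmetric spherical parcel atlas.

    Parcels split evenly across hemispheres; right-hemisphere centroids are
    mirror images (x -> -x) of matched left parcels.  Communities are
    contiguous spherical caps around seven seed parcels and hierarchy levels
    are four contiguous latitude bands, so label maps are spatially
    autocorrelated.
    """
    if n_parcels % 2 != 0 or n_parcels < 14:
        raise ValueError("n_parcels must be even and at least 14")
    rng = np.random.default_rng(seed)
    n_l = n_parcels // 2
    # uniform points on the left hemisphere's full unit sphere (each
    # hemisphere has its own sphere, as in surface-based registration)
    z = rng.uniform(-1.0, 1.0, size=n_l)
    phi = rng.uniform(0.0, 2 * np.pi, size=n_l)
    s = np.sqrt(1.0 - z**2)
    pts = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)

    # communities: caps around 7 seed parcels (a seed parcel is always
    # nearest to itself, so every community is represented per hemisphere)
    seed_idx = rng.choice(n_l, size=len(COMMUNITIES), replace=False)
    sims = pts @ pts[seed_idx].T
    comm_l = np.array(COMMUNITIES)[np.argmax(sims, axis=1)]

    # hierarchy: 4 contiguous latitude bands of (roughly) equal size
    order = np.argsort(pts[:, 2], kind="stable")
    hier_l = np.empty(n_l, dtype=object)
    for lev, band in zip(HIERARCHY_LEVELS, np.array_split(order, 4)):
        hier_l[band] = lev

    mirror = pts * np.array([-1.0, 1.0, 1.0])
    rows = []
    for i in range(n_l):
        rows.append((i, f"L_{comm_l[i]}_{i}", "L", *pts[i], comm_l[i], hier_l[i]))
    for i in range(n_l):
        rows.append((n_l + i, f"R_{comm_l[i]}_{i}", "R", *mirror[i], comm_l[i], hier_l[i]))
    table = pd.DataFrame(
        rows,
        columns=["parcel_id", "name", "hemisphere", "x", "y", "z", "community", "hierarchy"],
    )
    return ParcelAtlas(table=table, radius=radius)


def make_structural_connectome(
    atlas: ParcelAtlas,
    target_density: float,
    seed: int,
    decay_length: float = 30.0,
    community_boost: float = 1.0,
    weight_mu: float = 3.0,
    weight_sigma: float = 1.0,
    weight_decay_length: float = 60.0,
) -> Connectome:
    """Distance- and community-dependent random structural connectome.

    Connection probability is proportional to
    ``exp(-distance / decay_length) * (1 + community_boost * same_community)``
    scaled to reach ``target_density``; edge weights are log-normal with a
    distance-dependent location (stronger short-range connections), emulating
    streamline cross-section weights.  The realised graph is forced to a
    single connected component by adding the shortest missing inter-component
    edge when necessary.
    """
    if not 0.0 < target_density <= 1.0:
        raise ValueError("target_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    d = atlas.distances
    comm = atlas.communities
    same = comm[:, None] == comm[None, :]
    p = atlas.n_parcels
    iu = np.triu_indices(p, k=1)
    score = np.exp(-d[iu] / decay_length) * (1.0 + community_boost * same[iu])

    if target_density >= 1.0:
        prob = np.ones_like(score)
    else:
        lo, hi = 0.0, 1.0
        while np.minimum(hi * score, 1.0).mean() < target_density:
            hi *= 2.0
            if hi > 1e12:
                raise GenerationError(
                    "target density unreachable: connection scores decay to zero "
                    "faster than the requested density allows"
                )
        for _ in range(200):
            mid = (lo + hi) / 2
            if np.minimum(mid * score, 1.0).mean() < target_density:
                lo = mid
            else:
                hi = mid
        prob = np.minimum(hi * score, 1.0)

    present = rng.random(len(prob)) < prob
    adj = np.zeros((p, p), dtype=bool)
    adj[iu[0][present], iu[1][present]] = True
    adj |= adj.T

    # force a single component
    n_comp, labels = connected_components(adj, directed=False)
    while n_comp > 1:
        main = labels == np.bincount(labels).argmax()
        rest = ~main
        sub = d[np.ix_(np.flatnonzero(rest), np.flatnonzero(main))]
        i_r, i_m = np.unravel_index(np.argmin(sub), sub.shape)
        a = np.flatnonzero(rest)[i_r]
        b = np.flatnonzero(main)[i_m]
        adj[a, b] = adj[b, a] = True
        n_comp, labels = connected_components(adj, directed=False)

    w = np.zeros((p, p))
    sel = np.flatnonzero(adj[iu])
    mu = weight_mu - d[iu][sel] / weight_decay_length
    w[iu[0][sel], iu[1][sel]] = np.exp(rng.normal(mu, weight_sigma))
    w = w + w.T
    return Connectome(w, atlas=atlas, weight_kind="raw_streamline")


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortConfig:
    """Settings of a synthetic two-group cohort.

    ``effect_parcels`` receive a multiplicative SC perturbation of
    ``1 + effect_size`` on their rows/columns in the autism group, applied
    before subject-level noise.  ``ados_weights`` maps manifold feature
    indices (features are M1–M3 of the effect parcels, parcel-major) to
    linear coefficients of the symptom score; if None, coefficients are
    drawn once from N(0, 2).
    """

    n_per_group: int
    n_parcels: int = 200
    effect_parcels: Sequence[int] = ()
    effect_size: float = 0.0
    noise_sd: float = 1.0
    ados_weights: Optional[dict] = None
    ados_signal_sd: float = 3.0  # across-subject sd of the linear score signal
    seed: int = 0
    target_density: float = 0.15
    subject_jitter_sd: float = 0.25
    edge_dropout: float = 0.03
    include_fc: bool = False
    fc_dt: float = 1e-3
    fc_duration: float = 480.0
    fc_burn_in: float = 120.0
    fc_TR: float = 2.0
    w_mean: float = 0.53
    w_sd: float = 0.15
    i_mean: float = 0.325
    i_sd: float = 0.05
    g_true: float = 0.5
    sigma_true: float = 0.005

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        bad = [p for p in self.effect_parcels if not 0 <= p < self.n_parcels]
        if bad:
            raise ValueError(f"effect_parcels outside atlas: {bad}")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    site: str
    mean_fd: float
    sc: Connectome
    fc: Optional[np.ndarray]
    ados: dict
    thickness: np.ndarray
    curvature: np.ndarray
    embedding: Optional[mf.Embedding] = None
    bold_var: Optional[np.ndarray] = None  # per-region log BOLD variance


@dataclass
class GroundTruth:
    """Everything needed to verify recovery on a synthetic cohort."""

    effect_parcels: np.ndarray
    W: np.ndarray
    I: np.ndarray
    G: float
    sigma: float
    ados_weights: np.ndarray
    ados_intercepts: dict
    ados_factors: dict
    subject_features: np.ndarray
    template_embedding: mf.Embedding
    atlas: ParcelAtlas
    feature_center: Optional[np.ndarray] = None  # cohort mean of the features


def _ados_scores(base, rng, noise_sd):
    scores = {}
    for name in ADOS_SCORES:
        f = _ADOS_FACTORS[name]
        raw = _ADOS_INTERCEPTS[name] + f * base + rng.normal(0.0, noise_sd * f)
        scores[name] = round(max(0.0, raw), 1)
    return scores


def reconstruct_ados(gt: GroundTruth, subject_index: int) -> dict:
    """Noise-free ADOS reconstruction from ground-truth weights and features."""
    if len(gt.ados_weights):
        centred = gt.subject_features[subject_index] - gt.feature_center
        base = float(centred @ gt.ados_weights)
    else:
        base = 0.0
    return {
        name: round(max(0.0, gt.ados_intercepts[name] + gt.ados_factors[name] * base), 1)
        for name in ADOS_SCORES
    }


def make_cohort(config: CohortConfig) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate a seeded two-group cohort plus its ground truth.

    Pipeline: one atlas and one template SC; per subject the template is
    perturbed (autism group: rows/columns of the effect parcels scaled by
    ``1 + effect_size`` before noise), jittered with element-wise log-normal
    multiplicative noise, and sparsified by a small random edge dropout.
    Subject manifolds are embedded from each subject's own cosine affinity
    and Procrustes-aligned to the template embedding of the group-
    representative connectome; ADOS-like scores are a linear function of the
    aligned manifold coordinates over the effect parcels plus Gaussian
    noise, truncated at zero and rounded to one decimal.  If ``include_fc``
    is set, per-subject FC is simulated with the mean-field BOLD forward
    model from the known ground-truth parameters and the subject's own SC.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    atlas = make_atlas(cfg.n_parcels, seed=int(rng.integers(2**31 - 1)))
    template = make_structural_connectome(
        atlas, cfg.target_density, seed=int(rng.integers(2**31 - 1))
    )

    n = cfg.n_parcels
    W_true = np.clip(rng.normal(cfg.w_mean, cfg.w_sd, size=n), 0.1, 1.5)
    I_true = np.clip(rng.normal(cfg.i_mean, cfg.i_sd, size=n), 0.1, 0.6)

    # group effect: the autism group's effect parcels have their
    # connectivity redistributed toward their own community — within-
    # community edges scaled by (1 + effect_size) and cross-community edges
    # by 1/(1 + effect_size).  Scaling a parcel's entire row uniformly would
    # leave its cosine connectivity profile almost unchanged (cosine
    # similarity is row-scale-invariant), so the planted anomaly must change
    # the profile's *shape* at the effect parcels; the push-pull form does
    # that while approximately preserving total connection strength.
    effect = np.sort(np.asarray(list(cfg.effect_parcels), dtype=int))
    comm = atlas.communities
    same_comm = comm[:, None] == comm[None, :]
    up = np.zeros((n, n), dtype=bool)
    down = np.zeros((n, n), dtype=bool)
    for i in effect:
        up[i, same_comm[i]] = up[same_comm[i], i] = True
        down[i, ~same_comm[i]] = down[~same_comm[i], i] = True
    np.fill_diagonal(up, False)
    effect_outer = np.ones((n, n))
    effect_outer[up] = 1.0 + cfg.effect_size
    effect_outer[down] = 1.0 / (1.0 + cfg.effect_size)

    iu = np.triu_indices(n, k=1)
    z_cent = atlas.centroids[:, 2]
    thick_base = 2.5 + 0.3 * z_cent
    curv_base = 0.1 - 0.05 * z_cent

    groups = ["control"] * cfg.n_per_group + ["autism"] * cfg.n_per_group
    subjects: list[SubjectRecord] = []
    for si, group in enumerate(groups):
        w = template.weights.copy()
        if group == "autism":
            w = w * effect_outer
        jitter = np.zeros((n, n))
        jitter[iu] = rng.normal(0.0, cfg.subject_jitter_sd, size=len(iu[0]))
        jitter = jitter + jitter.T
        w = w * np.exp(jitter)
        if cfg.edge_dropout > 0:
            drop = np.zeros((n, n), dtype=bool)
            drop[iu] = rng.random(len(iu[0])) < cfg.edge_dropout
            dropped = w * (drop | drop.T)
            w = w * ~(drop | drop.T)
            # a parcel must keep at least one connection: restore the
            # strongest dropped edge of any isolated parcel
            for i in np.flatnonzero(w.sum(axis=1) == 0):
                j = int(np.argmax(dropped[i]))
                w[i, j] = w[j, i] = dropped[i, j]
        sc = Connectome(w, atlas=atlas, weight_kind="raw_streamline")
        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{si:03d}",
                group=group,
                age=float(rng.uniform(8, 30)),
                sex=str(rng.choice(["M", "F"])),
                site=str(rng.choice(["siteA", "siteB"])),
                mean_fd=float(np.abs(rng.normal(0.10, 0.03))),
                sc=sc,
                fc=None,
                ados={},
                thickness=thick_base + rng.normal(0.0, 0.1, size=n),
                curvature=curv_base + rng.normal(0.0, 0.02, size=n),
            )
        )

    # manifold template from the group-representative connectome
    log_scs = [log_transform(s.sc) for s in subjects]
    rep = group_representative(log_scs, atlas.distances, n_bins=10)
    template_emb = mf.embed_connectome(rep, k=3)
    for s, lsc in zip(subjects, log_scs):
        emb = mf.embed_connectome(lsc, k=3)
        s.embedding = mf.procrustes_align(emb, template_emb)

    n_feat = 3 * len(effect)
    features = np.stack(
        [s.embedding.coords[effect, :3].ravel() if len(effect) else np.zeros(0)
         for s in subjects]
    )
    if cfg.ados_weights is not None:
        weights = np.zeros(n_feat)
        for k, v in cfg.ados_weights.items():
            weights[int(k)] = v
    else:
        weights = rng.normal(0.0, 1.0, size=n_feat)
        if n_feat:
            # manifold coordinates live on an arbitrary scale; calibrate the
            # drawn coefficients so the linear score signal has a realistic
            # across-subject spread (otherwise one-decimal rounding could
            # swallow it entirely)
            base_sd = float(np.std(features @ weights))
            if base_sd > 0:
                weights *= cfg.ados_signal_sd / base_sd
    # the score signal is the centred linear combination, so the intercepts
    # set the cohort-level score location
    center = features.mean(axis=0) if n_feat else np.zeros(0)
    for si, s in enumerate(subjects):
        base = float((features[si] - center) @ weights) if n_feat else 0.0
        s.ados = _ados_scores(base, rng, cfg.noise_sd)

    if cfg.include_fc:
        for s in subjects:
            c_subj = normalize_sc(np.log1p(s.sc.weights))
            params = MeanFieldParams(C=c_subj, W=W_true, I=I_true,
                                     G=cfg.g_true, sigma=cfg.sigma_true)
            out = simulate_fc(
                params, dt=cfg.fc_dt, duration=cfg.fc_duration,
                burn_in=cfg.fc_burn_in, TR=cfg.fc_TR,
                seed=int(rng.integers(2**31 - 1)), return_bold=True,
            )
            s.fc = out.fc_sim
            s.bold_var = np.log(out.bold.var(axis=0))

    gt = GroundTruth(
        effect_parcels=effect,
        W=W_true,
        I=I_true,
        G=cfg.g_true,
        sigma=cfg.sigma_true,
        ados_weights=weights,
        ados_intercepts=dict(_ADOS_INTERCEPTS),
        ados_factors=dict(_ADOS_FACTORS),
        subject_features=features,
        feature_center=center,
        template_embedding=template_emb,
        atlas=atlas,
    )
    return subjects, gt


def make_seed_weights(
    atlas: ParcelAtlas,
    n_subjects: int,
    seed: int,
    names: Sequence[str] = ("thalamus", "caudate", "putamen", "cerebellum"),
) -> dict:
    """Per-subject seed-to-parcel streamline weights for subcortical seeds.

    Each seed structure gets a smooth nonnegative cortical projection profile
    (log-normal around a seed-specific spatial gradient) per subject, for use
    with :func:`gradsim.manifold.weighted_manifold`.
    """
    rng = np.random.default_rng(seed)
    cent = atlas.centroids
    out = {}
    for name in names:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        profile = np.exp(cent @ direction)  # smooth spatial gradient
        subj = np.exp(rng.normal(0.0, 0.3, size=(n_subjects, atlas.n_parcels)))
        out[name] = profile[None, :] * subj
    return out


# ---------------------------------------------------------------------------
# writers


def write_cohort(subjects: Sequence[SubjectRecord], gt: GroundTruth, outdir) -> None:
    """Write atlas TSV, per-subject SC CSVs, phenotype CSV, and a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt.atlas.write_tsv(outdir / "atlas.tsv")
    pheno = []
    ids = gt.atlas.table["parcel_id"].tolist()
    for s in subjects:
        pd.DataFrame(s.sc.weights, index=ids, columns=ids).to_csv(
            outdir / f"{s.subject_id}_sc.csv"
        )
        if s.fc is not None:
            pd.DataFrame(s.fc, index=ids, columns=ids).to_csv(
                outdir / f"{s.subject_id}_fc.csv"
            )
        row = {
            "subject_id": s.subject_id, "group": s.group, "age": s.age,
            "sex": s.sex, "site": s.site, "mean_fd": s.mean_fd,
        }
        row.update({f"ados_{k}": v for k, v in s.ados.items()})
        pheno.append(row)
    pd.DataFrame(pheno).to_csv(outdir / "phenotypes.csv", index=False)
    sidecar = {
        "effect_parcels": gt.effect_parcels.tolist(),
        "W": gt.W.tolist(),
        "I": gt.I.tolist(),
        "G": gt.G,
        "sigma": gt.sigma,
        "ados_weights": gt.ados_weights.tolist(),
        "ados_intercepts": gt.ados_intercepts,
        "ados_factors": gt.ados_factors,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


__all__ = [
    "COMMUNITIES",
    "HIERARCHY_LEVELS",
    "ADOS_SCORES",
    "ParcelAtlas",
    "CohortConfig",
    "SubjectRecord",
    "GroundTruth",
    "GenerationError",
    "make_atlas",
    "make_structural_connectome",
    "make_cohort",
    "make_seed_weights",
    "reconstruct_ados",
    "write_cohort",
]
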