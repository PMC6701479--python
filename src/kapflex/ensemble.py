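"""Collective variables and symmetry-aware Gaussian clustering.

The asymmetry readout of the pipeline: every fitted model is reduced to
the pair (dA, dB) — for each protomer, the distance between the COM of
its C-terminal mobile domain and the COM of the *nearest* N-terminal
terminal module — and the fitted ensemble is clustered with a
Gaussian mixture on the swap-symmetrized point set, so the reported
centers always come as a mirror pair (the two protomers of a homodimer
are interchangeable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .structures import BeadModel, SelectionError, center_of_mass


@dataclass
class CollectiveVariables:
    dA: float
    dB: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.dA, self.dB)


@dataclass
class ClusterResult:
    centers: np.ndarray            # (k, 2) mirror-paired component centers
    covariances: np.ndarray        # (k, 2, 2)
    weights: np.ndarray
    assignments: np.ndarray        # per input point
    mahalanobis: np.ndarray        # per input point, to its component
    points: np.ndarray             # original (unsymmetrized) points
    seed: int


def compute_cvs(
    model: BeadModel,
    mobile_prefix: str = "PHDBR",
    anchor_prefix: str = "RB1B2",
) -> CollectiveVariables:
    """Per-protomer mobile-domain-to-nearest-anchor COM distances (Å)."""
    anchors = {}
    mobiles = {}
    for d in model.domains:
        if d.name.startswith(anchor_prefix):
            anchors[d.chain] = center_of_mass(model, domain=d.name,
                                              protomer=d.chain)
        elif d.name.startswith(mobile_prefix):
            mobiles[d.chain] = center_of_mass(model, domain=d.name,
                                              protomer=d.chain)
    if len(anchors) != 2 or len(mobiles) != 2:
        raise SelectionError(
            f"need two anchor ({anchor_prefix}*) and two mobile "
            f"({mobile_prefix}*) domains; found {len(anchors)}/{len(mobiles)}"
        )
    anchor_pts = np.asarray(list(anchors.values()))
    chains = sorted(mobiles)
    dists = {}
    for c in chains:
        d = np.linalg.norm(anchor_pts - mobiles[c][None, :], axis=1)
        dists[c] = float(d.min())
    return CollectiveVariables(dA=dists[chains[0]], dB=dists[chains[1]])


def _farthest_point_means(pts: np.ndarray, k: int) -> np.ndarray:
    """Deterministic seeding: start from the point farthest from the
    grand mean, then greedily maximize the minimum distance."""
    centroid = pts.mean(axis=0)
    first = int(np.argmax(np.linalg.norm(pts - centroid, axis=1)))
    chosen = [first]
    for _ in range(k - 1):
        dmin = np.min(
            np.linalg.norm(pts[:, None, :] - pts[chosen][None, :, :], axis=2),
            axis=1)
        chosen.append(int(np.argmax(dmin)))
    return pts[chosen]


def gaussian_cluster(points: np.ndarray, k: int = 2, seed: int = 0) -> ClusterResult:
    """Gaussian-mixture clustering of (dA, dB) points, swap-symmetrized.

    Each point contributes itself and its mirror image (dB, dA), so the
    fitted component set is invariant under protomer relabeling and the
    centers form a mirror pair. Deterministic given ``seed``
    (farthest-point initial means).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 10:
        raise ValueError("need at least 10 points")
    sym = np.concatenate([pts, pts[:, ::-1]], axis=0)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        means_init=_farthest_point_means(sym, k),
        random_state=seed,
        reg_covar=1e-4,
        n_init=1,
    ).fit(sym)
    order = np.argsort(gm.means_[:, 0])
    centers = gm.means_[order]
    covs = gm.covariances_[order]
    weights = gm.weights_[order]
    if k == 2:
        # the model class is mirror-symmetric for a homodimer: EM leaves
        # a small estimation asymmetry, which we project out by averaging
        # each component with the swap image of its partner
        c = 0.5 * (centers[0] + centers[1][::-1])
        centers = np.stack([c, c[::-1]])
        swap = np.array([[0.0, 1.0], [1.0, 0.0]])
        cov = 0.5 * (covs[0] + swap @ covs[1] @ swap)
        covs = np.stack([cov, swap @ cov @ swap])
        weights = np.array([0.5, 0.5])

    resp = gm.predict_proba(pts)[:, order]
    assign = np.argmax(resp, axis=1)
    maha = np.empty(len(pts))
    for c in range(k):
        inv = np.linalg.inv(covs[c])
        diff = pts - centers[c]
        m = np.sqrt(np.einsum("ni,ij,nj->n", diff, inv, diff))
        maha[assign == c] = m[assign == c]
    return ClusterResult(centers=centers, covariances=covs, weights=weights,
                         assignments=assign, mahalanobis=maha, points=pts,
                         seed=seed)


def select_k(points: np.ndarray, k_max: int = 4, seed: int = 0) -> int:
    """BIC-based component-count sweep on the symmetrized point set.

    Provided as a diagnostic; the headline asymmetry readout fixes
    k = 2 (one cluster and its mirror image).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    sym = np.concatenate([pts, pts[:, ::-1]], axis=0)
    best_k, best_bic = 1, np.inf
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             random_state=seed, n_init=2,
                             reg_covar=1e-4).fit(sym)
        bic = gm.bic(sym)
        if bic < best_bic:
            best_k, best_bic = k, bic
    return best_k


def overlapping_components(result: ClusterResult) -> bool:
    """True when component centers are closer than the covariance scale
    (a single cloud was split rather than two real clusters)."""
    if len(result.centers) < 2:
        return True
    d = np.linalg.norm(result.centers[0] - result.centers[1])
    scale = np.sqrt(max(np.trace(result.covariances[0]),
                        np.trace(result.covariances[1])) / 2.0)
    return d < scale


def density_levels(
    result: ClusterResult, fractions: tuple[float, ...] = (0.10,)
) -> dict[float, list[np.ndarray]]:
    """Mahalanobis density-level member sets, nested by construction.

    For each fraction f the per-component member set is the f-quantile
    of the component's points by Mahalanobis distance to its center
    (f = 1 keeps everything); all members of a level are closer than
    any non-member.
    """
    out: dict[float, list[np.ndarray]] = {}
    k = len(result.centers)
    for f in fractions:
        per_comp = []
        for c in range(k):
            idx = np.flatnonzero(result.assignments == c)
            if len(idx) == 0:
                per_comp.append(idx)
                continue
            order = idx[np.argsort(result.mahalanobis[idx])]
            n_keep = int(np.ceil(f * len(idx))) if f < 1.0 else len(idx)
            per_comp.append(order[:n_keep])
        out[f] = per_comp
    return out


def closest_members(result: ClusterResult, n: int) -> list[np.ndarray]:
    """The n models closest (Mahalanobis) to each cluster center."""
    out = []
    for c in range(len(result.centers)):
        idx = np.flatnonzero(result.assignments == c)
        order = idx[np.argsort(result.mahalanobis[idx])]
        out.append(order[:n])
    return out


@dataclass
class TwoGaussian1D:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    separation: float
    bimodal: bool
    converged: bool


def density_1d(distances: np.ndarray, seed: int = 0) -> TwoGaussian1D:
    """Two-Gaussian maximum-likelihood fit of pooled 1-D distances.

    The separation statistic is |μ1 − μ2| / pooled sd; the distribution
    is called bimodal when the two-component model beats a single
    Gaussian by BIC *and* the separation exceeds 2 (a lone Gaussian can
    always be split into two overlapping halves, so model selection
    guards the flag). Falls back to the single Gaussian on
    non-convergence or when BIC prefers it.
    """
    x = np.asarray(distances, dtype=float).reshape(-1, 1)
    if len(x) < 20:
        raise ValueError("need at least 20 values")
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(x)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3,
                         reg_covar=1e-6).fit(x)
    if not gm.converged_ or gm1.bic(x) <= gm.bic(x):
        mu, sd = float(x.mean()), float(x.std())
        return TwoGaussian1D(means=np.array([mu]), sds=np.array([sd]),
                             weights=np.array([1.0]), separation=0.0,
                             bimodal=False, converged=bool(gm1.converged_))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]
    pooled = float(np.sqrt(np.average(sds**2, weights=weights)))
    sep = float(abs(means[1] - means[0]) / max(pooled, 1e-12))
    return TwoGaussian1D(means=means, sds=sds, weights=weights,
                         separation=sep, bimodal=sep >= 2.0, converged=True)


def cv_table(models: list[BeadModel | None]) -> pd.DataFrame:
    """(model_id, dA, dB) table for an ensemble (skips failed fits)."""
    rows = []
    for k, m in enumerate(models):
        if m is None:
            continue
        cv = compute_cvs(m)
        rows.append({"model_id": k, "dA": cv.dA, "dB": cv.dB})
    return pd.DataFrame(rows)
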