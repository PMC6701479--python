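"""Elastic-network normal modes and SAXS-driven flexible fitting.

The conformational search engine: an elastic network over the beads is
block-projected (RTB — rotations and translations of blocks: each rigid
domain is one block, each linker bead its own block), its slowest modes
are expressed as per-block instantaneous screw motions, and trial
conformations are produced by integrating those screws at finite
amplitude so rigid-block internal geometry is preserved exactly.
Fitting iterates: recompute modes, try every mode over an amplitude
grid (both signs), keep the single trial with the lowest χ² against the
experimental profile if it strictly improves, then restore local bond
topology by steepest descent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import coo_matrix, identity
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.spatial import cKDTree

from .structures import BeadModel
from . import saxs as saxs_mod


class NetworkError(ValueError):
    """Disconnected or otherwise unusable elastic network."""


# ----------------------------------------------------------------------
# elastic network


@dataclass
class ElasticNetwork:
    coords: np.ndarray
    pairs: np.ndarray            # (m, 2) spring endpoints
    rest_lengths: np.ndarray
    spring_k: float
    blocks: list[np.ndarray]     # bead indices per block
    block_of: np.ndarray         # (n,) block index per bead
    cutoff: float

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass
class ModeSet:
    """Slowest non-rigid modes as per-block screw generators.

    ``velocities[m, b]`` and ``omegas[m, b]`` are the instantaneous
    translation and angular velocity of block ``b`` in mode ``m``
    (mass-orthonormal linear modes); ``centers[b]`` is the rotation
    reference point. Exactly six near-zero (rigid-body) eigenvalues are
    excluded from the returned modes but counted in ``n_zero``.
    """

    eigenvalues: np.ndarray
    velocities: np.ndarray       # (n_modes, n_blocks, 3)
    omegas: np.ndarray           # (n_modes, n_blocks, 3)
    centers: np.ndarray          # (n_blocks, 3)
    blocks: list[np.ndarray]
    block_of: np.ndarray
    n_zero: int
    n_requested: int


def build_enm(model: BeadModel, cutoff: float = 12.0, spring_k: float = 1.0) -> ElasticNetwork:
    """All-pairs-within-cutoff elastic network with domain blocks.

    Rigid domains become single blocks; every bead of a flexible domain
    is its own block. Raises when the spring graph is disconnected.
    """
    coords = model.coords
    n = len(coords)
    tree = cKDTree(coords)
    pairs = np.asarray(sorted(tree.query_pairs(cutoff)), dtype=int)
    if len(pairs) == 0:
        raise NetworkError("no springs within cutoff")
    rest = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)

    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp != 1:
        sizes = np.bincount(labels)
        raise NetworkError(
            f"elastic network has {n_comp} components (sizes {sizes.tolist()})"
        )

    blocks: list[np.ndarray] = []
    block_of = np.full(n, -1, dtype=int)
    for d in model.domains:
        idx = model.select(domain=d.name, protomer=d.chain)
        if d.rigid:
            block_of[idx] = len(blocks)
            blocks.append(np.asarray(idx))
        else:
            for i in idx:
                block_of[i] = len(blocks)
                blocks.append(np.asarray([i]))
    if np.any(block_of < 0):
        # beads outside any domain: treat as individual blocks
        for i in np.flatnonzero(block_of < 0):
            block_of[i] = len(blocks)
            blocks.append(np.asarray([i]))
    return ElasticNetwork(coords=coords, pairs=pairs, rest_lengths=rest,
                          spring_k=spring_k, blocks=blocks,
                          block_of=block_of, cutoff=cutoff)


def _hessian(network: ElasticNetwork):
    """Sparse 3N×3N ANM Hessian (unit spring constant blocks k·uuᵀ)."""
    i, j = network.pairs[:, 0], network.pairs[:, 1]
    dx = network.coords[j] - network.coords[i]
    d = np.linalg.norm(dx, axis=1)
    u = dx / d[:, None]
    K = network.spring_k * np.einsum("ma,mb->mab", u, u)  # (m,3,3)

    rows, cols, vals = [], [], []
    for a in range(3):
        for b in range(3):
            v = K[:, a, b]
            rows.extend([3 * i + a, 3 * j + a, 3 * i + a, 3 * j + a])
            cols.extend([3 * i + b, 3 * j + b, 3 * j + b, 3 * i + b])
            vals.extend([v, v, -v, -v])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n3 = 3 * network.n_beads
    return coo_matrix((vals, (rows, cols)), shape=(n3, n3)).tocsr()


def compute_modes(network: ElasticNetwork, n_modes: int = 60) -> ModeSet:
    """Slowest ``n_modes`` non-rigid RTB modes of the network.

    The Hessian is projected onto per-block rigid motions (orthonormal
    basis per block; rank-deficient generators of collinear blocks are
    pruned), the projected problem is solved by shift-invert Lanczos
    (dense for small systems), and eigenvectors are mapped back to
    per-block translation/rotation screw generators.
    """
    H = _hessian(network)
    n = network.n_beads
    nb = network.n_blocks
    centers = np.asarray([network.coords[b].mean(axis=0) for b in network.blocks])

    # per-block orthonormal rigid basis and its (v, w) back-map
    rows, cols, vals = [], [], []
    backmaps = []        # per block: (col offset, rank, pinv(G) @ Q)
    offset = 0
    for b, idx in enumerate(network.blocks):
        r = network.coords[idx] - centers[b]
        nbk = len(idx)
        G = np.zeros((3 * nbk, 6))
        for t, i in enumerate(idx):
            G[3 * t:3 * t + 3, 0:3] = np.eye(3)
            rx, ry, rz = r[t]
            G[3 * t:3 * t + 3, 3:6] = np.array(
                [[0.0, rz, -ry], [-rz, 0.0, rx], [ry, -rx, 0.0]]
            )
        if nbk == 1:
            Q = G[:, :3]
            rank = 3
            vw_map = np.zeros((6, 3))
            vw_map[:3, :3] = np.eye(3)
        else:
            U, s, _ = np.linalg.svd(G, full_matrices=False)
            rank = int(np.sum(s > 1e-10 * s[0]))
            Q = U[:, :rank]
            vw_map = np.linalg.pinv(G) @ Q  # (6, rank)
        backmaps.append((offset, rank, vw_map))
        for t, i in enumerate(idx):
            for a in range(3):
                for cidx in range(rank):
                    rows.append(3 * i + a)
                    cols.append(offset + cidx)
                    vals.append(Q[3 * t + a, cidx])
        offset += rank
    ndof = offset
    P = coo_matrix((vals, (rows, cols)), shape=(3 * n, ndof)).tocsr()
    Hp = (P.T @ H @ P).tocsc()

    k_want = min(n_modes + 6, ndof)
    if ndof <= max(300, k_want + 2):
        w, V = np.linalg.eigh(Hp.toarray())
        w, V = w[:k_want], V[:, :k_want]
    else:
        try:
            # deterministic start vector: ARPACK's default is random
            v0 = np.full(ndof, 1.0 / np.sqrt(ndof))
            w, V = eigsh(Hp + 1e-9 * identity(ndof, format="csc"),
                         k=k_want, sigma=-1e-4, which="LM", v0=v0)
        except Exception as exc:  # pragma: no cover - solver fallback
            warnings.warn(f"shift-invert failed ({exc}); dense fallback",
                          RuntimeWarning)
            w, V = np.linalg.eigh(Hp.toarray())
            w, V = w[:k_want], V[:, :k_want]
        order = np.argsort(w)
        w, V = w[order], V[:, order]

    # classify rigid-body modes by overlap with the global rigid space
    # (magnitude thresholds misfile genuinely soft internal modes)
    com = network.coords.mean(axis=0)
    rig = np.zeros((3 * n, 6))
    rig[0::3, 0] = rig[1::3, 1] = rig[2::3, 2] = 1.0
    r = network.coords - com
    rig[1::3, 3], rig[2::3, 3] = -r[:, 2], r[:, 1]
    rig[0::3, 4], rig[2::3, 4] = r[:, 2], -r[:, 0]
    rig[0::3, 5], rig[1::3, 5] = -r[:, 1], r[:, 0]
    Y = P.T @ rig
    # rank-aware orthonormal basis (a collinear molecule has only 5
    # rigid motions; plain QR would invent a spurious sixth direction)
    U_y, s_y, _ = np.linalg.svd(Y, full_matrices=False)
    rank_rig = int(np.sum(s_y > 1e-8 * s_y[0]))
    Yq = U_y[:, :rank_rig]
    scores = np.sum((Yq.T @ V) ** 2, axis=0) / np.sum(V**2, axis=0)
    nonrigid = scores < 0.5
    n_zero = int(np.sum(~nonrigid))
    w_keep = w[nonrigid][:n_modes]
    V_keep = V[:, nonrigid][:, :n_modes]

    nm = V_keep.shape[1]
    vel = np.zeros((nm, nb, 3))
    om = np.zeros((nm, nb, 3))
    for b in range(nb):
        off, rank, vw_map = backmaps[b]
        y = V_keep[off:off + rank, :]          # (rank, nm)
        vw = vw_map @ y                        # (6, nm)
        vel[:, b, :] = vw[:3].T
        om[:, b, :] = vw[3:].T
    return ModeSet(eigenvalues=w_keep, velocities=vel, omegas=om,
                   centers=centers, blocks=network.blocks,
                   block_of=network.block_of, n_zero=n_zero,
                   n_requested=n_modes)


# ----------------------------------------------------------------------
# finite screw deformation


def _screws_to_transforms(centers, v, om, amplitude):
    """Per-block rotation matrices and offsets for a finite screw step.

    Each block's instantaneous (v, ω) is integrated over ``amplitude``:
    rotation by |ω|·a about the mode's screw axis (through the point
    offset (ω×v)/|ω|² from the block centre) plus the parallel
    translation a·(v·ω̂)ω̂; pure translation when ω ≈ 0.
    """
    nb = len(centers)
    R = np.tile(np.eye(3), (nb, 1, 1))
    t = np.zeros((nb, 3))
    for b in range(nb):
        w = om[b]
        wn = np.linalg.norm(w)
        if wn < 1e-14:
            t[b] = amplitude * v[b]
            continue
        axis = w / wn
        theta = amplitude * wn
        rho = centers[b] + np.cross(w, v[b]) / wn**2
        t_par = amplitude * np.dot(v[b], axis) * axis
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        Rb = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        R[b] = Rb
        t[b] = rho - Rb @ rho + t_par
    return R, t


def nonlinear_deform(model: BeadModel, modes: ModeSet, mode_index: int,
                     amplitude: float) -> BeadModel:
    """Finite screw-motion deformation of the model along one mode."""
    R, t = _screws_to_transforms(modes.centers,
                                 modes.velocities[mode_index],
                                 modes.omegas[mode_index], amplitude)
    bo = modes.block_of
    new = np.einsum("nij,nj->ni", R[bo], model.coords) + t[bo]
    return model.with_coords(new)


# ----------------------------------------------------------------------
# numba hot path: trial scan


@njit(cache=True, fastmath=True)
def _profile_chi2(coords32, masses32, f2, sinc_tab, inv_bw, I_exp, inv_sig2):
    """Binned weighted Debye profile of ``coords32`` and reduced χ².

    Single-precision throughout: the χ² used to rank trial
    deformations is accurate to ~1e-4, far below the acceptance
    threshold, at roughly half the cost of the double path.
    """
    n = coords32.shape[0]
    nbins = sinc_tab.shape[0]
    nq = f2.shape[0]
    counts = np.zeros(nbins, dtype=np.float32)
    self_term = np.float32(0.0)
    for i in range(n):
        self_term += masses32[i] * masses32[i]
    for i in range(n - 1):
        xi, yi, zi = coords32[i, 0], coords32[i, 1], coords32[i, 2]
        mi = masses32[i]
        for j in range(i + 1, n):
            dx = coords32[j, 0] - xi
            dy = coords32[j, 1] - yi
            dz = coords32[j, 2] - zi
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            k = int(d * inv_bw)
            if k >= nbins:
                k = nbins - 1
            counts[k] += mi * masses32[j]
    I = f2 * (self_term + np.float32(2.0) * np.dot(counts, sinc_tab))
    # closed-form scale/offset weighted least squares (double accumulators)
    sw = 0.0; swx = 0.0; swy = 0.0; swxx = 0.0; swxy = 0.0
    for q in range(nq):
        wq = np.float64(inv_sig2[q])
        x = np.float64(I[q])
        y = np.float64(I_exp[q])
        sw += wq
        swx += wq * x
        swy += wq * y
        swxx += wq * x * x
        swxy += wq * x * y
    det = sw * swxx - swx * swx
    if det <= 0:
        return 1e300
    c = (sw * swxy - swx * swy) / det
    b = (swxx * swy - swx * swxy) / det
    chi2 = 0.0
    for q in range(nq):
        r = c * np.float64(I[q]) + b - np.float64(I_exp[q])
        chi2 += np.float64(inv_sig2[q]) * r * r
    return chi2 / max(nq - 2, 1)


@njit(cache=True, fastmath=True)
def _apply_screws_numba(coords0, block_of, centers, v, om, amplitude, out):
    nb = centers.shape[0]
    R = np.empty((nb, 3, 3))
    T = np.empty((nb, 3))
    for b in range(nb):
        wx, wy, wz = om[b, 0], om[b, 1], om[b, 2]
        wn = np.sqrt(wx * wx + wy * wy + wz * wz)
        if wn < 1e-14:
            for a in range(3):
                for c in range(3):
                    R[b, a, c] = 1.0 if a == c else 0.0
                T[b, a] = amplitude * v[b, a]
            continue
        ax, ay, az = wx / wn, wy / wn, wz / wn
        theta = amplitude * wn
        st, ct = np.sin(theta), np.cos(theta)
        # Rodrigues
        R[b, 0, 0] = ct + ax * ax * (1 - ct)
        R[b, 0, 1] = ax * ay * (1 - ct) - az * st
        R[b, 0, 2] = ax * az * (1 - ct) + ay * st
        R[b, 1, 0] = ay * ax * (1 - ct) + az * st
        R[b, 1, 1] = ct + ay * ay * (1 - ct)
        R[b, 1, 2] = ay * az * (1 - ct) - ax * st
        R[b, 2, 0] = az * ax * (1 - ct) - ay * st
        R[b, 2, 1] = az * ay * (1 - ct) + ax * st
        R[b, 2, 2] = ct + az * az * (1 - ct)
        # screw axis point and parallel translation
        cxv0 = (wy * v[b, 2] - wz * v[b, 1]) / (wn * wn)
        cxv1 = (wz * v[b, 0] - wx * v[b, 2]) / (wn * wn)
        cxv2 = (wx * v[b, 1] - wy * v[b, 0]) / (wn * wn)
        rx = centers[b, 0] + cxv0
        ry = centers[b, 1] + cxv1
        rz = centers[b, 2] + cxv2
        vpar = amplitude * (v[b, 0] * ax + v[b, 1] * ay + v[b, 2] * az)
        T[b, 0] = rx - (R[b, 0, 0] * rx + R[b, 0, 1] * ry + R[b, 0, 2] * rz) + vpar * ax
        T[b, 1] = ry - (R[b, 1, 0] * rx + R[b, 1, 1] * ry + R[b, 1, 2] * rz) + vpar * ay
        T[b, 2] = rz - (R[b, 2, 0] * rx + R[b, 2, 1] * ry + R[b, 2, 2] * rz) + vpar * az
    n = coords0.shape[0]
    for i in range(n):
        b = block_of[i]
        x, y, z = coords0[i, 0], coords0[i, 1], coords0[i, 2]
        out[i, 0] = R[b, 0, 0] * x + R[b, 0, 1] * y + R[b, 0, 2] * z + T[b, 0]
        out[i, 1] = R[b, 1, 0] * x + R[b, 1, 1] * y + R[b, 1, 2] * z + T[b, 1]
        out[i, 2] = R[b, 2, 0] * x + R[b, 2, 1] * y + R[b, 2, 2] * z + T[b, 2]


@njit(cache=True, fastmath=True)
def _scan_trials(coords0, masses32, block_of, centers, vel, om, amps,
                 f2, sinc_tab, inv_bw, I_exp, inv_sig2):
    """Evaluate χ² for every (mode, amplitude) trial; return the best."""
    n_modes = vel.shape[0]
    n_amps = amps.shape[1]
    n = coords0.shape[0]
    best_chi2 = 1e300
    best_m = -1
    best_a = 0.0
    trial = np.empty_like(coords0)
    trial32 = np.empty((n, 3), dtype=np.float32)
    for m in range(n_modes):
        for j in range(n_amps):
            a = amps[m, j]
            _apply_screws_numba(coords0, block_of, centers,
                                vel[m], om[m], a, trial)
            for i in range(n):
                trial32[i, 0] = trial[i, 0]
                trial32[i, 1] = trial[i, 1]
                trial32[i, 2] = trial[i, 2]
            chi2 = _profile_chi2(trial32, masses32, f2, sinc_tab, inv_bw,
                                 I_exp, inv_sig2)
            if chi2 < best_chi2:
                best_chi2 = chi2
                best_m = m
                best_a = a
    return best_chi2, best_m, best_a


# ----------------------------------------------------------------------
# topology regularization


def _restraint_pairs(model: BeadModel, network_blocks_of: np.ndarray | None = None):
    """Bond (1-2) and pseudo-angle (1-3) restraint pairs.

    1-3 pairs are included when their middle bead is flexible (inside a
    rigid block the geometry is preserved by construction).
    """
    bonds = model.bonds
    rigid_dom = {d.name for d in model.domains if d.rigid}
    flexible = np.asarray([d not in rigid_dom for d in model.domain_id])
    pid = model.protomer_id
    n = model.n_beads
    i = np.arange(n - 2)
    same = (pid[:-2] == pid[2:])
    mid_flex = flexible[1:-1]
    sel = same & mid_flex
    angles = np.stack([i[sel], i[sel] + 2], axis=1)
    pairs = np.concatenate([bonds, angles], axis=0)
    return pairs, len(bonds)


def regularize_topology(
    model: BeadModel,
    reference: BeadModel,
    tolerance: float = 0.1,
    max_steps: int = 500,
    step0: float = 0.05,
) -> BeadModel:
    """Restore local topology (bonds, pseudo-angles) toward a reference.

    Steepest descent on a harmonic restraint energy over 1-2 and 1-3
    distances with rigid blocks moved only as rigid bodies (net force →
    translation, net torque → small rotation). Stops when the largest
    bond-length deviation drops below ``tolerance`` Å.
    """
    if model.n_beads != reference.n_beads:
        raise ValueError("model and reference must share topology")
    pairs, n_bonds = _restraint_pairs(model)
    ref_d = np.linalg.norm(
        reference.coords[pairs[:, 0]] - reference.coords[pairs[:, 1]], axis=1)
    rigid_dom = {d.name for d in model.domains if d.rigid}
    rigid_blocks = []
    for d in model.domains:
        if d.name in rigid_dom:
            rigid_blocks.append(model.select(domain=d.name, protomer=d.chain))
    free = np.ones(model.n_beads, dtype=bool)
    for idx in rigid_blocks:
        free[idx] = False

    x = model.coords.copy()
    gamma = step0

    def energy_forces(x):
        d_vec = x[pairs[:, 0]] - x[pairs[:, 1]]
        d = np.linalg.norm(d_vec, axis=1)
        dev = d - ref_d
        E = float(np.sum(dev**2))
        f_pair = (2.0 * dev / np.maximum(d, 1e-12))[:, None] * d_vec
        F = np.zeros_like(x)
        np.subtract.at(F, pairs[:, 0], f_pair)
        np.add.at(F, pairs[:, 1], f_pair)
        bond_dev = np.abs(dev[:n_bonds])
        return E, F, float(bond_dev.max() if n_bonds else 0.0)

    E, F, max_dev = energy_forces(x)
    for _ in range(max_steps):
        if max_dev < tolerance:
            break
        x_new = x.copy()
        x_new[free] += gamma * F[free]
        for idx in rigid_blocks:
            f_net = F[idx].mean(axis=0)
            c = x[idx].mean(axis=0)
            torque = np.cross(x[idx] - c, F[idx]).mean(axis=0)
            x_new[idx] = x[idx] + gamma * f_net
            tn = np.linalg.norm(torque)
            if tn > 1e-12:
                theta = gamma * tn / max(np.linalg.norm(x[idx] - c, axis=1).max(), 1.0)
                axis = torque / tn
                K = np.array([[0, -axis[2], axis[1]],
                              [axis[2], 0, -axis[0]],
                              [-axis[1], axis[0], 0]])
                Rb = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
                x_new[idx] = (x_new[idx] - c) @ Rb.T + c
        E_new, F_new, max_dev_new = energy_forces(x_new)
        if E_new < E:
            x, E, F, max_dev = x_new, E_new, F_new, max_dev_new
            gamma = min(gamma * 1.2, 0.5)
        else:
            gamma *= 0.5
            if gamma < 1e-6:
                break
    else:
        warnings.warn(
            f"topology regularization stopped at bond deviation {max_dev:.3f} Å",
            RuntimeWarning)
    return model.with_coords(x)


# ----------------------------------------------------------------------
# flexible fitting


@dataclass
class FitTrajectory:
    records: pd.DataFrame
    converged: bool
    n_iterations: int
    chi2_initial: float
    chi2_final: float


def _fit_tables(exp_profile: saxs_mod.ScatteringProfile,
                bead_width: float, bin_width: float, r_max: float):
    """Precompute the single-precision tables for the trial-scan kernel."""
    q = exp_profile.q
    nbins = int(np.ceil(r_max / bin_width))
    centres = (np.arange(nbins) + 0.5) * bin_width
    qr = np.outer(centres, q)
    sinc_tab = np.ascontiguousarray(np.sinc(qr / np.pi), dtype=np.float32)
    f2 = np.exp(-((q * bead_width) ** 2)).astype(np.float32)
    if exp_profile.sigma is None:
        raise saxs_mod.ProfileError("experimental profile needs sigma")
    # rescale intensities so f32 accumulation keeps full headroom
    scale = 1.0 / float(exp_profile.I.max())
    I_exp = (exp_profile.I * scale).astype(np.float32)
    inv_sig2 = (1.0 / (exp_profile.sigma * scale) ** 2).astype(np.float32)
    return f2, sinc_tab, np.float32(1.0 / bin_width), I_exp, inv_sig2


def _model_extent(model: BeadModel) -> float:
    lo, hi = model.coords.min(axis=0), model.coords.max(axis=0)
    return float(np.linalg.norm(hi - lo))


def flexfit(
    start_model: BeadModel,
    exp_profile: saxs_mod.ScatteringProfile,
    n_iter: int = 100,
    n_modes: int = 60,
    amplitude_powers: int = 5,
    target_step: float = 5.0,
    cutoff: float = 12.0,
    bead_width: float = 3.0,
    stall_tol: float = 1e-3,
    stall_limit: int = 5,
    regularize: bool = True,
    bond_tolerance: float = 0.1,
    chi2_target: float = 1.0,
) -> tuple[BeadModel, FitTrajectory]:
    """χ²-minimizing flexible fit of a bead model to a SAXS profile.

    Each iteration recomputes the ``n_modes`` slowest RTB modes,
    evaluates finite screw deformations along every mode over a
    per-mode geometric amplitude grid ±w·2^k (w scaled so the largest
    trial moves the most mobile block ≈ ``target_step`` Å), accepts the
    single best trial only on strict χ² decrease (post-regularization),
    and stops early after ``stall_limit`` consecutive iterations
    without ≥ ``stall_tol`` improvement, or as soon as χ² reaches
    ``chi2_target`` — descending below the noise level would only fit
    the noise realization and lets the structure drift.
    """
    bin_width = 0.5
    r_max = max(2.5 * _model_extent(start_model), 400.0)
    f2, sinc_tab, inv_bw, I_exp, inv_sig2 = _fit_tables(
        exp_profile, bead_width, bin_width, r_max)

    current = start_model.copy()
    reference = start_model
    masses32 = np.ascontiguousarray(current.masses, dtype=np.float32)

    def chi2_of(coords: np.ndarray) -> float:
        return float(_profile_chi2(
            np.ascontiguousarray(coords, dtype=np.float32),
            masses32, f2, sinc_tab, inv_bw, I_exp, inv_sig2))

    chi2_cur = chi2_of(current.coords)
    chi2_init = chi2_cur

    rows = []
    stall = 0
    it_done = 0
    step_scale = 1.0  # annealed on rejection for fine late-stage moves
    for it in range(n_iter):
        if chi2_target is not None and chi2_cur <= chi2_target:
            break
        it_done = it + 1
        net = build_enm(current, cutoff=cutoff)
        modes = compute_modes(net, n_modes=n_modes)
        # per-mode amplitude scale: displacement rate of the most mobile block
        block_extent = np.asarray(
            [np.linalg.norm(current.coords[b] - modes.centers[k], axis=1).max()
             if len(b) > 1 else 0.0
             for k, b in enumerate(modes.blocks)])
        rate = (np.linalg.norm(modes.velocities, axis=2)
                + np.linalg.norm(modes.omegas, axis=2) * block_extent[None, :]
                ).max(axis=1)
        rate = np.maximum(rate, 1e-12)
        w0 = step_scale * target_step / (rate * 2.0 ** (amplitude_powers - 1))
        powers = 2.0 ** np.arange(amplitude_powers)
        amps = np.concatenate([w0[:, None] * powers[None, :],
                               -w0[:, None] * powers[None, :]], axis=1)

        best_chi2, best_m, best_a = _scan_trials(
            np.ascontiguousarray(current.coords), masses32,
            modes.block_of.astype(np.int64),
            np.ascontiguousarray(modes.centers),
            np.ascontiguousarray(modes.velocities),
            np.ascontiguousarray(modes.omegas),
            np.ascontiguousarray(amps),
            f2, sinc_tab, inv_bw, I_exp, inv_sig2)

        accepted = False
        if best_m >= 0 and best_chi2 < chi2_cur:
            trial = nonlinear_deform(current, modes, best_m, best_a)
            if regularize:
                trial = regularize_topology(trial, reference,
                                            tolerance=bond_tolerance)
            chi2_reg = chi2_of(trial.coords)
            if chi2_reg < chi2_cur:
                improvement = chi2_cur - chi2_reg
                current = trial
                chi2_cur = chi2_reg
                accepted = True
                stall = stall + 1 if improvement < stall_tol else 0
                step_scale = min(1.0, step_scale * 2.0)
            else:
                stall += 1
                step_scale = max(step_scale * 0.5, 1.0 / 16.0)
        else:
            stall += 1
            step_scale = max(step_scale * 0.5, 1.0 / 16.0)

        from .structures import radius_of_gyration
        rows.append({"iteration": it, "mode": int(best_m),
                     "amplitude": float(best_a), "accepted": accepted,
                     "chi2": chi2_cur,
                     "rg": radius_of_gyration(current)})
        if stall >= stall_limit:
            break

    converged = chi2_cur <= 2.0
    records = pd.DataFrame(
        rows, columns=["iteration", "mode", "amplitude", "accepted",
                       "chi2", "rg"])
    traj = FitTrajectory(records=records, converged=converged,
                         n_iterations=it_done, chi2_initial=chi2_init,
                         chi2_final=chi2_cur)
    return current, traj


def run_ensemble(
    start_models: list[BeadModel],
    exp_profile: saxs_mod.ScatteringProfile,
    fit_config: dict | None = None,
) -> dict:
    """Independently flex-fit every start model; tabulate the ensemble.

    Returns a dict with the fitted models, per-model trajectories and a
    summary DataFrame of initial/final χ² and Rg. Individual failures
    are logged in the summary, not fatal.
    """
    from .structures import radius_of_gyration

    if not start_models:
        raise ValueError("no start models")
    cfg = dict(fit_config or {})
    fitted, trajectories, rows = [], [], []
    for k, m in enumerate(start_models):
        try:
            fm, traj = flexfit(m, exp_profile, **cfg)
            fitted.append(fm)
            trajectories.append(traj)
            rows.append({
                "model": k, "ok": True,
                "chi2_initial": traj.chi2_initial,
                "chi2_final": traj.chi2_final,
                "rg_initial": radius_of_gyration(m),
                "rg_final": radius_of_gyration(fm),
                "iterations": traj.n_iterations,
            })
        except Exception as exc:
            fitted.append(None)
            trajectories.append(None)
            rows.append({"model": k, "ok": False, "error": str(exc)})
    return {"models": fitted, "trajectories": trajectories,
            "summary": pd.DataFrame(rows)}
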