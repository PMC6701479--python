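"""Synthetic inputs for every pipeline stage.

Everything downstream — model-free SAXS, flexible fitting, clustering,
single-molecule kinetics, ITC — can be exercised on data produced here,
with the planted ground truth emitted next to each dataset.

The structural generator emulates an antiparallel dumbbell dimer: a
straight coiled-coil (CC) rod whose two ends carry compact terminal
modules (RB1B2 surrogates) separated by the rod length (default 160 Å),
with each protomer's C-terminal mobile module (PHD-Br surrogate)
tethered by a ~200-residue random-coil linker. The mobile modules can
be placed at planted distances (dA*, dB*) from the terminal modules to
create asymmetric ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import (
    BeadModel,
    DomainDefinition,
    IDEAL_BOND,
    center_of_mass,
)
from . import saxs as saxs_mod
from . import itc as itc_mod


class ConstructionError(ValueError):
    """Geometrically impossible template or placement."""


class InfeasibleLinkerError(ConstructionError):
    """Anchors further apart than the fully stretched chain."""


# ----------------------------------------------------------------------
# templates


@dataclass
class DimerTemplate:
    """Geometry of the synthetic antiparallel dumbbell dimer.

    ``cc_length`` is the terminal-module COM separation (the coiled-coil
    length). Linkers count ``linker_residues`` beads each. ``d_planted``
    holds optional ground-truth terminal-domain displacements (dA*, dB*)
    in Å, measured from the mobile-module COM to the nearest terminal
    module COM.
    """

    cc_length: float = 160.0
    module_radius: float = 25.0
    mobile_radius: float = 18.0
    cc_beads: int = 43
    module_beads: int = 60
    mobile_beads: int = 50
    linker_residues: int = 200
    strand_offset: float = 5.0
    d_planted: tuple[float, float] | None = None
    max_displacement: float = 140.0
    # residue counts each coarse domain stands for: bead masses (and
    # scattering weights) are residues/beads so the folded domains keep
    # their real share of the scattering mass relative to the linkers
    module_residues: int = 150
    cc_residues: int = 207
    mobile_residues: int = 220

    def __post_init__(self) -> None:
        if self.cc_length <= 0 or self.module_radius < 0 or self.mobile_radius < 0:
            raise ConstructionError("template dimensions must be positive")
        if self.d_planted is not None:
            for d in self.d_planted:
                if not (0.0 <= d <= self.max_displacement):
                    raise ConstructionError(
                        f"planted displacement {d} outside [0, {self.max_displacement}]"
                    )


@dataclass
class NoiseSpec:
    """Noise levels for all simulators; the seed is recorded in outputs."""

    saxs_rel_sigma: float = 0.01   # relative sigma at I(0)
    trace_background: float = 0.0  # camera baseline level
    trace_snr: float = 10.0        # bright-level / noise-sd
    itc_heat_frac: float = 0.01    # fraction of the first-injection heat
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.saxs_rel_sigma, self.trace_snr, self.itc_heat_frac) < 0:
            raise ValueError("noise scales must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ----------------------------------------------------------------------
# geometry helpers


def _ball_spiral(n: int, radius: float, step: float = IDEAL_BOND) -> np.ndarray:
    """A connected bead path coiled inside a sphere.

    Beads wind along a helical path whose radius follows the sphere
    surface at shrinking latitudes, giving consecutive distances equal
    to ``step`` so the module is a topologically valid chain segment.
    """
    if n <= 0:
        return np.empty((0, 3))
    if radius < 1e-9:
        return np.zeros((n, 3))
    if n == 1:
        return np.zeros((1, 3))
    pts = np.empty((n, 3))
    # winding stays below |z| = 0.8 R so the latitude radius never
    # shrinks fast enough to force a bond beyond `step`
    span = 1.6 * radius
    dz = min(span / (n - 1), 0.6 * step)
    z0 = -dz * (n - 1) / 2.0
    theta = 0.0
    z = z0
    rho = math.sqrt(radius**2 - z**2)
    pts[0] = (rho, 0.0, z)
    for i in range(1, n):
        z_next = z0 + i * dz
        rho_next = math.sqrt(radius**2 - z_next**2)
        # exact step length: solve the azimuthal increment from the chord
        c = (rho**2 + rho_next**2 + dz**2 - step**2) / (2.0 * rho * rho_next)
        theta += math.acos(min(max(c, -1.0), 1.0))
        pts[i] = (rho_next * math.cos(theta), rho_next * math.sin(theta), z_next)
        z, rho = z_next, rho_next
    pts -= pts.mean(axis=0)
    return pts


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


def _terminal_module(n: int, radius: float, center: np.ndarray,
                     exit_dir: np.ndarray) -> np.ndarray:
    """A ball-spiral module centred at ``center`` whose last bead faces
    ``exit_dir`` so the following chain segment can bond to it."""
    pts = _ball_spiral(n, radius)
    if radius >= 1e-9 and n > 1:
        e = np.asarray(exit_dir, dtype=float)
        e = e / np.linalg.norm(e)
        z = np.array([0.0, 0.0, 1.0])
        rot, _ = Rotation.align_vectors(e[None, :], z[None, :])
        pts = pts @ rot.as_matrix().T
    return pts + np.asarray(center, dtype=float)


def _protomer_core(t: DimerTemplate, n_end: np.ndarray, c_end: np.ndarray,
                   sgn: float) -> tuple[np.ndarray, np.ndarray]:
    """Terminal module plus its CC strand for one protomer.

    The strand leaves the module surface through a short junction arc
    onto the rod axis (offset ``strand_offset``/2 to this protomer's
    side), then runs straight to the protomer's C-terminal rod end; the
    two antiparallel strands therefore lie side by side along the rod,
    keeping the elastic network of the dimer connected regardless of
    where the mobile domains sit.
    """
    off = t.strand_offset / 2.0
    axis = (c_end - n_end) / np.linalg.norm(c_end - n_end)
    module = _terminal_module(t.module_beads, t.module_radius, n_end, axis)
    p_end = c_end + np.array([0.0, sgn * off, 0.0])
    n_cc = max(t.cc_beads, 2)
    exit_pt = module[-1]
    # junction target: on-axis point level with the module exit
    along = float(np.dot(exit_pt - n_end, axis))
    p_axis = n_end + max(along, 0.0) * axis + np.array([0.0, sgn * off, 0.0])
    d_j = np.linalg.norm(p_axis - exit_pt)
    n_j = min(max(int(np.ceil(d_j / 3.5)) + 1, 2), n_cc - 2)
    u = (p_axis - exit_pt)
    un = np.linalg.norm(u)
    u = u / un if un > 1e-9 else axis
    j_start = exit_pt + IDEAL_BOND * u
    s = np.linspace(0.0, 1.0, n_j)[:, None]
    junction = j_start[None, :] * (1 - s) + p_axis[None, :] * s
    n_rod = n_cc - n_j
    s = np.linspace(0.0, 1.0, n_rod + 1)[1:, None]
    rod = p_axis[None, :] * (1 - s) + p_end[None, :] * s
    strand = np.concatenate([junction, rod], axis=0)
    return module, strand


# ----------------------------------------------------------------------
# linker growth


def grow_linker(
    anchor_start: np.ndarray,
    anchor_end: np.ndarray | None,
    n_residues: int,
    rng: np.random.Generator,
    bond: float = IDEAL_BOND,
    clash: float = 2.0,
    max_restarts: int = 200,
) -> np.ndarray:
    """Grow a random-coil bead chain, optionally bridging two anchors.

    The chain has ``n_residues`` beads with consecutive distances equal
    to ``bond``; its first bead lies one bond from ``anchor_start`` and
    (when ``anchor_end`` is given) its last bead lies within one bond of
    ``anchor_end``. Bridged growth uses Brownian-bridge step directions:
    each step mixes an isotropic random direction with the direction to
    the far anchor, weighted by how taut the remaining chain is.
    Non-consecutive beads closer than ``clash`` are rejected and the
    step (then the chain) resampled.
    """
    a0 = np.asarray(anchor_start, dtype=float)
    a1 = None if anchor_end is None else np.asarray(anchor_end, dtype=float)
    if n_residues < 1:
        raise ConstructionError("linker needs at least one residue")
    if a1 is not None:
        reach = (n_residues + 1) * bond
        if np.linalg.norm(a1 - a0) >= reach:
            raise InfeasibleLinkerError(
                f"anchors {np.linalg.norm(a1 - a0):.1f} Å apart exceed the "
                f"{reach:.1f} Å reach of a {n_residues}-residue linker"
            )

    for _ in range(max_restarts):
        chain = np.empty((n_residues, 3))
        pos = a0
        ok = True
        for i in range(n_residues):
            remaining = n_residues - i  # steps left including this one
            placed = False
            for _try in range(40):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                if a1 is not None:
                    to_end = a1 - pos
                    dist = np.linalg.norm(to_end)
                    slack = remaining * bond
                    # tautness in [0, 1]: 1 means the chain must go straight
                    taut = min(dist / slack, 1.0) if slack > 0 else 1.0
                    kappa = 4.0 * taut / max(1.0 - taut, 0.02)
                    if dist > 1e-9:
                        u = u + kappa * to_end / dist
                        u /= np.linalg.norm(u)
                cand = pos + bond * u
                if i >= 2:
                    d = np.linalg.norm(chain[: i - 1] - cand, axis=1)
                    if d.min() < clash:
                        continue
                placed = True
                break
            if not placed:
                ok = False
                break
            chain[i] = cand
            pos = cand
        if not ok:
            continue
        if a1 is not None and np.linalg.norm(chain[-1] - a1) > bond:
            continue
        return chain
    raise ConstructionError("linker growth failed to bridge the anchors")


# ----------------------------------------------------------------------
# dumbbell construction

_DOMAIN_ORDER = ("RB1B2", "CC", "LINKER", "PHDBR")


def build_dumbbell_dimer(
    template: DimerTemplate | None = None,
    rng: np.random.Generator | None = None,
) -> BeadModel:
    """Build the antiparallel dumbbell dimer from a template.

    Protomer A runs N→C as RB1B2-A (terminal module at rod end 1),
    CC-A (one strand of the rod, end 1 → end 2), LINKER-A, PHDBR-A;
    protomer B is the antiparallel mirror (RB1B2-B at end 2). The two
    terminal-module COMs sit exactly ``cc_length`` apart. Mobile-module
    placements use ``template.d_planted`` when given, otherwise the
    mobile modules rest one bond beyond their linker attachment.
    """
    t = template or DimerTemplate()
    rng = rng or np.random.default_rng(0)
    L = t.cc_length
    off = t.strand_offset / 2.0

    end1 = np.array([-L / 2.0, 0.0, 0.0])
    end2 = np.array([+L / 2.0, 0.0, 0.0])

    coords, prot, dom, mass = [], [], [], []
    domains: list[DomainDefinition] = []

    def add(chain: str, name: str, pts: np.ndarray, rigid: bool,
            bead_mass: float = 1.0) -> None:
        start = sum(1 for p in prot if p == chain)
        coords.extend(pts)
        prot.extend([chain] * len(pts))
        dom.extend([name] * len(pts))
        mass.extend([bead_mass] * len(pts))
        domains.append(
            DomainDefinition(name=name, chain=chain, start=start,
                             end=start + len(pts), rigid=rigid)
        )

    planted = t.d_planted
    for chain, sgn in (("A", +1.0), ("B", -1.0)):
        n_end = end1 if chain == "A" else end2
        c_end = end2 if chain == "A" else end1
        module, strand = _protomer_core(t, n_end, c_end, sgn)
        add(chain, f"RB1B2-{chain}", module, rigid=True,
            bead_mass=t.module_residues / max(len(module), 1))
        add(chain, f"CC-{chain}", strand, rigid=True,
            bead_mass=t.cc_residues / max(len(strand), 1))

        # mobile-module target position
        anchor = strand[-1]
        other_module_com = c_end  # terminal module COM at the linker end
        if planted is not None:
            d_star = planted[0 if chain == "A" else 1]
            direction = np.array([0.0, sgn * 0.35, 0.93])
            direction /= np.linalg.norm(direction)
            mobile_com = other_module_com + d_star * direction
        else:
            direction = np.array([0.0, sgn, 0.0])
            mobile_com = anchor + (t.mobile_radius + 2 * IDEAL_BOND) * direction

        mobile = _ball_spiral(t.mobile_beads, t.mobile_radius)
        mobile = mobile @ _random_rotation(rng).T + mobile_com

        linker = grow_linker(anchor, mobile[0], t.linker_residues, rng)
        add(chain, f"LINKER-{chain}", linker, rigid=False)
        add(chain, f"PHDBR-{chain}", mobile, rigid=True,
            bead_mass=t.mobile_residues / max(len(mobile), 1))

    model = BeadModel(
        coords=np.asarray(coords),
        protomer_id=np.asarray(prot, dtype=object),
        domain_id=np.asarray(dom, dtype=object),
        domains=domains,
        masses=np.asarray(mass),
        metadata={"template": asdict(t) if not isinstance(t, dict) else t},
    )
    model.validate_domains()
    return model


def build_rbcc_dumbbell(template: DimerTemplate | None = None) -> BeadModel:
    """The RBCC-only construct: the dumbbell without linkers and mobile
    modules (rod plus two terminal modules)."""
    t = template or DimerTemplate()
    L = t.cc_length
    off = t.strand_offset / 2.0
    end1 = np.array([-L / 2.0, 0.0, 0.0])
    end2 = np.array([+L / 2.0, 0.0, 0.0])
    coords, prot, dom, mass = [], [], [], []
    domains = []
    for chain, sgn in (("A", +1.0), ("B", -1.0)):
        n_end = end1 if chain == "A" else end2
        c_end = end2 if chain == "A" else end1
        module, strand = _protomer_core(t, n_end, c_end, sgn)
        n_cc = len(strand)
        start = 0
        domains.append(DomainDefinition(f"RB1B2-{chain}", chain, start,
                                        start + len(module), True))
        domains.append(DomainDefinition(f"CC-{chain}", chain, start + len(module),
                                        start + len(module) + n_cc, True))
        coords.extend(module)
        coords.extend(strand)
        prot.extend([chain] * (len(module) + n_cc))
        dom.extend([f"RB1B2-{chain}"] * len(module) + [f"CC-{chain}"] * n_cc)
        mass.extend([t.module_residues / max(len(module), 1)] * len(module)
                    + [t.cc_residues / max(n_cc, 1)] * n_cc)
    model = BeadModel(np.asarray(coords), np.asarray(prot, dtype=object),
                      np.asarray(dom, dtype=object), domains,
                      masses=np.asarray(mass))
    model.validate_domains()
    return model


def randomize_termini(
    model: BeadModel,
    template: DimerTemplate,
    D: float = 140.0,
    rng: np.random.Generator | None = None,
    planted: tuple[float, float] | None = None,
) -> BeadModel:
    """Re-place both mobile terminal modules at random poses.

    Each mobile module receives an independent uniform random rotation
    about its COM and a new COM drawn uniformly from the ball of radius
    ``D`` around its linker attachment point (or a planted displacement
    when ``planted`` forces exact ground truth); the linker is regrown
    to bridge. Returns a new model.
    """
    rng = rng or np.random.default_rng(0)
    if 0 < D < template.mobile_radius:
        raise ConstructionError("D smaller than the mobile-module radius")
    out = model.copy()
    for k, chain in enumerate(("A", "B")):
        mob_idx = model.select(domain=f"PHDBR-{chain}")
        lnk_idx = model.select(domain=f"LINKER-{chain}")
        cc_idx = model.select(domain=f"CC-{chain}")
        anchor = model.coords[cc_idx[-1]]
        mob = model.coords[mob_idx]
        com = mob.mean(axis=0)
        R = _random_rotation(rng)
        if planted is not None:
            ref_idx = model.select(domain=f"RB1B2-{'B' if chain == 'A' else 'A'}")
            other_idx = model.select(domain=f"RB1B2-{chain}")
            ref_com = model.coords[ref_idx].mean(axis=0)
            other_com = model.coords[other_idx].mean(axis=0)
            new_com = None
            for _ in range(500):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = ref_com + planted[k] * u
                # the planted value must be the distance to the *nearest*
                # terminal module, and the pose must stay within reach
                if (np.linalg.norm(cand - anchor) <= D
                        and np.linalg.norm(cand - other_com) > planted[k]):
                    new_com = cand
                    break
            if new_com is None:
                raise ConstructionError(
                    f"cannot place planted displacement {planted[k]} within D={D}"
                )
        elif D == 0:
            new_com = com  # degenerate: rotation about the current COM only
        else:
            # uniform in the ball of radius D around the attachment point
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = D * rng.uniform() ** (1.0 / 3.0)
            new_com = anchor + r * u
        new_mob = (mob - com) @ R.T + new_com
        out.coords[mob_idx] = new_mob
        out.coords[lnk_idx] = grow_linker(anchor, new_mob[0],
                                          len(lnk_idx), rng)
    out.metadata["D"] = D
    if planted is not None:
        out.metadata["planted"] = tuple(planted)
    return out


# ----------------------------------------------------------------------
# SAXS simulation

DEFAULT_Q_GRID = np.geomspace(0.0025, 0.6, 101)


def simulate_saxs(
    model: BeadModel,
    q_grid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> saxs_mod.ScatteringProfile:
    """Noisy Debye profile: σ(q) = a·√(I(q)·I(0)), Gaussian errors.

    The √I scaling approximates photon-counting statistics; ``a`` is the
    relative uncertainty at q → 0.
    """
    noise = noise or NoiseSpec()
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    truth = saxs_mod.debye_profile(model, q)
    I0 = truth.I[0]
    a = noise.saxs_rel_sigma
    if a == 0:
        return saxs_mod.ScatteringProfile(
            q, truth.I.copy(), None,
            {**truth.metadata, "seed": noise.seed, "noise": 0.0})
    sigma = a * np.sqrt(np.maximum(truth.I, 0.0) * I0)
    rng = noise.rng()
    I_noisy = truth.I + rng.normal(scale=sigma)
    return saxs_mod.ScatteringProfile(
        q, I_noisy, sigma,
        {**truth.metadata, "seed": noise.seed, "noise": a})


# ----------------------------------------------------------------------
# single-molecule dwell processes and traces


def draw_bright_times(kinetic_model, n: int, rng: np.random.Generator) -> np.ndarray:
    """Bright (bound) durations from the two-exponential mixture (s)."""
    a1 = kinetic_model.A1 / 100.0
    comp = rng.uniform(size=n) < a1
    t = np.where(
        comp,
        rng.exponential(kinetic_model.tau_off_1, size=n),
        rng.exponential(kinetic_model.tau_off_2, size=n),
    )
    return t


def draw_dark_times(kinetic_model, n: int, rng: np.random.Generator) -> np.ndarray:
    """Dark (unbound) durations: exponential with rate k_on·[HP1] (s)."""
    rate = kinetic_model.k_on * kinetic_model.concentration
    return rng.exponential(1.0 / rate, size=n)


def simulate_smtirf_traces(
    kinetic_model,
    n_traces: int,
    frame_rate: float = 20.0,
    n_frames: int = 10_000,
    label_efficiency: float = 1.0,
    dimer_fraction: float = 0.0,
    stuck_fraction: float = 0.0,
    bleach_time_s: float = 10.0,
    noise: NoiseSpec | None = None,
):
    """Simulate fluorescence time traces of an alternating binding process.

    Dark durations are exponential (rate k_on·[ligand]); bright durations
    come from the two-exponential mixture. Each binding event is a dimer
    with probability ``dimer_fraction``; each protomer of a binder
    carries a dye independently with probability ``label_efficiency``
    (a dimer carries up to 2). Events with zero visible dyes merge into
    the surrounding dark time. Intensity is 1 unit per visible dye plus
    Gaussian camera noise of sd = 1/snr. Dwell times are drawn in
    continuous time and floored to the frame grid; sub-frame events
    vanish from the trace (but stay in the returned ground truth). A
    ``stuck_fraction`` of traces emulates immobilized single dyes that
    stay bright from the first frame until one exponential bleaching
    step (mean ``bleach_time_s``), then go permanently dark.

    Returns (traces, ground_truth) where each trace is a dict with
    ``time_s`` and ``intensity`` arrays and ground_truth collects the
    continuous-time events per trace.
    """
    from .smtirf import FluorescenceTrace  # local import to avoid a cycle

    if kinetic_model.tau_off_1 <= 1.0 / frame_rate:
        import warnings

        warnings.warn("fast dwell component at or below one frame; events "
                      "may be unresolvable", RuntimeWarning)
    noise = noise or NoiseSpec()
    rng = noise.rng()
    dt = 1.0 / frame_rate
    t_total = n_frames * dt
    noise_sd = 1.0 / noise.trace_snr if noise.trace_snr > 0 else 0.0

    traces, truth = [], []
    for k in range(n_traces):
        if rng.uniform() < stuck_fraction:
            # immobilized molecule: bright from the start until the dye
            # bleaches in a single step, then permanently dark
            t_bleach = rng.exponential(bleach_time_s)
            intensity = np.full(n_frames, noise.trace_background)
            f1 = min(int(np.floor(t_bleach / dt)), n_frames)
            intensity[:f1] += 1.0
            if noise_sd > 0:
                intensity = intensity + rng.normal(scale=noise_sd,
                                                   size=n_frames)
            traces.append(FluorescenceTrace(
                time_s=np.arange(n_frames) * dt, intensity=intensity,
                metadata={"seed": noise.seed, "trace": k, "stuck": True,
                          "concentration_M": kinetic_model.concentration,
                          "frame_rate_hz": frame_rate}))
            truth.append({"bright_s": [], "start_s": [], "n_dyes": [],
                          "is_dimer": [], "stuck": True,
                          "bleach_s": t_bleach})
            continue
        t = 0.0
        events = []  # (start, duration, n_dyes, is_dimer)
        while t < t_total:
            t += draw_dark_times(kinetic_model, 1, rng)[0]
            if t >= t_total:
                break
            dur = draw_bright_times(kinetic_model, 1, rng)[0]
            is_dimer = rng.uniform() < dimer_fraction
            n_sites = 2 if is_dimer else 1
            n_dyes = int(rng.binomial(n_sites, label_efficiency))
            events.append((t, dur, n_dyes, is_dimer))
            t += dur
        intensity = np.full(n_frames, noise.trace_background, dtype=float)
        for start, dur, n_dyes, _ in events:
            if n_dyes == 0:
                continue
            f0 = int(np.ceil(start / dt))
            f1 = int(np.floor((start + dur) / dt))
            if f1 <= f0:  # sub-frame event
                continue
            intensity[f0:min(f1, n_frames)] += float(n_dyes)
        if noise_sd > 0:
            intensity = intensity + rng.normal(scale=noise_sd, size=n_frames)
        traces.append(
            FluorescenceTrace(
                time_s=np.arange(n_frames) * dt,
                intensity=intensity,
                metadata={"seed": noise.seed, "trace": k,
                          "concentration_M": kinetic_model.concentration,
                          "frame_rate_hz": frame_rate},
            )
        )
        truth.append(
            {
                "bright_s": [e[1] for e in events],
                "start_s": [e[0] for e in events],
                "n_dyes": [e[2] for e in events],
                "is_dimer": [e[3] for e in events],
                "stuck": False,
            }
        )
    return traces, truth


# ----------------------------------------------------------------------
# ITC simulation


def simulate_itc(
    experiment_design=None,
    N: float = 1.0,
    Kd: float = 176e-9,
    dH: float = -10_000.0,
    noise: NoiseSpec | None = None,
):
    """One-set-of-sites isotherm with Gaussian heat noise.

    ``dH`` in cal/mol; heats are returned in μcal per injection inside a
    TitrationExperiment. Noise sd is ``itc_heat_frac`` of the
    first-injection heat magnitude.
    """
    noise = noise or NoiseSpec()
    exp = experiment_design or itc_mod.TitrationExperiment()
    heats = itc_mod.one_set_of_sites_heat(exp, N=N, Kd=Kd, dH=dH)
    if noise.itc_heat_frac > 0 and dH != 0:
        rng = noise.rng()
        sd = noise.itc_heat_frac * abs(heats[0])
        heats = heats + rng.normal(scale=sd, size=len(heats))
    out = itc_mod.TitrationExperiment(
        cell_volume_ul=exp.cell_volume_ul,
        injection_volume_ul=exp.injection_volume_ul,
        n_injections=exp.n_injections,
        cell_conc_M=exp.cell_conc_M,
        syringe_conc_M=exp.syringe_conc_M,
        temperature_K=exp.temperature_K,
        heats_ucal=heats,
    )
    out.metadata = {"seed": noise.seed, "truth": {"N": N, "Kd_M": Kd,
                                                  "dH_cal_mol": dH}}
    return out


# ----------------------------------------------------------------------
# ground-truth sidecar


def write_ground_truth(path, **truth) -> None:
    """Write planted ground truth as JSON next to a synthetic dataset."""
    def clean(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        return v

    with open(path, "w") as fh:
        json.dump({k: clean(v) for k, v in truth.items()}, fh, indent=1)
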