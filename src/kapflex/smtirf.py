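"""Single-molecule fluorescence trace analysis.

Event detection on intensity time traces, dwell-time survival
statistics, exponential kinetics fitting (double-exponential
dissociation, mono-exponential association) and intensity-based
oligomer quantification.

Dwell-time conventions: traces are uniformly sampled (default 20 Hz);
bright/dark intervals are integer frame counts converted to seconds;
intervals truncated by the trace boundaries are flagged and excluded
from kinetic fits. Because durations are floored to the frame grid,
the empirical survival of recorded durations evaluated *at frame
multiples* equals the survival of the underlying continuous durations,
so fitting on that grid is discretization-unbiased; dropping sub-frame
events only rescales the mixture amplitudes, which the fitters undo
analytically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass
class FluorescenceTrace:
    """Uniformly sampled intensity trace."""

    time_s: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("trace must be uniformly sampled")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0]) if len(self.time_s) > 1 else 0.0


@dataclass
class EventList:
    """Alternating bright/dark intervals extracted from one trace."""

    bright_s: np.ndarray
    dark_s: np.ndarray
    bright_levels: np.ndarray          # per-event mean intensity above baseline
    bright_truncated: np.ndarray       # boundary-truncation flags
    dark_truncated: np.ndarray
    baseline: float = 0.0
    threshold: float = 0.0
    #: single bright stretch from the first frame then permanent dark —
    #: the signature of an immobilized dye bleaching, not of exchange
    bleach_suspect: bool = False


@dataclass
class KineticModel:
    """Double-exponential dissociation plus association rate.

    ``A1``/``A2`` are percentages (A1 + A2 = 100); τ in seconds; k_on in
    M⁻¹s⁻¹ at the given ligand concentration (M).
    """

    tau_off_1: float
    A1: float
    tau_off_2: float
    A2: float
    k_on: float
    concentration: float

    def __post_init__(self) -> None:
        if abs(self.A1 + self.A2 - 100.0) > 1e-6:
            raise ValueError("A1 + A2 must equal 100")
        if min(self.tau_off_1, self.tau_off_2) <= 0:
            raise ValueError("tau values must be positive")

    @property
    def mean_bright_s(self) -> float:
        return (self.A1 * self.tau_off_1 + self.A2 * self.tau_off_2) / 100.0


@dataclass
class DissociationFit:
    tau_off_1: float
    A1: float                 # %
    tau_off_2: float
    A2: float                 # %
    mono: bool
    n: int
    ci_tau_1: tuple[float, float] | None = None
    ci_tau_2: tuple[float, float] | None = None
    ci_A2: tuple[float, float] | None = None


# ----------------------------------------------------------------------
# event detection


def detect_events(
    trace: FluorescenceTrace, k_mad: float = 3.0, min_frames: int = 2,
    smooth: int = 3,
) -> EventList:
    """Threshold-based event detection on a single trace.

    Baseline is the trace median; the threshold sits ``k_mad`` scaled
    median-absolute-deviations above it (MAD × 1.4826, the Gaussian-
    consistent scale). The thresholded state sequence is computed on a
    ``smooth``-frame running median (default 3), which bridges
    single-frame noise dropouts inside events without shifting event
    edges by more than a frame. Contiguous supra-threshold runs of at
    least ``min_frames`` frames are bright events; everything else is
    dark. Per-event levels are measured on the raw trace.
    """
    y_raw = trace.intensity
    if len(y_raw) < 100:
        raise ValueError("trace too short (< 100 frames)")
    if smooth and smooth > 1:
        from scipy.ndimage import median_filter
        y = median_filter(y_raw, size=smooth, mode="nearest")
    else:
        y = y_raw
    dt = trace.dt
    baseline = float(np.median(y_raw))
    mad = float(np.median(np.abs(y_raw - baseline))) * 1.4826
    if mad == 0:
        if y.max() == baseline:
            warnings.warn("constant trace: zero MAD, no events", RuntimeWarning)
            return EventList(np.array([]), np.array([len(y) * dt]),
                             np.array([]), np.array([], dtype=bool),
                             np.array([True]), baseline, baseline)
        # noise-free trace: split baseline and signal at half amplitude
        thr = baseline + 0.5 * (y.max() - baseline)
    else:
        thr = baseline + k_mad * mad
    above = y > thr

    # run-length encode the smoothed state sequence
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [len(y)]])
    states = above[starts]

    # step-fit refinement: snap each event's edges to the half-amplitude
    # crossing on the raw trace (boundary frames erode below the k·MAD
    # threshold far more often than below half amplitude)
    runs = []
    prev_end = 0
    for s, e, st in zip(starts, ends, states):
        if not st or e - s < min_frames:
            continue
        level = float(y_raw[s:e].mean())
        half = baseline + 0.5 * (level - baseline)
        while s > prev_end and y_raw[s - 1] > half:
            s -= 1
        while e < len(y_raw) and y_raw[e] > half:
            e += 1
        while e - s > 1 and y_raw[s] <= half:
            s += 1
        while e - s > 1 and y_raw[e - 1] <= half:
            e -= 1
        if e - s >= min_frames:
            runs.append((s, e))
            prev_end = e

    bright, dark, levels = [], [], []
    btrunc, dtrunc = [], []
    pos = 0
    for s, e in runs:
        if s > pos:
            dark.append((s - pos) * dt)
            dtrunc.append(pos == 0)
        bright.append((e - s) * dt)
        levels.append(float(y_raw[s:e].mean() - baseline))
        btrunc.append(s == 0 or e == len(y_raw))
        pos = e
    if pos < len(y_raw):
        dark.append((len(y_raw) - pos) * dt)
        dtrunc.append(True)
    bleach = (len(runs) == 1 and runs[0][0] == 0
              and runs[0][1] < len(y_raw)
              and runs[0][1] - runs[0][0] >= 5 * min_frames)
    return EventList(
        bright_s=np.asarray(bright), dark_s=np.asarray(dark),
        bright_levels=np.asarray(levels),
        bright_truncated=np.asarray(btrunc, dtype=bool),
        dark_truncated=np.asarray(dtrunc, dtype=bool),
        baseline=baseline, threshold=thr, bleach_suspect=bool(bleach),
    )


# ----------------------------------------------------------------------
# survival statistics


@dataclass
class SurvivalCurve:
    """Empirical survival function S(t) = P(T ≥ t) of pooled dwells."""

    t: np.ndarray
    S: np.ndarray
    durations: np.ndarray

    @classmethod
    def from_durations(cls, durations: np.ndarray) -> "SurvivalCurve":
        d = np.sort(np.asarray(durations, dtype=float))
        n = len(d)
        if n == 0:
            raise ValueError("no durations")
        t = np.unique(d)
        S = 1.0 - np.searchsorted(d, t, side="left") / n
        # prepend S(0+) = 1
        t = np.concatenate([[0.0], t])
        S = np.concatenate([[1.0], S])
        return cls(t=t, S=S, durations=d)

    def at(self, t: np.ndarray) -> np.ndarray:
        """Evaluate P(T ≥ t) exactly from the pooled sample."""
        return 1.0 - np.searchsorted(self.durations, np.asarray(t),
                                     side="left") / len(self.durations)


def dwell_histograms(
    event_lists: list[EventList],
) -> tuple[SurvivalCurve, SurvivalCurve]:
    """Pooled normalized cumulative survival histograms (bright, dark).

    Boundary-truncated intervals are excluded.
    """
    bright = np.concatenate(
        [e.bright_s[~e.bright_truncated] for e in event_lists]
        or [np.array([])])
    dark = np.concatenate(
        [e.dark_s[~e.dark_truncated] for e in event_lists]
        or [np.array([])])
    if len(bright) + len(dark) < 30:
        warnings.warn("fewer than 30 pooled intervals", RuntimeWarning)
    return (SurvivalCurve.from_durations(bright),
            SurvivalCurve.from_durations(dark))


def _survival_grid(curve: SurvivalCurve, dt: float):
    """Evaluation grid at frame multiples, shifted to the first frame.

    Returns (t_shifted, S_conditional) with t measured from the first
    frame and S renormalized there, plus the frame interval actually
    used; the conditional survival of a censored exponential mixture on
    this grid is again a sum of exponentials with the same τ's.
    """
    tmax = curve.durations.max()
    k = np.arange(1, max(int(round(tmax / dt)), 3) + 1)
    t = k * dt
    S = curve.at(t)
    keep = S > 0
    t, S = t[keep], S[keep]
    S0 = S[0]
    return t - t[0], S / S0


def _infer_dt(durations: np.ndarray) -> float:
    """Frame interval from the duration grid (durations are multiples)."""
    d = np.unique(durations)
    gaps = np.diff(np.concatenate([[0.0], d]))
    dt = float(gaps[gaps > 1e-12].min())
    # continuous (un-discretized) durations: use a practical grid instead
    return max(dt, float(d.max()) / 2000.0)


def fit_dissociation(
    bright_survival: SurvivalCurve,
    n_bootstrap: int = 200,
    seed: int = 0,
    frame_interval: float | None = None,
    method: str = "lsq",
) -> DissociationFit:
    """Fit the bright-time survival with a two-exponential mixture.

    ``method="lsq"`` (default, matching the cumulative-histogram
    practice): least squares of A·exp(−t/τ1) + (1−A)·exp(−t/τ2) on the
    conditional survival at frame multiples (τ1 < τ2 by convention),
    with amplitudes de-censored back to the underlying mixture weights.
    ``method="mle"``: maximum likelihood of the frame-binned durations
    under the same mixture, conditioned on surviving the first frame.
    Either way the fit falls back to (and flags) a mono-exponential
    when the two time constants are not separated (τ2/τ1 < 2) or the
    bootstrap CI of A2 includes zero. Bootstrap resamples intervals.
    """
    if method not in ("lsq", "mle"):
        raise ValueError("method must be 'lsq' or 'mle'")
    dur = bright_survival.durations
    if len(dur) < 100:
        warnings.warn("fewer than 100 intervals: unstable fit", RuntimeWarning)
    dt = frame_interval or _infer_dt(dur)

    def two_exp_lsq(durations: np.ndarray):
        curve = SurvivalCurve.from_durations(durations)
        t, S = _survival_grid(curve, dt)
        tbar = float(np.sum(durations)) / len(durations)

        def resid(p):
            a = 1.0 / (1.0 + np.exp(-p[0]))  # logistic keeps a in (0,1)
            t1, t2 = np.exp(p[1]), np.exp(p[2])
            return a * np.exp(-t / t1) + (1 - a) * np.exp(-t / t2) - S

        x0 = np.array([1.0, np.log(max(tbar / 2, dt)), np.log(tbar * 3)])
        sol = least_squares(resid, x0, method="lm", max_nfev=2000)
        a = 1.0 / (1.0 + np.exp(-sol.x[0]))
        t1, t2 = np.exp(sol.x[1]), np.exp(sol.x[2])
        if t1 > t2:
            t1, t2, a = t2, t1, 1.0 - a
        # de-censor: conditional amplitudes back to mixture weights
        w1 = a * np.exp(dt / t1)
        w2 = (1 - a) * np.exp(dt / t2)
        A1 = w1 / (w1 + w2)
        return t1, A1, t2, 1.0 - A1

    def two_exp_mle(durations: np.ndarray):
        from scipy.optimize import minimize

        k, counts = np.unique(np.round(durations / dt).astype(int),
                              return_counts=True)
        tbar = float(np.mean(durations))

        def surv(t, a, t1, t2):
            return a * np.exp(-t / t1) + (1 - a) * np.exp(-t / t2)

        def nll(p):
            a = 1.0 / (1.0 + np.exp(-p[0]))
            t1, t2 = np.exp(p[1]), np.exp(p[2])
            pk = surv(k * dt, a, t1, t2) - surv((k + 1) * dt, a, t1, t2)
            pk = pk / surv(dt, a, t1, t2)
            return -float(np.sum(counts * np.log(np.maximum(pk, 1e-300))))

        x0 = np.array([1.0, np.log(max(tbar / 2, dt)), np.log(tbar * 3)])
        sol = minimize(nll, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-7,
                                "fatol": 1e-9})
        a = 1.0 / (1.0 + np.exp(-sol.x[0]))
        t1, t2 = np.exp(sol.x[1]), np.exp(sol.x[2])
        if t1 > t2:
            t1, t2, a = t2, t1, 1.0 - a
        return t1, a, t2, 1.0 - a

    two_exp_fit = two_exp_lsq if method == "lsq" else two_exp_mle

    def mono_fit(durations: np.ndarray) -> float:
        curve = SurvivalCurve.from_durations(durations)
        t, S = _survival_grid(curve, dt)
        w = np.sqrt(np.maximum(S, 1e-12))

        def resid(p):
            return (np.exp(-t / np.exp(p[0])) - S) / w

        tbar = float(np.mean(durations))
        sol = least_squares(resid, np.array([np.log(tbar)]), method="lm")
        return float(np.exp(sol.x[0]))

    t1, A1, t2, A2 = two_exp_fit(dur)

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        sample = rng.choice(dur, size=len(dur), replace=True)
        try:
            boots.append(two_exp_fit(sample))
        except Exception:
            continue
    if boots:
        boots = np.asarray(boots)
        ci = lambda col: tuple(np.percentile(boots[:, col], [2.5, 97.5]))
        ci_t1, ci_t2, ci_a2 = ci(0), ci(2), ci(3)
    else:
        ci_t1 = ci_t2 = ci_a2 = None

    mono = t2 / t1 < 2.0 or (ci_a2 is not None and ci_a2[0] <= 0.0)
    if mono:
        tau = mono_fit(dur)
        return DissociationFit(tau_off_1=tau, A1=100.0, tau_off_2=tau,
                               A2=0.0, mono=True, n=len(dur),
                               ci_tau_1=ci_t1, ci_tau_2=ci_t2, ci_A2=ci_a2)
    return DissociationFit(
        tau_off_1=float(t1), A1=float(100 * A1),
        tau_off_2=float(t2), A2=float(100 * A2),
        mono=False, n=len(dur),
        ci_tau_1=ci_t1, ci_tau_2=ci_t2,
        ci_A2=(100 * ci_a2[0], 100 * ci_a2[1]) if ci_a2 else None,
    )


def fit_association(
    dark_survival: SurvivalCurve,
    concentration: float,
    frame_interval: float | None = None,
) -> tuple[float, float, float]:
    """Mono-exponential fit of dark times → (k_on, tau_dark, R²).

    k_on = 1 / (τ_dark · concentration), concentration in M.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    dur = dark_survival.durations
    dt = frame_interval or _infer_dt(dur)
    curve = SurvivalCurve.from_durations(dur)
    t, S = _survival_grid(curve, dt)

    def resid(p):
        return np.exp(-t / np.exp(p[0])) - S

    sol = least_squares(resid, np.array([np.log(np.mean(dur))]), method="lm")
    tau_dark = float(np.exp(sol.x[0]))
    model = np.exp(-t / tau_dark)
    ss_res = float(np.sum((S - model) ** 2))
    ss_tot = float(np.sum((S - S.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < 0.9:
        warnings.warn(f"poor mono-exponential dark-time fit (R² = {r2:.3f})",
                      RuntimeWarning)
    return 1.0 / (tau_dark * concentration), tau_dark, r2


# ----------------------------------------------------------------------
# intensity / oligomer analysis


def infer_dimer_fraction(observed_two_dye_fraction: float,
                         label_efficiency: float) -> float:
    """Invert the binomial labeling model.

    Among visible bound species, with dimer fraction f and labeling
    probability p, the fraction of observations showing two dyes is
    f·p / (1 + f·(1 − p)); solving for f gives
    f = f2 / (p − f2·(1 − p)).
    """
    p, f2 = label_efficiency, observed_two_dye_fraction
    denom = p - f2 * (1.0 - p)
    if denom <= 0:
        raise ValueError("observed two-dye fraction incompatible with "
                         "the labeling efficiency")
    return f2 / denom


def intensity_oligomers(
    event_lists: list[EventList],
    label_efficiency: float,
    seed: int = 0,
):
    """Quantify 1-dye vs 2-dye observations and infer the dimer fraction.

    Fits a two-Gaussian mixture to the normalized per-event intensity
    levels at nominal levels 1× and 2×; reports the observed 2-dye
    fraction and the dimer fraction inferred via the binomial labeling
    model (see :func:`infer_dimer_fraction`).
    """
    if not 0 < label_efficiency <= 1:
        raise ValueError("label efficiency must be in (0, 1]")
    levels = np.concatenate([e.bright_levels for e in event_lists])
    levels = levels[np.isfinite(levels) & (levels > 0)]
    if len(levels) < 20:
        raise ValueError("too few events for intensity analysis")
    # normalize so the dominant (monomer) level sits at 1
    unit = float(np.median(levels))
    x = (levels / unit).reshape(-1, 1)

    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=2, random_state=seed,
        means_init=[[1.0], [2.0]], reg_covar=1e-4,
    ).fit(x)
    means = gm.means_.ravel()
    order = np.argsort(means)
    means = means[order]
    weights = gm.weights_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])

    # a level is real only if it actually captures events: EM collapses
    # an empty component to negligible weight at an arbitrary location
    resolved = (weights.min() >= 0.02
                and means[1] - means[0] > sds.mean()
                and means[1] - means[0] > 0.3)
    # count observations above the midpoint of the two levels (the
    # mixture weight is unreliable when components overlap)
    midpoint = 0.5 * (means[0] + means[1]) if resolved else 1.5
    frac2 = float(np.mean(x.ravel() > midpoint))
    out = {
        "level_means": means,
        "level_weights": weights,
        "two_dye_fraction_observed": frac2,
        "resolved": bool(resolved),
        "n_events": int(len(levels)),
    }
    if resolved:
        out["dimer_fraction_inferred"] = infer_dimer_fraction(
            float(weights[1]), label_efficiency)
    return out
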