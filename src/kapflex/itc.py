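"""One-set-of-sites ITC model, fitting and thermodynamics.

The forward model follows the standard instrument convention: each
injection of volume dV into a cell of volume V0 displaces an equal
volume of the pre-injection average composition, total concentrations
are updated, the bound concentration comes from the quadratic
one-set-of-sites equilibrium, and the injection heat is
ΔH·V0·Δ[bound] with the displaced-complex correction.

Thermodynamic bookkeeping uses ΔG = ΔH − TΔS = −RT ln Ka with
R = 1.98 cal mol⁻¹ K⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

R_CAL = 1.98  # cal / (mol K)


@dataclass
class TitrationExperiment:
    """Titration geometry, concentrations and (optionally) heats.

    Defaults mirror a typical 19-injection experiment: 2 μl per
    injection into a 300 μl cell, 15 μM macromolecule in the cell and
    170 μM titrant in the syringe at 25 °C. Heats are μcal per
    injection.
    """

    cell_volume_ul: float = 300.0
    injection_volume_ul: float = 2.0
    n_injections: int = 19
    cell_conc_M: float = 15e-6
    syringe_conc_M: float = 170e-6
    temperature_K: float = 298.15
    heats_ucal: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.cell_volume_ul, self.injection_volume_ul,
               self.cell_conc_M, self.syringe_conc_M) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if self.n_injections < 1:
            raise ValueError("need at least one injection")
        if self.heats_ucal is not None:
            self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
            if len(self.heats_ucal) != self.n_injections:
                raise ValueError("heats length must equal the injection count")

    def molar_ratios(self) -> np.ndarray:
        """Cumulative syringe/cell molar ratio after each injection."""
        _, ratios = _titration_state(self)
        return ratios


@dataclass
class BindingFit:
    N: float
    Kd_M: float
    dH_cal_mol: float
    dG_cal_mol: float
    dS_cal_mol_K: float
    baseline_slope: float
    baseline_offset: float
    chi2: float
    warning: str | None = None


def _titration_state(exp: TitrationExperiment):
    """Per-injection total concentrations (M, X) and molar ratios."""
    V0 = exp.cell_volume_ul
    dV = exp.injection_volume_ul
    dil = V0 / (V0 + dV)
    M = exp.cell_conc_M
    X = 0.0
    rows = []
    ratios = []
    for _ in range(exp.n_injections):
        M = M * dil
        X = (X * V0 + exp.syringe_conc_M * dV) / (V0 + dV)
        rows.append((M, X))
        ratios.append(X / M)
    return np.asarray(rows), np.asarray(ratios)


def _bound(M: np.ndarray, X: np.ndarray, N: float, Kd: float) -> np.ndarray:
    """Bound titrant concentration from the quadratic equilibrium."""
    s = X + N * M + Kd
    disc = np.maximum(s**2 - 4.0 * N * M * X, 0.0)
    return 0.5 * (s - np.sqrt(disc))


def one_set_of_sites_heat(
    experiment: TitrationExperiment, N: float, Kd: float, dH: float
) -> np.ndarray:
    """Per-injection heats (μcal) of the one-set-of-sites model.

    ``dH`` in cal/mol. The i-th heat is ΔH·V0·(b_i − b_{i−1}·V0/(V0+dV)):
    the complex present before the injection is first diluted by the
    displaced volume, then re-equilibrated.
    """
    if N <= 0 or Kd <= 0:
        raise ValueError("N and Kd must be positive")
    conc, _ = _titration_state(experiment)
    b = _bound(conc[:, 0], conc[:, 1], N, Kd)
    V0_l = experiment.cell_volume_ul * 1e-6
    dil = experiment.cell_volume_ul / (
        experiment.cell_volume_ul + experiment.injection_volume_ul)
    b_prev = np.concatenate([[0.0], b[:-1]])
    q_cal = dH * V0_l * (b - b_prev * dil)
    return q_cal * 1e6  # μcal


def thermodynamics(Kd: float, dH: float, T: float = 298.15) -> tuple[float, float]:
    """(ΔG, ΔS) from Kd and ΔH; ΔG = −RT ln(1/Kd), ΔS = (ΔH − ΔG)/T.

    All energies in cal/mol, ΔS in cal/(mol·K).
    """
    if Kd <= 0 or T <= 0:
        raise ValueError("Kd and T must be positive")
    dG = -R_CAL * T * np.log(1.0 / Kd)
    dS = (dH - dG) / T
    return float(dG), float(dS)


def fit_itc(
    experiment: TitrationExperiment,
    subtract_baseline: bool = True,
    n_baseline: int = 3,
    discard_first: bool = False,
) -> BindingFit:
    """Fit the one-set-of-sites model to measured injection heats.

    A straight-line heat-of-dilution baseline, initialized by least
    squares through the last ``n_baseline`` injections, is refined
    together with (N, Kd, ΔH) in the nonlinear fit (keeping it fixed at
    the tail estimate would fold residual post-saturation binding heat
    into the baseline and bias Kd); ΔG and ΔS follow from the
    thermodynamic identity. ``subtract_baseline=False`` pins the
    baseline at zero for dilution-free synthetic data.
    """
    if experiment.heats_ucal is None:
        raise ValueError("experiment has no heats to fit")
    heats = experiment.heats_ucal.copy()
    idx = np.arange(len(heats), dtype=float)
    if subtract_baseline:
        tail = slice(len(heats) - n_baseline, len(heats))
        slope0, offset0 = np.polyfit(idx[tail], heats[tail], 1)
    else:
        slope0, offset0 = 0.0, 0.0

    use = np.ones(len(heats), dtype=bool)
    if discard_first:
        use[0] = False
    if use.sum() < 8:
        raise ValueError("need at least 8 informative injections")

    _, ratios = _titration_state(experiment)
    if np.any(np.diff(ratios) <= 0):
        raise ValueError("non-monotone cumulative molar ratio")

    scale = np.abs(heats[use]).max() or 1.0
    V0_l = experiment.cell_volume_ul * 1e-6
    dh0 = heats[0] * 1e-6 / (V0_l * experiment.syringe_conc_M *
                             experiment.injection_volume_ul /
                             experiment.cell_volume_ul)
    params = lmfit.Parameters()
    params.add("N", value=1.0, min=0.05, max=5.0)
    params.add("logKd", value=np.log10(experiment.cell_conc_M / 10), min=-13, max=-2)
    params.add("dH", value=dh0 if dh0 != 0 else -1e4)
    params.add("bl_slope", value=slope0, vary=subtract_baseline)
    params.add("bl_offset", value=offset0, vary=subtract_baseline)

    def residual(p):
        model = one_set_of_sites_heat(
            experiment, p["N"].value, 10.0 ** p["logKd"].value, p["dH"].value)
        model = model + p["bl_slope"].value * idx + p["bl_offset"].value
        return (model[use] - heats[use]) / scale

    out = lmfit.minimize(residual, params, method="leastsq")
    N = float(out.params["N"].value)
    Kd = float(10.0 ** out.params["logKd"].value)
    dH = float(out.params["dH"].value)
    slope = float(out.params["bl_slope"].value)
    offset = float(out.params["bl_offset"].value)
    dG, dS = thermodynamics(Kd, dH, experiment.temperature_K)
    chi2 = float(np.sum(out.residual**2))

    warning = None
    c_value = N * experiment.cell_conc_M / Kd
    # flat isotherm: no saturation transition in the data itself
    span = np.abs(heats).max()
    drop = (np.abs(heats[:3].mean()) - np.abs(heats[-3:].mean())) / span \
        if span > 0 else 0.0
    if c_value < 1.0 or drop < 0.3:
        warning = (f"flat isotherm (c = {c_value:.2g}, transition drop "
                   f"{drop:.2f}): parameters poorly determined")
        warnings.warn(warning, RuntimeWarning)
    return BindingFit(N=N, Kd_M=Kd, dH_cal_mol=dH, dG_cal_mol=dG,
                      dS_cal_mol_K=dS, baseline_slope=float(slope),
                      baseline_offset=float(offset), chi2=chi2, warning=warning)


# ----------------------------------------------------------------------
# CSV isotherm IO


def write_isotherm_csv(experiment: TitrationExperiment, path) -> None:
    import pandas as pd

    ratios = experiment.molar_ratios()
    pd.DataFrame({
        "injection": np.arange(1, experiment.n_injections + 1),
        "cumulative_molar_ratio": ratios,
        "heat_ucal": experiment.heats_ucal,
    }).to_csv(path, index=False)


def read_isotherm_heats(path) -> np.ndarray:
    """Read per-injection heats from a CSV isotherm; the cumulative molar
    ratio column must be strictly increasing (rows in injection order)."""
    import pandas as pd

    tbl = pd.read_csv(path)
    if "cumulative_molar_ratio" in tbl.columns:
        r = tbl["cumulative_molar_ratio"].to_numpy()
        if np.any(np.diff(r) <= 0):
            raise ValueError("non-monotone cumulative molar ratio: "
                             "injections out of order")
    return tbl["heat_ucal"].to_numpy(dtype=float)
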