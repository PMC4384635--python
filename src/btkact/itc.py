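"""One-site isothermal titration calorimetry: forward model, fit, identities.

The forward model is the standard single-class-of-sites isotherm for a
fixed-volume (overflow) calorimeter cell.  After each injection the cell
macromolecule and accumulated ligand are diluted by (1 - v/V0), the injected
ligand is added, the binding equilibrium

    b = amount of bound ligand, with N*Mt sites:  b*(Kd + X - b ...) ...
    b = (S + X + Kd - sqrt((S + X + Kd)^2 - 4*S*X)) / 2,  S = N*Mt

is re-solved exactly (numerically stable quadratic root), and the measured
heat is dH times the change in moles bound within the active volume.  Heats
are normalized per mole of injectant, the form in which integrated ITC data
are reported and fit.

Fitting minimizes squared deviations of simulated from observed normalized
heats over (N, Ka, dH), with multi-start initialization over the association
constant; standard errors come from the local curvature at the optimum.
The binding entropy follows from dS = (dH + R*T*ln Ka)/T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

__all__ = [
    "BindingParameters",
    "ITCExperiment",
    "Isotherm",
    "FitResult",
    "NoBindingError",
    "simulate_isotherm",
    "fit_one_site",
    "entropy_from_thermo",
    "kd_from_ka",
]

R_KCAL = 1.9872e-3  # gas constant, kcal / (mol K)


@dataclass(frozen=True)
class BindingParameters:
    """One-site binding model parameters.

    N: sites per macromolecule; Ka: association constant (M^-1);
    dH: binding enthalpy (kcal/mol); T: temperature (K), default 20 C.
    """

    N: float
    Ka: float
    dH: float
    T: float = 293.15

    def __post_init__(self) -> None:
        if not (self.N > 0):
            raise ValueError(f"stoichiometry N must be positive, got {self.N!r}")
        if not (self.Ka > 0):
            raise ValueError(f"association constant Ka must be positive, got {self.Ka!r}")
        if not (self.T > 0):
            raise ValueError(f"temperature T must be positive, got {self.T!r}")

    @property
    def Kd_nM(self) -> float:
        return kd_from_ka(self.Ka)

    @property
    def dS(self) -> float:
        return entropy_from_thermo(self.dH, self.Ka, self.T)


@dataclass(frozen=True)
class ITCExperiment:
    """Injection schedule and cell contents.

    Defaults mirror the titrations behind the binding table: 20 uM
    macromolecule in the cell, 300 uM ligand in the syringe, an initial
    0.5 ul injection (simulated but excluded from analysis) followed by
    14 x 3 ul injections spaced 180 s apart at 20 C.  The active cell
    volume is the instrument's sensed volume, 200 ul.
    """

    cell_volume: float = 200e-6            # liters
    cell_conc: float = 20e-6               # molar
    syringe_conc: float = 300e-6           # molar
    injections: tuple[float, ...] = (0.5e-6,) + (3e-6,) * 14  # liters
    spacing: float = 180.0                 # seconds
    discard_first: bool = True

    def __post_init__(self) -> None:
        if not (self.cell_volume > 0 and self.cell_conc > 0 and self.syringe_conc > 0):
            raise ValueError("cell volume and concentrations must be positive")
        if len(self.injections) == 0 or any(v <= 0 for v in self.injections):
            raise ValueError("injection volumes must be positive")


@dataclass(frozen=True)
class Isotherm:
    """Per-injection molar ratios and normalized heats.

    molar_ratio: total ligand / total macromolecule in the cell after each
    injection; heat: kcal per mole of injectant; usable: mask excluding the
    discarded pre-injection.  ``details`` carries the per-injection cell
    state from the forward model (empty for measured data).
    """

    molar_ratio: np.ndarray
    heat: np.ndarray
    usable: np.ndarray
    experiment: ITCExperiment
    details: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar ratios must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection_index": np.arange(1, len(self.heat) + 1),
                "volume_ul": np.asarray(self.experiment.injections) * 1e6,
                "molar_ratio": self.molar_ratio,
                "heat_kcal_per_mol": self.heat,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _bound_conc(sites: float, ligand: float, kd: float) -> float:
    """Bound-ligand concentration from the one-site quadratic, stable root."""
    b = sites + ligand + kd
    c = sites * ligand
    disc = b * b - 4.0 * c
    if disc < 0.0:  # guard tiny negative from cancellation
        disc = 0.0
    return 2.0 * c / (b + math.sqrt(disc))


def simulate_isotherm(params: BindingParameters, exp: ITCExperiment | None = None) -> Isotherm:
    """Forward-model the per-injection heats for a one-site titration.

    Each injection of volume v displaces an equal volume of cell contents
    (fixed-volume cell): totals are diluted by (1 - v/V0) before the
    injected ligand v*Xs/V0 is added.  The reported heat is
    dH * V0 * (b_i - b_{i-1}*(1 - v/V0)), i.e. the enthalpy of the newly
    formed complex in the sensed volume, normalized per mole of injectant.
    """
    if exp is None:
        exp = ITCExperiment()
    v0 = exp.cell_volume
    kd = 1.0 / params.Ka
    mt = exp.cell_conc   # total macromolecule in cell, molar
    xt = 0.0             # total ligand in cell, molar
    b_prev = 0.0

    rows = []
    for v in exp.injections:
        dil = 1.0 - v / v0
        mt *= dil
        xt = xt * dil + exp.syringe_conc * (v / v0)
        b = _bound_conc(params.N * mt, xt, kd)
        q = params.dH * v0 * (b - b_prev * dil)           # kcal
        ndh = q / (v * exp.syringe_conc)                  # kcal / mol injectant
        rows.append((v, mt, xt, b, q, ndh))
        b_prev = b

    details = pd.DataFrame(
        rows, columns=["volume_L", "Mt_M", "Xt_M", "bound_M", "q_kcal", "ndh_kcal_per_mol"]
    )
    usable = np.ones(len(rows), dtype=bool)
    if exp.discard_first:
        usable[0] = False
    return Isotherm(
        molar_ratio=(details["Xt_M"] / details["Mt_M"]).to_numpy(),
        heat=details["ndh_kcal_per_mol"].to_numpy(),
        usable=usable,
        experiment=exp,
        details=details,
    )


class NoBindingError(Exception):
    """The isotherm carries no detectable binding signal."""


@dataclass(frozen=True)
class FitResult:
    """One-site fit with curvature standard errors and derived quantities."""

    params: BindingParameters
    stderr: dict = field(default_factory=dict)   # per-parameter, same units
    dS: float = float("nan")                     # cal / (mol K)
    Kd_nM: float = float("nan")
    residual_norm: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "N": self.params.N,
            "Ka_per_M": self.params.Ka,
            "dH_kcal_per_mol": self.params.dH,
            "T_K": self.params.T,
            "stderr": dict(self.stderr),
            "dS_cal_per_mol_K": self.dS,
            "Kd_nM": self.Kd_nM,
            "residual_norm": self.residual_norm,
        }


def _residuals(p, iso: Isotherm, T: float) -> np.ndarray:
    model = simulate_isotherm(
        BindingParameters(N=p["N"].value, Ka=10.0 ** p["log10Ka"].value, dH=p["dH"].value, T=T),
        iso.experiment,
    )
    return model.heat[iso.usable] - iso.heat[iso.usable]


def fit_one_site(
    iso: Isotherm,
    init: BindingParameters | None = None,
    flat_tol: float = 1e-3,
) -> FitResult:
    """Least-squares fit of (N, Ka, dH) to an isotherm's normalized heats.

    Parameters
    ----------
    iso
        Observed (or synthetic) isotherm; only injections flagged usable
        enter the objective.
    init
        Optional starting parameters.  By default N starts at the molar
        ratio where the cumulative heat reaches half its total, dH at the
        first usable heat, and the association constant is multi-started
        over 1e5..1e9 M^-1 with the best run kept.
    flat_tol
        Heat range (kcal/mol) below which the isotherm is declared flat and
        a :class:`NoBindingError` is raised — the no-binding outcome seen
        when a mutation abolishes the interaction.
    """
    heats = iso.heat[iso.usable]
    ratios = iso.molar_ratio[iso.usable]
    if len(heats) < 5:
        raise ValueError(f"need >= 5 usable injections, got {len(heats)}")
    if max(np.ptp(heats), np.max(np.abs(heats))) < flat_tol:
        raise NoBindingError(
            f"heat range {np.ptp(heats):.2e} kcal/mol below detection ({flat_tol:g})"
        )
    T = init.T if init is not None else 293.15

    # data-driven starting guesses
    cum = np.cumsum(heats)
    i_half = int(np.searchsorted(np.abs(cum), 0.5 * abs(cum[-1])))
    n0 = float(np.clip(ratios[min(i_half, len(ratios) - 1)], 0.1, 5.0))
    dh0 = float(heats[0])
    if init is not None:
        starts = [(init.N, math.log10(init.Ka), init.dH)]
    else:
        starts = [(n0, lka, dh0) for lka in (5.0, 6.0, 7.0, 8.0, 9.0)]

    best = None
    for n_s, lka_s, dh_s in starts:
        p = Parameters()
        p.add("N", value=n_s, min=1e-3)
        p.add("log10Ka", value=lka_s, min=0.0, max=15.0)
        p.add("dH", value=dh_s)
        try:
            res = minimize(_residuals, p, args=(iso, T), method="leastsq")
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise RuntimeError("one-site fit did not converge from any start")

    n_fit = best.params["N"].value
    lka_fit = best.params["log10Ka"].value
    ka_fit = 10.0 ** lka_fit
    dh_fit = best.params["dH"].value
    stderr = {}
    if best.params["N"].stderr is not None:
        stderr["N"] = best.params["N"].stderr
        stderr["dH"] = best.params["dH"].stderr
        # delta method: se(Ka) = ln(10) * Ka * se(log10 Ka)
        stderr["Ka"] = math.log(10.0) * ka_fit * best.params["log10Ka"].stderr
    fitted = BindingParameters(N=n_fit, Ka=ka_fit, dH=dh_fit, T=T)
    return FitResult(
        params=fitted,
        stderr=stderr,
        dS=fitted.dS,
        Kd_nM=fitted.Kd_nM,
        residual_norm=float(np.sqrt(best.chisqr)),
    )


def entropy_from_thermo(dH: float, Ka: float, T: float) -> float:
    """Binding entropy dS = (dH + R*T*ln Ka) / T, in cal/(mol K).

    dH in kcal/mol, Ka in M^-1, T in kelvin; R = 1.9872e-3 kcal/(mol K).
    """
    if not (Ka > 0):
        raise ValueError(f"Ka must be positive, got {Ka!r}")
    if not (T > 0):
        raise ValueError(f"T must be positive, got {T!r}")
    return (dH + R_KCAL * T * math.log(Ka)) / T * 1000.0


def kd_from_ka(Ka: float) -> float:
    """Dissociation constant in nanomolar from Ka in M^-1: 1e9 / Ka."""
    if not (Ka > 0):
        raise ValueError(f"Ka must be positive, got {Ka!r}")
    return 1e9 / Ka
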