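"""Autocatalytic trans-autophosphorylation kinetics of Btk.

The model is a four-reaction mass-action scheme in which two Btk molecules
form a transient encounter complex, one partner phosphorylates the other on
the activation loop, and the phosphorylated product is a markedly better
kinase than the unphosphorylated one — the source of autocatalysis::

    (1)  Btk  + Btk  <=[k1, k-1]=>  Btk.Btk
    (2)  Btk.Btk     --[k2]-->      pBtk + Btk
    (3)  pBtk + Btk  <=[k3, k-3]=>  pBtk.Btk
    (4)  pBtk.Btk    --[k4]-->      pBtk + pBtk

Soluble IP6, by occupying the peripheral site on the PH-TH module, raises the
dimerization on-rates k1 and k3 about 10-fold; everything else is unchanged.
With the default rates the dimer dissociation constant k-1/k1 is 2 mM without
IP6 and 200 uM with IP6, far above the ~1 uM protein concentrations used in
solution assays, so the dimer is always a trace species and activation
kinetics are limited by encounter-complex formation.

The scheme contains no phosphatase, so the phosphorylated fraction
(pBtk + pBtk.Btk, counted in monomer units) is non-decreasing and tends to 1.

State variables (all molar): M = Btk monomer, P = pBtk monomer,
MM = Btk.Btk complex, PM = pBtk.Btk complex.  Monomer units are conserved:
M + P + 2*MM + 2*PM = total0 at all times.

Deterministic integration uses an adaptive stiff solver on a uM/seconds
scaling; an exact stochastic (Gillespie) simulator of the same scheme in a
small virtual volume is provided as an independent small-instance oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "RateParameters",
    "ProgressCurve",
    "TimeToHalfNotReached",
    "make_rate_parameters",
    "simulate_progress",
    "ssa_progress",
    "phospho_fraction",
    "time_to_half",
    "dimer_kd",
    "equilibrium_dimer_fraction",
]

#: Default rate constants per scenario.  On-rates in M^-1 s^-1, others s^-1.
SCENARIO_DEFAULTS = {
    "no_IP6": dict(k1=1e4, k_minus1=20.0, k2=0.1, k3=1e4, k_minus3=20.0, k4=1.0),
    "with_IP6": dict(k1=1e5, k_minus1=20.0, k2=0.1, k3=1e5, k_minus3=20.0, k4=1.0),
}

_RATE_NAMES = ("k1", "k_minus1", "k2", "k3", "k_minus3", "k4")


@dataclass(frozen=True)
class RateParameters:
    """Rate constants of the four-reaction scheme.

    k1, k3 are bimolecular association rates (M^-1 s^-1); k_minus1, k_minus3
    dissociation rates (s^-1); k2, k4 catalytic rates (s^-1) of the
    unphosphorylated and phosphorylated encounter complexes respectively.
    """

    k1: float
    k_minus1: float
    k2: float
    k3: float
    k_minus3: float
    k4: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in _RATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"rate {name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"rate {name} must be non-negative, got {v!r}")


def make_rate_parameters(scenario: str, **overrides: float) -> RateParameters:
    """Build :class:`RateParameters` for a named scenario.

    Parameters
    ----------
    scenario
        ``"no_IP6"`` (k1 = k3 = 1e4 M^-1 s^-1) or ``"with_IP6"``
        (k1 = k3 = 1e5 M^-1 s^-1, the 10-fold on-rate enhancement by
        saturating IP6).  Both share k-1 = k-3 = 20 s^-1, k2 = 0.1 s^-1,
        k4 = 1.0 s^-1.
    **overrides
        Individual rate constants replacing the scenario defaults.
    """
    if scenario not in SCENARIO_DEFAULTS:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIO_DEFAULTS)}"
        )
    rates = dict(SCENARIO_DEFAULTS[scenario])
    for name, v in overrides.items():
        if name not in rates:
            raise ValueError(f"unknown rate {name!r}")
        if v < 0:
            raise ValueError(f"override {name} must be non-negative, got {v!r}")
        rates[name] = float(v)
    return RateParameters(label=scenario, **rates)


@dataclass(frozen=True)
class ProgressCurve:
    """Time course of the four species (molar) on a fixed time grid."""

    t: np.ndarray          # seconds
    M: np.ndarray          # molar
    P: np.ndarray
    MM: np.ndarray
    PM: np.ndarray
    total0: float          # initial total monomer units, molar
    params: RateParameters

    def conservation_error(self) -> np.ndarray:
        """Relative deviation of M + P + 2*MM + 2*PM from total0."""
        total = self.M + self.P + 2.0 * self.MM + 2.0 * self.PM
        return (total - self.total0) / self.total0

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as CSV-ready columns (concentrations in uM)."""
        return pd.DataFrame(
            {
                "time_s": self.t,
                "M_uM": self.M * 1e6,
                "P_uM": self.P * 1e6,
                "MM_uM": self.MM * 1e6,
                "PM_uM": self.PM * 1e6,
                "phospho_fraction": phospho_fraction(self),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rhs(t, y, k1, km1, k2, k3, km3, k4):
    # y in uM, rates pre-scaled to uM/s units
    M, P, MM, PM = y
    a1 = k1 * M * M - km1 * MM
    a3 = k3 * P * M - km3 * PM
    return [
        -2.0 * a1 + k2 * MM - a3,
        k2 * MM - a3 + 2.0 * k4 * PM,
        a1 - k2 * MM,
        a3 - k4 * PM,
    ]


def _jac(t, y, k1, km1, k2, k3, km3, k4):
    M, P, MM, PM = y
    return np.array(
        [
            [-4.0 * k1 * M - k3 * P, -k3 * M, 2.0 * km1 + k2, km3],
            [-k3 * P, -k3 * M, k2, km3 + 2.0 * k4],
            [2.0 * k1 * M, 0.0, -km1 - k2, 0.0],
            [k3 * P, k3 * M, 0.0, -km3 - k4],
        ]
    )


def simulate_progress(
    params: RateParameters,
    total0: float,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> ProgressCurve:
    """Integrate the mass-action ODEs from an all-unphosphorylated start.

    Parameters
    ----------
    params
        Rate constants (on-rates in M^-1 s^-1).
    total0
        Initial Btk monomer concentration in molar; the initial state is
        M = total0, P = MM = PM = 0.
    t_grid
        Increasing output times in seconds, starting at 0.
    rtol, atol
        Integrator tolerances; atol applies on the uM scale.

    Notes
    -----
    Integration is carried out in uM/seconds units (bimolecular rates scaled
    by 1e-6) with LSODA, which switches to a BDF method if the problem
    stiffens; species are returned in molar.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must be a 1-D sequence of at least 2 times")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if not (total0 > 0 and np.isfinite(total0)):
        raise ValueError(f"total0 must be positive and finite, got {total0!r}")

    total0_uM = total0 * 1e6
    args = (
        params.k1 * 1e-6,       # M^-1 s^-1 -> uM^-1 s^-1
        params.k_minus1,
        params.k2,
        params.k3 * 1e-6,
        params.k_minus3,
        params.k4,
    )
    sol = solve_ivp(
        _rhs,
        (0.0, float(t_grid[-1])),
        [total0_uM, 0.0, 0.0, 0.0],
        method="LSODA",
        t_eval=t_grid,
        jac=_jac,
        args=args,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    M, P, MM, PM = np.clip(sol.y, 0.0, None) * 1e-6
    return ProgressCurve(t=t_grid, M=M, P=P, MM=MM, PM=PM, total0=total0, params=params)


def phospho_fraction(curve: ProgressCurve) -> np.ndarray:
    """Fraction of monomer units carrying the activating phosphate.

    Counts free pBtk and the pBtk half of the pBtk.Btk complex:
    (P + PM) / total0, in [0, 1] and non-decreasing (the scheme has no
    dephosphorylation step).
    """
    if curve.total0 <= 0:
        raise ValueError("total0 must be positive")
    return (curve.P + curve.PM) / curve.total0


class TimeToHalfNotReached(Exception):
    """Raised when the phospho-fraction never attains 0.5 in the window."""


def time_to_half(curve: ProgressCurve) -> float:
    """Time (s) at which the phospho-fraction first crosses 0.5.

    Linear interpolation between the bracketing output times; raises
    :class:`TimeToHalfNotReached` if 0.5 is never attained.
    """
    f = phospho_fraction(curve)
    above = np.nonzero(f >= 0.5)[0]
    if len(above) == 0:
        raise TimeToHalfNotReached(
            f"phospho-fraction reached only {f.max():.4f} by t={curve.t[-1]:g} s"
        )
    i = above[0]
    if i == 0:
        return float(curve.t[0])
    t0, t1 = curve.t[i - 1], curve.t[i]
    f0, f1 = f[i - 1], f[i]
    return float(t0 + (0.5 - f0) / (f1 - f0) * (t1 - t0))


def dimer_kd(params: RateParameters) -> float:
    """Dissociation constant of the unphosphorylated encounter complex.

    Kd = k_minus1 / k1 in molar, with the forward flux convention k1*M^2
    (so at equilibrium M^2 / MM = k_minus1 / k1): 2 mM for the no-IP6
    defaults, 200 uM with IP6.
    """
    if params.k1 == 0:
        raise ValueError("k1 must be positive to define a dissociation constant")
    return params.k_minus1 / params.k1


def equilibrium_dimer_fraction(total0: float, kd: float) -> float:
    """Fraction of monomer units residing in dimers at equilibrium.

    For the monomer-dimer equilibrium M + 2D = total0, M^2/D = Kd the free
    monomer is M = (-Kd + sqrt(Kd^2 + 8 Kd total0)) / 4 and the returned
    fraction is 2D/total0 in [0, 1).
    """
    if not (total0 > 0):
        raise ValueError(f"total0 must be positive, got {total0!r}")
    if not (kd > 0):
        raise ValueError(f"kd must be positive, got {kd!r}")
    m = (-kd + np.sqrt(kd * kd + 8.0 * kd * total0)) / 4.0
    return float(1.0 - m / total0)


def ssa_progress(
    params: RateParameters,
    total0: float,
    t_grid: Sequence[float],
    volume_L: float = 1e-15,
    n_runs: int = 200,
    seed: int | np.random.Generator | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact stochastic (Gillespie) ensemble of the four-reaction scheme.

    Serves as a small-instance oracle for the deterministic integrator: in a
    femtoliter virtual volume 1 uM is ~600 molecules, small enough for exact
    simulation yet large enough that the ensemble mean tracks the mean-field
    ODE solution.

    The bimolecular propensities use the conventions matching the
    deterministic fluxes k1*[M]^2 and k3*[P][M]: homodimerization propensity
    c1*n_M*(n_M-1)/2 with c1 = 2*k1/(Na*V), heteroassociation c3*n_P*n_M
    with c3 = k3/(Na*V).

    Returns
    -------
    mean, sem
        Ensemble mean and standard error of the phospho-fraction sampled at
        ``t_grid``, each of shape ``(len(t_grid),)``.
    """
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    na_v = 6.02214076e23 * volume_L        # molecules per molar
    n0 = int(round(total0 * na_v))
    if n0 < 2:
        raise ValueError("fewer than 2 molecules in the virtual volume")

    c1 = 2.0 * params.k1 / na_v
    c3 = params.k3 / na_v
    km1, k2, km3, k4 = params.k_minus1, params.k2, params.k_minus3, params.k4

    log = math.log
    fractions = np.empty((n_runs, len(t_grid)))
    for r in range(n_runs):
        nM, nP, nMM, nPM = n0, 0, 0, 0
        t = 0.0
        out = np.empty(len(t_grid))
        i_out = 0
        # scalar Gillespie direct method; per-event numpy overhead avoided
        while i_out < len(t_grid):
            a1 = c1 * nM * (nM - 1) * 0.5   # (1) forward
            a2 = km1 * nMM                  # (1) reverse
            a3 = k2 * nMM                   # (2)
            a4 = c3 * nP * nM               # (3) forward
            a5 = km3 * nPM                  # (3) reverse
            a6 = k4 * nPM                   # (4)
            a0 = a1 + a2 + a3 + a4 + a5 + a6
            if a0 == 0.0:
                t_next = np.inf
            else:
                t_next = t - log(1.0 - rng.random()) / a0
            while i_out < len(t_grid) and t_grid[i_out] < t_next:
                out[i_out] = (nP + nPM) / n0
                i_out += 1
            if i_out >= len(t_grid):
                break
            t = t_next
            u = rng.random() * a0
            if u < a1:
                nM -= 2; nMM += 1
            elif u < a1 + a2:
                nM += 2; nMM -= 1
            elif u < a1 + a2 + a3:
                nM += 1; nP += 1; nMM -= 1
            elif u < a1 + a2 + a3 + a4:
                nP -= 1; nM -= 1; nPM += 1
            elif u < a1 + a2 + a3 + a4 + a5:
                nP += 1; nM += 1; nPM -= 1
            else:
                nP += 2; nPM -= 1
        fractions[r] = out

    mean = fractions.mean(axis=0)
    sem = fractions.std(axis=0, ddof=1) / np.sqrt(n_runs)
    return mean, sem
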