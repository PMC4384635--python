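"""Estimators for the coupled kinase assay and dose-response analyses.

Covers the four readouts used to quantify Btk activity in solution:

* initial rate v0 — ordinary least-squares slope of the coupled-assay signal
  over the first 150 s, reported per minute;
* activation slope — early-window slope of activity versus pre-incubation
  time, with a curvature flag because activation time courses are sigmoidal
  and the slope is only a rough measure;
* Michaelis-Menten (Km, Vmax) for the PLC-gamma2-derived substrate peptide
  (reported Km for phosphorylated full-length Btk: 925 +/- 117 uM);
* EC50 of ligand-induced activation, by a four-parameter logistic on
  log10 dose (the IP6 dose-response gives an EC50 around 20 uM).

All estimators are deterministic, seed-free functions of their input tables;
standard errors come from the local curvature of the objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LinearRate",
    "MMFit",
    "EC50Fit",
    "initial_rate",
    "activation_slope",
    "fit_michaelis_menten",
    "fit_ec50",
]


@dataclass(frozen=True)
class LinearRate:
    slope_per_min: float
    stderr_per_min: float
    intercept: float
    n_points: int
    nonlinearity_flag: bool = False


def initial_rate(time_s, signal, window: float = 150.0) -> LinearRate:
    """Initial rate by linear regression over the first ``window`` seconds.

    Fits signal = a + v*t (with intercept) to all points with t <= window
    and converts the slope to per-minute units.  Invariant to constant
    offsets in the signal.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(signal, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    mask = t <= window
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 points in [0, {window:g}] s, got {int(mask.sum())}")
    res = stats.linregress(t[mask], y[mask])
    return LinearRate(
        slope_per_min=res.slope * 60.0,
        stderr_per_min=res.stderr * 60.0,
        intercept=res.intercept,
        n_points=int(mask.sum()),
    )


def activation_slope(
    time_s, activity, window: float | None = None, alpha: float = 0.01
) -> LinearRate:
    """Rate of activation from activity vs pre-incubation time.

    Least-squares slope over points with t <= window (all points by
    default).  Activation time courses are sigmoidal, so the slope is only
    a rough comparative measure; the ``nonlinearity_flag`` is set when a
    quadratic term improves the fit significantly (partial F-test at
    ``alpha``).
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(activity, dtype=float)
    if window is not None:
        keep = t <= window
        t, y = t[keep], y[keep]
    if len(t) < 3:
        raise ValueError(f"need >= 3 points, got {len(t)}")
    res = stats.linregress(t, y)
    rss1 = float(np.sum((y - res.intercept - res.slope * t) ** 2))

    flag = False
    if len(t) >= 4:
        coef2 = np.polyfit(t, y, 2)
        rss2 = float(np.sum((y - np.polyval(coef2, t)) ** 2))
        if rss2 < rss1 and rss2 > 0:
            f = (rss1 - rss2) / (rss2 / (len(t) - 3))
            flag = stats.f.sf(f, 1, len(t) - 3) < alpha
        elif rss2 == 0.0 and rss1 > 0:
            flag = True
    return LinearRate(
        slope_per_min=res.slope * 60.0,
        stderr_per_min=(res.stderr if np.isfinite(res.stderr) else 0.0) * 60.0,
        intercept=res.intercept,
        n_points=len(t),
        nonlinearity_flag=flag,
    )


@dataclass(frozen=True)
class MMFit:
    Vmax: float
    Km: float            # same units as the substrate input
    Vmax_stderr: float
    Km_stderr: float


def fit_michaelis_menten(substrate, rate) -> MMFit:
    """Nonlinear least-squares fit of v = Vmax*S / (Km + S).

    Initialized from the Lineweaver-Burk linearization; requires substrate
    levels spanning enough of the hyperbola for Km to be identifiable
    (curvature check on the design).
    """
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(rate, dtype=float)
    if len(np.unique(s[s > 0])) < 4:
        raise ValueError("need >= 4 distinct positive substrate levels")
    # Lineweaver-Burk start (positive rates only), guarded
    pos = (s > 0) & (v > 0)
    if pos.sum() >= 2:
        b, a = np.polyfit(1.0 / s[pos], 1.0 / v[pos], 1)
        vmax0 = 1.0 / a if a > 0 else v.max()
        km0 = b * vmax0 if b * vmax0 > 0 else np.median(s[s > 0])
    else:
        vmax0, km0 = v.max(), np.median(s[s > 0])

    def mm(s_, vmax, km):
        return vmax * s_ / (km + s_)

    popt, pcov = optimize.curve_fit(
        mm, s, v, p0=[vmax0, km0], maxfev=10000,
        bounds=([0.0, 0.0], [np.inf, np.inf]),
    )
    perr = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(perr)) or perr[1] > 100 * popt[1]:
        raise RuntimeError(
            "Km is unidentifiable from this design (no curvature information)"
        )
    return MMFit(Vmax=popt[0], Km=popt[1], Vmax_stderr=perr[0], Km_stderr=perr[1])


@dataclass(frozen=True)
class EC50Fit:
    ec50: float          # molar
    hill: float
    floor: float
    ceiling: float
    ec50_stderr: float
    hill_stderr: float


def fit_ec50(dose, response) -> EC50Fit:
    """Four-parameter logistic fit on log10 dose.

    response = floor + (ceiling - floor) / (1 + 10^(hill*(log10 EC50 - log10 d))).
    Zero doses anchor the floor directly rather than being log-transformed.
    The EC50 estimate is invariant under affine transforms of the response.
    """
    d = np.asarray(dose, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    if len(np.unique(d)) < 5:
        raise ValueError("need >= 5 distinct doses, including near-zero and saturating")

    pos = d > 0
    logd = np.log10(d[pos])
    spearman = stats.spearmanr(d, y).statistic
    increasing = spearman >= 0
    if abs(spearman) < 0.5:
        warnings.warn("dose-response is not clearly monotone", stacklevel=2)

    lo0 = float(np.min(y)) if increasing else float(np.max(y))
    hi0 = float(np.max(y)) if increasing else float(np.min(y))
    if np.isclose(lo0, hi0):
        raise RuntimeError("flat response: plateau unidentifiable")
    # EC50 start: dose whose response is nearest the half-height
    half = 0.5 * (lo0 + hi0)
    ec50_0 = d[pos][np.argmin(np.abs(y[pos] - half))]

    def fpl(d_, log_ec50, hill, lo, hi):
        out = np.full_like(d_, lo, dtype=float)
        p = d_ > 0
        out[p] = lo + (hi - lo) / (1.0 + 10.0 ** (hill * (log_ec50 - np.log10(d_[p]))))
        return out

    p0 = [np.log10(ec50_0), 1.0 if increasing else 1.0, lo0, hi0]
    popt, pcov = optimize.curve_fit(
        fpl, d, y, p0=p0, maxfev=20000,
        bounds=([logd.min() - 3, 0.05, -np.inf, -np.inf],
                [logd.max() + 3, 20.0, np.inf, np.inf]),
    )
    perr = np.sqrt(np.diag(pcov))
    log_ec50, hill, lo, hi = popt
    if not np.isfinite(perr[3]) and not np.isclose(fpl(d.max(), *popt), hi, rtol=0.2):
        raise RuntimeError("upper plateau unidentifiable: extend the dose range")
    ec50 = 10.0 ** log_ec50
    return EC50Fit(
        ec50=ec50,
        hill=hill,
        floor=lo,
        ceiling=hi,
        ec50_stderr=np.log(10.0) * ec50 * perr[0],  # delta method from log10 scale
        hill_stderr=perr[1],
    )
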