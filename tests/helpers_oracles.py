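"""Independent brute-force oracles used only by the tests.

The fixed-step explicit-Euler integrator below re-derives the mass-action
right-hand side from the reaction scheme independently of the package's
adaptive solver, so agreement between the two is a genuine cross-check.
Units: uM and seconds (bimolecular rates must be passed in uM^-1 s^-1).
"""

import numba
import numpy as np


@numba.njit(cache=True)
def _euler_core(y0, rates, dt, t_out):
    k1, km1, k2, k3, km3, k4 = rates
    M, P, MM, PM = y0
    out = np.empty((len(t_out), 4))
    t = 0.0
    i = 0
    # assumes t_out[0] == 0 and t_out increasing
    while i < len(t_out):
        if t >= t_out[i] - dt * 0.5:
            out[i, 0] = M; out[i, 1] = P; out[i, 2] = MM; out[i, 3] = PM
            i += 1
            if i == len(t_out):
                break
        f1 = k1 * M * M - km1 * MM
        f3 = k3 * P * M - km3 * PM
        dM = -2.0 * f1 + k2 * MM - f3
        dP = k2 * MM - f3 + 2.0 * k4 * PM
        dMM = f1 - k2 * MM
        dPM = f3 - k4 * PM
        M += dt * dM
        P += dt * dP
        MM += dt * dMM
        PM += dt * dPM
        t += dt
    return out


def euler_trajectory(params, total0_M, t_out, dt=1e-3):
    """Explicit-Euler solution of the four-species scheme, species in molar.

    Returns an array of shape (len(t_out), 4) with columns M, P, MM, PM.
    """
    rates = np.array(
        [params.k1 * 1e-6, params.k_minus1, params.k2,
         params.k3 * 1e-6, params.k_minus3, params.k4]
    )
    y0 = np.array([total0_M * 1e6, 0.0, 0.0, 0.0])
    out = _euler_core(y0, rates, dt, np.asarray(t_out, dtype=float))
    return out * 1e-6
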