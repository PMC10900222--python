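"""Numba kernel for overdamped (Euler-Maruyama) torsion-angle dynamics.

The state is a single unwrapped dihedral angle in degrees.  The update is

    omega <- omega - beta * D * dV/domega * dt + sqrt(2 D dt) * eta

with eta a standard normal draw.  The potential is a sum of cosine terms
(V/2) * (1 + cos(n*omega - gamma)) plus an optional harmonic restraint
0.5 * k * d(omega, ref)^2 with a minimum-image angular difference.

The kernel is deterministic for a given seed (numba's own Mersenne-Twister
state, seeded inside the jitted function).  Samples are saved every
``save_stride`` steps; optional early stopping tests the wrapped angle
against a threshold at save resolution only, matching event detection at
sample resolution downstream.
"""

import numpy as np
from numba import njit

_DEG = np.pi / 180.0


@njit(cache=True, fastmath=True)
def em_run(
    omega0,
    n_save,
    save_stride,
    drift_coef,  # per-term: beta*D*dt*(V/2)*n*pi/180 (alpha already folded in)
    term_n,
    term_phase,
    restraint_coef,  # beta*D*dt*k_r
    restraint_ref,
    sigma,  # sqrt(2*D*dt)
    seed,
    reflect_hi,  # reflecting wall position, NaN disables
    reflect_lo,
    stop_ts,  # early-stop threshold on the wrapped angle
    stop_dir,  # +1: stop when wrapped < stop_ts; -1: stop when wrapped > stop_ts; 0: off
    out,
):
    np.random.seed(seed)
    om = omega0
    out[0] = om
    n_terms = drift_coef.shape[0]
    use_hi = not np.isnan(reflect_hi)
    use_lo = not np.isnan(reflect_lo)
    for j in range(n_save):
        eta = np.random.standard_normal(save_stride)
        for i in range(save_stride):
            drift = 0.0
            for t in range(n_terms):
                drift += drift_coef[t] * np.sin(_DEG * (term_n[t] * om - term_phase[t]))
            if restraint_coef != 0.0:
                d = om - restraint_ref
                d = (d + 180.0) % 360.0 - 180.0
                drift -= restraint_coef * d
            om = om + drift + sigma * eta[i]
            if use_hi and om > reflect_hi:
                om = 2.0 * reflect_hi - om
            if use_lo and om < reflect_lo:
                om = 2.0 * reflect_lo - om
        out[j + 1] = om
        if stop_dir != 0:
            w = ((om + 90.0) % 360.0) - 90.0
            if (stop_dir > 0 and w < stop_ts) or (stop_dir < 0 and w > stop_ts):
                return j + 1
    return n_save
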