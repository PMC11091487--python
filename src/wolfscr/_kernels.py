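"""Hot single-site sweep kernels for the Metropolis-within-Gibbs samplers.

All randomness is passed in as pre-drawn arrays so the numba-compiled and
pure-Python code paths produce bit-identical chains.  The functions mutate
their state arrays in place and return the updated global quantities they
track (running intensity totals).
"""

from __future__ import annotations

import numpy as np


def _softplus(x: float) -> float:
    if x > 30.0:
        return x
    return np.log1p(np.exp(x))


def _car_logit_sweep(
    eps, zbin, xb, indptr, indices, deg, sigma2, phi, soft_var, steps, nrand, urand, accept
):
    """Site-wise Metropolis update of a CAR random field under a
    Bernoulli-logit likelihood: z_i ~ Bern(expit(xb_i + eps_i)),
    eps ~ CAR(sigma2, phi) with a soft sum-to-zero constraint."""
    n = eps.shape[0]
    S = 0.0
    for i in range(n):
        S += eps[i]
    for i in range(n):
        e = eps[i]
        ep = e + steps[i] * nrand[i]
        d = deg[i]
        if d > 0:
            m = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                m += eps[indices[k]]
            m = phi * m / d
            q = d / sigma2
        else:
            m = 0.0
            q = 1.0 / sigma2
        dlp = -0.5 * q * ((ep - m) ** 2 - (e - m) ** 2)
        Sp = S - e + ep
        dlp += -0.5 * (Sp * Sp - S * S) / soft_var
        a = xb[i] + e
        ap = xb[i] + ep
        dlp += zbin[i] * (ap - a) - (_softplus(ap) - _softplus(a))
        if np.log(urand[i]) < dlp:
            eps[i] = ep
            S = Sp
            accept[i] = 1
        else:
            accept[i] = 0
    return S


def _zocc_sweep(z, psi, logL1, logL0, lam, counts, n_active, T, gate, urand):
    """Sequential Gibbs update of the latent occupancy states.

    With ``gate=1`` the activity-centre point process is renormalised over
    occupied cells, so flipping a cell changes the total intensity T and the
    update carries the factor (T0/T1)^n_active; cells holding an active
    activity centre are forced occupied."""
    n = z.shape[0]
    for i in range(n):
        if gate == 1 and counts[i] > 0:
            if z[i] == 0:
                T += lam[i]
                z[i] = 1
            continue
        lo = np.log(psi[i]) - np.log1p(-psi[i]) + logL1[i] - logL0[i]
        if gate == 1:
            T0 = T - lam[i] * z[i]
            if n_active > 0 and T0 <= 1e-300:
                znew = 1
            else:
                if n_active > 0:
                    lo += n_active * (np.log(T0) - np.log(T0 + lam[i]))
                znew = 1 if urand[i] < 1.0 / (1.0 + np.exp(-lo)) else 0
            T = T0 + lam[i] * znew
            z[i] = znew
        else:
            z[i] = 1 if urand[i] < 1.0 / (1.0 + np.exp(-lo)) else 0
    return T


def _dens_field_sweep(
    eps, logw, zocc, counts, n_active, T,
    indptr, indices, deg, sigma2, phi, soft_var, steps, nrand, urand, accept,
):
    """Site-wise Metropolis update of the CAR field in the log-density of
    activity centres.  lam_i = exp(logw_i + eps_i) on occupied cells; the
    likelihood is multinomial over the n_active current centre placements,
    hence counts_i * eps_i - n_active * log(T)."""
    n = eps.shape[0]
    S = 0.0
    for i in range(n):
        S += eps[i]
    for i in range(n):
        e = eps[i]
        ep = e + steps[i] * nrand[i]
        d = deg[i]
        if d > 0:
            m = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                m += eps[indices[k]]
            m = phi * m / d
            q = d / sigma2
        else:
            m = 0.0
            q = 1.0 / sigma2
        dlp = -0.5 * q * ((ep - m) ** 2 - (e - m) ** 2)
        Sp = S - e + ep
        dlp += -0.5 * (Sp * Sp - S * S) / soft_var
        dT = 0.0
        if zocc[i] == 1:
            lam_old = np.exp(logw[i] + e)
            lam_new = np.exp(logw[i] + ep)
            dT = lam_new - lam_old
            dlp += counts[i] * (ep - e)
            if n_active > 0:
                dlp += -n_active * (np.log(T + dT) - np.log(T))
        if np.log(urand[i]) < dlp:
            eps[i] = ep
            S = Sp
            T = T + dT
            accept[i] = 1
        else:
            accept[i] = 0
    return T


try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    _softplus = njit(cache=True)(_softplus)
    car_logit_sweep = njit(cache=True)(_car_logit_sweep)
    zocc_sweep = njit(cache=True)(_zocc_sweep)
    dens_field_sweep = njit(cache=True)(_dens_field_sweep)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    car_logit_sweep = _car_logit_sweep
    zocc_sweep = _zocc_sweep
    dens_field_sweep = _dens_field_sweep
    HAVE_NUMBA = False
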