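"""Independent brute-force reference implementations used as oracles.

Everything here is written from first principles (explicit loops,
scipy.stats pmfs, direct distance computations) and deliberately avoids the
package's internal caching/factorisation tricks, so that agreement with the
package is a meaningful check.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.special import expit
from scipy.stats import binom


# ---------------------------------------------------------------------------
# occupancy


def transect_event_prob(event, occupied, P1, P2, G, M):
    if occupied:
        row = [1 - P2, P2 * G * (1 - M), P2 * G * M, P2 * (1 - G)]
    else:
        row = [1 - P1, 0.0, P1 * G, P1 * (1 - G)]
    return row[event]


def camera_event_prob(event, occupied, P3):
    if occupied:
        return [1 - P3, P3][event]
    return [1.0, 0.0][event]


def occupancy_marginal_loglik(
    events, G, psi, P1, P2L, P2H, theta, M, cam_events=None, P3=None
):
    """Marginal over per-cell occupancy state and mixture class by full
    enumeration.  ``events`` is (n, T) with -1 for missing; scalar
    parameters apply to every cell-session."""
    n, T = events.shape
    total = 0.0
    for c in range(n):
        like = 0.0
        for z in (0, 1):
            for k in (0, 1):
                w = (psi if z else 1 - psi) * (theta if k else 1 - theta)
                p = 1.0
                for t in range(T):
                    ev = events[c, t]
                    if ev < 0:
                        continue
                    P2 = P2H if k else P2L
                    p *= transect_event_prob(int(ev), z, P1, P2, G[c], M)
                if cam_events is not None:
                    for t in range(T):
                        ev = cam_events[c, t]
                        if ev < 0:
                            continue
                        p *= camera_event_prob(int(ev), z, P3)
                like += w * p
        total += np.log(like)
    return total


def occupancy_conditional_lik(events, G, psi, P1, P2L, P2H, theta, M, z_occ):
    """Likelihood conditional on a full z_occ configuration (mixture
    summed out within occupied cells)."""
    n, T = events.shape
    total = 1.0
    for c in range(n):
        z = z_occ[c]
        state_w = psi if z else 1 - psi
        like = 0.0
        for k in (0, 1):
            w = theta if k else 1 - theta
            p = 1.0
            for t in range(T):
                ev = events[c, t]
                if ev < 0:
                    continue
                P2 = P2H if k else P2L
                p *= transect_event_prob(int(ev), z, P1, P2, G[c], M)
            like += w * p
        total *= state_w * like
    return total


# ---------------------------------------------------------------------------
# SCR


def standardize(x):
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def sub_mean_halfnormal(cell_xy, det_xy, sigma):
    """Average of exp(-d^2/2sigma^2) over the detector's 100 sub-detector
    points, from explicit 2-D distances."""
    offs = np.arange(10) - 4.5
    ox, oy = np.meshgrid(offs, offs)
    dx = cell_xy[0] - (det_xy[0] + ox.ravel())
    dy = cell_xy[1] - (det_xy[1] + oy.ravel())
    d2 = dx**2 + dy**2
    return float(np.mean(np.exp(-d2 / (2 * sigma**2))))


def scr_individual_marginal(y_row, comp_probs, comp_weights, cell_weights, K):
    """P(y_row) marginal over activity-centre cell and mixture component.

    comp_probs: (C, n_cells, n_det) detection probabilities.
    """
    C, n_cells, n_det = comp_probs.shape
    total = 0.0
    for k in range(C):
        for c in range(n_cells):
            p = comp_weights[k] * cell_weights[c]
            for d in range(n_det):
                p *= binom.pmf(y_row[d], K, comp_probs[k, c, d])
            total += p
    return total


def scr_marginal_loglik(
    y, M_aug, psi_aug, comp_probs, comp_weights, cell_weights, K
):
    """Marginal SCR likelihood over z, s and component for every individual
    (detected rows of y first, augmented all-zero rows implied)."""
    n_det_ind = y.shape[0]
    zero = np.zeros(y.shape[1], dtype=int)
    total = 0.0
    for i in range(n_det_ind):
        m = scr_individual_marginal(y[i], comp_probs, comp_weights, cell_weights, K)
        total += np.log(psi_aug * m)  # z=0 impossible for a detected history
    m0 = scr_individual_marginal(zero, comp_probs, comp_weights, cell_weights, K)
    total += (M_aug - n_det_ind) * np.log(psi_aug * m0 + (1 - psi_aug))
    return total


def integrated_marginal_loglik(
    events, G, psi, P1, P2L, P2H, theta, M,
    y, M_aug, psi_aug, comp_probs, comp_weights, lam, K,
):
    """Joint marginal over all 2^n occupancy configurations; the SCR
    activity-centre distribution is the gated, renormalised intensity."""
    n = events.shape[0]
    terms = []
    for z_occ in product((0, 1), repeat=n):
        z_occ = np.array(z_occ)
        occ_lik = occupancy_conditional_lik(
            events, G, psi, P1, P2L, P2H, theta, M, z_occ
        )
        lam_g = lam * z_occ
        if lam_g.sum() <= 0:
            continue
        w = lam_g / lam_g.sum()
        scr_ll = scr_marginal_loglik(y, M_aug, psi_aug, comp_probs, comp_weights, w, K)
        if occ_lik > 0:
            terms.append(np.log(occ_lik) + scr_ll)
    if not terms:
        return -np.inf
    terms = np.array(terms)
    m = terms.max()
    return float(m + np.log(np.exp(terms - m).sum()))
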