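"""Numba-compiled numerical kernels.

These are the hot paths of the pipeline: internal-to-Cartesian chain
building (NeRF), the repulsive prior energy, restraint evaluation and the
Metropolis inner loops of annealing and replica-exchange sampling.  All
kernels operate on plain arrays compiled by :class:`~incellfold.molecule.ChainTemplate`
and the restraint compiler in :mod:`~incellfold.cybay`.

Angle arguments are radians throughout; distances are Angstrom.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def nerf_build(ref_a, ref_b, ref_c, bond, angle, tor_base, tor_idx, torsions):
    """Sequential internal-to-Cartesian placement.

    Atom ``k`` is placed from its reference triple
    ``(A, B, C) = (ref_a[k], ref_b[k], ref_c[k])`` (indices of already
    placed atoms) at distance ``bond[k]`` from ``C``, with angle
    ``angle[k]`` at ``C`` to ``B``, and dihedral ``tor_base[k]`` (+ the
    named torsion value if ``tor_idx[k] >= 0``) about the ``B - C`` axis.
    The first three atoms (ref indices < 0) span the canonical frame:
    atom0 at the origin, atom1 on +x, atom2 in the xy-plane.
    """
    n = bond.shape[0]
    out = np.empty((n, 3))
    for k in range(n):
        if ref_c[k] < 0:
            if k == 0:
                out[0, 0] = 0.0
                out[0, 1] = 0.0
                out[0, 2] = 0.0
            elif k == 1:
                out[1, 0] = bond[1]
                out[1, 1] = 0.0
                out[1, 2] = 0.0
            else:
                # in xy-plane, +y side, at angle[2] from atom0 direction
                out[2, 0] = out[1, 0] - bond[2] * np.cos(angle[2])
                out[2, 1] = bond[2] * np.sin(angle[2])
                out[2, 2] = 0.0
            continue
        tau = tor_base[k]
        if tor_idx[k] >= 0:
            tau += torsions[tor_idx[k]]
        a = ref_a[k]
        b = ref_b[k]
        c = ref_c[k]
        # frame at C: bc = unit(C-B), n = unit(bc x ab-normal)
        b1x = out[b, 0] - out[a, 0]
        b1y = out[b, 1] - out[a, 1]
        b1z = out[b, 2] - out[a, 2]
        b2x = out[c, 0] - out[b, 0]
        b2y = out[c, 1] - out[b, 1]
        b2z = out[c, 2] - out[b, 2]
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        b2x /= nb2
        b2y /= nb2
        b2z /= nb2
        # n = b1 x b2, normalized
        nx = b1y * b2z - b1z * b2y
        ny = b1z * b2x - b1x * b2z
        nz = b1x * b2y - b1y * b2x
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx /= nn
        ny /= nn
        nz /= nn
        # m = n x b2
        mx = ny * b2z - nz * b2y
        my = nz * b2x - nx * b2z
        mz = nx * b2y - ny * b2x
        st = np.sin(angle[k])
        d2x = -bond[k] * np.cos(angle[k])
        d2y = bond[k] * st * np.cos(tau)
        d2z = bond[k] * st * np.sin(tau)
        out[k, 0] = out[c, 0] + d2x * b2x + d2y * mx + d2z * nx
        out[k, 1] = out[c, 1] + d2x * b2y + d2y * my + d2z * ny
        out[k, 2] = out[c, 2] + d2x * b2z + d2y * mz + d2z * nz
    return out


@njit(cache=True)
def repulsion_energy(coords, pair_i, pair_j, pair_rmin, k_rep):
    """k_rep * sum over pairs of max(0, rmin - r)^2."""
    e = 0.0
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = pair_rmin[p] - r
        if d > 0.0:
            e += d * d
    return k_rep * e


@njit(cache=True)
def torsion_energy(torsions, k_tor):
    """Threefold staggering potential k_tor * sum(1 + cos(3 theta))."""
    e = 0.0
    for t in range(torsions.shape[0]):
        e += 1.0 + np.cos(3.0 * torsions[t])
    return k_tor * e


@njit(cache=True)
def prior_energy_arrays(coords, torsions, pair_i, pair_j, pair_rmin,
                        k_rep, k_tor):
    return (repulsion_energy(coords, pair_i, pair_j, pair_rmin, k_rep)
            + torsion_energy(torsions, k_tor))


@njit(cache=True)
def effective_distances(coords, opt_i, opt_j, opt_start, opt_end):
    """r_eff = (sum over options r^-6)^(-1/6) for each restraint."""
    nr = opt_start.shape[0]
    out = np.empty(nr)
    for r in range(nr):
        s = 0.0
        for o in range(opt_start[r], opt_end[r]):
            i = opt_i[o]
            j = opt_j[o]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            s += 1.0 / (d2 * d2 * d2)
        out[r] = s ** (-1.0 / 6.0)
    return out


@njit(cache=True)
def distance_target(coords, opt_i, opt_j, opt_start, opt_end, lower, upper):
    """Sum of squared bound violations of effective distances (Angstrom^2)."""
    t = 0.0
    nr = opt_start.shape[0]
    for r in range(nr):
        s = 0.0
        for o in range(opt_start[r], opt_end[r]):
            i = opt_i[o]
            j = opt_j[o]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            s += 1.0 / (d2 * d2 * d2)
        reff = s ** (-1.0 / 6.0)
        if reff > upper[r]:
            t += (reff - upper[r]) ** 2
        elif reff < lower[r]:
            t += (lower[r] - reff) ** 2
    return t


@njit(cache=True)
def dihedral_target(torsions, dih_idx, dih_lo, dih_hi, weight):
    """Weighted squared violations of torsion interval restraints.

    Violations are measured as the shortest angular distance (radians wrap)
    to the allowed interval, in degrees, then squared and weighted to
    Angstrom^2 units.
    """
    t = 0.0
    for k in range(dih_idx.shape[0]):
        th = np.degrees(torsions[dih_idx[k]])
        lo = dih_lo[k]
        hi = dih_hi[k]
        if th < lo or th > hi:
            dlo = np.abs(th - lo)
            if dlo > 180.0:
                dlo = 360.0 - dlo
            dhi = np.abs(th - hi)
            if dhi > 180.0:
                dhi = 360.0 - dhi
            d = min(dlo, dhi)
            t += d * d
    return weight * t


@njit(cache=True)
def total_target(torsions, ref_a, ref_b, ref_c, bond, angle, tor_base,
                 tor_idx, opt_i, opt_j, opt_start, opt_end, lower, upper,
                 dih_idx, dih_lo, dih_hi, dih_weight):
    coords = nerf_build(ref_a, ref_b, ref_c, bond, angle, tor_base,
                        tor_idx, torsions)
    return (distance_target(coords, opt_i, opt_j, opt_start, opt_end,
                            lower, upper)
            + dihedral_target(torsions, dih_idx, dih_lo, dih_hi, dih_weight))


@njit(cache=True)
def _wrap_pi(x):
    while x <= -np.pi:
        x += TWO_PI
    while x > np.pi:
        x -= TWO_PI
    return x


@njit(cache=True)
def anneal_run(torsions0, ref_a, ref_b, ref_c, bond, angle, tor_base,
               tor_idx, opt_i, opt_j, opt_start, opt_end, lower, upper,
               dih_idx, dih_lo, dih_hi, dih_weight,
               pair_i, pair_j, pair_rmin, k_rep, k_tor, prior_weight,
               n_steps, t_start, t_end, w_start, w_end, seed):
    """Metropolis simulated annealing over torsion space.

    Energy = restraint target + prior_weight * prior energy; geometric
    temperature and move-width schedules; returns the best-so-far torsions
    and their restraint target value.
    """
    np.random.seed(seed)
    nt = torsions0.shape[0]
    cur = torsions0.copy()
    coords = nerf_build(ref_a, ref_b, ref_c, bond, angle, tor_base,
                        tor_idx, cur)
    cur_t = (distance_target(coords, opt_i, opt_j, opt_start, opt_end,
                             lower, upper)
             + dihedral_target(cur, dih_idx, dih_lo, dih_hi, dih_weight))
    cur_e = cur_t + prior_weight * prior_energy_arrays(
        coords, cur, pair_i, pair_j, pair_rmin, k_rep, k_tor)
    best = cur.copy()
    best_t = cur_t
    best_e = cur_e
    if n_steps > 1:
        t_fac = (t_end / t_start) ** (1.0 / (n_steps - 1))
        w_fac = (w_end / w_start) ** (1.0 / (n_steps - 1))
    else:
        t_fac = 1.0
        w_fac = 1.0
    temp = t_start
    width = w_start
    for step in range(n_steps):
        k = np.random.randint(0, nt)
        old = cur[k]
        cur[k] = _wrap_pi(old + np.random.normal() * width)
        coords = nerf_build(ref_a, ref_b, ref_c, bond, angle, tor_base,
                            tor_idx, cur)
        new_t = (distance_target(coords, opt_i, opt_j, opt_start, opt_end,
                                 lower, upper)
                 + dihedral_target(cur, dih_idx, dih_lo, dih_hi, dih_weight))
        new_e = new_t + prior_weight * prior_energy_arrays(
            coords, cur, pair_i, pair_j, pair_rmin, k_rep, k_tor)
        if new_e <= cur_e or np.random.random() < np.exp(-(new_e - cur_e) / temp):
            cur_e = new_e
            cur_t = new_t
            if new_e < best_e:
                best_e = new_e
                best_t = new_t
                best[:] = cur
        else:
            cur[k] = old
        temp *= t_fac
        width *= w_fac
    return best, best_t, best_e


@njit(cache=True)
def loglik_and_stats(coords, opt_i, opt_j, opt_start, opt_end, log_i,
                     spec_id, c_s, sigma_s):
    """Gaussian log-likelihood of log NOE intensities given the structure.

    For restraint k of spectrum s: ln I_k ~ N(c_s - 6 ln r_eff,k, sigma_s^2).
    Returns (loglik, per-spectrum n, per-spectrum sum(ln I + 6 ln r_eff),
    per-spectrum residual sum of squares).
    """
    ns = c_s.shape[0]
    n_k = np.zeros(ns)
    sum_obs = np.zeros(ns)
    ss = np.zeros(ns)
    reff = effective_distances(coords, opt_i, opt_j, opt_start, opt_end)
    loglik = 0.0
    for k in range(reff.shape[0]):
        s = spec_id[k]
        obs = log_i[k] + 6.0 * np.log(reff[k])
        resid = obs - c_s[s]
        n_k[s] += 1.0
        sum_obs[s] += obs
        ss[s] += resid * resid
        loglik += -resid * resid / (2.0 * sigma_s[s] ** 2) - np.log(sigma_s[s])
    return loglik, n_k, sum_obs, ss


@njit(cache=True)
def posterior_chain_segment(torsions, c_s, sigma_s, beta, n_steps, width,
                            ref_a, ref_b, ref_c, bond, angle, tor_base,
                            tor_idx, opt_i, opt_j, opt_start, opt_end,
                            log_i, spec_id, pair_i, pair_j, pair_rmin,
                            k_rep, k_tor, mu0, tau0, alpha0, beta0, seed):
    """Run ``n_steps`` single-torsion Metropolis updates at inverse scale beta.

    The target is the full log-posterior: log-likelihood of log intensities
    + normal prior on c_s + inverse-gamma prior on sigma_s^2 - prior energy.
    Nuisance parameters are fixed within the segment (Gibbs updates happen
    between segments).  Returns (torsions, log_posterior, accepted moves).
    """
    np.random.seed(seed)
    nt = torsions.shape[0]
    cur = torsions.copy()

    # nuisance prior terms (constant within the segment, but part of logpost)
    nuis = 0.0
    for s in range(c_s.shape[0]):
        nuis += -((c_s[s] - mu0) ** 2) / (2.0 * tau0 * tau0)
        sig2 = sigma_s[s] * sigma_s[s]
        nuis += -(alpha0 + 1.0) * np.log(sig2) - beta0 / sig2

    coords = nerf_build(ref_a, ref_b, ref_c, bond, angle, tor_base,
                        tor_idx, cur)
    ll, _, _, _ = loglik_and_stats(coords, opt_i, opt_j, opt_start, opt_end,
                                   log_i, spec_id, c_s, sigma_s)
    ep = prior_energy_arrays(coords, cur, pair_i, pair_j, pair_rmin,
                             k_rep, k_tor)
    cur_lp = ll - ep + nuis
    accepted = 0
    for step in range(n_steps):
        k = np.random.randint(0, nt)
        old = cur[k]
        cur[k] = _wrap_pi(old + np.random.normal() * width)
        coords = nerf_build(ref_a, ref_b, ref_c, bond, angle, tor_base,
                            tor_idx, cur)
        ll, _, _, _ = loglik_and_stats(coords, opt_i, opt_j, opt_start,
                                       opt_end, log_i, spec_id, c_s, sigma_s)
        ep = prior_energy_arrays(coords, cur, pair_i, pair_j, pair_rmin,
                                 k_rep, k_tor)
        new_lp = ll - ep + nuis
        if new_lp >= cur_lp or np.random.random() < np.exp(beta * (new_lp - cur_lp)):
            cur_lp = new_lp
            accepted += 1
        else:
            cur[k] = old
    return cur, cur_lp, accepted
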