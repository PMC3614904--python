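"""Numba-compiled hot loops: chain rebuilding, pairwise energy/forces and the
packer's subset energies. Functional forms mirror restrelax.energy exactly."""

from __future__ import annotations

import math

import numpy as np
from numba import njit

REP_LIN_FRACTION = 0.6
ATR_EPS = 0.2
ATR_CUTOFF = 6.0
ATR_SWITCH = 5.5
_F0 = REP_LIN_FRACTION ** -12 - 1.0
_S0 = 12.0 * REP_LIN_FRACTION ** -13


@njit(cache=True)
def place_program(prog_i: np.ndarray, prog_f: np.ndarray, torsions: np.ndarray,
                  root: np.ndarray, n_atoms: int) -> np.ndarray:
    """Execute the placement program: prog_i rows are (tgt, a3, a2, a1, tref),
    prog_f rows are (bond, angle_deg, offset_deg). tref < 0 means fixed."""
    X = np.empty((n_atoms, 3))
    X[0] = root[0]
    X[1] = root[1]
    X[2] = root[2]
    for r in range(prog_i.shape[0]):
        tgt, i3, i2, i1, tref = (prog_i[r, 0], prog_i[r, 1], prog_i[r, 2],
                                 prog_i[r, 3], prog_i[r, 4])
        bond, angle, off = prog_f[r, 0], prog_f[r, 1], prog_f[r, 2]
        tors = off if tref < 0 else torsions[tref] + off
        theta = math.radians(angle)
        phi = math.radians(tors)
        bcx = X[i1, 0] - X[i2, 0]
        bcy = X[i1, 1] - X[i2, 1]
        bcz = X[i1, 2] - X[i2, 2]
        nb = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx /= nb
        bcy /= nb
        bcz /= nb
        abx = X[i2, 0] - X[i3, 0]
        aby = X[i2, 1] - X[i3, 1]
        abz = X[i2, 2] - X[i3, 2]
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        nn = math.sqrt(nx * nx + ny * ny + nz * nz)
        nx /= nn
        ny /= nn
        nz /= nn
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        d0 = -bond * math.cos(theta)
        d1 = bond * math.sin(theta) * math.cos(phi)
        d2 = bond * math.sin(theta) * math.sin(phi)
        X[tgt, 0] = X[i1, 0] + d0 * bcx + d1 * mx + d2 * nx
        X[tgt, 1] = X[i1, 1] + d0 * bcy + d1 * my + d2 * ny
        X[tgt, 2] = X[i1, 2] + d0 * bcz + d1 * mz + d2 * nz
    return X


@njit(inline="always")
def _pair_e_dedr(d: float, sig: float, sig_rep: float, w_rep: float,
                 w_atr: float):
    """Fused rep+atr energy and d(E)/dd for one pair."""
    e = 0.0
    g = 0.0
    if w_rep > 0.0 and d < sig_rep:
        dlin = REP_LIN_FRACTION * sig_rep
        if d >= dlin:
            x = sig_rep / d
            x12 = x ** 12
            e += w_rep * (x12 - 1.0)
            g += w_rep * (-12.0 * x12 / d)
        else:
            e += w_rep * (_F0 + _S0 / sig_rep * (dlin - d))
            g += w_rep * (-_S0 / sig_rep)
    if w_atr > 0.0 and d < ATR_CUTOFF:
        if d >= sig:
            x6 = (sig / d) ** 6
            ea = ATR_EPS * (x6 * x6 - 2.0 * x6)
            ga = ATR_EPS * (-12.0 * x6 * x6 + 12.0 * x6) / d
        else:
            ea = -ATR_EPS
            ga = 0.0
        if d > ATR_SWITCH:
            t = (d - ATR_SWITCH) / (ATR_CUTOFF - ATR_SWITCH)
            s = 1.0 - t * t * (3.0 - 2.0 * t)
            ds = -6.0 * t * (1.0 - t) / (ATR_CUTOFF - ATR_SWITCH)
            ga = ga * s + ea * ds
            ea = ea * s
        e += w_atr * ea
        g += w_atr * ga
    return e, g


@njit(cache=True)
def pair_energy_forces(X: np.ndarray, pi: np.ndarray, pj: np.ndarray,
                       sigma: np.ndarray, soft: float, w_rep: float,
                       w_atr: float):
    """Total weighted rep+atr energy over the pair list and dE/dx."""
    F = np.zeros_like(X)
    e_tot = 0.0
    for k in range(pi.shape[0]):
        i, j = pi[k], pj[k]
        dx = X[i, 0] - X[j, 0]
        dy = X[i, 1] - X[j, 1]
        dz = X[i, 2] - X[j, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        sig = sigma[k]
        if d >= ATR_CUTOFF and d >= sig:
            continue
        e, g = _pair_e_dedr(d, sig, sig * soft, w_rep, w_atr)
        e_tot += e
        if g != 0.0 and d > 0.0:
            s = g / d
            F[i, 0] += s * dx
            F[i, 1] += s * dy
            F[i, 2] += s * dz
            F[j, 0] -= s * dx
            F[j, 1] -= s * dy
            F[j, 2] -= s * dz
    return e_tot, F


@njit(cache=True)
def pair_energy_by_residue(X: np.ndarray, pi: np.ndarray, pj: np.ndarray,
                           sigma: np.ndarray, res_of: np.ndarray, n_res: int,
                           soft: float):
    """Unweighted (E_rep, E_atr, rep_by_res, atr_by_res) over the pair list."""
    rep_res = np.zeros(n_res)
    atr_res = np.zeros(n_res)
    e_rep = 0.0
    e_atr = 0.0
    for k in range(pi.shape[0]):
        i, j = pi[k], pj[k]
        dx = X[i, 0] - X[j, 0]
        dy = X[i, 1] - X[j, 1]
        dz = X[i, 2] - X[j, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        sig = sigma[k]
        if d >= ATR_CUTOFF and d >= sig:
            continue
        er, _ = _pair_e_dedr(d, sig, sig * soft, 1.0, 0.0)
        ea, _ = _pair_e_dedr(d, sig, sig, 0.0, 1.0)
        e_rep += er
        e_atr += ea
        rep_res[res_of[i]] += 0.5 * er
        rep_res[res_of[j]] += 0.5 * er
        atr_res[res_of[i]] += 0.5 * ea
        atr_res[res_of[j]] += 0.5 * ea
    return e_rep, e_atr, rep_res, atr_res


@njit(cache=True)
def group_env_energy(G: np.ndarray, X: np.ndarray, incl: np.ndarray,
                     sigma: np.ndarray, soft: float, w_rep: float,
                     w_atr: float) -> float:
    """Energy of group atoms G (rows map to incl/sigma rows) against all
    environment atoms flagged in incl (m x N boolean)."""
    e_tot = 0.0
    for a in range(G.shape[0]):
        gx, gy, gz = G[a, 0], G[a, 1], G[a, 2]
        for b in range(X.shape[0]):
            if not incl[a, b]:
                continue
            dx = gx - X[b, 0]
            dy = gy - X[b, 1]
            dz = gz - X[b, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            sig = sigma[a, b]
            if d >= ATR_CUTOFF and d >= sig:
                continue
            e, _ = _pair_e_dedr(d, sig, sig * soft, w_rep, w_atr)
            e_tot += e
    return e_tot


@njit(cache=True)
def design_env_energy(G: np.ndarray, rad_g: np.ndarray, dN_g: np.ndarray,
                      dC_g: np.ndarray, X: np.ndarray, rad_e: np.ndarray,
                      res_e: np.ndarray, dN_e: np.ndarray, dC_e: np.ndarray,
                      pos: int, scale15: float, soft: float, w_rep: float,
                      w_atr: float) -> float:
    """Candidate sidechain (residue index `pos`, 0-based) against a flat
    environment. Bond separations are derived from per-atom depths to the
    residue's N/C exits: pairs <= 3 bonds are excluded, == 4 attenuated."""
    e_tot = 0.0
    for a in range(G.shape[0]):
        gx, gy, gz = G[a, 0], G[a, 1], G[a, 2]
        for b in range(X.shape[0]):
            rj = res_e[b]
            if rj == pos:
                continue
            if rj == pos - 1:
                bd = dN_g[a] + 1 + dC_e[b]
            elif rj == pos + 1:
                bd = dC_g[a] + 1 + dN_e[b]
            else:
                bd = 99
            if bd <= 3:
                continue
            dx = gx - X[b, 0]
            dy = gy - X[b, 1]
            dz = gz - X[b, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            sig = rad_g[a] + rad_e[b]
            if bd == 4:
                sig *= scale15
            if d >= ATR_CUTOFF and d >= sig:
                continue
            e, _ = _pair_e_dedr(d, sig, sig * soft, w_rep, w_atr)
            e_tot += e
    return e_tot


@njit(cache=True)
def group_intra_energy(G: np.ndarray, incl: np.ndarray, sigma: np.ndarray,
                       soft: float, w_rep: float, w_atr: float) -> float:
    """Energy among group atoms themselves (upper triangle of incl)."""
    e_tot = 0.0
    m = G.shape[0]
    for a in range(m):
        for b in range(a + 1, m):
            if not incl[a, b]:
                continue
            dx = G[a, 0] - G[b, 0]
            dy = G[a, 1] - G[b, 1]
            dz = G[a, 2] - G[b, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            sig = sigma[a, b]
            if d >= ATR_CUTOFF and d >= sig:
                continue
            e, _ = _pair_e_dedr(d, sig, sig * soft, w_rep, w_atr)
            e_tot += e
    return e_tot
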