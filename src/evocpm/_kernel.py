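"""Numba-compiled inner loops of the Cellular Potts engine.

The lattice update follows the classic Metropolis scheme: per Monte
Carlo step (MCS), L*L lattice sites are drawn at random; for each drawn
site a random Moore neighbour may copy its spin into it.  The energy
change of a copy is computed incrementally (area term + adhesion term
over the Moore interaction neighbourhood) and the copy is accepted with
probability min(1, exp(-(dH + Y)/T)), where Y collects the migration and
chemotaxis work terms of the extending cell.

Randomness inside the kernel comes from an inlined xorshift64* stream
whose 64-bit state is seeded from the simulation's master seed; the
kernel state is part of a checkpoint, so runs are bit-reproducible.

Boundary conditions are closed: copies from outside the lattice are
never proposed and border sites simply have fewer neighbours.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Moore neighbourhood offsets (row, col)
MOORE = np.array([(-1, -1), (-1, 0), (-1, 1),
                  (0, -1), (0, 1),
                  (1, -1), (1, 0), (1, 1)], dtype=np.int64)

#: cells below this many sites are culled as debris
MIN_CELL_SITES = 5

_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _next_u64(state):
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return x * np.uint64(2685821657736338717)


@njit(cache=True, inline="always")
def _next_float(state):
    return (_next_u64(state) >> np.uint64(11)) * _INV_2_53


@njit(cache=True)
def seed_state(seed):
    """Derive a non-zero xorshift64* state from an integer seed."""
    s = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(
        1442695040888963407)
    if s == np.uint64(0):
        s = np.uint64(0x9E3779B97F4A7C15)
    return s


@njit(cache=True, fastmath=True)
def run_mcs(spins, field, J, area, At, sx, sy, chs, chx, chy,
            px, py, behav, lam, T, mu_p, mu_chi, rng_state,
            stat_attempts, stat_accepts, collect_stats):
    """One Monte Carlo step: L*L random copy attempts.

    All per-cell bookkeeping (area, coordinate sums, chi-weighted sums)
    is updated incrementally on every accepted copy.  Site coordinates
    come from multiply-shift scaling of disjoint 32-bit halves of one
    xorshift64* draw (division-free and unbiased to ~2^-32).
    """
    L = spins.shape[0]
    n_draws = L * L
    L_u = np.uint64(L)
    m32 = np.uint64(0xFFFFFFFF)
    c32 = np.uint64(32)
    for _ in range(n_draws):
        r = _next_u64(rng_state)
        x = np.int64(((r >> c32) * L_u) >> c32)
        y = np.int64(((r & m32) * L_u) >> c32)
        st = spins[x, y]
        k = np.int64(r & np.uint64(7))
        xs = x + MOORE[k, 0]
        ys = y + MOORE[k, 1]
        if xs < 0 or xs >= L or ys < 0 or ys >= L:
            continue
        ss = spins[xs, ys]
        if ss == st:
            continue
        # adhesion: interfaces of (x, y) with its Moore neighbours
        dH = 0.0
        for k2 in range(8):
            xn = x + MOORE[k2, 0]
            yn = y + MOORE[k2, 1]
            if xn < 0 or xn >= L or yn < 0 or yn >= L:
                continue
            sn = spins[xn, yn]
            dH += J[ss, sn] - J[st, sn]
        # area constraint of the (at most two) affected cells
        if st > 0:
            a = area[st]
            t = At[st]
            dH += lam * ((a - 1 - t) ** 2 - (a - t) ** 2)
        if ss > 0:
            a = area[ss]
            t = At[ss]
            dH += lam * ((a + 1 - t) ** 2 - (a - t) ** 2)
        # work terms: only the extending migratory cell is biased
        Y = 0.0
        if ss > 0 and behav[ss] == 1 and area[ss] > 0:
            a_f = np.float64(area[ss])
            comx = sx[ss] / a_f
            comy = sy[ss] / a_f
            dxv = x - comx
            dyv = y - comy
            dn = np.sqrt(dxv * dxv + dyv * dyv)
            if dn > 1e-12:
                Y -= mu_p * (px[ss] * dxv + py[ss] * dyv) / dn
                cs = chs[ss]
                # integer test for a locally flat perceived field
                if (chx[ss] * area[ss] == sx[ss] * cs
                        and chy[ss] * area[ss] == sy[ss] * cs):
                    theta = 6.283185307179586 * _next_float(rng_state)
                    Y -= mu_chi * np.cos(theta)
                else:
                    gx = chx[ss] / cs - comx
                    gy = chy[ss] / cs - comy
                    gn = np.sqrt(gx * gx + gy * gy)
                    Y -= mu_chi * (gx * dxv + gy * dyv) / (gn * dn)
        tot = dH + Y
        if collect_stats:
            b = np.int64(np.rint(tot))
            if 0 <= b < stat_attempts.shape[0] and abs(tot - b) < 1e-9:
                stat_attempts[b] += 1
        accept = False
        if tot < 0.0:
            accept = True
        elif _next_float(rng_state) < np.exp(-tot / T):
            accept = True
        if accept:
            if collect_stats:
                b = np.int64(np.rint(tot))
                if 0 <= b < stat_accepts.shape[0] and abs(tot - b) < 1e-9:
                    stat_accepts[b] += 1
            f = np.int64(field[x, y])
            if st > 0:
                area[st] -= 1
                sx[st] -= x
                sy[st] -= y
                chs[st] -= f
                chx[st] -= f * x
                chy[st] -= f * y
            if ss > 0:
                area[ss] += 1
                sx[ss] += x
                sy[ss] += y
                chs[ss] += f
                chx[ss] += f * x
                chy[ss] += f * y
            spins[x, y] = ss


@njit(cache=True)
def copy_delta_h(spins, field_unused, J, area, At, lam, x, y, ss):
    """Energy change dH (area + adhesion) of copying spin ``ss`` into
    site (x, y).  Mirrors the incremental computation inside
    :func:`run_mcs`; exposed separately so tests can compare it against a
    full-Hamiltonian recomputation."""
    L = spins.shape[0]
    st = spins[x, y]
    dH = 0.0
    for k2 in range(8):
        xn = x + MOORE[k2, 0]
        yn = y + MOORE[k2, 1]
        if xn < 0 or xn >= L or yn < 0 or yn >= L:
            continue
        sn = spins[xn, yn]
        dH += J[ss, sn] - J[st, sn]
    if st > 0:
        a = area[st]
        t = At[st]
        dH += lam * ((a - 1 - t) ** 2 - (a - t) ** 2)
    if ss > 0:
        a = area[ss]
        t = At[ss]
        dH += lam * ((a + 1 - t) ** 2 - (a - t) ** 2)
    return dH


@njit(cache=True)
def update_cells(mcs, n_spins, alive, behav, area, At, sx, sy, chs,
                 px, py, ref_comx, ref_comy,
                 w_in, w_reg, w_out, rho_reg, rho_out, phi,
                 reg_state, out_state, streak, ndiv,
                 grn_phase, p_phase, next_size_mcs,
                 divide_flag, cull_flag,
                 grn_period, tau_p, eta_init, max_div, base_At,
                 size_interval):
    """Per-MCS cell maintenance: GRN ticks (per-cell phase), behaviour
    transitions, target-area growth/shrink ticks, persistence-vector
    refresh, division triggers and debris flags."""
    any_flag = False
    for c in range(1, n_spins + 1):
        if alive[c] == 0:
            continue
        if area[c] < MIN_CELL_SITES:
            cull_flag[c] = 1
            any_flag = True
            continue
        if mcs % grn_period == grn_phase[c]:
            conc = chs[c] / np.float64(area[c])
            s0 = phi[c, 0] * conc
            s1 = phi[c, 1] * np.float64(ndiv[c])
            new_reg = np.zeros(3, dtype=np.int8)
            for i in range(3):
                r = s0 * w_in[c, 0, i] + s1 * w_in[c, 1, i]
                for kk in range(3):
                    r += reg_state[c, kk] * w_reg[c, kk, i]
                if r > rho_reg[c, i]:
                    new_reg[i] = 1
            r_o = 0.0
            for kk in range(3):
                r_o += reg_state[c, kk] * w_out[c, kk]
            new_out = 1 if r_o > rho_out[c] else 0
            for i in range(3):
                reg_state[c, i] = new_reg[i]
            out_state[c] = new_out
            old_b = behav[c]
            if new_out == 0:
                streak[c] = 0
                if old_b != 1:
                    behav[c] = 1
                    next_size_mcs[c] = mcs + size_interval
            else:
                streak[c] += 1
                if streak[c] * grn_period >= eta_init:
                    if ndiv[c] < max_div:
                        if old_b != 2:
                            behav[c] = 2
                            next_size_mcs[c] = mcs + size_interval
                    else:
                        behav[c] = 3
        # target-area dynamics
        if behav[c] == 2:
            if At[c] < 2 * base_At and mcs >= next_size_mcs[c]:
                At[c] += 1
                next_size_mcs[c] = mcs + size_interval
            if At[c] >= 2 * base_At and 10 * area[c] >= 9 * 2 * base_At:
                divide_flag[c] = 1
                any_flag = True
        elif behav[c] == 1 and At[c] > base_At and mcs >= next_size_mcs[c]:
            At[c] -= 1
            next_size_mcs[c] = mcs + size_interval
        # persistence refresh from realized displacement
        if mcs % tau_p == p_phase[c] and area[c] > 0:
            a_f = np.float64(area[c])
            comx = sx[c] / a_f
            comy = sy[c] / a_f
            dx = comx - ref_comx[c]
            dy = comy - ref_comy[c]
            norm = np.sqrt(dx * dx + dy * dy)
            if norm > 1e-12:
                px[c] = dx / norm
                py[c] = dy / norm
            ref_comx[c] = comx
            ref_comy[c] = comy
    return any_flag


@njit(cache=True)
def run_block(n_mcs, start_mcs, spins, field, J, area, At, sx, sy, chs,
              chx, chy, px, py, behav, lam, T, mu_p, mu_chi, rng_state,
              stat_attempts, stat_accepts, collect_stats,
              n_spins, alive, ref_comx, ref_comy,
              w_in, w_reg, w_out, rho_reg, rho_out, phi,
              reg_state, out_state, streak, ndiv,
              grn_phase, p_phase, next_size_mcs, divide_flag, cull_flag,
              grn_period, tau_p, eta_init, max_div, base_At,
              size_interval):
    """Run up to ``n_mcs`` Monte Carlo steps, returning early (with the
    number of steps completed) as soon as a division or debris flag is
    raised so the caller can handle it in Python."""
    done = 0
    for m in range(n_mcs):
        mcs = start_mcs + m
        run_mcs(spins, field, J, area, At, sx, sy, chs, chx, chy,
                px, py, behav, lam, T, mu_p, mu_chi, rng_state,
                stat_attempts, stat_accepts, collect_stats)
        flagged = update_cells(mcs, n_spins, alive, behav, area, At,
                               sx, sy, chs, px, py, ref_comx, ref_comy,
                               w_in, w_reg, w_out, rho_reg, rho_out, phi,
                               reg_state, out_state, streak, ndiv,
                               grn_phase, p_phase, next_size_mcs,
                               divide_flag, cull_flag,
                               grn_period, tau_p, eta_init, max_div,
                               base_At, size_interval)
        done += 1
        if flagged:
            break
    return done


@njit(cache=True)
def accumulate_chi(spins, field, chs, chx, chy):
    """Recompute per-cell chi-weighted sums from scratch (after a field
    rebuild or a checkpoint restore)."""
    chs[:] = 0
    chx[:] = 0
    chy[:] = 0
    L = spins.shape[0]
    for x in range(L):
        for y in range(L):
            s = spins[x, y]
            if s > 0:
                f = np.int64(field[x, y])
                chs[s] += f
                chx[s] += f * x
                chy[s] += f * y


@njit(cache=True)
def accumulate_geometry(spins, area, sx, sy):
    """Recompute per-cell areas and coordinate sums from scratch."""
    area[:] = 0
    sx[:] = 0
    sy[:] = 0
    L = spins.shape[0]
    for x in range(L):
        for y in range(L):
            s = spins[x, y]
            if s > 0:
                area[s] += 1
                sx[s] += x
                sy[s] += y
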