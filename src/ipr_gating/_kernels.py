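"""Numba-compiled inner loops for the cluster simulation.

The tridiagonal (Thomas) factorization is done once in Python; the kernel
reuses the factors every step, advancing only channels whose field is away
from rest.  Gating uses exact jump sampling within each field step at frozen
local Ca2+, so no transition-probability step-size restriction applies.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["thomas_factor", "run_cluster_kernel"]


def thomas_factor(lower: np.ndarray, diag: np.ndarray, upper: np.ndarray):
    """Forward-elimination factors of a constant tridiagonal matrix.

    Returns (cp, denom) such that a solve reduces to one forward and one
    backward substitution over the right-hand side.
    """
    n = len(diag)
    cp = np.empty(n)
    denom = np.empty(n)
    denom[0] = diag[0]
    cp[0] = upper[0] / denom[0]
    for i in range(1, n):
        denom[i] = diag[i] - lower[i] * cp[i - 1]
        if i < n - 1:
            cp[i] = upper[i] / denom[i]
        else:
            cp[i] = 0.0
    return cp, denom


@njit(cache=False)
def _solve_inplace(lower, cp, denom, x, work):
    n = x.shape[0]
    work[0] = x[0] / denom[0]
    for i in range(1, n):
        work[i] = (x[i] - lower[i] * work[i - 1]) / denom[i]
    x[n - 1] = work[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = work[i] - cp[i] * x[i + 1]


@njit(cache=False)
def run_cluster_kernel(
    n_steps, stride, dt,
    r_grid, low_ca, cp_ca, den_ca, low_dy, cp_dy, den_dy,
    src,
    B_total, k_on, k_off, c_rest, b_rest,
    dists, center_dists, obs_radius,
    log_c_grid, rate_table, exit_table,
    trans_from, trans_to,
    states0, n_open_states, seed,
):
    np.random.seed(seed)
    nchan = states0.shape[0]
    n = r_grid.shape[0]
    n_trans = trans_from.shape[0]

    c = np.full((nchan, n), c_rest)
    b = np.full((nchan, n), b_rest)
    work = np.empty(n)
    states = states0.copy()
    is_open = np.zeros(nchan, dtype=np.uint8)
    for j in range(nchan):
        if states[j] < n_open_states:
            is_open[j] = 1
    active = np.zeros(nchan, dtype=np.uint8)
    for j in range(nchan):
        active[j] = is_open[j]

    # interpolation stencils for pairwise distances, centre and observation shell
    pair_idx = np.empty((nchan, nchan), dtype=np.int64)
    pair_frac = np.empty((nchan, nchan))
    for i in range(nchan):
        for j in range(nchan):
            d = dists[i, j]
            if d <= r_grid[0]:
                pair_idx[i, j] = 0
                pair_frac[i, j] = 0.0
            else:
                k = np.searchsorted(r_grid, d) - 1
                if k >= n - 1:
                    k = n - 2
                pair_idx[i, j] = k
                pair_frac[i, j] = (d - r_grid[k]) / (r_grid[k + 1] - r_grid[k])
    cen_idx = np.empty(nchan, dtype=np.int64)
    cen_frac = np.empty(nchan)
    for j in range(nchan):
        d = center_dists[j]
        k = np.searchsorted(r_grid, d) - 1
        if k < 0:
            k = 0
        if k >= n - 1:
            k = n - 2
        cen_idx[j] = k
        cen_frac[j] = (d - r_grid[k]) / (r_grid[k + 1] - r_grid[k])
    k = np.searchsorted(r_grid, obs_radius) - 1
    if k < 0:
        k = 0
    if k >= n - 1:
        k = n - 2
    obs_idx = k
    obs_frac = (obs_radius - r_grid[k]) / (r_grid[k + 1] - r_grid[k])

    lc0 = log_c_grid[0]
    dlc = log_c_grid[1] - log_c_grid[0]
    n_lc = log_c_grid.shape[0]

    n_rec = n_steps // stride
    rec_n_open = np.zeros(n_rec, dtype=np.int8)
    rec_bits = np.zeros((n_rec, nchan), dtype=np.uint8)
    rec_ca = np.zeros(n_rec)
    rec_dye = np.zeros(n_rec)

    relax_check = 2000
    local_ca = np.empty(nchan)

    for step in range(n_steps):
        # --- field update (active channels only)
        for j in range(nchan):
            if active[j] == 0:
                continue
            cj = c[j]
            bj = b[j]
            if is_open[j] == 1:
                # source folded into the implicit diffusion solve
                for m in range(n):
                    cj[m] += dt * src[m]
            _solve_inplace(low_ca, cp_ca, den_ca, cj, work)
            _solve_inplace(low_dy, cp_dy, den_dy, bj, work)
            for m in range(n):
                bm = (bj[m] + dt * k_off * B_total) / (
                    1.0 + dt * (k_off + k_on * cj[m])
                )
                cj[m] = (cj[m] + dt * k_off * (B_total - bm)) / (
                    1.0 + dt * k_on * bm
                )
                bj[m] = bm
            if cj[0] < 0.0 or not np.isfinite(cj[0]):
                return rec_n_open, rec_bits, rec_ca, rec_dye, 1

        # --- local Ca2+ by superposition (rest counted once)
        for i in range(nchan):
            acc = c_rest
            for j in range(nchan):
                if active[j] == 0:
                    continue
                k0 = pair_idx[i, j]
                f = pair_frac[i, j]
                val = c[j, k0] + (c[j, k0 + 1] - c[j, k0]) * f
                acc += val - c[j, n - 1]
            local_ca[i] = acc

        # --- gating: exact jump sampling within dt at frozen local Ca2+
        for i in range(nchan):
            ca = local_ca[i]
            if ca < 1e-30:
                ca = 1e-30
            pos = (np.log10(ca) - lc0) / dlc
            if pos < 0.0:
                pos = 0.0
            if pos > n_lc - 1.000001:
                pos = n_lc - 1.000001
            k0 = int(pos)
            f = pos - k0
            t_loc = 0.0
            s = states[i]
            for _ in range(100000):
                e = exit_table[k0, s] + (exit_table[k0 + 1, s] - exit_table[k0, s]) * f
                if e <= 0.0:
                    break
                t_loc += np.random.exponential(1.0 / e)
                if t_loc >= dt:
                    break
                u = np.random.random() * e
                acc = 0.0
                for m in range(n_trans):
                    if trans_from[m] == s:
                        rm = rate_table[k0, m] + (rate_table[k0 + 1, m] - rate_table[k0, m]) * f
                        acc += rm
                        if u <= acc:
                            s = trans_to[m]
                            break
            if s != states[i]:
                states[i] = s
                was_open = is_open[i]
                now_open = np.uint8(1) if s < n_open_states else np.uint8(0)
                is_open[i] = now_open
                if now_open == 1:
                    active[i] = 1

        # --- deactivate relaxed fields occasionally
        if step % relax_check == relax_check - 1:
            for j in range(nchan):
                if active[j] == 1 and is_open[j] == 0:
                    dev = 0.0
                    for m in range(n):
                        d0 = abs(c[j, m] - c_rest)
                        if d0 > dev:
                            dev = d0
                    if dev < 1e-7:
                        for m in range(n):
                            c[j, m] = c_rest
                            b[j, m] = b_rest
                        active[j] = 0

        # --- record
        if (step + 1) % stride == 0:
            idx = (step + 1) // stride - 1
            if idx < n_rec:
                tot = 0
                ca_c = 0.0
                dye = 0.0
                for j in range(nchan):
                    rec_bits[idx, j] = is_open[j]
                    tot += is_open[j]
                    if active[j] == 1:
                        k0 = cen_idx[j]
                        f = cen_frac[j]
                        ca_c += c[j, k0] + (c[j, k0 + 1] - c[j, k0]) * f - c[j, n - 1]
                        dye += b_rest - (b[j, obs_idx] + (b[j, obs_idx + 1] - b[j, obs_idx]) * obs_frac)
                rec_n_open[idx] = tot
                rec_ca[idx] = ca_c
                rec_dye[idx] = dye

    return rec_n_open, rec_bits, rec_ca, rec_dye, 0
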