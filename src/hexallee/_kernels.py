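"""Numba kernels for the stochastic lattice engine.

The random sequential update draws, per time step, Q(t) agents with
replacement for movement and then Q(t) agents with replacement for growth.
Crowding functions enter only through lookup tables indexed by the occupied
neighbour count k (the local density is exactly k / |N_r|), which makes the
inner loops branch-free in Python objects and bit-reproducible.

Per-realization RNG: each realization seeds numba's Mersenne Twister once;
the draw order is fixed as (agent selection, event acceptance, destination
choice), so identical seeds give identical trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _build_agent_list(occ, agents, pos):
    Q = 0
    for s in range(occ.size):
        if occ[s] == 1:
            agents[Q] = s
            pos[s] = Q
            Q += 1
        else:
            pos[s] = -1
    return Q


@njit(cache=True)
def _movement_sweep(occ, agents, pos, Q, nbr, gtab, M, flux, ifc, dxw, flux_on):
    nm = nbr.shape[1]
    for _ in range(Q):
        idx = np.random.randint(0, Q)
        s = agents[idx]
        k = 0
        for t in range(nm):
            k += occ[nbr[s, t]]
        if np.random.random() < M * gtab[k]:
            nv = nm - k
            if nv > 0:
                jch = np.random.randint(0, nv)
                c = 0
                for t in range(nm):
                    nb = nbr[s, t]
                    if occ[nb] == 0:
                        if c == jch:
                            occ[s] = 0
                            occ[nb] = 1
                            pos[s] = -1
                            pos[nb] = idx
                            agents[idx] = nb
                            if flux_on:
                                flux[ifc[s, t]] += dxw[s, t]
                            break
                        c += 1
    return Q


@njit(cache=True)
def _growth_sweep(occ, agents, pos, Q, nbr, ftab, P):
    ng = nbr.shape[1]
    Q0 = Q
    for _ in range(Q0):
        if Q == 0:
            break
        idx = np.random.randint(0, Q)
        s = agents[idx]
        k = 0
        for t in range(ng):
            k += occ[nbr[s, t]]
        f = ftab[k]
        if f > 0.0:
            if np.random.random() < P * f:
                nv = ng - k
                if nv > 0:
                    jch = np.random.randint(0, nv)
                    c = 0
                    for t in range(ng):
                        nb = nbr[s, t]
                        if occ[nb] == 0:
                            if c == jch:
                                occ[nb] = 1
                                agents[Q] = nb
                                pos[nb] = Q
                                Q += 1
                                break
                            c += 1
        elif f < 0.0:
            if np.random.random() < P * (-f):
                occ[s] = 0
                ls = agents[Q - 1]
                agents[idx] = ls
                pos[ls] = idx
                Q -= 1
                pos[s] = -1
    return Q


@njit(cache=True)
def single_sweep(occ, nbr, tab, rate, seed, kind):
    """One seeded sweep on a flat occupancy array: kind 0 = move, 1 = growth."""
    np.random.seed(seed)
    N = occ.size
    agents = np.empty(N, dtype=np.int64)
    pos = np.empty(N, dtype=np.int64)
    Q = _build_agent_list(occ, agents, pos)
    if kind == 0:
        flux = np.zeros(1, dtype=np.float64)
        ifc = np.zeros((1, 1), dtype=np.int64)
        dxw = np.zeros((1, 1), dtype=np.float64)
        Q = _movement_sweep(occ, agents, pos, Q, nbr, tab, rate, flux, ifc, dxw, False)
    else:
        Q = _growth_sweep(occ, agents, pos, Q, nbr, tab, rate)
    return Q


@njit(cache=True)
def run_realization(
    occ,            # uint8[N], modified in place
    nbr_m,          # int64[N, |Nm|]
    nbr_g,          # int64[N, |Ng|]
    gtab,           # float64[|Nm|+1]: M-multiplier G(k/|Nm|)
    ftab,           # float64[|Ng|+1]: signed F(k/|Ng|)
    M, P,
    n_steps,
    record_steps,   # int64[n_rec], sorted ascending; may start at 0
    col,            # int64[N]: column index of each site
    ifc,            # int64[N, |Nm|]: interface attributed to each move
    dxw,            # float64[N, |Nm|]: signed horizontal weight of each move
    flux,           # float64[I]: accumulated interface weights (flux mode)
    colacc,         # float64[I]: time-accumulated column occupancy (flux mode)
    flux_on,
    prof,           # float64[n_rec, I]: column occupied counts at record steps
    tot,            # float64[n_rec]: Q at record steps
    seed,
    q_lo, q_hi,     # early-exit thresholds on Q (absorbing-state guards); <0 disables
):
    np.random.seed(seed)
    N = occ.size
    agents = np.empty(N, dtype=np.int64)
    pos = np.empty(N, dtype=np.int64)
    Q = _build_agent_list(occ, agents, pos)

    n_rec = record_steps.size
    rec_i = 0
    if rec_i < n_rec and record_steps[rec_i] == 0:
        for s in range(N):
            if occ[s] == 1:
                prof[rec_i, col[s]] += 1.0
        tot[rec_i] = Q
        rec_i += 1

    step_done = 0
    for step in range(1, n_steps + 1):
        Q = _movement_sweep(occ, agents, pos, Q, nbr_m, gtab, M, flux, ifc, dxw, flux_on)
        Q = _growth_sweep(occ, agents, pos, Q, nbr_g, ftab, P)
        if flux_on:
            for s in range(N):
                if occ[s] == 1:
                    colacc[col[s]] += 1.0
        if rec_i < n_rec and record_steps[rec_i] == step:
            for s in range(N):
                if occ[s] == 1:
                    prof[rec_i, col[s]] += 1.0
            tot[rec_i] = Q
            rec_i += 1
        step_done = step
        if q_lo >= 0 and Q <= q_lo:
            break
        if q_hi >= 0 and Q >= q_hi:
            break
    return Q, step_done
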