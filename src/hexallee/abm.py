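"""Stochastic lattice engine: sweeps, ensembles and empirical flux.

One time step tau consists of a movement sweep followed by a growth sweep.
Each sweep performs Q(t) agent selections uniformly at random *with
replacement* from the live-agent list (Q(t) evaluated at sweep start).  A
selected agent at site s moves with probability M G(K_s) to a uniformly
chosen vacant site of its movement template, and undergoes a growth event
with probability P |F(K_s)| on the growth template: a birth places a daughter
on a uniformly chosen vacant template site when F(K_s) > 0, a death removes
the agent when F(K_s) < 0.

Because local density on a template of size n only takes the values k/n,
crowding functions are pre-tabulated at those densities; this is exact, not
an approximation.

Ensemble statistics follow the standard estimators: mean site occupancy over
V identically prepared realizations, the column density (occupancy averaged
over rows and realizations), and the total density (average over the whole
lattice).  Realization v uses seed base_seed + v.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .crowding import CrowdingFunctionF, CrowdingFunctionG, RateConstants
from .hexlattice import HexGeometry, HexState, neighbor_table, template_offsets

__all__ = [
    "SimulationConfig",
    "EnsembleResult",
    "FluxProfile",
    "movement_sweep",
    "growth_sweep",
    "step",
    "simulate_ensemble",
    "measure_flux",
]

_MAX_SEED = 2**31 - 1


@dataclasses.dataclass
class SimulationConfig:
    """Everything needed to run an ensemble of realizations."""

    rates: RateConstants
    G: CrowdingFunctionG
    F: CrowdingFunctionF
    geometry: HexGeometry
    r_move: int = 1
    r_growth: int = 4
    n_realizations: int = 1
    base_seed: int = 0
    t_end: float = 0.0
    record_times: Sequence[float] = ()

    def __post_init__(self):
        if self.r_move < 1 or self.r_growth < 1:
            raise ValueError("template diameters must be >= 1")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


@dataclasses.dataclass
class EnsembleResult:
    """Ensemble averages at the recorded times.

    column_density has shape (n_times, I); total_density is its mean over
    columns (the two are consistent by construction).  site_occupancy is the
    per-site occupancy fraction at the final recorded time, shape (J, I).
    """

    times: np.ndarray
    column_density: np.ndarray
    column_sem: np.ndarray
    total_density: np.ndarray
    total_sem: np.ndarray
    site_occupancy: np.ndarray


@dataclasses.dataclass
class FluxProfile:
    """Measured horizontal flux at the I column interfaces.

    x[q] is the nominal position of the interface between columns q and q+1;
    J_x > 0 points toward increasing x.  column_density is the time-averaged
    column density over the measurement window (for comparison with
    -D(C) dC/dx).
    """

    x: np.ndarray
    Jx: np.ndarray
    Jx_sem: np.ndarray
    column_density: np.ndarray


# ---------------------------------------------------------------------------
# lookup tables


def _g_table(config: SimulationConfig) -> np.ndarray:
    n = 3 * config.r_move * (config.r_move + 1)
    k = np.arange(n + 1)
    g = np.asarray(config.G.value(k / n), dtype=float)
    if not np.all(np.isfinite(g)) or g.min() < -1e-12 or g.max() > 1.0 + 1e-12:
        raise ValueError(
            f"G takes values outside [0, 1] on the template densities "
            f"(range [{g.min():.3g}, {g.max():.3g}]); M*G would not be a probability"
        )
    return np.clip(g, 0.0, 1.0)


def _f_table(config: SimulationConfig) -> np.ndarray:
    n = 3 * config.r_growth * (config.r_growth + 1)
    k = np.arange(n + 1)
    f = np.asarray(config.F.value(k / n), dtype=float)
    if not np.all(np.isfinite(f)) or np.max(np.abs(f)) > 1.0 + 1e-12:
        raise ValueError("|F| exceeds 1 on the template densities; P*F would not be a probability")
    if config.rates.P * np.max(np.abs(f)) > 1.0 + 1e-12:
        raise ValueError("P * |F| exceeds 1")
    return np.clip(f, -1.0, 1.0)


def _neighbor_tables(config: SimulationConfig):
    geom = config.geometry
    nbr_m = neighbor_table(geom, template_offsets(config.r_move))
    if config.r_growth == config.r_move:
        nbr_g = nbr_m
    else:
        nbr_g = neighbor_table(geom, template_offsets(config.r_growth))
    return nbr_m, nbr_g


def _flux_tables(config: SimulationConfig, nbr_m: np.ndarray):
    """Interface attribution and signed horizontal weight for each move.

    A move between neighbouring sites carries weight dx/delta (+-1 for
    horizontal moves, +-1/2 for diagonal ones) and is attributed to the
    interface between the two columns involved; a diagonal move within a
    single column is attributed to that column's right-edge interface, so a
    move and its reverse always tally at the same interface with opposite
    signs.  Only defined for r_move = 1 (nearest-neighbour moves).
    """
    if config.r_move != 1:
        raise ValueError("flux measurement is defined for r_move = 1")
    geom = config.geometry
    I, J = geom.n_cols, geom.n_rows
    N = I * J
    col = np.tile(np.arange(I, dtype=np.int64), J)
    jj = np.repeat(np.arange(J), I)
    x = col + (jj % 2) * 0.5  # in units of delta

    ifc = np.empty_like(nbr_m)
    dxw = np.empty(nbr_m.shape, dtype=float)
    for t in range(nbr_m.shape[1]):
        dest = nbr_m[:, t]
        dx = x[dest] - x[np.arange(N)]
        dx = (dx + I / 2.0) % I - I / 2.0  # wrap to (-I/2, I/2]
        dxw[:, t] = dx
        cs, cd = col, col[dest]
        same = cs == cd
        right = cd == (cs + 1) % I
        ifc[:, t] = np.where(same, cs, np.where(right, cs, cd))
    return col, ifc, dxw


# ---------------------------------------------------------------------------
# single sweeps (thin wrappers over the kernels, for tests and small studies)


def _seed_from(rng) -> int:
    if isinstance(rng, (int, np.integer)):
        return int(rng) & _MAX_SEED
    return int(rng.integers(_MAX_SEED))


def movement_sweep(state: HexState, config: SimulationConfig, rng) -> HexState:
    """One movement sweep: Q(t) selections, agent count conserved."""
    occ = state.occupancy.ravel().copy()
    nbr_m = neighbor_table(config.geometry, template_offsets(config.r_move))
    gtab = _g_table(config)
    _kernels.single_sweep(occ, nbr_m, gtab, config.rates.M, _seed_from(rng), 0)
    return HexState(state.geometry, occ.reshape(state.occupancy.shape))


def growth_sweep(state: HexState, config: SimulationConfig, rng) -> HexState:
    """One growth sweep: Q(t) selections, births and deaths applied."""
    occ = state.occupancy.ravel().copy()
    nbr_g = neighbor_table(config.geometry, template_offsets(config.r_growth))
    ftab = _f_table(config)
    _kernels.single_sweep(occ, nbr_g, ftab, config.rates.P, _seed_from(rng), 1)
    return HexState(state.geometry, occ.reshape(state.occupancy.shape))


def step(state: HexState, config: SimulationConfig, rng) -> HexState:
    """Advance one time step tau: movement sweep then growth sweep."""
    out = movement_sweep(state, config, rng)
    return growth_sweep(out, config, rng)


# ---------------------------------------------------------------------------
# ensembles


def _initial_occupancy(initial, v: int, config: SimulationConfig) -> np.ndarray:
    if isinstance(initial, HexState):
        return initial.occupancy.ravel().copy()
    st = initial(v)
    if not isinstance(st, HexState):
        raise TypeError("initial factory must return a HexState")
    return st.occupancy.ravel().copy()


def simulate_ensemble(config: SimulationConfig, initial) -> EnsembleResult:
    """Run V identically prepared realizations and aggregate the estimators.

    ``initial`` is either a HexState (shared by all realizations) or a
    callable ``v -> HexState`` building the v-th initial condition (used for
    random well-mixed initial states).
    """
    geom = config.geometry
    I, J = geom.n_cols, geom.n_rows
    tau = config.rates.tau
    record_steps = np.unique(np.round(np.asarray(config.record_times, dtype=float) / tau)).astype(np.int64)
    if record_steps.size == 0:
        record_steps = np.array([int(round(config.t_end / tau))], dtype=np.int64)
    n_steps = int(max(record_steps.max(initial=0), round(config.t_end / tau)))
    n_rec = record_steps.size

    nbr_m, nbr_g = _neighbor_tables(config)
    gtab, ftab = _g_table(config), _f_table(config)
    col = np.tile(np.arange(I, dtype=np.int64), J)
    dummy_ifc = np.zeros_like(nbr_m)
    dummy_dxw = np.zeros(nbr_m.shape, dtype=float)
    dummy_flux = np.zeros(I)
    dummy_colacc = np.zeros(I)

    prof_sum = np.zeros((n_rec, I))
    prof_sq = np.zeros((n_rec, I))
    tot_sum = np.zeros(n_rec)
    tot_sq = np.zeros(n_rec)
    site_sum = np.zeros(I * J)

    V = config.n_realizations
    for v in range(V):
        occ = _initial_occupancy(initial, v, config)
        prof = np.zeros((n_rec, I))
        tot = np.zeros(n_rec)
        seed = (config.base_seed + v) & _MAX_SEED
        _kernels.run_realization(
            occ, nbr_m, nbr_g, gtab, ftab,
            config.rates.M, config.rates.P,
            n_steps, record_steps,
            col, dummy_ifc, dummy_dxw, dummy_flux, dummy_colacc, False,
            prof, tot, seed, -1, -1,
        )
        prof /= J
        tot /= I * J
        prof_sum += prof
        prof_sq += prof**2
        tot_sum += tot
        tot_sq += tot**2
        site_sum += occ

    col_mean = prof_sum / V
    tot_mean = tot_sum / V
    if V > 1:
        col_sem = np.sqrt(np.maximum(prof_sq / V - col_mean**2, 0.0) / (V - 1))
        tot_sem = np.sqrt(np.maximum(tot_sq / V - tot_mean**2, 0.0) / (V - 1))
    else:
        col_sem = np.zeros_like(col_mean)
        tot_sem = np.zeros_like(tot_mean)

    return EnsembleResult(
        times=record_steps.astype(float) * tau,
        column_density=col_mean,
        column_sem=col_sem,
        total_density=tot_mean,
        total_sem=tot_sem,
        site_occupancy=(site_sum / V).reshape(J, I),
    )


def measure_flux(config: SimulationConfig, initial, window_steps: int) -> FluxProfile:
    """Empirical horizontal flux from a crossing tally over a time window.

    Every executed move adds its signed horizontal weight (dx/delta) to the
    interface between the columns involved; the flux estimate at interface q
    is the accumulated weight divided by (window duration x number of rows),
    in units of delta/tau, averaged over realizations.  A window of at least
    ~100 steps is needed for a usable signal.
    """
    if window_steps < 1:
        raise ValueError("window_steps must be >= 1")
    geom = config.geometry
    I, J = geom.n_cols, geom.n_rows
    nbr_m, nbr_g = _neighbor_tables(config)
    gtab, ftab = _g_table(config), _f_table(config)
    col, ifc, dxw = _flux_tables(config, nbr_m)
    record_steps = np.array([window_steps], dtype=np.int64)

    V = config.n_realizations
    flux_sum = np.zeros(I)
    flux_sq = np.zeros(I)
    colacc_sum = np.zeros(I)
    for v in range(V):
        occ = _initial_occupancy(initial, v, config)
        flux = np.zeros(I)
        colacc = np.zeros(I)
        prof = np.zeros((1, I))
        tot = np.zeros(1)
        seed = (config.base_seed + v) & _MAX_SEED
        _kernels.run_realization(
            occ, nbr_m, nbr_g, gtab, ftab,
            config.rates.M, config.rates.P,
            window_steps, record_steps,
            col, ifc, dxw, flux, colacc, True,
            prof, tot, seed, -1, -1,
        )
        jx = flux * geom.delta / (window_steps * config.rates.tau * J)
        flux_sum += jx
        flux_sq += jx**2
        colacc_sum += colacc / (window_steps * J)

    jx_mean = flux_sum / V
    if V > 1:
        jx_sem = np.sqrt(np.maximum(flux_sq / V - jx_mean**2, 0.0) / (V - 1))
    else:
        jx_sem = np.zeros_like(jx_mean)
    x_ifc = (np.arange(I) + 0.75) * geom.delta
    return FluxProfile(
        x=x_ifc,
        Jx=jx_mean,
        Jx_sem=jx_sem,
        column_density=colacc_sum / V,
    )
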