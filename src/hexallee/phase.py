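"""Survival/extinction analysis: fate classification and the (w, P/M) phase diagram.

A bistable population started from a central strip of width w either dies out
(total density -> 0) or invades the whole domain (total density -> 1).  The
classifier integrates the continuum model (or runs the discrete model) up to
a decision time T = 1e4 with early exit as soon as the total density leaves
[0.01, 0.99]; the binary outcome is decided by the residue at T being above
or below 1/2, and a run still in mid-flight at T raises an explicit
``UndecidedFateError`` rather than silently labelling it.

For each rate ratio P/M there is a critical strip width w*: extinction below,
survival above.  ``critical_width`` extracts w* by bisection with the
continuum engine; ``phase_diagram`` classifies a rectangular (w, P/M) mesh
and extracts the survival/extinction boundary per diffusivity model.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import abm, continuum
from .crowding import (
    CrowdingFunctionG,
    DiffusivityFunction,
    RateConstants,
    catalogue,
    diffusivity_from_crowding,
    strong_allee_growth,
)
from .hexlattice import HexGeometry, init_strip

__all__ = [
    "FateOutcome",
    "PhaseDiagram",
    "UndecidedFateError",
    "classify_fate",
    "critical_width",
    "phase_diagram",
]

DECISION_TIME = 1.0e4
EXTINCT_GUARD = 0.01
SURVIVE_GUARD = 0.99


class UndecidedFateError(RuntimeError):
    """Raised when the dynamics have not settled by the decision time."""


@dataclasses.dataclass
class FateOutcome:
    w: float
    P_over_M: float
    outcome: str  # "survive" | "extinct"
    C_final: float
    decision_time: float
    survival_fraction: float | None = None  # discrete engine only

    @property
    def survived(self) -> bool:
        return self.outcome == "survive"


@dataclasses.dataclass
class PhaseDiagram:
    models: tuple
    w_grid: np.ndarray
    ratio_grid: np.ndarray
    outcomes: dict        # model -> int array (n_ratio, n_w): 1 survive, 0 extinct
    C_final: dict         # model -> float array (n_ratio, n_w)
    boundary: dict        # model -> w*(ratio) array (nan where no crossing)
    monotone_violations: dict  # model -> list of (ratio_index, w_index)


def _resolve_D(model, D0: float) -> DiffusivityFunction:
    """Accept a catalogue name, a DiffusivityFunction, or a CrowdingFunctionG."""
    if isinstance(model, str):
        return catalogue(model, D0=D0)[1]
    if isinstance(model, DiffusivityFunction):
        if model.D0 != D0:
            return model.rescaled(D0)
        return model
    if isinstance(model, CrowdingFunctionG):
        return diffusivity_from_crowding(model, D0=D0)
    raise TypeError(f"cannot interpret diffusivity model {model!r}")


def _resolve_G(model) -> CrowdingFunctionG:
    if isinstance(model, str):
        return catalogue(model)[0]
    if isinstance(model, CrowdingFunctionG):
        return model
    raise TypeError("discrete engine needs a crowding function (catalogue name or CrowdingFunctionG)")


def classify_fate(
    model,
    w: float,
    P: float,
    M: float = 1.0,
    T: float = DECISION_TIME,
    engine: str = "continuum",
    L: float = 100.0,
    A: float = 0.4,
    grid_n: int = 200,
    n_rows: int | None = None,
    V: int = 5,
    base_seed: int = 0,
) -> FateOutcome:
    """Classify survival vs extinction from a central strip of width w.

    With the default dimensionless scales (delta = tau = 1) the continuum
    parameters are D0 = M/4 and lam = P.  The discrete engine runs V
    realizations with early exit on the same density guards and takes the
    majority outcome, recording the survival fraction.
    """
    rates = RateConstants(M=M, P=P)
    F = strong_allee_growth(A)
    if engine == "continuum":
        return _classify_continuum(model, w, rates, F, T, L, grid_n)
    if engine == "discrete":
        return _classify_discrete(model, w, rates, F, T, L, n_rows, V, base_seed)
    raise ValueError("engine must be 'continuum' or 'discrete'")


def _classify_continuum(model, w, rates, F, T, L, grid_n) -> FateOutcome:
    D = _resolve_D(model, D0=rates.D0)
    grid = continuum.Grid1D(L=L, n=grid_n)
    C0 = continuum.strip_profile(grid, w)

    def ev_lo(t, y):
        return float(np.mean(y)) - EXTINCT_GUARD

    def ev_hi(t, y):
        return float(np.mean(y)) - SURVIVE_GUARD

    ev_lo.terminal = True
    ev_lo.direction = -1.0
    ev_hi.terminal = True
    ev_hi.direction = 1.0

    if w == 0.0 or continuum.total_density(C0) <= EXTINCT_GUARD:
        return FateOutcome(w=w, P_over_M=rates.P / rates.M, outcome="extinct",
                           C_final=continuum.total_density(C0), decision_time=0.0)

    sol = continuum.solve_pde(
        D, F, rates.lam, C0, t_end=T, record_times=[T], grid=grid,
        events=[ev_lo, ev_hi],
    )
    C_final = continuum.total_density(sol.profiles[-1])
    t_final = float(sol.times[-1])
    if sol.diagnostics["status"] != 1 and 0.05 <= C_final <= 0.95:
        dC = abs(float(np.mean(rates.lam * sol.profiles[-1] * np.asarray(F.value(sol.profiles[-1]), float))))
        if dC > 1e-6:
            raise UndecidedFateError(
                f"C({T:g}) = {C_final:.3f} still evolving (|dC/dt| = {dC:.2e}); "
                "increase the decision time T"
            )
    outcome = "survive" if C_final > 0.5 else "extinct"
    return FateOutcome(w=w, P_over_M=rates.P / rates.M, outcome=outcome,
                       C_final=C_final, decision_time=t_final)


def _classify_discrete(model, w, rates, F, T, L, n_rows, V, base_seed) -> FateOutcome:
    from . import _kernels
    from .hexlattice import neighbor_table, template_offsets

    G = _resolve_G(model)
    I = int(round(L / rates.delta))
    J = n_rows if n_rows is not None else I
    geom = HexGeometry(n_cols=I, n_rows=J, delta=rates.delta)
    config = abm.SimulationConfig(
        rates=rates, G=G, F=F, geometry=geom,
        n_realizations=V, base_seed=base_seed, t_end=T,
    )
    nbr_m, nbr_g = abm._neighbor_tables(config)
    gtab, ftab = abm._g_table(config), abm._f_table(config)
    col = np.tile(np.arange(I, dtype=np.int64), J)
    dummy_ifc = np.zeros((1, 1), dtype=np.int64)
    dummy_dxw = np.zeros((1, 1))
    dummy_flux = np.zeros(I)
    dummy_colacc = np.zeros(I)
    n_steps = int(round(T / rates.tau))
    record_steps = np.array([n_steps], dtype=np.int64)
    N = I * J
    q_lo = int(np.floor(EXTINCT_GUARD * N))
    q_hi = int(np.ceil(SURVIVE_GUARD * N))

    init = init_strip(geom, w)
    survived = 0
    c_finals = []
    t_last = 0.0
    for v in range(V):
        occ = init.occupancy.ravel().copy()
        prof = np.zeros((1, I))
        tot = np.zeros(1)
        seed = (base_seed + v) & (2**31 - 1)
        Q, step_done = _kernels.run_realization(
            occ, nbr_m, nbr_g, gtab, ftab, rates.M, rates.P,
            n_steps, record_steps, col, dummy_ifc, dummy_dxw,
            dummy_flux, dummy_colacc, False, prof, tot, seed, q_lo, q_hi,
        )
        c_fin = Q / N
        c_finals.append(c_fin)
        t_last = max(t_last, step_done * rates.tau)
        if step_done == n_steps and 0.05 <= c_fin <= 0.95:
            raise UndecidedFateError(
                f"realization {v}: Q/N = {c_fin:.3f} undecided at T = {T:g}"
            )
        if c_fin > 0.5:
            survived += 1
    frac = survived / V
    outcome = "survive" if frac > 0.5 else "extinct"
    return FateOutcome(
        w=w, P_over_M=rates.P / rates.M, outcome=outcome,
        C_final=float(np.mean(c_finals)), decision_time=t_last,
        survival_fraction=frac,
    )


def critical_width(
    model,
    P_over_M: float,
    M: float = 1.0,
    tol_w: float = 0.25,
    w_lo: float = 0.0,
    w_hi: float = 40.0,
    T: float = DECISION_TIME,
    L: float = 100.0,
    grid_n: int = 200,
) -> float:
    """Critical strip width w* separating extinction from survival.

    Bisection with the continuum engine between a known-extinct w_lo and a
    known-surviving w_hi; raises if the bracket endpoints do not actually
    bracket the transition (e.g. survival impossible at that rate ratio).
    """
    P = P_over_M * M

    def fate(w):
        return classify_fate(model, w, P=P, M=M, T=T, L=L, grid_n=grid_n).survived

    if fate(w_lo):
        raise ValueError(f"w_lo = {w_lo} already survives; no bracket")
    if not fate(w_hi):
        raise ValueError(f"w_hi = {w_hi} goes extinct; survival not reachable in bracket")
    lo, hi = float(w_lo), float(w_hi)
    while hi - lo > tol_w:
        mid = 0.5 * (lo + hi)
        if fate(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def phase_diagram(
    models: Sequence,
    w_values: Sequence[float],
    ratio_values: Sequence[float],
    M: float = 1.0,
    T: float = DECISION_TIME,
    L: float = 100.0,
    grid_n: int = 200,
) -> PhaseDiagram:
    """Classify every (w, P/M) node per model and extract the boundary.

    The boundary w*(P/M) is the midpoint between the last extinct and first
    surviving node along each ratio row (single-crossing rule); rows whose
    outcomes are not monotone in w are flagged in ``monotone_violations``
    and rows without a crossing yield NaN.
    """
    w_grid = np.asarray(sorted(w_values), dtype=float)
    ratio_grid = np.asarray(sorted(ratio_values), dtype=float)
    outcomes: dict = {}
    cfin: dict = {}
    boundary: dict = {}
    violations: dict = {}
    for model in models:
        key = model if isinstance(model, str) else getattr(model, "label", repr(model))
        out = np.zeros((ratio_grid.size, w_grid.size), dtype=int)
        cf = np.zeros_like(out, dtype=float)
        for a, ratio in enumerate(ratio_grid):
            for b, w in enumerate(w_grid):
                res = classify_fate(model, w, P=ratio * M, M=M, T=T, L=L, grid_n=grid_n)
                out[a, b] = 1 if res.survived else 0
                cf[a, b] = res.C_final
        outcomes[key] = out
        cfin[key] = cf
        bd = np.full(ratio_grid.size, np.nan)
        viol = []
        for a in range(ratio_grid.size):
            row = out[a]
            if np.any(np.diff(row) < 0):
                viol.extend((a, int(b)) for b in np.where(np.diff(row) < 0)[0])
            if row.min() == 0 and row.max() == 1:
                first_s = int(np.argmax(row))
                bd[a] = 0.5 * (w_grid[first_s - 1] + w_grid[first_s])
        boundary[key] = bd
        violations[key] = viol
    return PhaseDiagram(
        models=tuple(models),
        w_grid=w_grid,
        ratio_grid=ratio_grid,
        outcomes=outcomes,
        C_final=cfin,
        boundary=boundary,
        monotone_violations=violations,
    )
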