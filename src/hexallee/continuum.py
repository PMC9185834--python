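"""Deterministic twin of the lattice model: the 1D reaction-diffusion equation.

For initial conditions independent of the vertical coordinate on a periodic
domain, the column density obeys

    dC/dt = d/dx ( D(C) dC/dx ) + lam * C * F(C),          x in [0, L),

with the nonlinear diffusivity D(C) inherited from the movement crowding
function and the strong-Allee source R(C) = lam C F(C).  The solver uses a
conservative finite-volume discretization in space (arithmetic-mean interface
diffusivities, periodic wrap) and stiff adaptive time integration (BDF with a
periodic-tridiagonal Jacobian sparsity pattern).

The well-mixed reference dC/dt = lam C F(C) is the zero-gradient limit of the
PDE and doubles as the classical strong-Allee ODE: extinction for C(0) below
the Allee threshold A, survival (C -> 1) above it.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .crowding import CrowdingFunctionF, DiffusivityFunction

__all__ = [
    "Grid1D",
    "PDESolution",
    "FluxDecomposition",
    "strip_profile",
    "total_density",
    "solve_pde",
    "analytic_flux",
    "solve_wellmixed_ode",
]

_NEG_TOL = 1e-7


@dataclasses.dataclass(frozen=True)
class Grid1D:
    """Uniform periodic grid: n nodes x_k = k h on [0, L), h = L / n."""

    L: float
    n: int

    def __post_init__(self):
        if self.L <= 0 or self.n < 4:
            raise ValueError("need L > 0 and at least 4 nodes")

    @property
    def h(self) -> float:
        return self.L / self.n

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.n) * self.h


@dataclasses.dataclass
class PDESolution:
    grid: Grid1D
    times: np.ndarray
    profiles: np.ndarray  # shape (n_times, n)
    diagnostics: dict


@dataclasses.dataclass
class FluxDecomposition:
    """J_x = -D(C) dC/dx split as -D0 (1 + H(C)) dC/dx."""

    x: np.ndarray
    Jx: np.ndarray
    linear: np.ndarray      # -D0 dC/dx
    correction: np.ndarray  # -D0 H(C) dC/dx


def strip_profile(grid: Grid1D, w: float) -> np.ndarray:
    """Indicator of the central strip [(L-w)/2, (L+w)/2), sampled at nodes.

    No smoothing is applied; for widths commensurate with the grid the mean
    equals w / L exactly.
    """
    if not 0.0 <= w <= grid.L:
        raise ValueError(f"strip width {w} outside [0, {grid.L}]")
    x = grid.x
    return ((x >= (grid.L - w) / 2.0) & (x < (grid.L + w) / 2.0)).astype(float)


def total_density(profile: np.ndarray) -> float:
    """Spatial mean of the density, exact for a uniform periodic grid."""
    return float(np.mean(profile))


def _rhs_factory(grid: Grid1D, D: DiffusivityFunction, F: CrowdingFunctionF | None, lam: float):
    h2 = grid.h**2

    def rhs(t, C):
        # Degenerate diffusivities (D ~ C^m) are evaluated on the non-negative
        # part of C so that roundoff-level undershoots at front toes cannot
        # produce spurious negative (or complex) diffusivities; the density
        # state itself is never clipped here.
        Dc = np.asarray(D.value(np.maximum(C, 0.0)), dtype=float)
        if Dc.min() < 0.0:
            raise ValueError(f"negative diffusivity encountered (min {Dc.min():.3g})")
        Dp = 0.5 * (Dc + np.roll(Dc, -1))  # interface k+1/2
        dCp = np.roll(C, -1) - C
        div = (Dp * dCp - np.roll(Dp * dCp, 1)) / h2
        if F is not None and lam != 0.0:
            return div + lam * C * np.asarray(F.value(C), dtype=float)
        return div

    return rhs


def _jac_sparsity(n: int):
    main = np.ones(n)
    J = sparse.diags([main, main[:-1], main[:-1]], [0, 1, -1], format="lil")
    J[0, n - 1] = 1.0
    J[n - 1, 0] = 1.0
    return J.tocsr()


def solve_pde(
    D: DiffusivityFunction,
    F: CrowdingFunctionF | None,
    lam: float,
    initial: np.ndarray,
    t_end: float,
    record_times: Sequence[float] | None = None,
    grid: Grid1D | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
    events: Sequence[Callable] | None = None,
) -> PDESolution:
    """Method-of-lines solution of the 1D nonlinear reaction-diffusion PDE.

    Parameters mirror the model: D(C) from the crowding framework, growth
    crowding function F with rate lam (pass ``F=None`` or ``lam=0`` for pure
    diffusion), an initial profile on the grid, and the output times.
    Degenerate diffusivities (D(0) = 0) can undershoot slightly at front
    toes; undershoots beyond -1e-7 trigger a warning, and outputs are clipped
    to [0, 1] after integration (never inside the right-hand side, which
    would corrupt the integrator's error control).
    """
    initial = np.asarray(initial, dtype=float)
    if grid is None:
        raise ValueError("a Grid1D must be supplied")
    if initial.shape != (grid.n,):
        raise ValueError("initial profile must live on the grid nodes")
    if initial.min() < 0.0 or initial.max() > 1.0:
        raise ValueError("initial profile must take values in [0, 1]")
    if record_times is None:
        record_times = [t_end]
    t_eval = np.asarray(sorted(set(float(t) for t in record_times)), dtype=float)
    if t_eval.max() > t_end:
        raise ValueError("record_times must not exceed t_end")

    rhs = _rhs_factory(grid, D, F, lam)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        initial,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac_sparsity=_jac_sparsity(grid.n) if method in ("BDF", "Radau") else None,
        events=events,
    )
    if not sol.success:
        raise RuntimeError(f"PDE integration failed: {sol.message}")

    if sol.status == 1:  # terminated early by an event: append the terminal state
        k = _first_event(sol)
        y = np.asarray(sol.y, dtype=float)
        base = y.T if y.size else np.empty((0, grid.n))
        profiles = np.vstack([base, np.asarray(sol.y_events[k])[:1]])
        times = np.append(np.asarray(sol.t, dtype=float), sol.t_events[k][0])
    else:
        profiles = sol.y.T.copy()
        times = sol.t
    mn = profiles.min(initial=0.0)
    if mn < -_NEG_TOL:
        warnings.warn(
            f"density undershoot {mn:.3g} below -{_NEG_TOL:g}; clipping outputs",
            RuntimeWarning,
        )
    profiles = np.clip(profiles, 0.0, 1.0)

    return PDESolution(
        grid=grid,
        times=np.asarray(times, dtype=float),
        profiles=profiles,
        diagnostics={
            "status": sol.status,
            "message": sol.message,
            "nfev": sol.nfev,
            "njev": sol.njev,
            "rtol": rtol,
            "atol": atol,
            "method": method,
            "min_density": float(mn),
        },
    )


def _first_event(sol):
    for k, te in enumerate(sol.t_events):
        if te.size:
            return k
    raise RuntimeError("terminated without a recorded event")


def analytic_flux(grid: Grid1D, profile: np.ndarray, D: DiffusivityFunction) -> FluxDecomposition:
    """J_x = -D(C) dC/dx at the nodes (second-order central differences).

    Also returns the linear/correction split J_x = -D0 (1 + H(C)) dC/dx; the
    two representations are algebraically identical.
    """
    C = np.asarray(profile, dtype=float)
    dCdx = (np.roll(C, -1) - np.roll(C, 1)) / (2.0 * grid.h)
    Dc = np.asarray(D.value(C), dtype=float)
    lin = -D.D0 * dCdx
    corr = -D.D0 * D.H(C) * dCdx
    return FluxDecomposition(x=grid.x, Jx=-Dc * dCdx, linear=lin, correction=corr)


def solve_wellmixed_ode(
    F: CrowdingFunctionF,
    lam: float,
    C0: float,
    t_end: float,
    record_times: Sequence[float] | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """The spatially uniform reference dC/dt = lam C F(C).

    With the strong-Allee F this is the classical bistable ODE: C0 < A decays
    to extinction, C0 > A saturates at carrying capacity, C0 = A is the
    unstable equilibrium.  Returns (times, C).
    """
    if not 0.0 <= C0 <= 1.0:
        raise ValueError("C0 must lie in [0, 1]")
    if record_times is None:
        record_times = [t_end]
    t_eval = np.asarray(sorted(set(float(t) for t in record_times)), dtype=float)
    sol = solve_ivp(
        lambda t, y: lam * y * np.asarray(F.value(y), dtype=float),
        (0.0, float(t_end)),
        [C0],
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, np.clip(sol.y[0], 0.0, 1.0)
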