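"""Crowding functions, nonlinear diffusivities, and the maps between them.

In the lattice model, the ability of an individual to move or proliferate is
modulated by the occupied fraction ``C`` of a neighbourhood template.  A
*movement crowding function* ``G(C) in [0, 1]`` scales the per-step movement
probability, and a *growth crowding function* ``F(C) in [-1, 1]`` scales the
per-step growth probability, with the sign of ``F`` selecting birth (``F > 0``)
or death (``F < 0``).

In the continuum limit the movement mechanism gives rise to a nonlinear
diffusivity

    D(C) = D0 * [ C G'(C) + (1 + C) / (1 - C) * G(C) ],

with reference diffusivity ``D0 = M Delta^2 / (4 tau)``.  This module provides
that forward map, its inverse for power-law diffusivities ``D = D0 C^m``
(through the Gauss hypergeometric function 2F1), the flux correction
``H(C) = D(C)/D0 - 1``, the strong-Allee growth function, and a catalogue of
closed-form (G, D) pairs.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable

import numpy as np
from scipy import special

__all__ = [
    "CrowdingFunctionG",
    "CrowdingFunctionF",
    "DiffusivityFunction",
    "RateConstants",
    "CrowdingValidityWarning",
    "CATALOGUE_NAMES",
    "diffusivity_from_crowding",
    "crowding_from_powerlaw",
    "crowding_g_from_powerlaw",
    "powerlaw_diffusivity",
    "flux_correction",
    "strong_allee_growth",
    "catalogue",
    "finite_difference_derivative",
    "tabulate",
    "to_config",
    "g_from_config",
    "pair_from_config",
]

ArrayLike = "float | np.ndarray"


class CrowdingValidityWarning(UserWarning):
    """Advisory warning for crowding functions outside their physical range."""


# ---------------------------------------------------------------------------
# numerical helpers


def finite_difference_derivative(f: Callable, C, h: float = 1e-5):
    """Fourth-order finite-difference derivative of ``f`` on [0, 1].

    Central stencils are used in the interior and one-sided fourth-order
    stencils within ``2 h`` of the endpoints, so user-supplied crowding
    functions only ever get evaluated inside their domain of definition.
    """
    C = np.asarray(C, dtype=float)
    scalar = C.ndim == 0
    C = np.atleast_1d(C)
    out = np.empty_like(C)

    left = C < 2.0 * h
    right = C > 1.0 - 2.0 * h
    mid = ~(left | right)

    if np.any(mid):
        x = C[mid]
        out[mid] = (
            f(x - 2 * h) - 8.0 * f(x - h) + 8.0 * f(x + h) - f(x + 2 * h)
        ) / (12.0 * h)
    if np.any(left):
        x = C[left]
        out[left] = (
            -25.0 * f(x)
            + 48.0 * f(x + h)
            - 36.0 * f(x + 2 * h)
            + 16.0 * f(x + 3 * h)
            - 3.0 * f(x + 4 * h)
        ) / (12.0 * h)
    if np.any(right):
        x = C[right]
        out[right] = (
            25.0 * f(x)
            - 48.0 * f(x - h)
            + 36.0 * f(x - 2 * h)
            - 16.0 * f(x - 3 * h)
            + 3.0 * f(x - 4 * h)
        ) / (12.0 * h)
    return out[0] if scalar else out


_SERIES_CUT = 1e-4
_SERIES_K = np.arange(1, 9)


def _phi(C):
    """phi(C) = (1 - C) log(1 - C) / C, the kernel of the power-law inverses.

    phi(0) = -1 and phi(1) = 0 as analytic limits; a truncated power series
    is used for small C where log(1 - C)/C suffers catastrophic cancellation.
    The series is phi = -1 + sum_k C^k / (k (k + 1)).
    """
    C = np.asarray(C, dtype=float)
    scalar = C.ndim == 0
    C = np.atleast_1d(C)
    out = np.empty_like(C)
    small = np.abs(C) < _SERIES_CUT
    one = C >= 1.0
    mid = ~(small | one)
    if np.any(small):
        x = C[small, None]
        out[small] = -1.0 + (x ** _SERIES_K / (_SERIES_K * (_SERIES_K + 1))).sum(axis=1)
    if np.any(mid):
        x = C[mid]
        out[mid] = (1.0 - x) * np.log1p(-x) / x
    out[one] = 0.0
    return out[0] if scalar else out


def _psi(C):
    """psi(C) = (1 - 1/C^2) log(1 - C) - (1 - C)/C.

    This combination appears in the closed-form derivatives of the power-law
    crowding functions.  psi(0) = 3/2 and psi(1) = 0 as limits; for small C
    the series psi = 3/2 - 2 sum_k C^k / (k (k + 2)) avoids the 1/C
    cancellation.
    """
    C = np.asarray(C, dtype=float)
    scalar = C.ndim == 0
    C = np.atleast_1d(C)
    out = np.empty_like(C)
    small = np.abs(C) < _SERIES_CUT
    one = C >= 1.0
    mid = ~(small | one)
    if np.any(small):
        x = C[small, None]
        out[small] = 1.5 - 2.0 * (x ** _SERIES_K / (_SERIES_K * (_SERIES_K + 2))).sum(axis=1)
    if np.any(mid):
        x = C[mid]
        out[mid] = (1.0 - 1.0 / x**2) * np.log1p(-x) - (1.0 - x) / x
    out[one] = 0.0
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# domain types


@dataclasses.dataclass(frozen=True)
class CrowdingFunctionG:
    """A movement crowding function G(C) on [0, 1].

    Parameters
    ----------
    value
        Vectorised map C -> G(C), dimensionless.
    derivative
        Vectorised map C -> dG/dC.  When ``None`` a fourth-order
        finite-difference derivative is used.
    label
        Human-readable name.
    reduced
        Optional vectorised map C -> G(C)/(1 - C).  All catalogue members
        contain an explicit vacancy factor (1 - C); supplying the reduced
        form lets the forward map to D(C) cancel the (1 + C)/(1 - C) pole
        analytically at C = 1.
    """

    value: Callable
    derivative: Callable | None = None
    label: str = "G"
    reduced: Callable | None = None

    def __call__(self, C):
        return self.value(C)

    def d(self, C):
        """Derivative dG/dC (closed form when available, else finite diff)."""
        if self.derivative is not None:
            return self.derivative(C)
        return finite_difference_derivative(self.value, C)

    def validate(self, n: int = 401, tol_range: float = 1e-9, tol_deriv: float = 1e-6) -> bool:
        """Advisory validity check: range G in [0, 1] and derivative consistency.

        Emits :class:`CrowdingValidityWarning` on violation and returns the
        overall verdict; it never raises, because deliberately "unphysical"
        crowding functions (e.g. the power-law inverses with G(0) = 0) are
        legitimate modelling objects.
        """
        C = np.linspace(0.0, 1.0, n)
        g = np.asarray(self.value(C), dtype=float)
        ok = True
        if not np.all(np.isfinite(g)):
            warnings.warn(f"{self.label}: non-finite values on [0, 1]", CrowdingValidityWarning)
            ok = False
        elif g.min() < -tol_range or g.max() > 1.0 + tol_range:
            warnings.warn(
                f"{self.label}: range [{g.min():.3g}, {g.max():.3g}] outside [0, 1]",
                CrowdingValidityWarning,
            )
            ok = False
        if self.derivative is not None:
            Ci = np.linspace(0.05, 0.95, 91)
            fd = finite_difference_derivative(self.value, Ci)
            if np.max(np.abs(fd - self.derivative(Ci))) > tol_deriv:
                warnings.warn(
                    f"{self.label}: closed-form derivative disagrees with finite differences",
                    CrowdingValidityWarning,
                )
                ok = False
        return ok


@dataclasses.dataclass(frozen=True)
class CrowdingFunctionF:
    """A growth crowding function F(C) in [-1, 1] with Allee threshold A."""

    value: Callable
    allee_threshold: float = 0.4
    label: str = "F"

    def __call__(self, C):
        return self.value(C)

    def validate(self, n: int = 401, tol: float = 1e-9) -> bool:
        C = np.linspace(0.0, 1.0, n)
        f = np.asarray(self.value(C), dtype=float)
        if np.max(np.abs(f)) > 1.0 + tol:
            warnings.warn(
                f"{self.label}: |F| exceeds 1 (max {np.max(np.abs(f)):.3g})",
                CrowdingValidityWarning,
            )
            return False
        return True


@dataclasses.dataclass(frozen=True)
class DiffusivityFunction:
    """A population-level nonlinear diffusivity D(C) with reference D0."""

    value: Callable
    D0: float = 1.0
    label: str = "D"

    def __call__(self, C):
        return self.value(C)

    def H(self, C):
        """Flux correction H(C) = D(C)/D0 - 1 relative to linear diffusion."""
        return np.asarray(self.value(C), dtype=float) / self.D0 - 1.0

    def rescaled(self, D0: float) -> "DiffusivityFunction":
        """The same shape D(C)/D0 attached to a different reference constant."""
        ratio = D0 / self.D0
        inner = self.value
        return DiffusivityFunction(
            value=lambda C, _f=inner, _r=ratio: _r * np.asarray(_f(C), dtype=float),
            D0=D0,
            label=self.label,
        )


@dataclasses.dataclass(frozen=True)
class RateConstants:
    """Per-step event probabilities and the lattice scales they live on.

    M and P are the probabilities that an *isolated* agent attempts a movement
    (resp. growth) event during one time step tau; delta is the lattice
    spacing.  The continuum-limit constants are ``D0 = M delta^2 / (4 tau)``
    and ``lam = P / tau``.  The limit is only quantitative when growth is slow
    relative to movement (P << M), so a warning is emitted when P > M/10.
    """

    M: float
    P: float
    delta: float = 1.0
    tau: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.M <= 1.0 and 0.0 <= self.P <= 1.0):
            raise ValueError("M and P are per-step probabilities and must lie in [0, 1]")
        if self.delta <= 0 or self.tau <= 0:
            raise ValueError("delta and tau must be positive")
        if self.P > self.M / 10.0:
            warnings.warn(
                f"P = {self.P} is not small relative to M = {self.M}; "
                "the continuum limit assumes P << M",
                CrowdingValidityWarning,
            )

    @property
    def D0(self) -> float:
        return self.M * self.delta**2 / (4.0 * self.tau)

    @property
    def lam(self) -> float:
        return self.P / self.tau


# ---------------------------------------------------------------------------
# the forward map G -> D


def diffusivity_from_crowding(G: CrowdingFunctionG, D0: float = 1.0) -> DiffusivityFunction:
    """Map a movement crowding function to its continuum diffusivity.

    D(C) = D0 [ C G'(C) + (1 + C)/(1 - C) G(C) ].

    When ``G.reduced`` (i.e. G/(1 - C)) is available the pole at C = 1 is
    cancelled analytically.  Otherwise the second term is evaluated at
    ``C = 1 - 1e-9`` when C = 1 is requested, and a validity warning is
    emitted if the result exceeds 1e6 — which diagnoses G(1) != 0, a crowding
    function with no room left to move yet nonzero motility.
    """
    eps = 1e-9

    if G.reduced is not None:
        def value(C, _G=G, _D0=D0):
            C = np.asarray(C, dtype=float)
            return _D0 * (C * _G.d(C) + (1.0 + C) * np.asarray(_G.reduced(C), dtype=float))
    else:
        def value(C, _G=G, _D0=D0):
            C = np.asarray(C, dtype=float)
            scalar = C.ndim == 0
            C = np.atleast_1d(C)
            Csafe = np.minimum(C, 1.0 - eps)
            pole = (1.0 + Csafe) / (1.0 - Csafe) * np.asarray(_G.value(Csafe), dtype=float)
            if np.any(np.abs(pole) > 1e6):
                warnings.warn(
                    f"{_G.label}: (1+C)/(1-C) G(C) exceeds 1e6 near C = 1; "
                    "G(1) != 0 has no finite diffusivity limit",
                    CrowdingValidityWarning,
                )
            out = _D0 * (C * np.asarray(_G.d(Csafe), dtype=float) + pole)
            if not np.all(np.isfinite(out[(C > 0) & (C < 1)])):
                raise ValueError(f"{_G.label}: non-finite diffusivity at interior C")
            return out[0] if scalar else out

    return DiffusivityFunction(value=value, D0=D0, label=f"D[{G.label}]")


def flux_correction(D: DiffusivityFunction) -> Callable:
    """The correction H(C) = D(C)/D0 - 1 in J_x = -D0 (1 + H(C)) dC/dx.

    H > 0 means the nonlinear flux exceeds the linear-diffusion flux at equal
    density gradient (faster spreading), H < 0 means it is suppressed.
    """
    if D.D0 <= 0:
        raise ValueError("flux correction requires a positive reference D0")
    return D.H


# ---------------------------------------------------------------------------
# the inverse map for power-law diffusivities


def crowding_from_powerlaw(m: float, C):
    """Crowding function whose continuum diffusivity is D = D0 C^m.

    G(C) = C^m (1 - C)^2 2F1(2, m+1; m+2; C) / (m + 1),

    evaluated with the analytic endpoint limits G(1) = 0 for every m >= 0 and
    G(0) = 0 for m > 0 (G(0) = 1 for m = 0, where the formula collapses to
    G = 1 - C).  Near C = 0 a truncated Gauss series is used; near C = 1 the
    (1 - C)^2 prefactor tames the 2F1 pole, which scipy evaluates through its
    connection formulae, so no NaN is ever returned on [0, 1].
    """
    if m < 0:
        raise ValueError("power-law exponent m must be >= 0")
    C = np.asarray(C, dtype=float)
    scalar = C.ndim == 0
    C = np.atleast_1d(C).astype(float)
    if C.min() < 0.0 or C.max() > 1.0:
        raise ValueError("C must lie in [0, 1]")
    out = np.empty_like(C)

    zero = C == 0.0
    one = C == 1.0
    small = (~zero) & (C < _SERIES_CUT)
    mid = (~zero) & (~one) & (~small)

    out[zero] = 1.0 if m == 0 else 0.0
    out[one] = 0.0
    if np.any(small):
        # Gauss series of 2F1(2, m+1; m+2; C): term ratio (2+k)(m+1+k) C / ((m+2+k)(k+1))
        x = C[small]
        term = np.ones_like(x)
        s = np.ones_like(x)
        for k in range(6):
            term = term * (2.0 + k) * (m + 1.0 + k) / ((m + 2.0 + k) * (k + 1.0)) * x
            s += term
        out[small] = x**m * (1.0 - x) ** 2 * s / (m + 1.0)
    if np.any(mid):
        x = C[mid]
        out[mid] = x**m * (1.0 - x) ** 2 * special.hyp2f1(2.0, m + 1.0, m + 2.0, x) / (m + 1.0)
    return out[0] if scalar else out


def _powerlaw_closed_forms(m: int):
    """Closed-form (value, derivative, reduced) for integer m in {1, 2, 3}.

    The logarithmic closed forms are preferred over the hypergeometric
    representation for numerical stability at both endpoints; the helper
    kernels phi and psi carry the small-C series expansions.
    """
    if m == 1:
        value = lambda C: (1.0 - np.asarray(C, float)) * (1.0 + _phi(C))
        reduced = lambda C: 1.0 + _phi(C)
        deriv = lambda C: -1.0 + _psi(C)
    elif m == 2:
        value = lambda C: (1.0 - np.asarray(C, float)) * (2.0 - np.asarray(C, float) + 2.0 * _phi(C))
        reduced = lambda C: 2.0 - np.asarray(C, float) + 2.0 * _phi(C)
        deriv = lambda C: -3.0 + 2.0 * np.asarray(C, float) + 2.0 * _psi(C)
    elif m == 3:
        def value(C):
            C = np.asarray(C, float)
            return (1.0 - C) * ((6.0 - 3.0 * C - C**2) / 2.0 + 3.0 * _phi(C))

        def reduced(C):
            C = np.asarray(C, float)
            return (6.0 - 3.0 * C - C**2) / 2.0 + 3.0 * _phi(C)

        def deriv(C):
            C = np.asarray(C, float)
            return (-9.0 + 4.0 * C + 3.0 * C**2) / 2.0 + 3.0 * _psi(C)
    else:
        raise ValueError("closed forms available for m in {1, 2, 3}")
    return value, deriv, reduced


def crowding_g_from_powerlaw(m: float) -> CrowdingFunctionG:
    """The inverse-map crowding function for D = D0 C^m as a full object.

    Integer m in {1, 2, 3} get logarithmic closed forms (value, derivative
    and reduced form); other exponents use the hypergeometric representation
    with a finite-difference derivative and the always-regular reduced form
    G/(1 - C) = C^m (1 - C) 2F1 / (m + 1).
    """
    if m in (1, 2, 3) and float(m) == int(m):
        value, deriv, reduced = _powerlaw_closed_forms(int(m))
        return CrowdingFunctionG(value=value, derivative=deriv, reduced=reduced,
                                 label=f"powerlaw-m{int(m)}")

    def value(C, _m=m):
        return crowding_from_powerlaw(_m, C)

    def reduced(C, _m=m):
        C = np.asarray(C, dtype=float)
        scalar = C.ndim == 0
        C = np.atleast_1d(C)
        out = np.empty_like(C)
        zero = C == 0.0
        out[zero] = 1.0 if _m == 0 else 0.0
        nz = ~zero
        if np.any(nz):
            x = C[nz]
            out[nz] = x**_m * (1.0 - x) * special.hyp2f1(2.0, _m + 1.0, _m + 2.0, x) / (_m + 1.0)
        return out[0] if scalar else out

    return CrowdingFunctionG(value=value, derivative=None, reduced=reduced,
                             label=f"powerlaw-m{m:g}")


def powerlaw_diffusivity(m: float, D0: float = 1.0) -> DiffusivityFunction:
    """D(C) = D0 C^m (degenerate at C = 0 for m > 0)."""
    return DiffusivityFunction(
        value=lambda C, _m=m, _D0=D0: _D0 * np.asarray(C, dtype=float) ** _m,
        D0=D0,
        label=f"D0*C^{m:g}",
    )


# ---------------------------------------------------------------------------
# growth crowding function


def strong_allee_growth(A: float = 0.4) -> CrowdingFunctionF:
    """Strong-Allee growth crowding function F(C) = 2.5 (1 - C)(C - A).

    F is negative below the Allee threshold A (isolated individuals tend to
    die, with F(0) = -2.5 A), positive between A and the carrying capacity
    C = 1, and vanishes at both roots.  Because P |F| is a probability the
    construction rejects any A for which |F| exceeds 1 anywhere on [0, 1]
    (this bounds A <= 0.4 and makes F(0) = -1 exactly at A = 0.4).
    """
    if not 0.0 < A < 1.0:
        raise ValueError("Allee threshold A must lie in (0, 1)")
    max_abs = max(2.5 * A, 2.5 * (1.0 - A) ** 2 / 4.0)
    if max_abs > 1.0 + 1e-12:
        raise ValueError(
            f"|F| reaches {max_abs:.4g} > 1 on [0, 1] for A = {A}; "
            "P*F would not be a probability"
        )
    return CrowdingFunctionF(
        value=lambda C, _A=A: 2.5 * (1.0 - np.asarray(C, dtype=float)) * (np.asarray(C, dtype=float) - _A),
        allee_threshold=A,
        label=f"allee(A={A:g})",
    )


# ---------------------------------------------------------------------------
# built-in catalogue


CATALOGUE_NAMES = (
    "linear",
    "increasing",
    "decreasing",
    "powerlaw-m1",
    "powerlaw-m2",
    "powerlaw-m3",
)


def catalogue(name: str, D0: float = 1.0) -> tuple[CrowdingFunctionG, DiffusivityFunction]:
    """A named (G, D) pair with closed-form derivative and reduced form.

    ============  ==========================  ===============================
    name          G(C)                        D(C)/D0
    ============  ==========================  ===============================
    linear        1 - C                       1
    increasing    (1 - C)(1 + C/2)            1 + C (1 - C/2)
    decreasing    (1 - C)(1 - C/2)            1 - C (1 - C/2)
    powerlaw-mX   hypergeometric inverse      C^X            (X = 1, 2, 3)
    ============  ==========================  ===============================

    The "increasing"/"decreasing" labels refer to the monotonicity of D(C):
    a concave-down G (crowding hampers movement less than linearly) yields a
    diffusivity that grows with density, and vice versa.
    """
    if name == "linear":
        G = CrowdingFunctionG(
            value=lambda C: 1.0 - np.asarray(C, dtype=float),
            derivative=lambda C: np.full_like(np.asarray(C, dtype=float), -1.0),
            reduced=lambda C: np.ones_like(np.asarray(C, dtype=float)),
            label="linear",
        )
        D = DiffusivityFunction(
            value=lambda C, _D0=D0: np.full_like(np.asarray(C, dtype=float), _D0),
            D0=D0, label="D0",
        )
        return G, D
    if name == "increasing":
        G = CrowdingFunctionG(
            value=lambda C: (1.0 - np.asarray(C, float)) * (1.0 + np.asarray(C, float) / 2.0),
            derivative=lambda C: -0.5 - np.asarray(C, dtype=float),
            reduced=lambda C: 1.0 + np.asarray(C, dtype=float) / 2.0,
            label="increasing",
        )
        D = DiffusivityFunction(
            value=lambda C, _D0=D0: _D0 * (1.0 + np.asarray(C, float) * (1.0 - np.asarray(C, float) / 2.0)),
            D0=D0, label="D0[1+C(1-C/2)]",
        )
        return G, D
    if name == "decreasing":
        G = CrowdingFunctionG(
            value=lambda C: (1.0 - np.asarray(C, float)) * (1.0 - np.asarray(C, float) / 2.0),
            derivative=lambda C: -1.5 + np.asarray(C, dtype=float),
            reduced=lambda C: 1.0 - np.asarray(C, dtype=float) / 2.0,
            label="decreasing",
        )
        D = DiffusivityFunction(
            value=lambda C, _D0=D0: _D0 * (1.0 - np.asarray(C, float) * (1.0 - np.asarray(C, float) / 2.0)),
            D0=D0, label="D0[1-C(1-C/2)]",
        )
        return G, D
    if name in ("powerlaw-m1", "powerlaw-m2", "powerlaw-m3"):
        m = int(name[-1])
        return crowding_g_from_powerlaw(m), powerlaw_diffusivity(m, D0)
    raise ValueError(f"unknown catalogue entry {name!r}; choose from {CATALOGUE_NAMES}")


# ---------------------------------------------------------------------------
# serialization and tabulation


def to_config(obj) -> dict:
    """Serialize a catalogue/power-law/expression crowding object to a record."""
    from . import _expr

    if isinstance(obj, CrowdingFunctionG):
        label = obj.label
        if label in CATALOGUE_NAMES and not label.startswith("powerlaw"):
            return {"kind": "catalogue", "name": label}
        if label.startswith("powerlaw-m"):
            return {"kind": "powerlaw", "m": float(label[len("powerlaw-m"):])}
        if label.startswith("expr:"):
            return {"kind": "expression", "expression": label[len("expr:"):]}
        raise ValueError(f"cannot serialize ad-hoc crowding function {label!r}")
    if isinstance(obj, DiffusivityFunction):
        raise TypeError("serialize the crowding function; D is reconstructed from it")
    raise TypeError(f"unsupported object {type(obj)!r}")


def g_from_config(cfg: dict) -> CrowdingFunctionG:
    """Rebuild a movement crowding function from a config record."""
    from . import _expr

    kind = cfg.get("kind")
    if kind == "catalogue":
        return catalogue(cfg["name"])[0]
    if kind == "powerlaw":
        return crowding_g_from_powerlaw(float(cfg["m"]))
    if kind == "expression":
        fn = _expr.compile_expression(cfg["expression"])
        return CrowdingFunctionG(value=fn, label="expr:" + cfg["expression"])
    raise ValueError(f"unknown crowding config kind {kind!r}")


def pair_from_config(cfg: dict, D0: float = 1.0) -> tuple[CrowdingFunctionG, DiffusivityFunction]:
    """Rebuild a (G, D) pair; catalogue/power-law use closed-form D."""
    kind = cfg.get("kind")
    if kind == "catalogue":
        return catalogue(cfg["name"], D0=D0)
    if kind == "powerlaw":
        m = float(cfg["m"])
        return crowding_g_from_powerlaw(m), powerlaw_diffusivity(m, D0)
    G = g_from_config(cfg)
    return G, diffusivity_from_crowding(G, D0=D0)


def tabulate(G: CrowdingFunctionG, D: DiffusivityFunction, n: int = 101):
    """Tabulate C, G, dG/dC, D and H on a uniform grid as a DataFrame."""
    import pandas as pd

    C = np.linspace(0.0, 1.0, n)
    return pd.DataFrame(
        {
            "C": C,
            "G": np.asarray(G.value(C), dtype=float),
            "dGdC": np.asarray(G.d(C), dtype=float),
            "D": np.asarray(D.value(C), dtype=float),
            "H": D.H(C),
        }
    )
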