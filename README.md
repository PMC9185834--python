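# hexallee

Discrete–continuum modelling of bistable population dynamics with
crowding-driven nonlinear diffusion on a periodic hexagonal lattice.

## The problem

Whether a population survives or goes extinct is, in the classical strong
Allee effect model, decided by an unstable threshold density `A`: the ODE
`dC/dt = λ C F(C)` with `F(C) = 2.5 (1 − C)(C − A)` sends any initial
density below `A` to extinction and any density above it to the carrying
capacity `C = 1`. With space, migration matters too — a population released
in a strip of width `w` must occupy more than a *critical* initial area to
survive, and how fast it spreads (its diffusivity) shifts that threshold.

`hexallee` implements a stochastic lattice model in which this connection is
mechanistic rather than phenomenological. Agents occupy sites of a periodic
hexagonal lattice (spacing `Δ`, at most one agent per site). Per time step
`τ`, each of the `Q(t)` agents is given (on average) one movement and one
growth opportunity: an agent at site `s` moves with probability `M·G(K_s)`
to a uniformly chosen vacant neighbour, and proliferates/dies with
probability `P·|F(K_s)|`, where `K_s` is the occupied fraction of a
neighbourhood template of `3r(r+1)` sites (`r = 1` for movement, `r = 4`
for growth). The *movement crowding function* `G(C) ∈ [0, 1]` encodes how
local crowding hampers motility.

In the continuum limit (`Δ, τ → 0`, `P ≪ M`) the column density obeys

    ∂C/∂t = ∂/∂x ( D(C) ∂C/∂x ) + λ C F(C),
    D(C)  = D₀ [ C G′(C) + (1 + C)/(1 − C) · G(C) ],

with `D₀ = MΔ²/(4τ)` and `λ = P/τ`. The map `G ↔ D` runs both ways: the
package inverts power-law diffusivities `D = D₀Cᵐ` through the Gauss
hypergeometric function,

    G(C) = Cᵐ (1 − C)² · ₂F₁(2, m+1; m+2; C) / (m + 1),

and the flux decomposition `J_x = −D₀ (1 + H(C)) ∂C/∂x` with
`H(C) = D(C)/D₀ − 1` explains *why* a given `D(C)` promotes or suppresses
extinction: crowding functions that enhance the flux (`H > 0`) thin the
population below the Allee threshold over a larger region.

## What's in the package

| module                | contents                                                              |
|-----------------------|-----------------------------------------------------------------------|
| `hexallee.crowding`   | crowding/diffusivity algebra: forward map `G → D`, power-law inverse, flux correction `H`, strong-Allee `F`, built-in catalogue |
| `hexallee.hexlattice` | periodic hex geometry, `3r(r+1)` templates, local density, strip and well-mixed initial conditions, snapshot formats |
| `hexallee.abm`        | numba-accelerated random-sequential-update engine, ensemble statistics, empirical flux measurement |
| `hexallee.continuum`  | finite-volume method-of-lines solver for the 1D PDE, analytic flux, well-mixed ODE reference |
| `hexallee.phase`      | fate classification (continuum or discrete engine), critical-width bisection, `(w, P/M)` phase diagrams |
| `hexallee.cli`        | `hexallee` command group with run manifests (see `FORMATS.md`)       |

## Worked example

```python
import numpy as np
import hexallee as hx

# the increasing-diffusivity crowding function G = (1-C)(1+C/2)
G, D = hx.catalogue("increasing", D0=0.25)
print(hx.diffusivity_from_crowding(G, D0=1.0).value(0.5))  # 1.375 = 1 + C(1-C/2)

# fate of a strip release, continuum engine (M=1, P=6/1000, L=100, A=0.4)
for name in ("decreasing", "linear", "increasing"):
    res = hx.classify_fate(name, w=20.0, P=0.006)
    print(name, res.outcome, round(res.C_final, 3))
```

prints

```
1.375
decreasing survive 0.99
linear survive 0.99
increasing extinct 0.01
```

i.e. from the same `w = 20` strip, only the model whose crowding function
*enhances* spreading (`H ≥ 0`) dies out — faster spreading dilutes the
population below the Allee threshold. The corresponding critical widths,
`hx.critical_width(name, 6e-3)`, come out ordered
`w*(decreasing) ≈ 17.0 < w*(linear) ≈ 19.0 < w*(increasing) ≈ 20.1`.

The same experiment runs stochastically:

```python
geom = hx.HexGeometry(100, 100)
cfg = hx.SimulationConfig(
    rates=hx.RateConstants(M=1.0, P=0.006),
    G=hx.catalogue("linear")[0], F=hx.strong_allee_growth(0.4),
    geometry=geom, n_realizations=40, base_seed=1,
    t_end=600.0, record_times=[600.0])
res = hx.simulate_ensemble(cfg, hx.init_strip(geom, 10.0))
print(res.total_density)  # [0.0222475] — decaying toward extinction
```

and agrees with the PDE column density to better than 0.01 (max norm) at
`V = 40` realizations.

From the shell:

```sh
hexallee tabulate-crowding --name powerlaw-m2 --out tab
hexallee solve-pde --diffusivity increasing --w 20 --tend 1e4 --out pde
hexallee phase-diagram --models linear,increasing,decreasing \
    --w 0:40:41 --ratio 0.001:0.04:40 --out phase
```

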