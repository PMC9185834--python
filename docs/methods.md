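# Methods

## Model summary

Agents live on a periodic two-dimensional hexagonal lattice with `I` columns,
`J` rows (even) and spacing `Δ`; site `(i, j)` sits at
`x = iΔ + (j mod 2)Δ/2`, `y = j·(√3/2)Δ`, so each site has six neighbours at
distance `Δ`. A neighbourhood template of diameter `r` contains the
`3r(r+1)` sites within hexagonal graph distance `r` (its `r` concentric
rings); local density `K_s` is the occupied fraction of that template.

One time step `τ` applies a random sequential update: `Q(t)` agent
selections with replacement for movement, then `Q(t)` selections with
replacement for growth (`Q(t)` frozen at each sweep's start, selections
drawn from the live-agent list so a death mid-sweep shrinks the pool). A
selected agent moves with probability `M·G(K_s)` to a uniformly chosen
vacant site of its movement template (`r = 1`), and undergoes a growth event
with probability `P·|F(K_s)|` on the growth template (`r = 4`): birth onto a
uniformly chosen vacant template site if `F > 0`, removal if `F < 0`. If a
move is accepted but the template has no vacancy (only possible when
`G(1) ≠ 0`), the event aborts silently. Because `K_s` takes only the values
`k/|N_r|`, the crowding functions are tabulated exactly at those densities
before the inner loops run.

With `F(C) = 2.5(1−C)(C−A)` the growth mechanism realizes a strong Allee
effect: death dominates below the threshold `A`, birth between `A` and the
carrying capacity. `A ≤ 0.4` is required so that `|F| ≤ 1` remains a valid
probability multiplier (at `A = 0.4`, `F(0) = −1` exactly).

## Parameters, units, defaults

| symbol | meaning | default | notes |
|--------|---------|---------|-------|
| `Δ`, `τ` | lattice spacing, time step | 1, 1 | dimensionless working units |
| `M`, `P` | per-step movement / growth attempt probabilities of an isolated agent | `M = 1`, `P = 6/1000` | continuum limit requires `P ≪ M`; a warning fires at `P > M/10` |
| `D₀ = MΔ²/(4τ)` | reference diffusivity | 1/4 | |
| `λ = P/τ` | growth rate | 6/1000 | |
| `r` (move, growth) | template diameters | 1, 4 | nearest-neighbour motility, distal daughter placement |
| `A` | Allee threshold | 0.4 | valid range (0, 0.4] |
| `L` | domain width | 100 | `I = L/Δ` columns |
| `J` | rows | `= I` | see below |
| `w` | initial strip width | — | occupied columns: `x ∈ [(L−w)/2, (L+w)/2)` |
| `V` | ensemble size | context-dependent | 40 for profile comparisons |

The number of rows is a declared convention: all reported quantities are
column averages of a vertically homogeneous problem, so `J` only sets the
effective ensemble size per column. The suite verifies this directly
(doubling `J` leaves block-averaged column profiles unchanged within the
V = 30 standard error, tolerance 0.03 on 5-column blocks).

## The crowding ↔ diffusivity maps

Forward: `D(C) = D₀[C G′(C) + (1+C)/(1−C)·G(C)]`. Every catalogue `G`
carries an explicit vacancy factor `(1−C)`, and the catalogue stores the
reduced form `G/(1−C)` so the pole at `C = 1` cancels analytically. For
user-supplied `G` without a reduced form, the pole term is evaluated at
`C = 1 − 10⁻⁹` and a validity warning fires if it exceeds 10⁶ (diagnosing
`G(1) ≠ 0`, motility without anywhere to go). Missing derivatives fall back
to fourth-order finite differences (step 10⁻⁵, one-sided at the endpoints).

Inverse (power law `D = D₀Cᵐ`, `m ≥ 0`):
`G(C) = Cᵐ(1−C)²·₂F₁(2, m+1; m+2; C)/(m+1)`. Endpoints are returned as the
analytic limits `G(0) = 0` (for `m > 0`; `G = 1−C` at `m = 0`) and
`G(1) = 0`. The interior uses `scipy.special.hyp2f1`; below `C = 10⁻⁴` a
six-term Gauss series avoids any cancellation. For `m ∈ {1, 2, 3}` the
catalogue prefers the logarithmic closed forms, written in terms of the
kernels `φ = (1−C)ln(1−C)/C` and `ψ = (1−1/C²)ln(1−C) − (1−C)/C`, each with
a truncated power series below `C = 10⁻⁴` (the raw expressions lose ~8
digits to `ln(1−C)/C` cancellation there). Their closed-form derivatives
were derived by hand and are cross-checked in the suite against finite
differences (10⁻⁶) and against the forward-map round trip to `D₀Cᵐ` (10⁻⁸).

Validity checking is advisory (warnings) because deliberately "unphysical"
crowding functions — the power-law inverses have `G(0) = 0`, isolated agents
that never move — are legitimate objects of study. The one hard error is a
probability overflow: `G ∉ [0,1]` or `P·|F| > 1` on the template densities.

## Continuum solver

Method of lines on a uniform periodic grid `x_k = kh` (default `h = 0.5`,
200 nodes for `L = 100`), conservative finite-volume form

    dC_k/dt = [D_{k+½}(C_{k+1} − C_k) − D_{k−½}(C_k − C_{k−1})]/h² + λ C_k F(C_k)

with arithmetic-mean interface diffusivities, integrated by `solve_ivp`
(BDF, `rtol = 10⁻⁸`, `atol = 10⁻¹⁰`) with the periodic-tridiagonal Jacobian
sparsity pattern. Numerical choices:

- **Degenerate diffusivities.** `D = D₀Cᵐ` produces compactly supported,
  sharp-fronted profiles whose toes can undershoot zero at roundoff level.
  The right-hand side evaluates `D` at `max(C, 0)` so such undershoots
  cannot manufacture negative diffusivities; the density state itself is
  never modified inside the RHS (which would corrupt the integrator's error
  control). Undershoots beyond −10⁻⁷ trigger a warning and outputs are
  clipped to `[0, 1]` after integration. A genuinely negative user-supplied
  `D` is an error.
- **Initial condition.** The strip is the exact indicator of
  `[(L−w)/2, (L+w)/2)` sampled at the nodes, no smoothing, so the initial
  mean is exactly `w/L` for commensurate widths. Half-open sampling makes
  the profile symmetric about the midpoint of its own support (`50 − h/2`),
  which the symmetry test uses as the reflection axis.
- **Convergence.** On smooth data the scheme is second order (measured order
  2.0 for linear, increasing and degenerate power-law `D`). On the
  indicator initial condition the *observed* order drops to ~1 because
  re-sampling the indicator at each resolution shifts its effective edge by
  `O(h)` — a property of the data, not the scheme — so the order test uses
  a smooth initial profile with the same rates and diffusivity.
- **Mass.** With `λ = 0` the discretization conserves the mean to 10⁻⁸ over
  `t = 200` for every catalogue `D`.

The well-mixed reference `dC/dt = λC F(C)` is solved with LSODA at
`rtol = 10⁻¹⁰`; for spatially uniform states the PDE trajectory matches it
to 10⁻⁶ for every catalogue diffusivity (the diffusion term vanishes
identically).

## Flux measurement

Analytic: `J_x = −D(C)∂C/∂x`, returned both directly and in the
decomposition `−D₀(1 + H(C))∂C/∂x` with `H = D/D₀ − 1` (the two agree to
machine precision; `H ≥ 0` exactly where `D ≥ D₀`).

Empirical: every executed move adds its signed horizontal weight `dx/Δ`
(±1 horizontal, ±½ diagonal) to the interface between the columns involved;
a diagonal move within one column is attributed to that column's right-edge
interface, so any move and its reverse tally at the same interface with
opposite signs (uniform occupancy therefore gives exactly zero mean). The
flux estimate is the accumulated weight divided by (window length × `J`),
in units of `Δ/τ`. Enumerating the mean-field transition probabilities on a
frozen smooth profile and weighting them with these same tables reproduces
`−D(C)∂C/∂x` to the accuracy of the Taylor truncation (max error < 2×10⁻⁴
on a sine profile), which pins down the bookkeeping; in live simulations the
measured flux from a strip release matches `−D₀∂⟨C⟩/∂x` within 0.003 at
`V = 20`, window 150 steps.

## Fate classification and phase diagram

The classifier integrates the continuum model from the strip indicator up to
`T = 10⁴` with terminal events at total density 0.01 (extinct) and 0.99
(survive); the binary outcome is `C(T) > ½`, and a run still inside
`[0.05, 0.95]` with `|d⟨C⟩/dt| > 10⁻⁶` at `T` raises `UndecidedFateError`
rather than guessing. The degenerate power-law models at `P/M = 10⁻³`,
`w = 20` genuinely need a longer horizon — their fronts fill the domain at
`t ≈ 1.15×10⁴` — so those runs are classified with `T = 2×10⁴`.

The discrete engine classifies by majority over `V` realizations with the
same density guards as early exits, and reports the survival fraction
rather than hiding near-boundary stochasticity. The suite checks
discrete/continuum agreement at two nodes far from the boundary with
`V = 5`; the engines agree there deterministically.

`critical_width` bisects `w` (default tolerance 0.25, bracket `[0, 40]`)
with the continuum engine; `phase_diagram` classifies a rectangular
`(w, P/M)` mesh, flags any non-monotone row, and takes the boundary as the
midpoint between the last extinct and first surviving node of each row. The
CLI default mesh is 41×40 over `w ∈ [0, 40]`, `P/M ∈ [10⁻³, 4×10⁻²]`; the
test suite exercises a 9×8 subgrid (and the three-model critical-width
ordering at `P/M = 6×10⁻³`) to keep the default run short — the full mesh
is a single CLI invocation away.

## Reproducibility

Each realization `v` seeds an independent Mersenne Twister stream with
`base_seed + v`; the draw order is fixed as (selection index, event
acceptance, destination choice). Identical configuration plus seed gives
bit-identical ensembles, which the suite asserts, and every CLI run writes a
manifest (config echo, seed, version, SHA-256 checksums) sufficient to
reproduce its outputs exactly.

## What the test problems do and do not show

The study conditions are the model's own: dimensionless lattice `Δ = τ = 1`,
`L = 100`, `A = 0.4`, `M = 1` with `P ∈ {1, 6}/1000`, strip releases
`w ∈ [0, 40]`, ensembles of 2–40 realizations. Passing tests show internal
consistency of the discrete and continuum descriptions under these
conditions — they do not calibrate the model to any experimental system,
and the continuum agreement degrades by construction when `P` approaches
`M` (growth too fast for the mean-field limit) or when occupancy
correlations matter at very small templates.

## Known limitations

- The movement flux tally is defined for nearest-neighbour motility
  (`r_move = 1`) only; larger movement templates simulate fine but their
  multi-interface crossings are not tallied.
- Fate classification near the critical width is intrinsically slow (the
  dynamics linger near the unstable equilibrium); bisection tolerance below
  ~0.1 multiplies solver time accordingly.
- The 2D continuum equation is never solved as a PDE; vertical homogeneity
  is assumed (and verified statistically for the strip problem). Non-strip
  initial shapes and multi-species extensions are out of scope.
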