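# Output formats

All commands write into a run directory together with `manifest.json`.

## manifest.json

| key       | meaning                                                        |
|-----------|----------------------------------------------------------------|
| `package`, `version` | producer identification                             |
| `command` | CLI command name                                               |
| `config`  | fully resolved configuration (file values overridden by flags) |
| `seed`    | base random seed (realization v uses `seed + v`)               |
| `started`, `finished` | ISO wall-clock timestamps                          |
| `outputs` | map file name -> SHA-256 checksum                              |

Re-running the same command with the `config` and `seed` recorded in a
manifest reproduces all stochastic outputs bit-identically.

## CSV files

`crowding.csv` (tabulate-crowding): `C, G, dGdC, D, H` — density, movement
crowding function, its derivative, diffusivity, flux correction
`H = D/D0 - 1`.

`profiles.csv` (solve-pde): long format `t, x, C` — column density of the
continuum model at the recorded times.

`total_density.csv` (solve-pde / simulate-abm): `t, total_density[, stderr]`
— spatial mean density; for the discrete model the standard error is over
realizations.

`column_density.csv` (simulate-abm): `t, x, mean_density, stderr` — ensemble
column density; `x` is the nominal column position `i * delta`.

`flux.csv` (measure-flux): `x, Jx, stderr, column_density` — empirical
horizontal flux at the interface between columns `q` and `q+1` (nominal
position `x = (q + 0.75) delta`), in units of `delta/tau`, with the
time-averaged column density over the measurement window.

`critical_width.csv` (critical-width): `model, P_over_M, w_star`.

`outcomes.csv` (phase-diagram): `model, w, P_over_M, outcome, C_final`.

`boundary.csv` (phase-diagram): `model, P_over_M, w_star` — midpoint between
the last extinct and the first surviving node of each ratio row; empty where
the row has no crossing.

## Snapshot formats

Site-list CSV: `i, j, x, y, occupied` with odd-row offset coordinates
(`x = i*delta + (j%2)*delta/2`, `y = j*sqrt(3)/2*delta`).

Run-length text (`.rle`): header `hexallee-rle I J delta`, then one line per
row of runs `COUNTxVALUE`.  Both formats round-trip losslessly.

## Exit codes

`0` success · `2` configuration error · `3` numerical failure ·
`4` undecided fate (dynamics not settled by the decision time).
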