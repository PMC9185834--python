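"""Periodic hexagonal lattice: geometry, templates, states and initial conditions.

Sites are stored in "odd-row offset" coordinates (i, j): row j sits at height
y = j * sqrt(3)/2 * delta, and odd rows are shifted by +delta/2 so that every
site has six nearest neighbours at distance delta.  Distance computations and
neighbourhood templates use axial coordinates internally; a template of
diameter r consists of the 3 r (r + 1) sites within hexagonal graph distance
r of a focal site (its r concentric rings).

The lattice is periodic in both directions.  The number of rows J must be
even so the offset pattern wraps consistently; vertical wrap identifies
(i, j) with (i, j + J), which is a genuine lattice translation for even J.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

__all__ = [
    "HexGeometry",
    "Template",
    "HexState",
    "template_offsets",
    "neighbor_table",
    "coordinates",
    "local_density",
    "init_strip",
    "init_uniform_random",
    "state_to_csv",
    "state_from_csv",
    "state_to_rle",
    "state_from_rle",
]

SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclasses.dataclass(frozen=True)
class HexGeometry:
    """Lattice dimensions: I columns, J rows (even), spacing delta."""

    n_cols: int
    n_rows: int
    delta: float = 1.0

    def __post_init__(self):
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.n_rows % 2 != 0:
            raise ValueError("n_rows must be even for a consistent periodic wrap")
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    @property
    def L(self) -> float:
        """Horizontal domain width I * delta."""
        return self.n_cols * self.delta

    @property
    def n_sites(self) -> int:
        return self.n_cols * self.n_rows


@dataclasses.dataclass(frozen=True)
class Template:
    """The neighbourhood N_r: 3 r (r + 1) sites within hex distance r."""

    r: int
    offsets: tuple  # axial (dq, dr) offsets, centre excluded
    @property
    def size(self) -> int:
        return len(self.offsets)


def template_offsets(r: int) -> Template:
    """Axial offsets of the sites at hexagonal graph distance 1..r.

    The count is exactly 3 r (r + 1): ring k holds 6 k sites.
    """
    if r < 1:
        raise ValueError("template diameter r must be >= 1")
    offs = []
    for dq in range(-r, r + 1):
        for dr in range(max(-r, -dq - r), min(r, -dq + r) + 1):
            if (dq, dr) != (0, 0):
                offs.append((dq, dr))
    t = Template(r=r, offsets=tuple(sorted(offs)))
    assert t.size == 3 * r * (r + 1)
    return t


def _to_axial(i, j):
    return i - (j - (j & 1)) // 2, j


def _from_axial(q, r):
    return q + (r - (r & 1)) // 2, r


def coordinates(geometry: HexGeometry, i: int, j: int) -> tuple[float, float]:
    """Cartesian position of site (i, j): odd rows shifted by +delta/2."""
    d = geometry.delta
    return i * d + (j % 2) * d / 2.0, j * SQRT3_2 * d


def neighbor_site(geometry: HexGeometry, i: int, j: int, dq: int, dr: int) -> tuple[int, int]:
    """The site reached from (i, j) by the axial offset (dq, dr), wrapped."""
    q, r = _to_axial(i, j)
    ni, nj = _from_axial(q + dq, r + dr)
    return ni % geometry.n_cols, nj % geometry.n_rows


def neighbor_table(geometry: HexGeometry, template: Template) -> np.ndarray:
    """Flat-index neighbour table of shape (n_sites, |N_r|).

    Site (i, j) has flat index j * I + i.  The lattice must exceed the
    template in both directions (I > 2r and J > 2r) so wrapped offsets map to
    distinct sites.
    """
    I, J, r = geometry.n_cols, geometry.n_rows, template.r
    if I <= 2 * r or J <= 2 * r:
        raise ValueError(f"lattice {I}x{J} too small for template r={r} under periodic wrap")
    jj, ii = np.meshgrid(np.arange(J), np.arange(I), indexing="ij")
    q = ii - (jj - (jj & 1)) // 2
    out = np.empty((J * I, template.size), dtype=np.int64)
    for t, (dq, dr) in enumerate(template.offsets):
        nr = jj + dr
        nq = q + dq
        ni = nq + (nr - (nr & 1)) // 2
        out[:, t] = ((nr % J) * I + (ni % I)).ravel()
    return out


@dataclasses.dataclass
class HexState:
    """Occupancy configuration: occupancy[j, i] in {0, 1}."""

    geometry: HexGeometry
    occupancy: np.ndarray

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=np.uint8)
        if occ.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError("occupancy shape must be (n_rows, n_cols)")
        if occ.max(initial=0) > 1:
            raise ValueError("occupancy must be binary")
        self.occupancy = occ

    @property
    def Q(self) -> int:
        """Current number of agents."""
        return int(self.occupancy.sum())

    def column_density(self) -> np.ndarray:
        """Occupied fraction per column (sites binned by column index i)."""
        return self.occupancy.mean(axis=0)

    def total_density(self) -> float:
        return float(self.occupancy.mean())

    def copy(self) -> "HexState":
        return HexState(self.geometry, self.occupancy.copy())


def local_density(state: HexState, site: tuple[int, int], template: Template) -> float:
    """Occupied fraction K_s of the template neighbours of ``site`` (wrapped)."""
    i, j = site
    geom = state.geometry
    if not (0 <= i < geom.n_cols and 0 <= j < geom.n_rows):
        raise ValueError(f"site {site} outside geometry")
    occ = state.occupancy
    total = 0
    for dq, dr in template.offsets:
        ni, nj = neighbor_site(geom, i, j, dq, dr)
        total += int(occ[nj, ni])
    return total / template.size


def init_strip(geometry: HexGeometry, w: float) -> HexState:
    """Fully occupied central vertical strip of width w, all else vacant.

    A column i (nominal position x = i * delta) is occupied when
    x in [(L - w)/2, (L + w)/2), which makes the occupied column count
    round(w / delta) and the initial total density w / L exactly for widths
    commensurate with the lattice.
    """
    L = geometry.L
    if not 0.0 <= w <= L:
        raise ValueError(f"strip width w = {w} outside [0, L = {L}]")
    x = np.arange(geometry.n_cols) * geometry.delta
    cols = (x >= (L - w) / 2.0) & (x < (L + w) / 2.0)
    occ = np.zeros((geometry.n_rows, geometry.n_cols), dtype=np.uint8)
    occ[:, cols] = 1
    return HexState(geometry, occ)


def init_uniform_random(geometry: HexGeometry, density: float, rng: np.random.Generator) -> HexState:
    """Well-mixed initial condition: each site occupied independently."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    occ = (rng.random((geometry.n_rows, geometry.n_cols)) < density).astype(np.uint8)
    return HexState(geometry, occ)


# ---------------------------------------------------------------------------
# snapshot formats


def state_to_csv(state: HexState, path) -> None:
    """Write a site-list CSV with columns i, j, x, y, occupied."""
    import pandas as pd

    geom = state.geometry
    jj, ii = np.meshgrid(np.arange(geom.n_rows), np.arange(geom.n_cols), indexing="ij")
    x = ii * geom.delta + (jj % 2) * geom.delta / 2.0
    y = jj * SQRT3_2 * geom.delta
    pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "x": x.ravel(),
            "y": y.ravel(),
            "occupied": state.occupancy.ravel(),
        }
    ).to_csv(path, index=False)


def state_from_csv(path) -> HexState:
    import pandas as pd

    df = pd.read_csv(path)
    I = int(df["i"].max()) + 1
    J = int(df["j"].max()) + 1
    if I > 1:
        delta = float(df.loc[(df["i"] == 1) & (df["j"] == 0), "x"].iloc[0])
    else:
        delta = float(df.loc[(df["j"] == 2) & (df["i"] == 0), "y"].iloc[0]) / (2 * SQRT3_2)
    geom = HexGeometry(n_cols=I, n_rows=J, delta=delta)
    occ = np.zeros((J, I), dtype=np.uint8)
    occ[df["j"].to_numpy(), df["i"].to_numpy()] = df["occupied"].to_numpy()
    return HexState(geom, occ)


def state_to_rle(state: HexState) -> str:
    """Compact run-length text: header line, then one RLE line per row."""
    geom = state.geometry
    lines = [f"hexallee-rle {geom.n_cols} {geom.n_rows} {geom.delta!r}"]
    for row in state.occupancy:
        runs = []
        val = int(row[0])
        count = 0
        for v in row:
            if int(v) == val:
                count += 1
            else:
                runs.append(f"{count}x{val}")
                val = int(v)
                count = 1
        runs.append(f"{count}x{val}")
        lines.append(" ".join(runs))
    return "\n".join(lines) + "\n"


def state_from_rle(text: str) -> HexState:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    tag, I, J, delta = lines[0].split()
    if tag != "hexallee-rle":
        raise ValueError("not a hexallee run-length snapshot")
    geom = HexGeometry(n_cols=int(I), n_rows=int(J), delta=float(delta))
    occ = np.zeros((geom.n_rows, geom.n_cols), dtype=np.uint8)
    for j, line in enumerate(lines[1:]):
        i = 0
        for run in line.split():
            count, val = run.split("x")
            occ[j, i : i + int(count)] = int(val)
            i += int(count)
        if i != geom.n_cols:
            raise ValueError(f"row {j} has {i} sites, expected {geom.n_cols}")
    return HexState(geom, occ)
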