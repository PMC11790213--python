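"""Gridded mountain landscapes with concentric elevational bands.

A landscape is a lattice of cells partitioned into ``n_bands`` concentric
elevational bands (band 0 = lowlands, outermost; highest band = highlands,
innermost).  Cell temperature is a band property: the lowland temperature
minus a fixed decrement per band.  Bands carry the elevation-dependent rate
profiles (species-level carrying capacity ``K`` and per-population
diversification rate ``lambda``) used by the simulation engine.

The lattice is realized as a polar ring grid: each band is a set of
concentric rings of cells, cells are adjacent to their two neighbours within
a ring and to the cells of the adjacent rings whose angular extents overlap.
Any realization that satisfies the area-fraction and connectivity invariants
is equivalent for the purposes of the model; the polar grid is used because
it reproduces the target band areas to the cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Cell",
    "Landscape",
    "LandscapeConfigError",
    "CONE_FRACTIONS",
    "PLATEAU_FRACTIONS",
    "BAND_NAMES",
    "TEMPERATURE_STEP",
    "build_cone_landscape",
    "build_plateau_landscape",
    "build_banded_landscape",
    "band_rate_profile",
]

#: Band area fractions, lowland -> highland, as fractions of the nominal cell
#: budget.  The cone values are 58/24/13/5.8 percent; the plateau values are
#: 20/19/16/40 percent.  Neither set sums exactly to one, so the realized
#: lattice size differs slightly from the nominal budget (see builders).
CONE_FRACTIONS = (0.58, 0.24, 0.13, 0.058)
PLATEAU_FRACTIONS = (0.20, 0.19, 0.16, 0.40)

BAND_NAMES = ("lowland", "midland-low", "midland-high", "highland")

#: Temperature drop (degrees C) from one band to the next higher one.
TEMPERATURE_STEP = 5.0

#: Minimum nominal cell budget accepted by the standard builders.
MIN_TOTAL_CELLS = 20


class LandscapeConfigError(ValueError):
    """Raised when a landscape cannot be built from the requested sizes."""


@dataclass(frozen=True)
class Cell:
    """A single lattice cell (a read-only view into a :class:`Landscape`)."""

    cell_id: int
    band: int
    temperature: float
    neighbors: frozenset[int]


@dataclass
class Landscape:
    """A banded mountain lattice.

    Attributes
    ----------
    band : (n_cells,) int array mapping cell id -> band index (0 = lowlands).
    temperature : (n_cells,) float array of cell temperatures (deg C).
    neighbors : tuple of int tuples; ``neighbors[i]`` are the cells adjacent
        to cell ``i`` (symmetric, irreflexive, |band difference| <= 1).
    shape_tag : "cone", "plateau" or "custom".
    band_K : per-band species carrying capacity (float; the engine enforces
        the integer capacity ``cell_capacity``), or None until assigned.
    band_lambda : per-band per-population diversification rate, or None.
    """

    band: np.ndarray
    temperature: np.ndarray
    neighbors: tuple[tuple[int, ...], ...]
    n_bands: int
    shape_tag: str
    band_K: np.ndarray | None = None
    band_lambda: np.ndarray | None = None
    nominal_total_cells: int | None = None

    @property
    def n_cells(self) -> int:
        return int(self.band.shape[0])

    @property
    def band_cell_counts(self) -> np.ndarray:
        return np.bincount(self.band, minlength=self.n_bands)

    @property
    def cell_capacity(self) -> np.ndarray:
        """Integer per-cell species capacity (band_K broadcast, min 1)."""
        if self.band_K is None:
            raise ValueError("band_K has not been assigned")
        cap = np.maximum(1, np.floor(self.band_K + 0.5)).astype(np.int64)
        return cap[self.band]

    @property
    def cell_lambda(self) -> np.ndarray:
        if self.band_lambda is None:
            raise ValueError("band_lambda has not been assigned")
        return np.asarray(self.band_lambda, dtype=float)[self.band]

    def set_band_rates(self, band_K: Sequence[float] | None = None,
                       band_lambda: Sequence[float] | None = None) -> "Landscape":
        """Attach per-band K and/or lambda profiles (returns self)."""
        if band_K is not None:
            band_K = np.asarray(band_K, dtype=float)
            if band_K.shape != (self.n_bands,):
                raise ValueError("band_K must have one entry per band")
            self.band_K = band_K
        if band_lambda is not None:
            band_lambda = np.asarray(band_lambda, dtype=float)
            if band_lambda.shape != (self.n_bands,):
                raise ValueError("band_lambda must have one entry per band")
            self.band_lambda = band_lambda
        return self

    def cells_in_band(self, band: int) -> np.ndarray:
        return np.flatnonzero(self.band == band)

    def cell(self, cell_id: int) -> Cell:
        return Cell(cell_id, int(self.band[cell_id]),
                    float(self.temperature[cell_id]),
                    frozenset(self.neighbors[cell_id]))

    def __iter__(self) -> Iterator[Cell]:
        return (self.cell(i) for i in range(self.n_cells))

    # ------------------------------------------------------------------
    # serialization: a plain TSV with a JSON header line
    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        header = {
            "shape_tag": self.shape_tag,
            "n_bands": self.n_bands,
            "nominal_total_cells": self.nominal_total_cells,
            "band_K": None if self.band_K is None else list(map(float, self.band_K)),
            "band_lambda": (None if self.band_lambda is None
                            else list(map(float, self.band_lambda))),
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            fh.write("cell_id\tband\ttemperature\tneighbors\n")
            for i in range(self.n_cells):
                nbrs = ",".join(map(str, self.neighbors[i]))
                fh.write(f"{i}\t{int(self.band[i])}\t{self.temperature[i]:g}\t{nbrs}\n")

    @classmethod
    def from_tsv(cls, path) -> "Landscape":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("missing JSON header line")
            header = json.loads(first[1:])
            fh.readline()  # column names
            bands, temps, nbrs = [], [], []
            for line in fh:
                cid, b, t, ns = line.rstrip("\n").split("\t")
                bands.append(int(b))
                temps.append(float(t))
                nbrs.append(tuple(int(x) for x in ns.split(",")) if ns else ())
        ls = cls(
            band=np.asarray(bands, dtype=np.int64),
            temperature=np.asarray(temps, dtype=float),
            neighbors=tuple(nbrs),
            n_bands=int(header["n_bands"]),
            shape_tag=header["shape_tag"],
            nominal_total_cells=header.get("nominal_total_cells"),
        )
        if header.get("band_K") is not None:
            ls.set_band_rates(band_K=header["band_K"])
        if header.get("band_lambda") is not None:
            ls.set_band_rates(band_lambda=header["band_lambda"])
        return ls


# ----------------------------------------------------------------------
# construction
# ----------------------------------------------------------------------

def _band_counts(total_cells: int, fractions: Sequence[float]) -> np.ndarray:
    """Per-band cell counts: round(fraction x budget), each band >= 1 cell."""
    counts = np.array([int(math.floor(f * total_cells + 0.5)) for f in fractions],
                      dtype=np.int64)
    for b, c in enumerate(counts):
        if c < 1:
            raise LandscapeConfigError(
                f"total_cells={total_cells} leaves the "
                f"'{BAND_NAMES[b] if b < len(BAND_NAMES) else b}' band empty"
            )
    return counts


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights` (each >= 1)."""
    weights = np.asarray(weights, dtype=float)
    if total < len(weights):
        raise ValueError("cannot give every part at least one unit")
    quota = weights / weights.sum() * total
    alloc = np.floor(quota).astype(np.int64)
    rem = quota - alloc
    for i in np.argsort(-rem)[: total - alloc.sum()]:
        alloc[i] += 1
    # guarantee a cell in every ring
    while (alloc == 0).any():
        alloc[int(np.argmin(alloc))] += 1
        alloc[int(np.argmax(alloc))] -= 1
    return alloc


def _ring_layout(band_counts: np.ndarray) -> list[tuple[int, int]]:
    """Plan concentric rings, innermost first.

    Returns a list of (band, n_cells_in_ring).  Bands are laid out from the
    highest band at the centre outwards to the lowlands; the number of rings
    per band tracks the band's radial extent on the equivalent disc and the
    cells per ring track the ring circumference.
    """
    n_bands = len(band_counts)
    total = int(band_counts.sum())
    disc_radius = math.sqrt(total / math.pi)  # in cell units
    rings: list[tuple[int, int]] = []
    r_in = 0.0  # normalized radius
    for b in range(n_bands - 1, -1, -1):
        frac = band_counts[b] / total
        r_out = math.sqrt(r_in * r_in + frac)
        k = max(1, int(round((r_out - r_in) * disc_radius)))
        k = min(k, int(band_counts[b]))
        mids = r_in + (np.arange(k) + 0.5) * (r_out - r_in) / k
        sizes = _largest_remainder(np.maximum(mids, 1e-9), int(band_counts[b]))
        rings.extend((b, int(m)) for m in sizes)
        r_in = r_out
    return rings


def _build_from_rings(rings: list[tuple[int, int]], base_temperature: float,
                      n_bands: int, shape_tag: str,
                      nominal_total: int | None) -> Landscape:
    total = sum(m for _, m in rings)
    band = np.empty(total, dtype=np.int64)
    starts = []
    pos = 0
    for b, m in rings:
        starts.append(pos)
        band[pos:pos + m] = b
        pos += m

    nbrs: list[set[int]] = [set() for _ in range(total)]

    def link(a: int, b_: int) -> None:
        if a != b_:
            nbrs[a].add(b_)
            nbrs[b_].add(a)

    # within-ring cyclic adjacency
    for (b, m), s in zip(rings, starts):
        if m == 2:
            link(s, s + 1)
        elif m >= 3:
            for i in range(m):
                link(s + i, s + (i + 1) % m)

    # between consecutive rings: angular-overlap adjacency, exact in integers
    for ((_, m1), s1), ((_, m2), s2) in zip(zip(rings, starts), zip(rings[1:], starts[1:])):
        for i in range(m1):
            j_lo = (i * m2) // m1
            j_hi = ((i + 1) * m2 - 1) // m1
            for j in range(j_lo, j_hi + 1):
                jj = j % m2
                # intervals [i*m2, (i+1)*m2) and [j*m1, (j+1)*m1) in 1/(m1*m2)
                if i * m2 < (j + 1) * m1 and j * m1 < (i + 1) * m2:
                    link(s1 + i, s2 + jj)

    temperature = base_temperature - TEMPERATURE_STEP * band.astype(float)
    return Landscape(
        band=band,
        temperature=temperature,
        neighbors=tuple(tuple(sorted(s)) for s in nbrs),
        n_bands=n_bands,
        shape_tag=shape_tag,
        nominal_total_cells=nominal_total,
    )


def build_banded_landscape(total_cells: int,
                           fractions: Sequence[float],
                           base_temperature: float = 20.0,
                           shape_tag: str = "custom") -> Landscape:
    """Build a concentric-band landscape with arbitrary band fractions.

    ``fractions`` are ordered lowland -> highland and are applied to the
    nominal ``total_cells`` budget; the realized lattice has
    ``sum(round(f * total_cells))`` cells, which differs from the budget
    when the fractions do not sum to one.
    """
    counts = _band_counts(total_cells, fractions)
    rings = _ring_layout(counts)
    return _build_from_rings(rings, base_temperature, len(counts), shape_tag,
                             total_cells)


def build_cone_landscape(total_cells: int = 1000,
                         base_temperature: float = 20.0) -> Landscape:
    """Cone-shaped mountain: lowlands 58%, then 24%, 13%, highlands 5.8%.

    Highlands form the innermost patch and lowlands the outer ring.  Raises
    :class:`LandscapeConfigError` when ``total_cells`` is too small for every
    band to receive a cell.
    """
    if total_cells < MIN_TOTAL_CELLS:
        raise LandscapeConfigError(
            f"total_cells={total_cells} < {MIN_TOTAL_CELLS}: the highland band "
            "(5.8% of area) cannot be realized reliably")
    return build_banded_landscape(total_cells, CONE_FRACTIONS,
                                  base_temperature, "cone")


def build_plateau_landscape(total_cells: int = 1000,
                            base_temperature: float = 20.0) -> Landscape:
    """Plateau mountain: a large flat top (40% of the budget) surrounded by
    intermediate bands of 16% and 19% and an outer lowland ring of 20%."""
    if total_cells < MIN_TOTAL_CELLS:
        raise LandscapeConfigError(
            f"total_cells={total_cells} < {MIN_TOTAL_CELLS}: the smallest "
            "band cannot be realized reliably")
    return build_banded_landscape(total_cells, PLATEAU_FRACTIONS,
                                  base_temperature, "plateau")


def band_rate_profile(direction: str, fold: float, base: float,
                      n_bands: int = 4) -> np.ndarray:
    """Per-band rate profile, lowland -> highland.

    ``direction`` is one of ``increase`` (rate grows with elevation),
    ``decrease`` or ``uniform``.  The minimum of the profile is ``base`` and
    the max/min ratio equals ``fold``; intermediate bands are spaced
    geometrically (equal fold per band step).
    """
    if base <= 0:
        raise ValueError("base rate must be positive")
    if direction == "uniform":
        return np.full(n_bands, float(base))
    if fold < 1:
        raise ValueError("fold must be >= 1; use the opposite direction "
                         "instead of a fold below one")
    steps = np.arange(n_bands) / (n_bands - 1)
    if direction == "increase":
        return base * fold ** steps
    if direction == "decrease":
        return base * fold ** steps[::-1]
    raise ValueError(f"unknown direction {direction!r}")
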