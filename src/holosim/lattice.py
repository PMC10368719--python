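"""Spatial ecology: nutrient gradient, 3x3 sharing, holobionts, death and
overgrowth.

Each lattice site has a nutrient influx set by a sector map (the gradient
runs along the columns).  Every time step the influx of a site is divided
equally over all cells — hosts and symbionts alike — within its 3x3
neighborhood, so a cell's share sums contributions from up to nine sites.
A holobiont (one host plus >= 1 symbionts) occupies one site; when the host
divides, the offspring overgrows a random neighboring site, killing any
previous occupant, and inherits each parental symbiont with probability p.
Holobionts die when their host dies, when the last symbiont dies, or when
their combined household-gene count (host + mean over symbionts) falls
below the viability minimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genome import ConfigError, MutationRates
from .regulation import Cell, CellEvent

__all__ = [
    "EcologyParams",
    "Holobiont",
    "Lattice",
    "RngStreams",
    "StepLog",
    "nutrient_shares",
    "host_divide",
    "symbiont_divide",
    "step_lattice",
    "default_sectors",
]

DEFAULT_INFLUXES = (1, 2, 5, 10, 20, 30, 40, 50, 60, 80, 100)


def default_sectors(cols: int = 275, influxes=DEFAULT_INFLUXES) -> list[tuple[int, float]]:
    """Ascending-influx sector table [(width, influx), ...] spanning ``cols``."""
    n = len(influxes)
    if cols % n:
        raise ConfigError(f"{cols} columns cannot be split evenly into {n} sectors")
    w = cols // n
    return [(w, float(f)) for f in influxes]


@dataclass
class EcologyParams:
    """Ecology-level parameters.

    d: random death probability per cell per step.
    inheritance_p: probability each symbiont moves to the offspring holobiont.
    h_min: minimum combined household count (host + mean over symbionts).
    h_min_free: per-cell household minimum in free-living mode.
    household_at_division_only: enforce the household rule only on division
        events instead of every step.
    cycle_disabled: skip cell-cycle progression (measurement mode for the
        random-death process alone).
    """

    d: float = 0.001
    inheritance_p: float = 0.5
    h_min: float = 100.0
    h_min_free: float = 50.0
    free_living: bool = False
    household_at_division_only: bool = False
    cycle_disabled: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.d <= 1.0):
            raise ConfigError(f"ecology.d={self.d} not in [0, 1]")
        if not (0.0 <= self.inheritance_p <= 1.0):
            raise ConfigError(f"ecology.inheritance_p={self.inheritance_p} not in [0, 1]")
        if self.h_min < 0 or self.h_min_free < 0:
            raise ConfigError("household minimum must be >= 0")


@dataclass
class Holobiont:
    """One host cell plus its symbionts, occupying a single lattice site.

    In free-living mode the symbiont list is empty and the cell in ``host``
    is an ordinary free prokaryote.
    """

    id: int
    parent_id: int | None
    host: Cell
    symbionts: list[Cell]
    birth_time: int = 0

    def cells(self) -> list[tuple[str, Cell]]:
        out = [("host", self.host)]
        out.extend(("symbiont", s) for s in self.symbionts)
        return out

    def household_score(self) -> float:
        """Host household count plus the mean over symbionts."""
        h = float(self.host.genome.household_count())
        if self.symbionts:
            h += sum(s.genome.household_count() for s in self.symbionts) / len(self.symbionts)
        return h


class Lattice:
    """rows x cols grid; rows (the short axis) are periodic, columns (the
    gradient axis) are not, and 3x3 neighborhoods truncate at open edges."""

    def __init__(self, rows: int, cols: int, sectors: list[tuple[int, float]] | None = None,
                 influx: np.ndarray | None = None):
        self.rows = int(rows)
        self.cols = int(cols)
        if self.rows < 1 or self.cols < 1:
            raise ConfigError("lattice dimensions must be >= 1")
        if influx is not None:
            influx = np.asarray(influx, dtype=float)
            if influx.shape != (self.rows, self.cols):
                raise ConfigError(f"influx grid shape {influx.shape} != {(self.rows, self.cols)}")
            self.influx = influx
        else:
            sectors = sectors if sectors is not None else default_sectors(self.cols)
            if sum(w for w, _ in sectors) != self.cols:
                raise ConfigError(f"sector widths {[w for w, _ in sectors]} do not sum to {self.cols} columns")
            row = np.concatenate([np.full(w, f, dtype=float) for w, f in sectors])
            self.influx = np.tile(row, (self.rows, 1))
        self.occupants: dict[tuple[int, int], Holobiont] = {}
        self._next_id = 0

    @property
    def capacity(self) -> int:
        return self.rows * self.cols

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id

    def place(self, site: tuple[int, int], holo: Holobiont) -> None:
        if site in self.occupants:
            raise ConfigError(f"site {site} already occupied")
        self.occupants[site] = holo

    def site_of(self, holo: Holobiont) -> tuple[int, int]:
        for site, h in self.occupants.items():
            if h is holo:
                return site
        raise KeyError("holobiont not on lattice")

    def neighbor_sites(self, site: tuple[int, int]) -> list[tuple[int, int]]:
        """Up to eight distinct neighbors: rows wrap, columns truncate; on
        degenerate (1-2 row) grids wrapped duplicates and self are dropped."""
        r, c = site
        out = []
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if dr == 0 and dc == 0:
                continue
            nc = c + dc
            if not (0 <= nc < self.cols):
                continue
            cand = ((r + dr) % self.rows, nc)
            if cand != site and cand not in out:
                out.append(cand)
        return out

    def occupancy_grid(self) -> np.ndarray:
        occ = np.zeros((self.rows, self.cols), dtype=np.int64)
        for (r, c), holo in self.occupants.items():
            occ[r, c] = 1 + len(holo.symbionts)
        return occ

    def population(self) -> int:
        return len(self.occupants)

    def cell_count(self) -> int:
        return int(sum(1 + len(h.symbionts) for h in self.occupants.values()))


def _box3(grid: np.ndarray) -> np.ndarray:
    """Sum over the 3x3 neighborhood: periodic along rows, truncated along
    columns (implemented by zero padding)."""
    padded = np.pad(grid, ((1, 1), (0, 0)), mode="wrap")
    padded = np.pad(padded, ((0, 0), (1, 1)), mode="constant")
    out = np.zeros_like(grid, dtype=float)
    for dr in range(3):
        for dc in range(3):
            out += padded[dr:dr + grid.shape[0], dc:dc + grid.shape[1]]
    return out


def share_grid(lattice: Lattice) -> np.ndarray:
    """Per-cell nutrient share for a cell sitting at each site.

    Site s with c(s) >= 1 cells in its 3x3 neighborhood contributes
    influx(s)/c(s) to each of them; influx of sites with empty neighborhoods
    is unconsumed.  The neighbor relation is symmetric, so a cell's share is
    the 3x3 sum of these per-site contributions.
    """
    occ = lattice.occupancy_grid().astype(float)
    c = _box3(occ)
    v = np.where(c > 0, lattice.influx / np.where(c > 0, c, 1.0), 0.0)
    return _box3(v)


def nutrient_shares(lattice: Lattice) -> dict[Cell, float]:
    """Mapping from every cell on the lattice to its nutrient share."""
    grid = share_grid(lattice)
    shares: dict[Cell, float] = {}
    for (r, c), holo in lattice.occupants.items():
        for _, cell in holo.cells():
            shares[cell] = float(grid[r, c])
    return shares


def consumed_influx(lattice: Lattice) -> float:
    """Total influx of sites with at least one cell in their neighborhood."""
    c = _box3(lattice.occupancy_grid().astype(float))
    return float(lattice.influx[c > 0].sum())


@dataclass
class RngStreams:
    """Named substreams derived from one master seed: lattice-level events,
    expression dynamics, and mutation."""

    ecology: np.random.Generator
    expression: np.random.Generator
    mutation: np.random.Generator

    @classmethod
    def from_seed(cls, seed: int) -> "RngStreams":
        eco, expr, mut = np.random.SeedSequence(seed).spawn(3)
        return cls(
            np.random.default_rng(eco),
            np.random.default_rng(expr),
            np.random.default_rng(mut),
        )


@dataclass
class StepLog:
    """Per-step event counts and division/death records."""

    time: int = 0
    cells_at_start: int = 0
    random_deaths: int = 0
    cycle_deaths: int = 0
    symbiont_divisions: int = 0
    host_divisions: int = 0
    holobiont_deaths: int = 0
    household_removals: int = 0
    births: list[tuple[int, int, tuple[int, int]]] = field(default_factory=list)  # (child, parent, site)
    deaths: list[int] = field(default_factory=list)  # holobiont ids removed
    symbionts_inherited: list[tuple[int, int]] = field(default_factory=list)  # (to_offspring, total)


@dataclass
class DivisionOutcome:
    parent: Holobiont | None
    offspring: Holobiont | None
    offspring_site: tuple[int, int]
    symbionts_to_offspring: int
    symbionts_total: int
    overgrown: Holobiont | None


def symbiont_divide(holo: Holobiont, symbiont: Cell, rates: MutationRates,
                    rng_mut: np.random.Generator) -> Holobiont:
    """Replace a dividing symbiont by its two (independently mutated)
    daughters; both stay in the holobiont."""
    i = holo.symbionts.index(symbiont)
    d0, d1 = symbiont.divide(rates, rng_mut)
    holo.symbionts[i:i + 1] = [d0, d1]
    return holo


def host_divide(lattice: Lattice, holo: Holobiont, eco: EcologyParams, rates: MutationRates,
                rng_eco: np.random.Generator, rng_mut: np.random.Generator,
                time: int = 0) -> DivisionOutcome:
    """Host division: the offspring holobiont overgrows a uniformly chosen
    neighboring site (killing any occupant) and inherits each symbiont with
    probability ``eco.inheritance_p``; a resulting holobiont with no
    symbionts dies immediately (unless free-living)."""
    site = lattice.site_of(holo)
    neighbors = lattice.neighbor_sites(site)
    target = neighbors[int(rng_eco.integers(len(neighbors)))]
    overgrown = lattice.occupants.pop(target, None)

    d0, d1 = holo.host.divide(rates, rng_mut)
    holo.host = d0  # one daughter stays
    keep, move = [], []
    for s in holo.symbionts:
        (move if rng_eco.random() < eco.inheritance_p else keep).append(s)
    total = len(holo.symbionts)
    holo.symbionts = keep
    offspring = Holobiont(lattice.new_id(), holo.id, d1, move, birth_time=time)
    lattice.place(target, offspring)

    parent_alive, offspring_alive = True, True
    if not eco.free_living:
        if not holo.symbionts:
            del lattice.occupants[site]
            parent_alive = False
        if not offspring.symbionts:
            del lattice.occupants[target]
            offspring_alive = False
    return DivisionOutcome(
        parent=holo if parent_alive else None,
        offspring=offspring if offspring_alive else None,
        offspring_site=target,
        symbionts_to_offspring=len(move),
        symbionts_total=total,
        overgrown=overgrown,
    )


def step_lattice(lattice: Lattice, eco: EcologyParams, rates: MutationRates,
                 streams: RngStreams, time: int = 0) -> StepLog:
    """One synchronous time step (AUT).

    Shares are computed from the pre-step configuration; cell events are
    resolved in uniformly random order; symbiont divisions are applied
    before host divisions; finally holobionts that lost their host or last
    symbiont, or that violate the household viability rule, are removed.
    """
    log = StepLog(time=time, cells_at_start=lattice.cell_count())
    grid = share_grid(lattice)

    entries = []  # (holo, site, role, index, cell)
    for site, holo in lattice.occupants.items():
        entries.append((holo, site, "host", 0, holo.host))
        for i, s in enumerate(holo.symbionts):
            entries.append((holo, site, "symbiont", i, s))
    order = streams.ecology.permutation(len(entries))

    dead_cells: set[int] = set()
    dividers: list[tuple[Holobiont, tuple[int, int], str, Cell]] = []
    for k in order:
        holo, site, role, idx, cell = entries[k]
        if eco.d > 0 and streams.ecology.random() < eco.d:
            dead_cells.add(id(cell))
            log.random_deaths += 1
            continue
        if eco.cycle_disabled:
            continue
        event = cell.advance(float(grid[site]), streams.expression)
        if event is CellEvent.DIE:
            dead_cells.add(id(cell))
            log.cycle_deaths += 1
        elif event is CellEvent.DIVIDE:
            dividers.append((holo, site, role, cell))

    # apply cell deaths
    doomed: list[tuple[int, int]] = []
    for site, holo in lattice.occupants.items():
        if id(holo.host) in dead_cells:
            doomed.append(site)
            continue
        holo.symbionts = [s for s in holo.symbionts if id(s) not in dead_cells]
        if not holo.symbionts and not eco.free_living:
            doomed.append(site)
    for site in doomed:
        log.deaths.append(lattice.occupants.pop(site).id)
        log.holobiont_deaths += 1

    sym_divs = [(h, s, c) for h, s, role, c in dividers
                if role == "symbiont" and id(c) not in dead_cells]
    for holo, site, cell in sym_divs:
        if lattice.occupants.get(site) is not holo:
            continue  # holobiont died or was overgrown earlier this step
        if any(s is cell for s in holo.symbionts):
            symbiont_divide(holo, cell, rates, streams.mutation)
            log.symbiont_divisions += 1

    host_divs = [(h, s, c) for h, s, role, c in dividers
                 if role == "host" and id(c) not in dead_cells]
    touched: list[tuple[int, int]] = []
    for holo, site, cell in host_divs:
        if lattice.occupants.get(site) is not holo or holo.host is not cell:
            continue  # overgrown earlier this step
        out = host_divide(lattice, holo, eco, rates, streams.ecology, streams.mutation, time=time)
        log.host_divisions += 1
        log.symbionts_inherited.append((out.symbionts_to_offspring, out.symbionts_total))
        if out.overgrown is not None:
            log.deaths.append(out.overgrown.id)
            log.holobiont_deaths += 1
        if out.offspring is not None:
            log.births.append((out.offspring.id, holo.id, out.offspring_site))
            touched.append(out.offspring_site)
        if out.parent is not None:
            touched.append(site)
        if out.parent is None:
            log.holobiont_deaths += 1
            log.deaths.append(holo.id)
        elif out.offspring is None:
            log.holobiont_deaths += 1  # offspring received no symbionts; never recorded as born

    # household viability: a standing rule by default, or checked only for
    # holobionts touched by a division this step
    limit = eco.h_min_free if eco.free_living else eco.h_min
    if eco.household_at_division_only:
        candidates = [s for s in dict.fromkeys(touched) if s in lattice.occupants]
    else:
        candidates = list(lattice.occupants)
    removed = [s for s in candidates if lattice.occupants[s].household_score() < limit]
    for site in removed:
        log.deaths.append(lattice.occupants.pop(site).id)
        log.household_removals += 1
        log.holobiont_deaths += 1
    return log
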