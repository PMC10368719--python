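"""Analytics: single-cell cycle tracking, growth-rate math, cell-cycle
efficiency, holobiont profiling, phase diagrams and asymmetry statistics.

The phenomenological population model behind the growth statistics is

    dN/dt = (rho/tau) N (1 - N) - ((1 - rho)/tau) N - delta N

for a clonal population executing a fixed cell cycle of mean duration tau
(AUT) with success fraction rho under an external death rate delta.  From it
follow the reproduction number R0 = rho / (delta tau + 1 - rho), the
instantaneous growth rate r = (2 rho - 1 - delta tau)/tau
= (rho/tau)(1 - 1/R0), and the stable equilibrium N* = max(0, r tau / rho).

The fastest possible cycle at genome size L and fixed nutrient share n is
tau_min = 3 + L/n (one step in each of G1, G2, M plus L/n S-steps), giving
the cell-cycle efficiency e = tau_min / tau averaged over the standard
condition set n in {100, 50, 20, 10, 5, 2, 1}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Genome, MutationRates
from .lattice import EcologyParams, Holobiont, Lattice, RngStreams, share_grid, step_lattice
from .regulation import Cell, CellEvent, StageSignatureTable

__all__ = [
    "CycleStats",
    "GrowthStats",
    "SectorProfile",
    "HolobiontProfile",
    "PhaseDiagram",
    "DEFAULT_CONDITIONS",
    "tau_min",
    "track_single_cell",
    "growth_from_cycle",
    "logistic_equilibrium",
    "cycle_efficiency",
    "phase_diagram",
    "profile_holobiont",
    "asymmetry_regression",
    "measure_random_death_frequency",
    "measure_inheritance_fraction",
    "AnalysisError",
]

DEFAULT_CONDITIONS = (100.0, 50.0, 20.0, 10.0, 5.0, 2.0, 1.0)
DEFAULT_TRACK_DURATION = 10_000


class AnalysisError(ValueError):
    pass


def tau_min(L: int, n: float) -> float:
    """Minimum duration of a successful cell cycle: 3 + L/n."""
    if n <= 0:
        raise AnalysisError("nutrient condition n must be > 0")
    return 3.0 + L / n


@dataclass
class CycleStats:
    """Tracked cell-cycle behavior at one fixed nutrient condition."""

    n: float
    duration: int
    n_success: int
    n_fail: int
    tau: float | None          # mean duration of completed cycles; None if none completed
    rho: float | None          # successes / attempts; None if no attempt finished
    cycle_durations: list[int] = field(default_factory=list)

    @property
    def tau_defined(self) -> bool:
        return self.tau is not None


def track_single_cell(
    genome: Genome,
    n: float,
    table: StageSignatureTable,
    rng: np.random.Generator,
    duration: int = DEFAULT_TRACK_DURATION,
    half_saturation: float = 0.02,
    injected_death_rate: float = 0.0,
) -> CycleStats:
    """Track one cell at a fixed nutrient share ``n`` for ``duration`` AUT.

    An attempt runs from birth/reset to DIVIDE or DIE; on DIVIDE one
    (unmutated) daughter continues, on DIE the cell restarts from a fresh
    copy of the input genome.  An attempt whose expression state falls into
    the all-off absorbing state (provably unable to ever divide) is counted
    as failed and restarted immediately.  External random death is excluded
    here (it enters the growth statistics analytically as delta); the
    optional ``injected_death_rate`` is a per-step hazard used to exercise
    the rho bookkeeping in tests.
    """
    if duration < 1:
        raise AnalysisError("tracking duration must be >= 1")
    zero = MutationRates.zero()
    cell = Cell(genome.copy(), table, half_saturation)
    durations: list[int] = []
    n_fail = 0
    for _ in range(duration):
        if injected_death_rate > 0 and rng.random() < injected_death_rate:
            n_fail += 1
            cell = Cell(genome.copy(), table, half_saturation)
            continue
        event = cell.advance(n, rng)
        if event is CellEvent.DIVIDE:
            durations.append(cell.age)
            cell, _ = cell.divide(zero, rng)
        elif event is CellEvent.DIE:
            n_fail += 1
            cell = Cell(genome.copy(), table, half_saturation)
    n_success = len(durations)
    attempts = n_success + n_fail
    return CycleStats(
        n=n,
        duration=duration,
        n_success=n_success,
        n_fail=n_fail,
        tau=float(np.mean(durations)) if durations else None,
        rho=(n_success / attempts) if attempts else None,
        cycle_durations=durations,
    )


@dataclass
class GrowthStats:
    """Reproduction number and instantaneous growth rate for one (tau, rho,
    delta)."""

    R0: float
    r: float
    delta: float
    divergent: bool = False  # R0 denominator <= 0 (r = rho/tau limit)


def growth_from_cycle(tau: float, rho: float, delta: float) -> GrowthStats:
    """R0 = rho/(delta tau + 1 - rho); r = (2 rho - 1 - delta tau)/tau,
    algebraically equal to (rho/tau)(1 - 1/R0)."""
    if tau <= 0:
        raise AnalysisError("tau must be > 0")
    if not (0.0 <= rho <= 1.0):
        raise AnalysisError("rho must be in [0, 1]")
    if delta < 0:
        raise AnalysisError("delta must be >= 0")
    denom = delta * tau + 1.0 - rho
    r = (2.0 * rho - 1.0 - delta * tau) / tau
    if denom <= 0:
        return GrowthStats(R0=math.inf, r=rho / tau, delta=delta, divergent=True)
    return GrowthStats(R0=rho / denom, r=r, delta=delta)


def logistic_equilibrium(rho: float, tau: float, delta: float) -> float:
    """Stable fixed point N* = max(0, (2 rho - 1 - delta tau)/rho) of the
    phenomenological logistic model; 0 when the population cannot persist."""
    if tau <= 0:
        raise AnalysisError("tau must be > 0")
    if not (0.0 < rho <= 1.0):
        raise AnalysisError("rho must be in (0, 1] for an equilibrium")
    return max(0.0, (2.0 * rho - 1.0 - delta * tau) / rho)


def cycle_efficiency(
    L: int,
    stats_by_n: dict[float, CycleStats],
    conditions=DEFAULT_CONDITIONS,
) -> tuple[float, list[float]]:
    """Mean of per-condition efficiencies e_n = (3 + L/n)/tau_n over the
    conditions where tau is defined; returns (e, excluded conditions)."""
    effs, excluded = [], []
    for n in conditions:
        st = stats_by_n.get(n)
        if st is None or not st.tau_defined:
            excluded.append(n)
            continue
        effs.append(tau_min(L, n) / st.tau)
    if not effs:
        raise AnalysisError("cell-cycle efficiency undefined: no condition produced a completed cycle")
    return float(np.mean(effs)), excluded


@dataclass
class PhaseDiagram:
    """Host and symbiont growth curves over fixed nutrient conditions.

    A crossing of r_H(n) = r_S(n) is *stable* when r_S - r_H increases
    through zero with n: a symbiont surplus lowers the per-cell nutrient
    level, which must push r_S below r_H for the perturbation to
    self-correct.
    """

    curves: pd.DataFrame  # n, tau/rho/r per role, valid_H, valid_S (rho > 0.5)
    crossings: list[tuple[float, bool]]  # (n*, stable)
    regime: str  # stable | unstable | symbiont_dominant | host_dominant | neutral_drift | mixed

    @property
    def stable_crossings(self) -> list[float]:
        return [n for n, stable in self.crossings if stable]


def _growth_value(stats: CycleStats, delta: float) -> float:
    """r for crossing detection; a condition with no completed cycle is
    treated as unboundedly negative growth."""
    if not stats.tau_defined or stats.rho is None:
        return -math.inf
    return growth_from_cycle(stats.tau, stats.rho, delta).r


def phase_diagram(
    host_genome: Genome,
    symbiont_genome: Genome,
    table: StageSignatureTable,
    rng: np.random.Generator,
    conditions=DEFAULT_CONDITIONS,
    delta: float = 0.001,
    duration: int = DEFAULT_TRACK_DURATION,
    half_saturation: float = 0.02,
    neutral_tol: float = 1e-9,
) -> PhaseDiagram:
    """Track host and symbiont independently over the condition grid and
    classify the r_H / r_S crossing structure."""
    ns = sorted(float(n) for n in conditions)
    rows = []
    for n in ns:
        sh = track_single_cell(host_genome, n, table, rng, duration, half_saturation)
        ss = track_single_cell(symbiont_genome, n, table, rng, duration, half_saturation)
        rows.append({
            "n": n,
            "tau_H": sh.tau, "rho_H": sh.rho, "r_H": _growth_value(sh, delta),
            "tau_S": ss.tau, "rho_S": ss.rho, "r_S": _growth_value(ss, delta),
            "valid_H": (sh.rho or 0.0) > 0.5, "valid_S": (ss.rho or 0.0) > 0.5,
        })
    curves = pd.DataFrame(rows)
    dr = curves["r_S"].to_numpy() - curves["r_H"].to_numpy()

    finite = np.isfinite(dr)
    if finite.any() and np.nanmax(np.abs(dr[finite]), initial=0.0) <= neutral_tol and finite.all():
        return PhaseDiagram(curves, [], "neutral_drift")

    crossings: list[tuple[float, bool]] = []
    for i in range(len(ns) - 1):
        a, b = dr[i], dr[i + 1]
        if a == 0.0:
            continue
        if a * b < 0 or (b == 0.0 and a != 0.0):
            if math.isfinite(a) and math.isfinite(b) and a != b:
                n_star = ns[i] + (ns[i + 1] - ns[i]) * (0.0 - a) / (b - a)
            else:
                n_star = 0.5 * (ns[i] + ns[i + 1])
            crossings.append((float(n_star), bool(b > a if math.isfinite(b - a) else b > 0)))
    if crossings:
        stables = [s for _, s in crossings]
        regime = "stable" if all(stables) else ("unstable" if not any(stables) else "mixed")
    else:
        valid = np.isfinite(dr)
        if valid.any() and (dr[valid] > 0).all():
            regime = "symbiont_dominant"
        elif valid.any() and (dr[valid] < 0).all():
            regime = "host_dominant"
        else:
            regime = "neutral_drift" if not valid.any() else "host_dominant"
    return PhaseDiagram(curves, crossings, regime)


@dataclass
class SectorProfile:
    influx: float
    invasion_speed: float      # sites/AUT, slope of front position vs time
    density: float             # occupied fraction of sites at steady state
    symbionts_per_host: float
    leftover_nutrients: float  # mean per-cell share at steady state
    viable: bool


@dataclass
class HolobiontProfile:
    sectors: list[SectorProfile]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.sectors])


def profile_holobiont(
    host_genome: Genome,
    symbiont_genome: Genome,
    table: StageSignatureTable,
    sector_influxes,
    seed: int,
    rows: int = 25,
    cols: int = 30,
    duration: int = 2000,
    n_symbionts: int = 2,
    eco: EcologyParams | None = None,
    half_saturation: float = 0.02,
) -> HolobiontProfile:
    """Clonal, mutation-free characterization of one holobiont type on each
    sector of the gradient.

    A strip at the left edge is seeded, range expansion is followed (front =
    right-most occupied column; speed = linear-fit slope from the first
    advance until the front reaches 90% of the strip), then density,
    symbionts per host and mean leftover per-cell share are averaged over
    the final quarter of the run.
    """
    eco = eco if eco is not None else EcologyParams()
    zero = MutationRates.zero()
    sectors = []
    for k, influx in enumerate(sector_influxes):
        streams = RngStreams.from_seed((seed * 1009 + k) % (2**31 - 1))
        lat = Lattice(rows, cols, influx=np.full((rows, cols), float(influx)))
        for r in range(rows):
            host = Cell(host_genome.copy(), table, half_saturation)
            symbionts = [Cell(symbiont_genome.copy(), table, half_saturation) for _ in range(n_symbionts)]
            lat.place((r, 0), Holobiont(lat.new_id(), None, host, symbionts))
        front, dens, sph, left = [], [], [], []
        for t in range(duration):
            step_lattice(lat, eco, zero, streams, time=t)
            if not lat.occupants:
                break
            front.append(max(c for _, c in lat.occupants))
            if t >= duration * 3 // 4:
                dens.append(lat.population() / lat.capacity)
                sph.append(float(np.mean([len(h.symbionts) for h in lat.occupants.values()])))
                grid = share_grid(lat)
                left.append(float(np.mean([grid[s] for s in lat.occupants])))
        if not lat.occupants or not dens:
            sectors.append(SectorProfile(float(influx), 0.0, 0.0, 0.0, 0.0, viable=False))
            continue
        speed = _invasion_speed(front, cols)
        sectors.append(SectorProfile(
            float(influx), speed, float(np.mean(dens)), float(np.mean(sph)),
            float(np.mean(left)), viable=True,
        ))
    return HolobiontProfile(sectors)


def _invasion_speed(front: list[int], cols: int) -> float:
    """Slope of front column vs time between the first advance and 90% of
    the strip length; 0 if the front never moved."""
    f = np.asarray(front)
    start0 = f[0]
    moved = np.nonzero(f > start0)[0]
    if moved.size == 0:
        return 0.0
    t0 = int(moved[0]) - 1
    limit = 0.9 * (cols - 1)
    past = np.nonzero(f >= limit)[0]
    t1 = int(past[0]) if past.size else len(f) - 1
    if t1 <= t0:
        return 0.0
    ts = np.arange(t0, t1 + 1)
    return float(np.polyfit(ts, f[t0:t1 + 1], 1)[0])


def measure_random_death_frequency(
    seed: int,
    rows: int = 30,
    cols: int = 40,
    n_symbionts: int = 2,
    min_cell_steps: int = 100_000,
    eco: EcologyParams | None = None,
) -> tuple[float, int]:
    """Empirical per-cell per-step random-death frequency.

    Runs a fully seeded, mutation-free lattice with cell-cycle progression
    disabled, so random death is the only event; returns (deaths /
    cell-steps, cell-steps).
    """
    from .fixtures import make_clock_fixture

    eco = eco if eco is not None else EcologyParams(cycle_disabled=True)
    if not eco.cycle_disabled:
        raise AnalysisError("death-frequency measurement requires cycle_disabled ecology")
    fx = make_clock_fixture(households=50)
    lat = Lattice(rows, cols, influx=np.full((rows, cols), 1.0))
    for r in range(rows):
        for c in range(cols):
            host = Cell(fx.genome.copy(), fx.table)
            lat.place((r, c), Holobiont(lat.new_id(), None, host,
                                        [Cell(fx.genome.copy(), fx.table) for _ in range(n_symbionts)]))
    streams = RngStreams.from_seed(seed)
    zero = MutationRates.zero()
    deaths = 0
    cell_steps = 0
    t = 0
    while cell_steps < min_cell_steps and lat.occupants:
        log = step_lattice(lat, eco, zero, streams, time=t)
        deaths += log.random_deaths
        cell_steps += log.cells_at_start
        t += 1
    if cell_steps < min_cell_steps:
        raise AnalysisError("population died out before reaching the requested cell-steps")
    return deaths / cell_steps, cell_steps


def measure_inheritance_fraction(
    seed: int,
    n_events: int = 10_000,
    n_symbionts: int = 10,
    eco: EcologyParams | None = None,
) -> tuple[float, int]:
    """Mean fraction of parental symbionts allocated to the offspring
    holobiont over ``n_events`` host divisions (default parameters, 10
    symbionts per parent); returns (mean fraction, events)."""
    from .fixtures import make_clock_fixture
    from .lattice import host_divide

    eco = eco if eco is not None else EcologyParams()
    fx = make_clock_fixture(households=50)
    table = fx.table
    zero = MutationRates.zero()
    streams = RngStreams.from_seed(seed)
    symbionts = [Cell(fx.genome.copy(), table) for _ in range(n_symbionts)]
    total = 0.0
    lat = Lattice(3, 3, influx=np.ones((3, 3)))
    for _ in range(n_events):
        lat.occupants.clear()
        host_genome = fx.genome.copy()
        host_genome.replication_progress = float(host_genome.size)
        holo = Holobiont(lat.new_id(), None, Cell(host_genome, table), list(symbionts))
        lat.place((1, 1), holo)
        out = host_divide(lat, holo, eco, zero, streams.ecology, streams.mutation)
        total += out.symbionts_to_offspring / out.symbionts_total
    return total / n_events, n_events


def asymmetry_regression(df: pd.DataFrame, x: str, y: str) -> dict:
    """Pearson correlation of two columns; returns r, R2, two-sided p and N."""
    xs = pd.to_numeric(df[x], errors="raise").to_numpy(dtype=float)
    ys = pd.to_numeric(df[y], errors="raise").to_numpy(dtype=float)
    ok = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[ok], ys[ok]
    if xs.size < 3:
        raise AnalysisError(f"need >= 3 finite points, got {xs.size}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise AnalysisError("zero variance in a regression column")
    res = sps.pearsonr(xs, ys)
    return {"r": float(res.statistic), "R2": float(res.statistic**2),
            "p": float(res.pvalue), "N": int(xs.size)}


def asymmetry_point(L_host: int, L_symbiont: int, e_host: float, e_symbiont: float) -> tuple[float, float]:
    """Asymmetry coordinates: (log2 genome-size ratio, efficiency
    difference), host relative to symbiont."""
    if L_host <= 0 or L_symbiont <= 0:
        raise AnalysisError("genome sizes must be positive")
    return math.log2(L_host / L_symbiont), e_host - e_symbiont
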