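"""Versioned wiring and stage-table fixtures, and the deterministic clock.

The *clock fixture* is a genome whose deterministic-limit dynamics cycle
G1 -> S -> G2 -> M with a known period; it makes every stochastic component
of the simulator testable against exact enumeration.  The same wiring is
the default "primitive" regulatory network used to found evolution runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .genome import Bead, BeadKind, ConfigError, Genome, make_primitive_genome
from .io import read_genome
from .regulation import Cell, Stage, StageSignatureTable

__all__ = [
    "load_wiring",
    "load_stage_table",
    "make_clock_fixture",
    "ClockFixture",
    "initialize_activity",
    "enumerate_deterministic_cycle",
]

WIRING_RESOURCE = "primitive_wiring_v1.tsv"
STAGE_RESOURCE = "stage_table_v1.tsv"


def _data_path(name: str):
    return resources.files("holosim.data") / name


def load_wiring(path=None) -> list[Bead]:
    """The primitive wiring table: 5 regulator genes plus their binding
    sites, in bead order (a site regulates the nearest gene downstream)."""
    genome = read_genome(path if path is not None else _data_path(WIRING_RESOURCE))
    if genome.household_count():
        raise ConfigError("wiring table may not contain household genes")
    return genome.beads


def load_stage_table(path=None) -> StageSignatureTable:
    src = path if path is not None else _data_path(STAGE_RESOURCE)
    with open(src) if isinstance(src, str) else src.open() as fh:
        lines = [l.rstrip("\n") for l in fh]
    if not lines or lines[0].strip() != "# holosim-stage-table v1":
        raise ConfigError(f"{src}: expected '# holosim-stage-table v1' header")
    rows = [l for l in lines[1:] if l.strip() and not l.startswith("#")]
    header = rows[0].split("\t")
    if header != ["stage", "t0", "t1", "t2", "t3", "t4"]:
        raise ConfigError(f"{src}: unexpected stage-table columns {header}")
    patterns: dict[Stage, tuple[int, ...]] = {}
    for row in rows[1:]:
        fields = row.split("\t")
        patterns[Stage(fields[0])] = tuple(int(b) for b in fields[1:6])
    return StageSignatureTable(patterns)


def initialize_activity(genome: Genome, table: StageSignatureTable) -> Genome:
    """Set regulator activities to the M signature so a fresh cell enters
    the cycle at G1, exactly like a newborn daughter."""
    m = table.patterns[Stage.M]
    for b in genome.beads:
        if b.kind is BeadKind.REGULATORY_GENE:
            b.activity = int(m[b.type_id])
    return genome


def enumerate_deterministic_cycle(
    genome: Genome, table: StageSignatureTable, max_steps: int = 64
) -> tuple[list[Stage], int]:
    """Follow the deterministic-limit dynamics from the genome's initial
    activity until the expression state recurs; returns the stage sequence
    of the limit cycle and its period.

    The deterministic map lives on at most 2^(#gene instances) states, so
    recurrence within ``max_steps`` is guaranteed for small fixtures.
    """
    from . import _kernels

    cell = Cell(genome.copy(), table, half_saturation=0.0)
    rng = np.random.default_rng(0)  # draws are ignored in the deterministic limit
    seen: dict[bytes, int] = {}
    stages: list[Stage] = []
    for step in range(max_steps):
        key = cell._act.tobytes()
        if key in seen:
            start = seen[key]
            return stages[start:], len(stages) - start
        seen[key] = step
        cell.expression_step(rng)
        idx = _kernels.match_stage_kernel(cell.core_pattern(), table.array)
        stages.append(Stage(("G1", "S", "G2", "M")[idx]) if idx >= 0 else Stage.NONE)
    raise ConfigError(f"no recurrence within {max_steps} deterministic steps")


@dataclass
class ClockFixture:
    """A genome with a verified deterministic-limit cycle through all four
    stage signatures."""

    genome: Genome
    table: StageSignatureTable
    stage_sequence: list[Stage] = field(default_factory=list)
    period: int = 0

    def verify(self) -> None:
        """Re-simulate in the deterministic limit and check the attached
        trajectory; raises on any tampering."""
        stages, period = enumerate_deterministic_cycle(self.genome, self.table)
        if period != self.period or stages != self.stage_sequence:
            raise ConfigError(
                f"clock fixture trajectory mismatch: recorded period {self.period} "
                f"{[s.value for s in self.stage_sequence]}, re-simulated {period} {[s.value for s in stages]}"
            )
        if set(self.stage_sequence) - {Stage.NONE} != {Stage.G1, Stage.S, Stage.G2, Stage.M}:
            raise ConfigError("clock cycle must visit all four stage signatures")


def make_clock_fixture(
    households: int = 50,
    table: StageSignatureTable | None = None,
    wiring: list[Bead] | None = None,
) -> ClockFixture:
    """Build the clock genome (wiring + household genes), enumerate its
    deterministic cycle, and return it with the verified trajectory.

    With genome size L, the clock completes replication in one S-visit at
    nutrient share n >= L; its cycle duration is then the designed period
    (4 by default), which equals tau_min = 3 + L/n exactly at n = L.
    """
    table = table if table is not None else load_stage_table()
    beads = wiring if wiring is not None else load_wiring()
    genome = make_primitive_genome(beads, households, stage_m_pattern=table.patterns[Stage.M])
    stages, period = enumerate_deterministic_cycle(genome, table)
    fixture = ClockFixture(genome, table, stages, period)
    fixture.verify()
    return fixture


def slow_clock_wiring() -> list[Bead]:
    """A second hand-built wiring whose deterministic cycle takes five steps
    (G1 -> S -> G2 -> gap -> M): a slower cell cycle with the same single
    S-visit, used to construct host/symbiont pairs with differentiated
    growth curves."""
    bs = lambda t, w: Bead(BeadKind.BINDING_SITE, type_id=t, weight=w)
    reg = lambda t: Bead(BeadKind.REGULATORY_GENE, type_id=t, threshold=1)
    return [
        bs(3, 1), bs(2, -2), reg(0),
        bs(4, 1), bs(2, -2), reg(1),
        bs(1, 1), bs(4, 1), reg(2),
        bs(2, 1), bs(3, 1), bs(0, -2), reg(3),
        bs(0, 1), bs(4, -2), reg(4),
    ]


def make_slow_clock_fixture(households: int = 24,
                            table: StageSignatureTable | None = None) -> ClockFixture:
    """Clock fixture over :func:`slow_clock_wiring` (period 5)."""
    return make_clock_fixture(households=households, table=table, wiring=slow_clock_wiring())


def _wiring_from_weight_rows(rows: list[tuple[tuple[int, ...], int]]) -> list[Bead]:
    bs = lambda t, w: Bead(BeadKind.BINDING_SITE, type_id=t, weight=w)
    out: list[Bead] = []
    for gene_type, (weights, threshold) in enumerate(rows):
        for target, w in enumerate(weights):
            if w:
                out.append(bs(target, w))
        out.append(Bead(BeadKind.REGULATORY_GENE, type_id=gene_type, threshold=threshold))
    return out


def host_clock_wiring() -> list[Bead]:
    """A period-10 wiring (G1 -> S -> G2 -> six gap states -> M), found by
    exhaustive search over threshold functions; its only non-trivial
    deterministic attractor is the 10-cycle.  Used as the *host* of
    constructed host/symbiont pairs: a host cycling roughly half as fast as
    its symbionts lets the symbiont number per holobiont equilibrate (each
    symbiont must divide about twice per host division to offset the 50%
    inheritance split)."""
    return _wiring_from_weight_rows([
        ((1, -1, 0, 1, -1), 1),
        ((0, -2, 2, -1, 1), 1),
        ((-1, -1, 2, 0, 2), 1),
        ((1, 1, 0, -1, -1), 1),
        ((1, 0, -1, 0, -1), 1),
    ])


def make_host_clock_fixture(households: int = 16,
                            table: StageSignatureTable | None = None) -> ClockFixture:
    """Clock fixture over :func:`host_clock_wiring` (period 10)."""
    return make_clock_fixture(households=households, table=table, wiring=host_clock_wiring())
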