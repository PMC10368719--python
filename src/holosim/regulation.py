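"""Stochastic expression dynamics, stage detection and the per-cell update.

The gene regulatory network is emergent: each binding site regulates the
nearest regulatory gene downstream of it on the bead string, and is bound
each step with a saturating probability A/(A + K) in the number A of active
copies of its target type.  Gene copy number feeds back on regulation
because replicated genes contribute extra copies, which is how replication
timing couples to expression.

The four cell-cycle stages are signatures of the 5-bit core activity
pattern.  A cell that reaches the M signature divides if it has visited
G1, S and G2 (in that order of first visits) since its last division *and*
has fully replicated its genome; reaching M prematurely kills it.
"""

from __future__ import annotations

import math

from enum import Enum

import numpy as np

from . import _kernels
from .genome import (
    Bead,
    BeadKind,
    ConfigError,
    Genome,
    MutationRates,
    advance_fork,
    finish_division,
    mutate_genome,
)

__all__ = [
    "Stage",
    "CellEvent",
    "StageSignatureTable",
    "Cell",
    "binding_probability",
    "expression_step",
    "detect_stage",
    "advance_cell",
]


class Stage(str, Enum):
    G1 = "G1"
    S = "S"
    G2 = "G2"
    M = "M"
    NONE = "NONE"


STAGE_ORDER = (Stage.G1, Stage.S, Stage.G2, Stage.M)

_EMPTY = np.empty(0)


class CellEvent(Enum):
    NONE = 0
    DIVIDE = 1
    DIE = 2


class StageSignatureTable:
    """Mapping from the four stages to distinct 5-bit core activity patterns."""

    def __init__(self, patterns: dict[Stage, tuple[int, ...]]):
        missing = [s for s in STAGE_ORDER if s not in patterns]
        if missing:
            raise ConfigError(f"stage table missing stages {missing}")
        rows = [tuple(int(b) for b in patterns[s]) for s in STAGE_ORDER]
        for row in rows:
            if len(row) != 5 or any(b not in (0, 1) for b in row):
                raise ConfigError(f"stage pattern {row} is not a 5-bit vector")
        if len(set(rows)) != 4:
            raise ConfigError("stage signature patterns must be pairwise distinct")
        self.patterns = {s: r for s, r in zip(STAGE_ORDER, rows)}
        self.array = np.array(rows, dtype=np.uint8)

    def __eq__(self, other) -> bool:
        return isinstance(other, StageSignatureTable) and self.patterns == other.patterns

    @classmethod
    def default(cls) -> "StageSignatureTable":
        from .fixtures import load_stage_table

        return load_stage_table()


def binding_probability(active_copies: int, half_saturation: float) -> float:
    """Saturating binding probability A/(A + K); strictly increasing in A."""
    if half_saturation <= 0:
        raise ConfigError(f"half_saturation must be > 0, got {half_saturation}")
    if active_copies < 0:
        raise ConfigError("active_copies must be >= 0")
    return active_copies / (active_copies + half_saturation)


def detect_stage(core_bits, table: StageSignatureTable) -> Stage:
    """Stage whose signature equals the 5-bit core vector, else NONE."""
    core = tuple(int(b) for b in core_bits)
    for stage, pattern in table.patterns.items():
        if pattern == core:
            return stage
    return Stage.NONE


class Cell:
    """A cell: genome + expression state + cell-cycle bookkeeping.

    The genome is compiled to flat arrays once per genome change (birth);
    per-step work happens in a compiled kernel.  ``half_saturation <= 0``
    selects the deterministic binding limit (a site is bound iff its target
    has at least one active copy), used for the clock fixtures and tests.
    """

    __slots__ = (
        "genome", "table", "half_saturation", "stage", "visited", "age",
        "_gene_bead_idx", "_gene_type", "_gene_thresh", "_act", "_act_buf",
        "_copies", "_site_ptr", "_site_target", "_site_weight", "_max_draws",
    )

    def __init__(self, genome: Genome, table: StageSignatureTable, half_saturation: float = 0.02):
        self.genome = genome
        self.table = table
        self.half_saturation = float(half_saturation)
        self.stage = Stage.NONE
        self.visited: list[Stage] = []
        self.age = 0
        self._compile()

    def _compile(self) -> None:
        beads = self.genome.beads
        gene_bead_idx, gene_type, gene_thresh, act0 = [], [], [], []
        site_of_gene: list[list[tuple[int, int]]] = []
        pending: list[tuple[int, int]] = []  # (target, weight) awaiting downstream gene
        for i, b in enumerate(beads):
            if b.kind is BeadKind.BINDING_SITE:
                pending.append((b.type_id, b.weight))
            elif b.kind is BeadKind.REGULATORY_GENE:
                gene_bead_idx.append(i)
                gene_type.append(b.type_id)
                gene_thresh.append(b.threshold)
                act0.append(b.activity)
                site_of_gene.append(pending)
                pending = []  # sites with no downstream regulator are inert
        n_genes = len(gene_type)
        self._gene_bead_idx = np.array(gene_bead_idx, dtype=np.int64)
        self._gene_type = np.array(gene_type, dtype=np.int64)
        self._gene_thresh = np.array(gene_thresh, dtype=np.int64)
        self._act = np.zeros((n_genes, 2), dtype=np.uint8)
        self._act[:, 0] = np.array(act0, dtype=np.uint8) if n_genes else 0
        self._act_buf = np.zeros_like(self._act)
        self._copies = np.ones(n_genes, dtype=np.uint8)
        ptr = np.zeros(n_genes + 1, dtype=np.int64)
        targets, weights = [], []
        for g, sites in enumerate(site_of_gene):
            for t, w in sites:
                targets.append(t)
                weights.append(w)
            ptr[g + 1] = len(targets)
        self._site_ptr = ptr
        self._site_target = np.array(targets, dtype=np.int64)
        self._site_weight = np.array(weights, dtype=np.int64)
        self._max_draws = 2 * len(targets)
        self._sync_copies()

    def _sync_copies(self) -> None:
        """Mark genes passed by the fork as two-copy; the new copy inherits
        the parent bead's activity at the moment the fork passes it."""
        front = math.floor(self.genome.replication_progress)
        passed = self._gene_bead_idx < front
        newly = passed & (self._copies == 1)
        if newly.any():
            self._act[newly, 1] = self._act[newly, 0]
            self._copies[passed] = 2

    @property
    def n_genes(self) -> int:
        return self._gene_type.size

    def core_pattern(self) -> np.ndarray:
        return _kernels.core_pattern_kernel(self._gene_type, self._act, self._copies)

    def is_absorbed(self) -> bool:
        """True iff every gene copy is inactive: with all thresholds >= 1 no
        site can ever bind again, so the expression state is provably stuck
        and the cell can never divide."""
        return not self._act.any()

    def expression_state(self) -> np.ndarray:
        """Activity bits per gene instance (copy-number aware), in genome order."""
        out = []
        for g in range(self.n_genes):
            out.append(int(self._act[g, 0]))
            if self._copies[g] == 2:
                out.append(int(self._act[g, 1]))
        return np.array(out, dtype=np.uint8)

    def set_core_activity(self, pattern) -> None:
        """Force every gene's activity to its type's bit in ``pattern``."""
        bits = np.asarray(pattern, dtype=np.uint8)
        self._act[:, 0] = bits[self._gene_type]
        self._act[:, 1] = np.where(self._copies == 2, bits[self._gene_type], 0).astype(np.uint8)

    def expression_step(self, rng: np.random.Generator) -> np.ndarray:
        """One synchronous stochastic update of all gene copies; returns the
        new 5-bit core pattern."""
        u = rng.random(self._max_draws) if self._max_draws else np.empty(0)
        _kernels.expression_step_kernel(
            self._gene_type, self._gene_thresh, self._act, self._copies,
            self._site_ptr, self._site_target, self._site_weight,
            self.half_saturation, u, self._act_buf,
        )
        self._act, self._act_buf = self._act_buf, self._act
        return self.core_pattern()

    def advance(self, nutrient_share: float, rng: np.random.Generator) -> CellEvent:
        """One AUT of life: expression update, stage detection, S-stage
        replication, and the divide/die decision at M."""
        u = rng.random(self._max_draws) if self._max_draws else _EMPTY
        stage_idx, absorbed = _kernels.advance_kernel(
            self._gene_type, self._gene_thresh, self._act, self._copies,
            self._site_ptr, self._site_target, self._site_weight,
            self.half_saturation, u, self._act_buf, self.table.array,
        )
        self._act, self._act_buf = self._act_buf, self._act
        stage = STAGE_ORDER[stage_idx] if stage_idx >= 0 else Stage.NONE
        self.stage = stage
        self.age += 1
        if stage is Stage.S:
            advance_fork(self.genome, nutrient_share)
            self._sync_copies()
        if stage in (Stage.G1, Stage.S, Stage.G2) and stage not in self.visited:
            self.visited.append(stage)
        if stage is Stage.M:
            if self.genome.replication_complete and self.visited == [Stage.G1, Stage.S, Stage.G2]:
                return CellEvent.DIVIDE
            return CellEvent.DIE
        if absorbed:
            # complete regulatory shutdown: no site can ever bind again, so
            # the cell is provably unable to cycle and dies
            return CellEvent.DIE
        return CellEvent.NONE

    def divide(self, rates: MutationRates, rng: np.random.Generator) -> tuple["Cell", "Cell"]:
        """Split into two daughter cells; each daughter genome is mutated
        independently and daughter copies inherit this cell's per-copy
        activities."""
        d0, d1 = finish_division(self.genome)
        for g, i in enumerate(self._gene_bead_idx):
            d0.beads[i].activity = int(self._act[g, 0])
            d1.beads[i].activity = int(self._act[g, 1] if self._copies[g] == 2 else self._act[g, 0])
        if (rates.dup or rates.delete or rates.weight_shift or rates.threshold_shift
                or rates.type_flip or rates.innovation):
            m0 = mutate_genome(d0, rates, rng)
            m1 = mutate_genome(d1, rates, rng)
            c0 = self._daughter(m0) if m0 is d0 else Cell(m0, self.table, self.half_saturation)
            c1 = self._daughter(m1) if m1 is d1 else Cell(m1, self.table, self.half_saturation)
            return c0, c1
        return self._daughter(d0), self._daughter(d1)

    def _daughter(self, genome: Genome) -> "Cell":
        """Fast construction of a daughter whose genome has the parent's
        structure: reuse the compiled arrays instead of recompiling."""
        c = object.__new__(Cell)
        c.genome = genome
        c.table = self.table
        c.half_saturation = self.half_saturation
        c.stage = Stage.NONE
        c.visited = []
        c.age = 0
        c._gene_bead_idx = self._gene_bead_idx
        c._gene_type = self._gene_type
        c._gene_thresh = self._gene_thresh.copy()
        c._act = np.zeros_like(self._act)
        c._act[:, 0] = [genome.beads[i].activity for i in self._gene_bead_idx]
        for g, i in enumerate(self._gene_bead_idx):
            c._gene_thresh[g] = genome.beads[i].threshold
        c._act_buf = np.zeros_like(self._act)
        c._copies = np.ones_like(self._copies)
        c._site_ptr = self._site_ptr
        c._site_target = self._site_target
        c._site_weight = self._site_weight
        c._max_draws = self._max_draws
        return c


def expression_step(cell: Cell, rng: np.random.Generator) -> np.ndarray:
    """Functional wrapper over :meth:`Cell.expression_step`."""
    return cell.expression_step(rng)


def advance_cell(cell: Cell, nutrient_share: float, rng: np.random.Generator) -> CellEvent:
    """Functional wrapper over :meth:`Cell.advance`."""
    return cell.advance(nutrient_share, rng)
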