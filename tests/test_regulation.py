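"""Expression dynamics, stage detection and the per-cell divide/die update."""

import itertools

import numpy as np
import pytest

from holosim.fixtures import enumerate_deterministic_cycle, load_wiring
from holosim.genome import Bead, BeadKind, ConfigError, Genome, MutationRates, make_primitive_genome
from holosim.regulation import (
    Cell,
    CellEvent,
    Stage,
    StageSignatureTable,
    binding_probability,
    detect_stage,
)


def test_binding_probability_values_and_validation():
    assert binding_probability(0, 1.0) == 0.0
    assert binding_probability(1, 1.0) == 0.5
    assert abs(binding_probability(1000, 1.0) - 1.0) < 1e-3
    with pytest.raises(ConfigError):
        binding_probability(1, 0.0)


def test_binding_probability_monotone_in_copies():
    ps = [binding_probability(a, 0.7) for a in range(6)]
    assert all(b > a for a, b in zip(ps, ps[1:]))


def test_stage_table_validation(stage_table):
    assert detect_stage(stage_table.patterns[Stage.M], stage_table) is Stage.M
    assert detect_stage((1, 1, 1, 1, 1), stage_table) is Stage.NONE
    dup = {s: stage_table.patterns[s] for s in stage_table.patterns}
    dup[Stage.S] = dup[Stage.G1]
    with pytest.raises(ConfigError):
        StageSignatureTable(dup)


def test_no_binding_sites_means_no_expression(stage_table, rng):
    beads = [Bead(BeadKind.REGULATORY_GENE, type_id=t, threshold=1, activity=1) for t in range(5)]
    cell = Cell(Genome(beads), stage_table, half_saturation=1.0)
    core = cell.expression_step(rng)
    assert not core.any()


def _brute_force_map(table):
    """Independent deterministic-limit oracle: 5-bit core update computed
    straight from the wiring definition (site bound iff target active)."""
    wiring = load_wiring()
    # assignment: each site regulates the nearest downstream regulator
    assigned = []
    pending = []
    for b in wiring:
        if b.kind is BeadKind.BINDING_SITE:
            pending.append((b.type_id, b.weight))
        else:
            assigned.append((b.type_id, b.threshold, list(pending)))
            pending = []

    def step(state):
        out = [0] * 5
        for gene_type, threshold, sites in assigned:
            total = sum(w for tgt, w in sites if state[tgt])
            out[gene_type] = int(total >= threshold)
        return tuple(out)

    return step


def test_deterministic_clock_matches_exhaustive_enumeration(clock, stage_table, rng):
    """In the deterministic limit the compiled dynamics must agree with a
    brute-force truth-table of the wiring from *every* one of the 2^5 core
    states, and the clock trajectory must be the designed 4-cycle."""
    oracle = _brute_force_map(stage_table)
    for state in itertools.product((0, 1), repeat=5):
        cell = Cell(clock.genome.copy(), stage_table, half_saturation=0.0)
        cell.set_core_activity(state)
        got = tuple(int(b) for b in cell.expression_step(rng))
        assert got == oracle(state), f"mismatch from state {state}"
    stages, period = enumerate_deterministic_cycle(clock.genome, stage_table)
    assert period == 4
    assert stages == [Stage.G1, Stage.S, Stage.G2, Stage.M]


def test_every_deterministic_trajectory_enters_a_cycle(clock, stage_table, rng):
    """Deterministic 5-bit dynamics must recur within 2^5 steps from any
    initial core state."""
    for state in itertools.product((0, 1), repeat=5):
        cell = Cell(clock.genome.copy(), stage_table, half_saturation=0.0)
        cell.set_core_activity(state)
        seen = set()
        for _ in range(33):
            key = cell._act.tobytes()
            if key in seen:
                break
            seen.add(key)
            cell.expression_step(rng)
        else:
            pytest.fail(f"no recurrence within 2^5 steps from {state}")


def test_premature_m_kills_and_complete_cycle_divides(clock, stage_table, rng):
    # full cycle at saturating share: DIVIDE on reaching M
    cell = Cell(clock.genome.copy(), stage_table, half_saturation=0.0)
    events = [cell.advance(float(clock.genome.size), rng) for _ in range(4)]
    assert events == [CellEvent.NONE, CellEvent.NONE, CellEvent.NONE, CellEvent.DIVIDE]
    assert cell.age == clock.period
    # starved cell: replication incomplete at M -> DIE
    cell = Cell(clock.genome.copy(), stage_table, half_saturation=0.0)
    events = [cell.advance(1.0, rng) for _ in range(4)]
    assert events[-1] == CellEvent.DIE


def test_skipped_stage_kills(clock, stage_table, rng):
    """A cell entering M without having visited G1/S/G2 in order dies even
    with a replicated genome."""
    g = clock.genome.copy()
    g.replication_progress = float(g.size)
    cell = Cell(g, stage_table, half_saturation=0.0)
    cell.set_core_activity(stage_table.patterns[Stage.G2])  # next step lands on M
    assert cell.advance(100.0, rng) is CellEvent.DIE


def test_daughters_inherit_per_copy_activity(clock, stage_table, rng):
    cell = Cell(clock.genome.copy(), stage_table, half_saturation=0.0)
    for _ in range(3):
        cell.advance(float(clock.genome.size), rng)
    d0, d1 = cell.divide(MutationRates.zero(), rng)
    for d in (d0, d1):
        assert d.genome.replication_progress == 0.0
        assert d.age == 0 and d.visited == []
        assert d.genome.signature() == clock.genome.signature()
    assert np.array_equal(d0._act[:, 0], d1._act[:, 0])  # copies made at the same fork pass


def test_replicated_copies_double_active_count(clock, stage_table, rng):
    cell = Cell(clock.genome.copy(), stage_table, half_saturation=0.0)
    cell.advance(float(clock.genome.size), rng)  # G1
    cell.advance(float(clock.genome.size), rng)  # S: full replication in one step
    assert cell.genome.replication_complete
    assert (cell._copies == 2).all()
    state = cell.expression_state()
    assert state.size == 2 * cell.n_genes


def test_absorbed_cell_dies(stage_table, rng):
    beads = [Bead(BeadKind.REGULATORY_GENE, type_id=t, threshold=1, activity=1) for t in range(5)]
    cell = Cell(Genome(beads), stage_table, half_saturation=1.0)
    assert cell.advance(10.0, rng) is CellEvent.DIE
    assert cell.is_absorbed()
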