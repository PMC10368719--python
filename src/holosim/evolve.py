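"""Experiment driver: primitive-FECA, complex-FECA and free-living runs,
with lineage recording and ancestor tracing.

A run founds a small population on the rich end of the nutrient gradient
and iterates the lattice for a configured number of time steps (AUT),
recording population snapshots, an event log, the holobiont lineage
(parent links, birth/death times, genome summaries at birth) and the final
genotypes.  Identical (config, seed) pairs produce identical outputs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .fixtures import initialize_activity, load_stage_table, load_wiring
from .genome import ConfigError, Genome, make_primitive_genome
from .io import LINEAGE_COLUMNS, SNAPSHOT_COLUMNS, read_genome, write_genome, write_table
from .lattice import EcologyParams, Holobiont, Lattice, RngStreams, share_grid, step_lattice
from .regulation import Cell, Stage, StageSignatureTable

__all__ = ["run_evolution", "RunResult", "LineageRecord", "LineageError",
           "trace_ancestor", "make_complex_feca", "lineage_frame"]

logger = logging.getLogger(__name__)


class LineageError(KeyError):
    """A lineage chain could not be followed (missing/pruned record)."""


@dataclass
class LineageRecord:
    holobiont_id: int
    parent_id: int | None
    birth_time: int
    death_time: int | None
    birth_site: tuple[int, int]
    host_summary: tuple[int, int, int]  # (L, household, repertoire)
    symbiont_summaries: list[tuple[int, int, int]] = field(default_factory=list)


def _summarize(cell: Cell) -> tuple[int, int, int]:
    g = cell.genome
    return (g.size, g.household_count(), g.repertoire_size())


@dataclass
class RunResult:
    config: RunConfig
    lattice: Lattice
    lineage: dict[int, LineageRecord]
    population_trajectory: list[int]
    extinction_time: int | None
    snapshots: pd.DataFrame
    out_dir: Path | None

    def final_cells(self) -> list[tuple[str, Cell]]:
        out = []
        for holo in self.lattice.occupants.values():
            out.extend(holo.cells())
        return out

    def mean_total_genome_size(self) -> float | None:
        """Mean over holobionts of (host L + summed symbiont L); None if
        extinct."""
        if not self.lattice.occupants:
            return None
        totals = [h.host.genome.size + sum(s.genome.size for s in h.symbionts)
                  for h in self.lattice.occupants.values()]
        return float(np.mean(totals))


def _founder_genomes(config: RunConfig, table: StageSignatureTable) -> tuple[Genome, Genome]:
    mode = config.experiment.mode
    if mode == "complex_feca":
        host = initialize_activity(read_genome(config.experiment.host_genome), table)
        symb = initialize_activity(read_genome(config.experiment.symbiont_genome), table)
        return host, symb
    wiring = load_wiring(None if config.genome.wiring == "primitive" else config.genome.wiring)
    g = make_primitive_genome(wiring, config.genome.households,
                              stage_m_pattern=table.patterns[Stage.M])
    return g, g.copy()


def _seed_population(lattice: Lattice, config: RunConfig, table: StageSignatureTable) -> None:
    """Found the run: every 5th site of the three richest sectors carries a
    holobiont of 1 host + ``initial_symbionts`` symbionts (or one free
    cell)."""
    host_g, symb_g = _founder_genomes(config, table)
    eco = config.ecology
    k = config.experiment.initial_symbionts
    half_sat = config.regulation.half_saturation
    n_sectors = len(eco.sector_influxes)
    width = eco.cols // n_sectors
    rich_start = (n_sectors - min(3, n_sectors)) * width
    sites = [(r, c) for r in range(eco.rows) for c in range(rich_start, eco.cols)]
    for j, site in enumerate(sites):
        if j % 5:
            continue
        host = Cell(host_g.copy(), table, half_sat)
        if config.experiment.mode == "free_living":
            symbionts = []
        else:
            symbionts = [Cell(symb_g.copy(), table, half_sat) for _ in range(k)]
        lattice.place(site, Holobiont(lattice.new_id(), None, host, symbionts))


def _snapshot_rows(lattice: Lattice, t: int) -> list[dict]:
    grid = share_grid(lattice)
    rows = []
    for (r, c), holo in sorted(lattice.occupants.items()):
        for role, cell in holo.cells():
            g = cell.genome
            rows.append({
                "time": t, "row": r, "col": c, "holobiont_id": holo.id, "role": role,
                "genome_size": g.size, "household_count": g.household_count(),
                "regulatory_repertoire": g.repertoire_size(), "stage": cell.stage.value,
                "symbiont_count_of_holobiont": len(holo.symbionts),
                "nutrient_share": round(float(grid[r, c]), 6),
            })
    return rows


def run_evolution(config: RunConfig, out_dir=None) -> RunResult:
    """Execute one evolution experiment; see module docstring.

    When ``out_dir`` is given, snapshots, the lineage table, an event log
    and the final genomes are written there as versioned TSV files.
    """
    table = (load_stage_table() if config.regulation.stage_table == "default"
             else load_stage_table(config.regulation.stage_table))
    eco_cfg = config.ecology
    eco = EcologyParams(
        d=eco_cfg.d, inheritance_p=eco_cfg.inheritance_p, h_min=eco_cfg.h_min,
        h_min_free=eco_cfg.h_min_free, free_living=(config.experiment.mode == "free_living"),
        household_at_division_only=eco_cfg.household_at_division_only,
    )
    rates = config.mutation.rates()
    n_sectors = len(eco_cfg.sector_influxes)
    sectors = [(eco_cfg.cols // n_sectors, float(f)) for f in eco_cfg.sector_influxes]
    lattice = Lattice(eco_cfg.rows, eco_cfg.cols, sectors=sectors)
    _seed_population(lattice, config, table)

    streams = RngStreams.from_seed(config.seed)
    lineage: dict[int, LineageRecord] = {}
    for site, holo in sorted(lattice.occupants.items()):
        lineage[holo.id] = LineageRecord(holo.id, None, 0, None, site,
                                         _summarize(holo.host),
                                         [_summarize(s) for s in holo.symbionts])

    snapshot_rows = _snapshot_rows(lattice, 0)
    trajectory = [lattice.population()]
    extinction_time = None
    event_rows = []
    horizon = config.experiment.lineage_prune_horizon

    for t in range(1, config.experiment.duration + 1):
        log = step_lattice(lattice, eco, rates, streams, time=t)
        for child, parent, site in log.births:
            holo = lattice.occupants.get(site)
            if holo is not None and holo.id == child:
                lineage[child] = LineageRecord(child, parent, t, None, site,
                                               _summarize(holo.host),
                                               [_summarize(s) for s in holo.symbionts])
        for hid in log.deaths:
            if hid in lineage:
                lineage[hid].death_time = t
        trajectory.append(lattice.population())
        event_rows.append({
            "time": t, "population": lattice.population(), "cells": lattice.cell_count(),
            "random_deaths": log.random_deaths, "cycle_deaths": log.cycle_deaths,
            "symbiont_divisions": log.symbiont_divisions, "host_divisions": log.host_divisions,
            "household_removals": log.household_removals,
        })
        if t % config.experiment.snapshot_every == 0:
            snapshot_rows.extend(_snapshot_rows(lattice, t))
        if t % config.experiment.log_every == 0:
            logger.info("t=%d population=%d cells=%d", t, lattice.population(), lattice.cell_count())
        if horizon is not None and t % max(1, horizon) == 0:
            _prune_lineage(lineage, lattice, t, horizon)
        if not lattice.occupants:
            extinction_time = t
            logger.info("population extinct at t=%d", t)
            break

    snapshots = pd.DataFrame(snapshot_rows, columns=SNAPSHOT_COLUMNS)
    result = RunResult(config, lattice, lineage, trajectory, extinction_time, snapshots,
                       Path(out_dir) if out_dir is not None else None)
    if out_dir is not None:
        _write_outputs(result, pd.DataFrame(event_rows))
    return result


def _prune_lineage(lineage: dict[int, LineageRecord], lattice: Lattice, t: int, horizon: int) -> None:
    """Drop dead side-branch records older than the horizon; the ancestral
    chain of every living holobiont is never pruned."""
    keep: set[int] = set()
    for holo in lattice.occupants.values():
        hid = holo.id
        while hid is not None and hid not in keep:
            keep.add(hid)
            rec = lineage.get(hid)
            hid = rec.parent_id if rec else None
    for hid in [h for h, rec in lineage.items()
                if h not in keep and rec.death_time is not None and rec.death_time < t - horizon]:
        del lineage[hid]


def lineage_frame(lineage: dict[int, LineageRecord]) -> pd.DataFrame:
    rows = []
    for rec in sorted(lineage.values(), key=lambda r: r.holobiont_id):
        sy = np.array(rec.symbiont_summaries) if rec.symbiont_summaries else np.zeros((0, 3))
        rows.append({
            "holobiont_id": rec.holobiont_id,
            "parent_id": -1 if rec.parent_id is None else rec.parent_id,
            "birth_time": rec.birth_time,
            "death_time": -1 if rec.death_time is None else rec.death_time,
            "birth_row": rec.birth_site[0], "birth_col": rec.birth_site[1],
            "host_size": rec.host_summary[0], "host_household": rec.host_summary[1],
            "host_repertoire": rec.host_summary[2],
            "n_symbionts": len(rec.symbiont_summaries),
            "symbiont_mean_size": float(sy[:, 0].mean()) if len(sy) else 0.0,
            "symbiont_mean_household": float(sy[:, 1].mean()) if len(sy) else 0.0,
            "symbiont_mean_repertoire": float(sy[:, 2].mean()) if len(sy) else 0.0,
        })
    return pd.DataFrame(rows, columns=LINEAGE_COLUMNS)


def _write_outputs(result: RunResult, events: pd.DataFrame) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    write_table(result.snapshots, out / "snapshots.tsv", "snapshot")
    write_table(lineage_frame(result.lineage), out / "lineage.tsv", "lineage")
    write_table(events, out / "events.tsv", "events")
    meta = pd.DataFrame([{
        "duration": result.config.experiment.duration,
        "seed": result.config.seed,
        "extinction_time": -1 if result.extinction_time is None else result.extinction_time,
        "final_population": result.lattice.population(),
    }])
    write_table(meta, out / "run_meta.tsv", "meta")
    gdir = out / "final_genomes"
    gdir.mkdir(exist_ok=True)
    for role in ("host", "symbiont"):
        for rank, (genome, count) in enumerate(_genotype_census(result, role)[:20]):
            write_genome(genome, gdir / f"{role}_{rank:03d}.tsv",
                         metadata={"count": count, "role": role, "rank": rank})


def _genotype_census(result: RunResult, role: str) -> list[tuple[Genome, int]]:
    counts: Counter = Counter()
    example: dict[tuple, Genome] = {}
    for r, cell in result.final_cells():
        if r != role:
            continue
        sig = cell.genome.signature()
        counts[sig] += 1
        example.setdefault(sig, cell.genome)
    return [(example[sig], n) for sig, n in counts.most_common()]


def trace_ancestor(lineage: dict[int, LineageRecord], holobiont_id: int, time: int) -> LineageRecord:
    """The unique ancestor of ``holobiont_id`` alive at ``time``, found by
    following parent links; raises :class:`LineageError` on a broken chain."""
    if holobiont_id not in lineage:
        raise LineageError(f"holobiont {holobiont_id} not in lineage")
    rec = lineage[holobiont_id]
    while rec.birth_time > time:
        if rec.parent_id is None:
            raise LineageError(
                f"holobiont {holobiont_id} has no ancestor at time {time} "
                f"(chain reaches founder {rec.holobiont_id} born at {rec.birth_time})")
        if rec.parent_id not in lineage:
            raise LineageError(f"lineage chain broken at pruned record {rec.parent_id}")
        rec = lineage[rec.parent_id]
    return rec


def make_complex_feca(result: RunResult, host_path, symbiont_path,
                      host_pick: int = 0, symbiont_pick: int = 0,
                      symbiont_result: RunResult | None = None) -> tuple[Path, Path]:
    """Write host and symbiont genome files for a complex-FECA start from
    the final genotypes of free-living (or holobiont) runs.

    Picks are abundance ranks (0 = most abundant).  Passing the same result
    and picks mimics identical host/symbiont starts; using two runs (via
    ``symbiont_result``) mimics mixed pairs.
    """
    sres = symbiont_result if symbiont_result is not None else result

    def pick(res: RunResult, rank: int) -> Genome:
        if not res.lattice.occupants:
            raise ConfigError("cannot pick founder genomes from an extinct run")
        census = _genotype_census(res, "host")
        if res.config.experiment.mode != "free_living" and not census:
            census = _genotype_census(res, "symbiont")
        if rank >= len(census):
            raise ConfigError(f"genotype rank {rank} out of range ({len(census)} genotypes)")
        return census[rank][0]

    host_g, symb_g = pick(result, host_pick), pick(sres, symbiont_pick)
    write_genome(host_g, host_path, metadata={"role": "host", "pick": host_pick})
    write_genome(symb_g, symbiont_path, metadata={"role": "symbiont", "pick": symbiont_pick})
    return Path(host_path), Path(symbiont_path)
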