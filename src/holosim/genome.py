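"""Bead-string genomes, replication-fork bookkeeping and mutation operators.

A genome is an ordered string of discrete *beads*: regulatory genes (one of
five core cell-cycle regulator types, each with an integer activation
threshold), household genes (no regulatory role; they stand in for all
non-cell-cycle functions), and transcription-factor binding sites (each
targeting one regulator type with an integer weight).  The genome is
replicated explicitly by a single fork whose speed is set by the nutrients
the cell receives, so genome size directly constrains cell-cycle speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "BeadKind",
    "Bead",
    "Genome",
    "MutationRates",
    "GenomeError",
    "ConfigError",
    "make_primitive_genome",
    "mutate_genome",
    "advance_fork",
    "copy_number",
    "finish_division",
]

N_TYPES = 5  # core cell-cycle regulator types
WEIGHT_MIN, WEIGHT_MAX = -2, 2


class GenomeError(ValueError):
    """Contract violation on a genome operation."""


class ConfigError(ValueError):
    """Invalid configuration value."""


class BeadKind(str, Enum):
    REGULATORY_GENE = "REG"
    HOUSEHOLD_GENE = "HOUSE"
    BINDING_SITE = "BS"


@dataclass(slots=True)
class Bead:
    """One genome element.

    ``type_id`` is the regulator type for a REG bead and the *target* type
    for a BS bead; ``threshold`` applies to REG beads only, ``weight`` to BS
    beads only (nonzero, in [-2, 2]).  ``activity`` is the initial/current
    expression bit of a REG bead.
    """

    kind: BeadKind
    type_id: int = -1
    threshold: int = 1
    weight: int = 0
    activity: int = 0

    def __post_init__(self) -> None:
        if self.kind is BeadKind.REGULATORY_GENE:
            if not (0 <= self.type_id < N_TYPES):
                raise ConfigError(f"regulatory gene type_id {self.type_id} not in 0..{N_TYPES - 1}")
            if self.threshold < 1:
                raise ConfigError("regulatory gene threshold must be >= 1")
        elif self.kind is BeadKind.BINDING_SITE:
            if not (0 <= self.type_id < N_TYPES):
                raise ConfigError(f"binding site target {self.type_id} not in 0..{N_TYPES - 1}")
            if self.weight == 0 or not (WEIGHT_MIN <= self.weight <= WEIGHT_MAX):
                raise ConfigError(f"binding site weight {self.weight} must be nonzero in [{WEIGHT_MIN}, {WEIGHT_MAX}]")

    def clone(self) -> "Bead":
        # hot path at division: bypass dataclass plumbing and re-validation
        b = object.__new__(Bead)
        b.kind = self.kind
        b.type_id = self.type_id
        b.threshold = self.threshold
        b.weight = self.weight
        b.activity = self.activity
        return b


def _regulatory_gene(type_id: int, threshold: int = 1, activity: int = 0) -> Bead:
    return Bead(BeadKind.REGULATORY_GENE, type_id=type_id, threshold=threshold, activity=activity)


def _household_gene() -> Bead:
    return Bead(BeadKind.HOUSEHOLD_GENE)


def _binding_site(target: int, weight: int) -> Bead:
    return Bead(BeadKind.BINDING_SITE, type_id=target, weight=weight)


@dataclass
class Genome:
    """An ordered bead string with a replication fork.

    ``replication_progress`` is a real number in [0, L]; beads strictly below
    ``floor(progress)`` are present in two copies.  Fractional nutrient
    credit carries over between S-steps rather than being floored, so
    replication never stalls at low influx.
    """

    beads: list[Bead] = field(default_factory=list)
    replication_progress: float = 0.0
    _household_count: int | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def size(self) -> int:
        """Total genome size L (bead count)."""
        return len(self.beads)

    @property
    def fractional_credit(self) -> float:
        return self.replication_progress - math.floor(self.replication_progress)

    @property
    def replication_complete(self) -> bool:
        return self.replication_progress >= len(self.beads)

    def household_count(self) -> int:
        # beads are fixed after construction (mutation builds a new genome),
        # so the count is computed once
        if self._household_count is None:
            self._household_count = sum(1 for b in self.beads if b.kind is BeadKind.HOUSEHOLD_GENE)
        return self._household_count

    def regulatory_gene_count(self) -> int:
        return sum(1 for b in self.beads if b.kind is BeadKind.REGULATORY_GENE)

    def binding_site_count(self) -> int:
        return sum(1 for b in self.beads if b.kind is BeadKind.BINDING_SITE)

    def repertoire_size(self, include_sites: bool = True) -> int:
        """Regulatory repertoire size R: regulator genes plus (by default)
        binding sites."""
        n = self.regulatory_gene_count()
        if include_sites:
            n += self.binding_site_count()
        return n

    def copy(self) -> "Genome":
        return Genome([b.clone() for b in self.beads], self.replication_progress)

    def signature(self) -> tuple:
        """Hashable genotype identity (ignores fork state and activity)."""
        return tuple(
            (b.kind.value, b.type_id, b.threshold if b.kind is BeadKind.REGULATORY_GENE else 0,
             b.weight if b.kind is BeadKind.BINDING_SITE else 0)
            for b in self.beads
        )


@dataclass(frozen=True)
class MutationRates:
    """Per-bead, per-division mutation probabilities.

    ``innovation`` is per genome per division (insert one random binding
    site at a random position).  The ``prokaryote_like`` regime multiplies
    every rate by ten.
    """

    dup: float = 5e-4
    delete: float = 5e-4
    weight_shift: float = 1e-3
    threshold_shift: float = 1e-3
    type_flip: float = 1e-3
    innovation: float = 1e-3
    regime: str = "default"

    def __post_init__(self) -> None:
        for name in ("dup", "delete", "weight_shift", "threshold_shift", "type_flip", "innovation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"mutation rate {name}={v} not in [0, 1]")
        if self.regime not in ("default", "prokaryote_like"):
            raise ConfigError(f"unknown mutation regime {self.regime!r}")

    @classmethod
    def zero(cls) -> "MutationRates":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    @classmethod
    def for_regime(cls, regime: str = "default") -> "MutationRates":
        base = cls()
        if regime == "default":
            return base
        if regime == "prokaryote_like":
            return cls(
                dup=base.dup * 10, delete=base.delete * 10,
                weight_shift=base.weight_shift * 10, threshold_shift=base.threshold_shift * 10,
                type_flip=base.type_flip * 10, innovation=min(1.0, base.innovation * 10),
                regime="prokaryote_like",
            )
        raise ConfigError(f"unknown mutation regime {regime!r}")


def make_primitive_genome(
    wiring: list[Bead],
    households: int = 50,
    stage_m_pattern: tuple[int, ...] = (1, 0, 0, 1, 0),
) -> Genome:
    """Assemble the primitive genome: the wiring table's regulator genes and
    binding sites followed by ``households`` household genes.

    Regulator activities are initialised to the M-stage signature so a fresh
    cell enters the cycle at G1 on its first update (exactly as a newborn
    daughter does).
    """
    if len(stage_m_pattern) != N_TYPES:
        raise ConfigError("stage_m_pattern must have one bit per regulator type")
    beads: list[Bead] = []
    n_reg = [0] * N_TYPES
    for b in wiring:
        if b.kind is BeadKind.HOUSEHOLD_GENE:
            raise ConfigError("wiring table may not contain household genes")
        nb = b.clone()
        if nb.kind is BeadKind.REGULATORY_GENE:
            n_reg[nb.type_id] += 1
            nb.activity = int(stage_m_pattern[nb.type_id])
        beads.append(nb)
    if any(n != 1 for n in n_reg):
        raise ConfigError(f"primitive wiring must contain exactly one regulator of each of the {N_TYPES} types, got {n_reg}")
    if households < 0:
        raise ConfigError("household count must be >= 0")
    beads.extend(_household_gene() for _ in range(households))
    return Genome(beads)


def mutate_genome(genome: Genome, rates: MutationRates, rng: np.random.Generator) -> Genome:
    """Apply per-bead duplication/deletion/shift mutations plus per-genome
    binding-site innovation; returns a fresh single-copy genome.

    Duplicates are placed adjacent (tandem) to the original, so a duplicated
    site keeps regulating the same downstream gene.  An empty genome is a
    legal (inviable) outcome.
    """
    L = len(genome.beads)
    innovate = rates.innovation > 0 and rng.random() < rates.innovation
    if L:
        # one vectorized draw block per operator (per-bead independent events)
        hit_del = rng.random(L) < rates.delete if rates.delete > 0 else None
        hit_dup = rng.random(L) < rates.dup if rates.dup > 0 else None
        hit_w = rng.random(L) < rates.weight_shift if rates.weight_shift > 0 else None
        hit_t = rng.random(L) < rates.type_flip if rates.type_flip > 0 else None
        hit_th = rng.random(L) < rates.threshold_shift if rates.threshold_shift > 0 else None
        if not innovate and not any(h is not None and h.any()
                                    for h in (hit_del, hit_dup, hit_w, hit_t, hit_th)):
            return genome  # no mutation event fired
    out: list[Bead] = []
    for i, bead in enumerate(genome.beads):
        # dup and del are independent per-bead events; a bead hit by both
        # nets out to a single copy, so E[dL] = 0 exactly when dup = del
        deleted = hit_del is not None and hit_del[i]
        duplicated = hit_dup is not None and hit_dup[i]
        n_copies = 1 - int(deleted) + int(duplicated)
        if n_copies == 0:
            continue
        nb = bead.clone()
        if nb.kind is BeadKind.BINDING_SITE:
            if hit_w is not None and hit_w[i]:
                nb.weight = _shift_weight(nb.weight, rng)
            if hit_t is not None and hit_t[i]:
                nb.type_id = _flip_type(nb.type_id, rng)
        elif nb.kind is BeadKind.REGULATORY_GENE:
            if hit_th is not None and hit_th[i]:
                nb.threshold = max(1, nb.threshold + (1 if rng.random() < 0.5 else -1))
        out.append(nb)
        if n_copies == 2:
            out.append(nb.clone())
    if innovate:
        weight = int(rng.choice([-2, -1, 1, 2]))
        site = _binding_site(int(rng.integers(N_TYPES)), weight)
        out.insert(int(rng.integers(len(out) + 1)), site)
    return Genome(out)


def _shift_weight(weight: int, rng: np.random.Generator) -> int:
    step = 1 if rng.random() < 0.5 else -1
    w = weight + step
    if w == 0:
        w += step
    return int(min(WEIGHT_MAX, max(WEIGHT_MIN, w)))


def _flip_type(current: int, rng: np.random.Generator) -> int:
    t = int(rng.integers(N_TYPES - 1))
    return t if t < current else t + 1


def advance_fork(genome: Genome, credit: float) -> Genome:
    """Advance the replication fork by ``credit`` beads (the cell's nutrient
    share this S-step); fractional remainders accumulate; capped at L."""
    if credit < 0:
        raise GenomeError(f"replication credit must be >= 0, got {credit}")
    genome.replication_progress = min(float(len(genome.beads)), genome.replication_progress + credit)
    return genome


def copy_number(genome: Genome, bead_index: int) -> int:
    """Copy number of the bead at ``bead_index``: 2 once the fork has fully
    passed it, else 1."""
    if not (0 <= bead_index < len(genome.beads)):
        raise GenomeError(f"bead index {bead_index} out of range for genome of size {len(genome.beads)}")
    return 2 if bead_index < math.floor(genome.replication_progress) else 1


def finish_division(genome: Genome) -> tuple[Genome, Genome]:
    """Split a fully replicated genome into two single-copy daughters with
    fork state reset; mutation is applied downstream by the caller.

    The first daughter takes over the parent's bead objects (the parent
    genome is consumed); the second gets fresh copies.
    """
    if not genome.replication_complete:
        raise GenomeError(
            f"cannot divide with incomplete replication ({genome.replication_progress:.2f}/{len(genome.beads)})"
        )
    return Genome(genome.beads), Genome([b.clone() for b in genome.beads])
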