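"""TSV readers and writers for genomes, snapshots, trajectories and lineages.

Every format carries a ``# holosim-<kind> v<N>`` version header; readers
reject unknown kinds/versions and report malformed rows with their line
number.  All functions accept plain or gzip-compressed paths transparently.
"""

from __future__ import annotations

import gzip
from pathlib import Path


import pandas as pd

from .genome import Bead, BeadKind, Genome

__all__ = [
    "FormatError",
    "read_genome",
    "write_genome",
    "read_table",
    "write_table",
    "SNAPSHOT_COLUMNS",
    "TRAJECTORY_COLUMNS",
    "LINEAGE_COLUMNS",
]

GENOME_MAGIC = "# holosim-genome v1"

SNAPSHOT_COLUMNS = [
    "time", "row", "col", "holobiont_id", "role", "genome_size",
    "household_count", "regulatory_repertoire", "stage",
    "symbiont_count_of_holobiont", "nutrient_share",
]
TRAJECTORY_COLUMNS = ["time", "stage", "t0", "t1", "t2", "t3", "t4", "replication_progress"]
LINEAGE_COLUMNS = [
    "holobiont_id", "parent_id", "birth_time", "death_time", "birth_row", "birth_col",
    "host_size", "host_household", "host_repertoire",
    "n_symbionts", "symbiont_mean_size", "symbiont_mean_household", "symbiont_mean_repertoire",
]


class FormatError(ValueError):
    """Malformed or unsupported file content."""


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_genome(genome: Genome, path, metadata: dict | None = None) -> None:
    with _open(path, "wt") as fh:
        fh.write(GENOME_MAGIC + "\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("index\tkind\ttype_id\tthreshold\tweight\n")
        for i, b in enumerate(genome.beads):
            if b.kind is BeadKind.REGULATORY_GENE:
                fh.write(f"{i}\tREG\t{b.type_id}\t{b.threshold}\t\n")
            elif b.kind is BeadKind.BINDING_SITE:
                fh.write(f"{i}\tBS\t{b.type_id}\t\t{b.weight}\n")
            else:
                fh.write(f"{i}\tHOUSE\t\t\t\n")


def read_genome(path) -> Genome:
    """Parse a bead-table genome file; lossless inverse of
    :func:`write_genome` (fork state is not persisted)."""
    beads: list[Bead] = []
    with _open(path, "rt") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != GENOME_MAGIC:
        head = lines[0].strip() if lines else "<empty file>"
        raise FormatError(f"{path}: line 1: expected header {GENOME_MAGIC!r}, found {head!r}")
    seen_columns = False
    expected_index = 0
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if not seen_columns:
            cols = line.split("\t")
            if cols[:5] != ["index", "kind", "type_id", "threshold", "weight"]:
                raise FormatError(f"{path}: line {lineno}: unexpected column header {cols}")
            seen_columns = True
            continue
        fields = line.split("\t")
        fields += [""] * (5 - len(fields))
        idx_s, kind_s, type_s, thr_s, w_s = (f.strip() for f in fields[:5])
        try:
            idx = int(idx_s)
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: bad bead index {idx_s!r}") from exc
        if idx != expected_index:
            raise FormatError(f"{path}: line {lineno}: bead index {idx} out of order (expected {expected_index})")
        expected_index += 1
        try:
            if kind_s == "REG":
                beads.append(Bead(BeadKind.REGULATORY_GENE, type_id=int(type_s), threshold=int(thr_s)))
            elif kind_s == "BS":
                beads.append(Bead(BeadKind.BINDING_SITE, type_id=int(type_s), weight=int(w_s)))
            elif kind_s == "HOUSE":
                beads.append(Bead(BeadKind.HOUSEHOLD_GENE))
            else:
                raise FormatError(f"{path}: line {lineno}: unknown bead kind {kind_s!r}")
        except FormatError:
            raise
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: malformed bead row {line!r}: {exc}") from exc
    if not seen_columns:
        raise FormatError(f"{path}: missing column header row")
    return Genome(beads)


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    """Write a versioned TSV table (snapshots, trajectories, lineages...)."""
    with _open(path, "wt") as fh:
        fh.write(f"# holosim-{kind} v1\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, kind: str) -> pd.DataFrame:
    with _open(path, "rt") as fh:
        magic = fh.readline().strip()
        if magic != f"# holosim-{kind} v1":
            raise FormatError(f"{path}: line 1: expected '# holosim-{kind} v1', found {magic!r}")
        try:
            return pd.read_csv(fh, sep="\t")
        except pd.errors.ParserError as exc:
            raise FormatError(f"{path}: {exc}") from exc
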