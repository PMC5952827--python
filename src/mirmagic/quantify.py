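"""Streaming quantification of a read library against a core index.

Each read is matched once against the core index; counting then follows the
once-per-group contract: a read contributes at most 1 to any single functional
group. When a read matches more than one group, the policy decides:

``all_groups`` (default)
    add 1 to every matched group — the literal once-per-group reading;
``discard_ambiguous``
    count the read only if exactly one group matched;
``fractional``
    split the read as 1/k over the k matched groups.

The number of ambiguous reads is always reported so the policy's impact is
visible. Identical reads are deduplicated internally (match once, multiply by
multiplicity), which is observationally equivalent to per-read matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Union

from .core_matching import CoreIndex, match_read
from .errors import FormatError
from .mirbase_io import PathLike, iter_fastq, normalize_sequence

logger = logging.getLogger(__name__)

POLICIES = ("all_groups", "discard_ambiguous", "fractional")

ReadSource = Union[PathLike, Iterable[str]]


@dataclass
class CountTable:
    """Per-group counts for one library, plus library-level tallies."""

    library_id: str
    counts: dict[str, float]
    n_reads_processed: int
    n_reads_matched: int
    n_reads_ambiguous: int
    policy: str

    @property
    def total_count(self) -> float:
        return sum(self.counts.values())


@dataclass
class LibraryStats:
    """Raw-read tallies used by the accuracy evaluation."""

    library_id: str
    n_raw_reads: int
    n_in_range_19_23: int
    total_count: float

    @property
    def ratio_total_to_raw(self) -> float:
        """Total count / raw reads; NaN when the library is empty."""
        if self.n_raw_reads == 0:
            return float("nan")
        return self.total_count / self.n_raw_reads


def _iter_sequences(reads: ReadSource):
    if isinstance(reads, (str, Path)):
        for _rid, seq in iter_fastq(reads):
            yield seq
    else:
        for seq in reads:
            yield normalize_sequence(seq)


def quantify_library(
    reads: ReadSource,
    index: CoreIndex,
    policy: str = "all_groups",
    library_id: str = "library",
) -> CountTable:
    """Match every read in a FASTQ file (or iterable of sequences) and count.

    The output is dense over the index's group universe: groups with zero
    count are present, so per-library tables align into a matrix downstream.
    Counts are independent of read order.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")

    # Deduplicate identical reads; each unique sequence is matched once.
    multiplicity = Counter(_iter_sequences(reads))

    counts: dict[str, float] = {gid: 0 for gid in index.all_group_ids}
    n_processed = 0
    n_matched = 0
    n_ambiguous = 0
    for seq, m in multiplicity.items():
        n_processed += m
        groups = match_read(seq, index)
        k = len(groups)
        if k == 0:
            continue
        n_matched += m
        if k > 1:
            n_ambiguous += m
        if policy == "all_groups":
            for gid in groups:
                counts[gid] += m
        elif policy == "discard_ambiguous":
            if k == 1:
                counts[next(iter(groups))] += m
        else:  # fractional
            for gid in groups:
                counts[gid] += m / k

    if n_processed == 0:
        logger.warning("library %s: no reads processed (empty input)", library_id)
    return CountTable(
        library_id=library_id,
        counts=counts,
        n_reads_processed=n_processed,
        n_reads_matched=n_matched,
        n_reads_ambiguous=n_ambiguous,
        policy=policy,
    )


def write_counts(
    table: CountTable,
    path: PathLike,
    stats: LibraryStats | None = None,
    stats_path: PathLike | None = None,
) -> None:
    """Write a count table as TSV, rows sorted by group id.

    Integer-valued counts are printed as integers; fractional-policy counts
    with 6 decimal places. An optional sidecar key=value stats file carries
    the library-level tallies.
    """
    with open(path, "wt") as out:
        out.write("#group_id\tcount\n")
        for gid in sorted(table.counts):
            c = table.counts[gid]
            if table.policy == "fractional":
                out.write(f"{gid}\t{c:.6f}\n")
            else:
                out.write(f"{gid}\t{int(c)}\n")
    if stats is not None:
        if stats_path is None:
            raise ValueError("stats_path is required when stats are given")
        write_stats(stats, stats_path, policy=table.policy)


def read_counts(path: PathLike) -> dict[str, float]:
    """Parse a count TSV written by :func:`write_counts`."""
    counts: dict[str, float] = {}
    with open(path, "rt") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            counts[cols[0]] = float(cols[1])
    return counts


def write_stats(stats: LibraryStats, path: PathLike, policy: str = "") -> None:
    with open(path, "wt") as out:
        out.write(f"library_id={stats.library_id}\n")
        out.write(f"n_raw_reads={stats.n_raw_reads}\n")
        out.write(f"n_in_range_19_23={stats.n_in_range_19_23}\n")
        out.write(f"total_count={stats.total_count:.6f}\n")
        out.write(f"ratio_total_to_raw={stats.ratio_total_to_raw:.6f}\n")
        if policy:
            out.write(f"policy={policy}\n")


def read_stats(path: PathLike) -> LibraryStats:
    kv: dict[str, str] = {}
    with open(path, "rt") as handle:
        for raw in handle:
            line = raw.strip()
            if not line or "=" not in line:
                continue
            key, value = line.split("=", 1)
            kv[key] = value
    try:
        return LibraryStats(
            library_id=kv["library_id"],
            n_raw_reads=int(kv["n_raw_reads"]),
            n_in_range_19_23=int(kv["n_in_range_19_23"]),
            total_count=float(kv["total_count"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing stats field {exc}") from exc
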