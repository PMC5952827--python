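"""Exact matching of reads to end-trimmed miRNA core regions.

The core region of a mature miRNA is the interior left after trimming a few
bases from each end. A read matches a functional group when the group's core
appears verbatim as a substring of the read. This absorbs 5' and 3' isomiRs —
templated end-shifts and untemplated end-additions leave the interior intact —
while any internal substitution (a polymorphic isomiR, or a sequencing error
inside the core) destroys the match. No mismatches, indels or alignment
heuristics are involved: matching is exact substring containment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import EmptyIndexError
from .mirbase_io import GroupTable, MatureMiRNA

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoreParams:
    """Core-extraction and read-gating parameters.

    Attributes
    ----------
    trim5, trim3 : int
        Bases removed from the 5'/3' ends of each mature sequence to form its
        core. Defaults of 2 nt each absorb the dominant +/-2 nt end variation
        of isomiRs.
    min_core_len : int
        Matures whose trimmed core would be shorter than this are excluded
        from the index (with a warning); short cores would match promiscuously.
    min_read_len, max_read_len : int
        Reads outside [min_read_len, max_read_len] are never matched; the
        upper gate keeps long non-miRNA fragments that happen to contain a
        core from being counted.
    """

    trim5: int = 2
    trim3: int = 2
    min_core_len: int = 16
    min_read_len: int = 16
    max_read_len: int = 30

    def __post_init__(self) -> None:
        if self.trim5 < 0 or self.trim3 < 0:
            raise ValueError("trim5 and trim3 must be >= 0")
        if self.min_core_len < 1:
            raise ValueError("min_core_len must be >= 1")
        if self.min_read_len > self.max_read_len:
            raise ValueError("min_read_len must be <= max_read_len")


@dataclass
class CoreIndex:
    """Exact-lookup structure from core sequence to functional groups.

    ``entries`` maps each distinct core string to the set of group ids whose
    members carry that core (set semantics: identical matures in one group
    contribute a single entry). ``provenance`` records which miRNAs produced
    each core, for reporting. ``all_group_ids`` is the full group universe of
    the table the index was built from, so that count tables can be emitted
    densely, including zero-count groups.
    """

    params: CoreParams
    entries: dict[str, frozenset[str]]
    core_lengths: tuple[int, ...]
    provenance: dict[str, frozenset[str]]
    all_group_ids: frozenset[str]
    n_excluded: int = 0

    @property
    def n_ambiguous_cores(self) -> int:
        """Number of cores shared by more than one group (ambiguity diagnostic)."""
        return sum(1 for groups in self.entries.values() if len(groups) > 1)


def extract_core(sequence: str, params: CoreParams) -> str | None:
    """Trim ``trim5``/``trim3`` bases off the ends; None if the remainder is
    shorter than ``min_core_len``."""
    core = sequence[params.trim5: len(sequence) - params.trim3]
    if len(core) < params.min_core_len:
        return None
    return core


def build_core_index(
    mirnas: list[MatureMiRNA],
    groups: GroupTable,
    params: CoreParams | None = None,
) -> CoreIndex:
    """Build the exact core -> groups lookup for a reference and group table."""
    if params is None:
        params = CoreParams()
    missing = [m.mirna_id for m in mirnas if m.mirna_id not in groups.assignments]
    if missing:
        raise KeyError(f"group table does not cover miRNAs: {missing[:5]}")

    entries: dict[str, set[str]] = {}
    provenance: dict[str, set[str]] = {}
    n_excluded = 0
    for m in mirnas:
        core = extract_core(m.sequence, params)
        if core is None:
            n_excluded += 1
            logger.warning(
                "miRNA %s (%d nt) excluded: core shorter than %d nt",
                m.mirna_id, m.length, params.min_core_len,
            )
            continue
        entries.setdefault(core, set()).add(groups.assignments[m.mirna_id])
        provenance.setdefault(core, set()).add(m.mirna_id)
    if not entries:
        raise EmptyIndexError(
            "no miRNA yielded a core of at least "
            f"{params.min_core_len} nt with trims ({params.trim5}, {params.trim3})"
        )
    index = CoreIndex(
        params=params,
        entries={c: frozenset(g) for c, g in entries.items()},
        core_lengths=tuple(sorted({len(c) for c in entries})),
        provenance={c: frozenset(p) for c, p in provenance.items()},
        all_group_ids=frozenset(groups.assignments.values()),
        n_excluded=n_excluded,
    )
    return index


def match_read(read_sequence: str, index: CoreIndex) -> set[str]:
    """Return the set of group ids whose core is a substring of the read.

    Reads outside the length gates match nothing. A substring containing N
    never matches (N is not equal to any base, including N itself).
    """
    n = len(read_sequence)
    params = index.params
    if n < params.min_read_len or n > params.max_read_len:
        return set()
    hits: set[str] = set()
    entries = index.entries
    for length in index.core_lengths:
        if length > n:
            break
        for i in range(n - length + 1):
            sub = read_sequence[i: i + length]
            groups = entries.get(sub)
            if groups is not None and "N" not in sub:
                hits.update(groups)
    return hits


def naive_match(
    read_sequence: str,
    mirnas: list[MatureMiRNA],
    groups: GroupTable,
    params: CoreParams | None = None,
) -> set[str]:
    """Index-free oracle with the same contract as :func:`match_read`.

    Scans every miRNA and tests core containment directly.
    """
    if params is None:
        params = CoreParams()
    n = len(read_sequence)
    if n < params.min_read_len or n > params.max_read_len:
        return set()
    hits: set[str] = set()
    for m in mirnas:
        core = extract_core(m.sequence, params)
        if core is None or "N" in core:
            continue
        if core in read_sequence:
            hits.add(groups.assignments[m.mirna_id])
    return hits
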