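"""Reading and writing miRNA references, group tables and name parsing.

Mature miRNA references come as miRBase-style FASTA: the first
whitespace-delimited header token is the miRNA name (e.g. ``mmu-miR-26a-5p``)
and the second, if present, is the MIMAT accession, optionally carrying an
underscore suffix (``MIMAT0000001_2``) for individualized or duplicated-locus
variants. Sequences are normalized to the DNA alphabet (uppercase, U mapped to
T) so that the reference and FASTQ reads share one alphabet.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

from Bio import SeqIO

from .errors import (
    DuplicateIdentifierError,
    EmptyReferenceError,
    FormatError,
    GroupConflictError,
)

PathLike = Union[str, Path]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class MatureMiRNA:
    """One mature miRNA reference entry.

    Attributes
    ----------
    mirna_id : str
        Full miRBase-style name, unique within a reference set.
    accession : str
        MIMAT-style token, possibly followed by ``_`` and a suffix for
        individualized/duplicated sequences; empty string if absent.
    sequence : str
        Uppercase DNA sequence over {A,C,G,T,N}; U is mapped to T on ingest.
    """

    mirna_id: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.mirna_id!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.mirna_id!r} contains invalid characters "
                f"{sorted(bad)} after normalization"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NameKey:
    """Structural decomposition of a miRBase-style mature miRNA name.

    ``parse_ok=False`` means the name did not fit the grammar; all structural
    fields are then empty and callers decide their own fallback policy.
    """

    family_class: str = ""  # "miR", "let" or "" when unparsed
    core_number: str = ""
    letter: str = ""
    arm: str = ""  # "5p", "3p" or ""
    locus_index: str = ""
    parse_ok: bool = False


@dataclass
class GroupTable:
    """Total mapping from miRNA identifier to functional-group identifier."""

    scheme: str  # "none", "mimat", "name" or "custom"
    assignments: dict[str, str] = field(default_factory=dict)

    def group_members(self) -> dict[str, list[str]]:
        """Invert the table: group_id -> sorted list of member miRNA ids."""
        members: dict[str, list[str]] = {}
        for mid, gid in self.assignments.items():
            members.setdefault(gid, []).append(mid)
        for gid in members:
            members[gid].sort()
        return members

    @property
    def n_groups(self) -> int:
        return len(set(self.assignments.values()))


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_mature_fasta(path: PathLike) -> list[MatureMiRNA]:
    """Read a mature miRNA reference FASTA (optionally gzip-compressed).

    Only the first two whitespace-delimited header tokens are used (name and
    accession); any trailing description text is ignored. Sequences are
    normalized via :func:`normalize_sequence`.

    Raises
    ------
    EmptyReferenceError
        if the file contains no FASTA records.
    DuplicateIdentifierError
        if two records share a name.
    FormatError
        if a record is malformed (empty sequence, invalid characters).
    """
    records: list[MatureMiRNA] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            tokens = rec.description.split()
            if not tokens:
                raise FormatError(f"{path}: FASTA record with empty header")
            name = tokens[0]
            accession = tokens[1] if len(tokens) > 1 else ""
            if name in seen:
                raise DuplicateIdentifierError(
                    f"{path}: duplicate miRNA identifier {name!r}"
                )
            seen.add(name)
            try:
                records.append(
                    MatureMiRNA(
                        mirna_id=name,
                        accession=accession,
                        sequence=normalize_sequence(str(rec.seq)),
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise EmptyReferenceError(f"{path}: no FASTA records found")
    return records


def write_mature_fasta(mirnas: list[MatureMiRNA], path: PathLike) -> None:
    """Write a reference back to FASTA (name + accession header tokens)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for m in mirnas:
            header = f">{m.mirna_id} {m.accession}".rstrip()
            out.write(f"{header}\n{m.sequence}\n")


# Grammar: <species>-<class>-<number><letter?>(-<locus_index>)?(-<arm>)?
# The species prefix is whatever precedes the first hyphen; the class token is
# case-folded (mir/miR equivalent, let distinct).
_NAME_RE = re.compile(
    r"^(?P<species>[^-\s]+)-(?P<cls>[A-Za-z]+)-(?P<num>\d+)(?P<letter>[a-z]+)?"
    r"(?:-(?P<locus>\d+))?(?:-(?P<arm>[35]p))?$"
)


def parse_mirna_name(mirna_id: str) -> NameKey:
    """Parse a miRBase-style mature name into its structural key.

    Total function: names that do not fit the grammar return
    ``NameKey(parse_ok=False)`` instead of raising.
    """
    m = _NAME_RE.match(mirna_id)
    if m is None:
        return NameKey()
    cls = m.group("cls").lower()
    if cls == "mir":
        family_class = "miR"
    elif cls == "let":
        family_class = "let"
    else:
        return NameKey()
    return NameKey(
        family_class=family_class,
        core_number=m.group("num"),
        letter=m.group("letter") or "",
        arm=m.group("arm") or "",
        locus_index=m.group("locus") or "",
        parse_ok=True,
    )


def write_group_table(table: GroupTable, path: PathLike) -> None:
    """Write a two-column TSV (mirna_id, group_id), lexicographic by mirna_id.

    A single ``#``-prefixed header line records the scheme so that a read
    round-trips to an equal table.
    """
    with open(path, "wt") as out:
        out.write(f"#scheme={table.scheme}\n")
        for mid in sorted(table.assignments):
            out.write(f"{mid}\t{table.assignments[mid]}\n")


def read_group_table(path: PathLike) -> GroupTable:
    """Read a two-column TSV group table.

    An optional single leading ``#`` line is treated as a header; if it has
    the form ``#scheme=<s>`` the scheme is recovered, otherwise the table is
    labeled ``custom``.

    Raises
    ------
    FormatError
        for rows that do not have exactly two columns.
    GroupConflictError
        if a miRNA appears twice with different groups.
    """
    scheme = "custom"
    assignments: dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if lineno == 1:
                    m = re.match(r"^#\s*scheme=(\S+)$", line)
                    if m:
                        scheme = m.group(1)
                    continue
                raise FormatError(f"{path}:{lineno}: unexpected comment line")
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(cols)}"
                )
            mid, gid = cols
            if not gid:
                raise FormatError(f"{path}:{lineno}: empty group id")
            if mid in assignments and assignments[mid] != gid:
                raise GroupConflictError(
                    f"{path}:{lineno}: miRNA {mid!r} assigned to both "
                    f"{assignments[mid]!r} and {gid!r}"
                )
            assignments[mid] = gid
    return GroupTable(scheme=scheme, assignments=assignments)


def iter_fastq(path: PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read_id, normalized sequence) pairs from FASTQ, gzip allowed.

    Raises FormatError with the index of the offending record on malformed
    input.
    """
    import pysam

    n = 0
    try:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                n += 1
                yield entry.name, normalize_sequence(entry.sequence or "")
    except OSError as exc:
        raise FormatError(f"{path}: malformed FASTQ near record {n + 1}: {exc}") from exc


def write_fastq(reads: list[tuple[str, str]], path: PathLike) -> None:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for rid, seq in reads:
            out.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
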