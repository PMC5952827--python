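"""Collapsing miRNAs into functional groups.

Three schemes are supported:

``none``
    no collapsing — every miRNA is its own singleton group;
``mimat``
    miRNAs sharing the same MIMAT accession before an underscore are merged
    (identical matures transcribed from multiple loci, and individualized
    sequence variants, share an accession prefix);
``name``
    miRNAs sharing the same family class (miR/let), core number, letter (if
    any) and 5p/3p arm are merged; the locus index and the species prefix are
    dropped from the group identifier.
"""

from __future__ import annotations

import logging

from .errors import DomainMismatchError, EmptyReferenceError
from .mirbase_io import GroupTable, MatureMiRNA, NameKey, parse_mirna_name

logger = logging.getLogger(__name__)

SCHEMES = ("none", "mimat", "name")


def name_group_id(key: NameKey) -> str:
    """Canonical group id for a parsed name: class + number + letter [+ arm]."""
    gid = f"{key.family_class}-{key.core_number}{key.letter}"
    if key.arm:
        gid += f"-{key.arm}"
    return gid


def build_groups(mirnas: list[MatureMiRNA], scheme: str) -> GroupTable:
    """Assign every miRNA in the reference to exactly one functional group.

    Under ``mimat``, miRNAs with an empty accession fall back to singleton
    groups keyed by their name; under ``name``, unparseable names do the same
    (with a logged warning) so that quantification never aborts on irregular
    miRBase entries.
    """
    if not mirnas:
        raise EmptyReferenceError("cannot build groups from an empty reference")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown grouping scheme {scheme!r}; expected one of {SCHEMES}")

    assignments: dict[str, str] = {}
    if scheme == "none":
        for m in mirnas:
            assignments[m.mirna_id] = m.mirna_id
    elif scheme == "mimat":
        for m in mirnas:
            if m.accession:
                assignments[m.mirna_id] = m.accession.split("_", 1)[0]
            else:
                assignments[m.mirna_id] = m.mirna_id
    else:  # name
        for m in mirnas:
            key = parse_mirna_name(m.mirna_id)
            if key.parse_ok:
                assignments[m.mirna_id] = name_group_id(key)
            else:
                logger.warning(
                    "miRNA name %r does not fit the naming grammar; "
                    "keeping it as a singleton group",
                    m.mirna_id,
                )
                assignments[m.mirna_id] = m.mirna_id
    return GroupTable(scheme=scheme, assignments=assignments)


def is_coarsening(fine: GroupTable, coarse: GroupTable) -> bool:
    """True iff miRNAs grouped together in `fine` stay together in `coarse`.

    Both tables must cover the same miRNA set.
    """
    if set(fine.assignments) != set(coarse.assignments):
        raise DomainMismatchError(
            "group tables cover different miRNA sets "
            f"({len(fine.assignments)} vs {len(coarse.assignments)} miRNAs)"
        )
    fine_to_coarse: dict[str, str] = {}
    for mid, fg in fine.assignments.items():
        cg = coarse.assignments[mid]
        if fg in fine_to_coarse:
            if fine_to_coarse[fg] != cg:
                return False
        else:
            fine_to_coarse[fg] = cg
    return True
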