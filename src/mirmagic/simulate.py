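"""Synthetic miRNA references and small RNA-seq libraries with ground truth.

The generator emulates the structure that makes miRNA quantification hard:
families transcribed from duplicated loci with identical mature sequences
(sharing a MIMAT accession prefix with ``_k`` suffixes and locus-indexed
names), right-skewed per-family abundances (log-normal), and read libraries
mixing canonical reads, 5'/3' end-shifted isomiRs, polymorphic isomiRs with a
single internal substitution, and non-miRNA background fragments.

Every read carries its provenance in the read id, and a :class:`SimTruth`
records which reads are *countable*: those an exact core matcher configured
with the declared :class:`~mirmagic.core_matching.CoreParams` should count —
canonical reads and end-shifted isomiRs whose deletions stay within the
trims, whose final length passes the read-length gates, and whose source
family yields a valid core. Polymorphic isomiRs and background are never
countable.

Construction guarantees that labels are exact for any seed: reference cores
are rejection-sampled to be unique across families and absent from other
families' matures, and any read whose random end-extensions or substitution
would create a spurious match to another family's core is resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_matching import CoreParams, extract_core
from .errors import GenerationError
from .grouping import build_groups
from .mirbase_io import GroupTable, MatureMiRNA

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

CLASS_LABELS = ("canonical", "iso5p", "iso3p", "polymorphic", "background")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated cohort.

    Defaults describe a typical adapter-clipped brain small RNA-seq library:
    mature lengths of 19-23 nt, log-normal (right-skewed) family abundances,
    3' isomiRs as the most common isomiR class, end shifts of up to 2 nt, and
    a background of non-miRNA fragments spanning the 16-30 nt window so both
    the length filter and the matcher gates are exercised.
    """

    n_families: int = 50
    p_duplicate_locus: float = 0.3
    mirna_len_range: tuple[int, int] = (19, 23)
    abundance_mu: float = 3.0       # natural-log scale
    abundance_sigma: float = 1.5
    frac_5p_isomir: float = 0.10
    frac_3p_isomir: float = 0.25
    frac_polymorphic: float = 0.05
    max_end_shift: int = 2
    n_mirna_reads: int = 10_000
    n_background_reads: int = 3_000
    background_len_range: tuple[int, int] = (16, 30)
    background_mirna_sized_frac: float = 0.2  # mixture weight of 19-23 nt fragments
    seq_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_5p_isomir, self.frac_3p_isomir, self.frac_polymorphic)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("isomiR class fractions must be in [0,1] and sum <= 1")
        if not (0 <= self.p_duplicate_locus <= 1):
            raise ValueError("p_duplicate_locus must be a probability")
        lo, hi = self.mirna_len_range
        if lo < 16 or hi > 30 or lo > hi:
            raise ValueError("mirna_len_range must lie within [16, 30]")
        if self.max_end_shift < 0:
            raise ValueError("max_end_shift must be >= 0")
        if not (0 <= self.seq_error_rate <= 1):
            raise ValueError("seq_error_rate must be a probability")


@dataclass
class SimTruth:
    """Per-read provenance and per-family countable ground truth.

    ``per_read`` maps read id to (source family group id or "background",
    isomiR class label). ``countable_counts`` maps family group id to the
    number of its reads an exact core matcher with the declared CoreParams
    should count, assuming error-free sequencing.
    """

    per_read: dict[str, tuple[str, str]]
    countable_counts: dict[str, int]

    @property
    def n_reads(self) -> int:
        return len(self.per_read)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


class _CoreScreen:
    """Substring screen over the reference cores, keyed by core length."""

    def __init__(self, core_to_family: dict[str, str]):
        self.core_to_family = core_to_family
        self.lengths = sorted({len(c) for c in core_to_family})

    def families_hit(self, seq: str) -> set[str]:
        hits: set[str] = set()
        n = len(seq)
        for L in self.lengths:
            if L > n:
                break
            for i in range(n - L + 1):
                fam = self.core_to_family.get(seq[i: i + L])
                if fam is not None:
                    hits.add(fam)
        return hits


def simulate_reference(
    params: SimParams,
    core_params: CoreParams | None = None,
    max_retries: int = 1000,
) -> tuple[list[MatureMiRNA], GroupTable]:
    """Generate a mature miRNA reference with duplicated-locus families.

    Returns the reference and the ground-truth GroupTable mapping each mature
    to its family. Family names follow the miRBase-like grammar
    (``sim-miR-<k>-5p``; duplicated loci ``sim-miR-<k>-<locus>-5p``) and
    duplicated loci share an accession prefix with ``_k`` suffixes and
    identical sequences, so that both the name-based and the MIMAT-based
    grouping schemes recover exactly the true families.

    Cores (under ``core_params``, default :class:`CoreParams`) are
    rejection-sampled to be unique across families and never contained in
    another family's full mature sequence. Deterministic given the seed.
    """
    if core_params is None:
        core_params = CoreParams()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.mirna_len_range

    mirnas: list[MatureMiRNA] = []
    assignments: dict[str, str] = {}
    cores: dict[str, str] = {}  # core -> family id (only valid cores)
    sequences: list[str] = []

    for k in range(1, params.n_families + 1):
        family_id = f"miR-{k}-5p"
        length = int(rng.integers(lo, hi + 1))
        for attempt in range(max_retries + 1):
            seq = _random_seq(rng, length)
            # No existing core may sit inside the new mature.
            if any(c in seq for c in cores):
                continue
            core = extract_core(seq, core_params)
            if core is None:
                break  # too short for a core under these trims; keep as-is
            # The new core must be unique and absent from existing matures.
            if core in cores or any(core in s for s in sequences):
                continue
            break
        else:
            raise GenerationError(
                f"could not draw a unique core for family {k} after "
                f"{max_retries} retries; try a larger mirna_len_range"
            )
        if core is not None:
            cores[core] = family_id
        accession = f"MIMAT{k:07d}"
        duplicated = rng.random() < params.p_duplicate_locus
        if duplicated:
            for locus in (1, 2):
                name = f"sim-miR-{k}-{locus}-5p"
                mirnas.append(
                    MatureMiRNA(name, f"{accession}_{locus}", seq)
                )
                assignments[name] = family_id
        else:
            name = f"sim-miR-{k}-5p"
            mirnas.append(MatureMiRNA(name, accession, seq))
            assignments[name] = family_id
        sequences.append(seq)

    return mirnas, GroupTable(scheme="truth", assignments=assignments)


def _apply_end_shift(
    rng: np.random.Generator, seq: str, shift: int, end: str
) -> tuple[str, int, int]:
    """Delete or extend ``shift`` bases at one end. Returns (read, del5, del3)."""
    if rng.random() < 0.5:  # deletion (templated end-shift)
        if end == "5p":
            return seq[shift:], shift, 0
        return seq[: len(seq) - shift], 0, shift
    extra = _random_seq(rng, shift)  # extension (untemplated addition)
    if end == "5p":
        return extra + seq, 0, 0
    return seq + extra, 0, 0


def simulate_reads(
    reference: list[MatureMiRNA],
    truth_groups: GroupTable,
    params: SimParams,
    core_params: CoreParams | None = None,
    library_id: str = "lib",
    max_retries: int = 100,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Simulate one read library with per-read ground truth.

    Family abundances are drawn log-normal (right-skewed) per library; each
    miRNA read draws a class (canonical / iso5p / iso3p / polymorphic),
    applies end shifts or one internal substitution, then flat per-base
    sequencing error. Background fragments are random sequences rejected if
    they contain any reference core. Read ids encode library, index, source
    family and class. Returns (list of (read_id, sequence), SimTruth).
    """
    if core_params is None:
        core_params = CoreParams()
    rng = np.random.default_rng(params.seed)

    # One representative sequence per family (duplicated loci are identical).
    family_seq: dict[str, str] = {}
    for m in reference:
        family_seq.setdefault(truth_groups.assignments[m.mirna_id], m.sequence)
    families = sorted(family_seq)
    if not families:
        raise GenerationError("reference has no families")

    core_to_family = {}
    for fam, seq in family_seq.items():
        core = extract_core(seq, core_params)
        if core is not None:
            core_to_family[core] = fam
    screen = _CoreScreen(core_to_family)

    weights = rng.lognormal(params.abundance_mu, params.abundance_sigma, len(families))
    probs = weights / weights.sum()
    fam_draws = rng.choice(len(families), size=params.n_mirna_reads, p=probs)

    p_canon = 1.0 - params.frac_5p_isomir - params.frac_3p_isomir - params.frac_polymorphic
    class_probs = [p_canon, params.frac_5p_isomir, params.frac_3p_isomir,
                   params.frac_polymorphic]
    class_draws = rng.choice(4, size=params.n_mirna_reads, p=class_probs)

    reads: list[tuple[str, str]] = []
    per_read: dict[str, tuple[str, str]] = {}
    countable: dict[str, int] = {fam: 0 for fam in families}

    for i in range(params.n_mirna_reads):
        fam = families[fam_draws[i]]
        seq = family_seq[fam]
        cls = CLASS_LABELS[class_draws[i]]
        del5 = del3 = 0
        if cls == "canonical":
            read = seq
        elif cls in ("iso5p", "iso3p"):
            shift = int(rng.integers(1, params.max_end_shift + 1)) \
                if params.max_end_shift > 0 else 0
            end = "5p" if cls == "iso5p" else "3p"
            for _ in range(max_retries):
                read, del5, del3 = _apply_end_shift(rng, seq, shift, end)
                # resample extensions that spuriously contain a foreign core
                if screen.families_hit(read) - {fam}:
                    continue
                break
            else:
                raise GenerationError("could not draw a clean end extension")
        else:  # polymorphic: one substitution strictly inside the core
            L = len(seq)
            lo_pos = core_params.trim5
            hi_pos = L - core_params.trim3
            if hi_pos <= lo_pos:  # no core region; substitute anywhere
                lo_pos, hi_pos = 0, L
            for _ in range(max_retries):
                pos = int(rng.integers(lo_pos, hi_pos))
                old = seq[pos]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                read = seq[:pos] + new + seq[pos + 1:]
                if screen.families_hit(read):
                    continue
                break
            else:
                raise GenerationError("could not draw a clean substitution")

        if params.seq_error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype="S1").astype("U1")
            hits = np.nonzero(rng.random(len(arr)) < params.seq_error_rate)[0]
            for pos in hits:
                arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
            read = "".join(arr)

        is_countable = (
            cls in ("canonical", "iso5p", "iso3p")
            and del5 <= core_params.trim5
            and del3 <= core_params.trim3
            and core_params.min_read_len <= len(read) <= core_params.max_read_len
            and extract_core(seq, core_params) is not None
        )
        if is_countable:
            countable[fam] += 1
        rid = f"{library_id}:{i}|fam={fam}|class={cls}|countable={int(is_countable)}"
        reads.append((rid, read))
        per_read[rid] = (fam, cls)

    blo, bhi = params.background_len_range
    mlo, mhi = max(blo, 19), min(bhi, 23)  # miRNA-sized component, if any
    for j in range(params.n_background_reads):
        # length mixture: half miRNA-sized (19-23 nt), half across the window
        if mlo <= mhi and rng.random() < params.background_mirna_sized_frac:
            length = int(rng.integers(mlo, mhi + 1))
        else:
            length = int(rng.integers(blo, bhi + 1))
        for _ in range(max_retries):
            read = _random_seq(rng, length)
            if not screen.families_hit(read):
                break
        else:
            raise GenerationError("could not draw a core-free background read")
        rid = f"{library_id}:bg{j}|fam=background|class=background|countable=0"
        reads.append((rid, read))
        per_read[rid] = ("background", "background")

    return reads, SimTruth(per_read=per_read, countable_counts=countable)


def true_group_counts(truth: SimTruth) -> dict[str, int]:
    """Countable ground truth in count-table form (family group ids)."""
    return dict(truth.countable_counts)


def project_truth(
    truth: SimTruth,
    truth_groups: GroupTable,
    table: GroupTable,
) -> dict[str, int]:
    """Expected quantifier counts for an arbitrary grouping of the reference.

    Under once-per-group counting, a group is credited once per countable
    read of every family it has at least one member of (family members are
    sequence-identical, so each member's core matches all the family's
    countable reads).
    """
    out: dict[str, int] = {}
    for gid, members in table.group_members().items():
        fams = {truth_groups.assignments[m] for m in members}
        out[gid] = sum(truth.countable_counts.get(f, 0) for f in fams)
    return out


def background_reads_for_fraction(
    params: SimParams,
    target_fraction: float,
    n_probe: int = 4000,
) -> int:
    """Background read count so the 19-23 nt read fraction hits a target.

    Estimates the probability that a miRNA-derived read and a background
    fragment fall in the 19-23 nt band by simulating read lengths only, then
    solves n_bg = n_mirna * (p_mirna - f) / (f - p_bg). Raises if the target
    is unreachable with the given length models.
    """
    if not (0 < target_fraction < 1):
        raise ValueError("target_fraction must be in (0, 1)")
    rng = np.random.default_rng(params.seed + 7)
    lo, hi = params.mirna_len_range
    base_len = rng.integers(lo, hi + 1, size=n_probe)
    cls = rng.choice(
        4, size=n_probe,
        p=[1 - params.frac_5p_isomir - params.frac_3p_isomir - params.frac_polymorphic,
           params.frac_5p_isomir, params.frac_3p_isomir, params.frac_polymorphic],
    )
    shift = rng.integers(1, max(params.max_end_shift, 1) + 1, size=n_probe)
    sign = rng.choice([-1, 1], size=n_probe)  # deletion vs extension
    length = base_len + np.where(cls % 3 != 0, sign * shift, 0)  # iso5p/iso3p
    p_mirna = float(np.mean((length >= 19) & (length <= 23)))

    blo, bhi = params.background_len_range
    mlo, mhi = max(blo, 19), min(bhi, 23)
    if mlo <= mhi:
        comp = rng.random(n_probe) < params.background_mirna_sized_frac
        blen = np.where(
            comp,
            rng.integers(mlo, mhi + 1, size=n_probe),
            rng.integers(blo, bhi + 1, size=n_probe),
        )
    else:
        blen = rng.integers(blo, bhi + 1, size=n_probe)
    p_bg = float(np.mean((blen >= 19) & (blen <= 23)))

    f = target_fraction
    if not (min(p_bg, p_mirna) < f < max(p_bg, p_mirna)):
        raise GenerationError(
            f"target fraction {f:.2f} outside achievable range "
            f"({min(p_bg, p_mirna):.2f}, {max(p_bg, p_mirna):.2f})"
        )
    n_bg = params.n_mirna_reads * (p_mirna - f) / (f - p_bg)
    return max(0, int(round(n_bg)))
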