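"""Accuracy evaluation: length-filtered input-read estimates and MSE.

A method's total output count, summed over all groups, should track the
number of miRNA-derived reads that entered the library. That input quantity
is estimated as the number of adapter-clipped reads of 19-23 nt — the length
band that contains the vast majority of mature miRNAs. Accuracy of a
quantification scheme over a cohort is then the mean squared error between
the per-library estimate and the per-library total count, with +/- one
standard error of the mean of the squared errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .mirbase_io import MatureMiRNA, PathLike, iter_fastq
from .quantify import LibraryStats


@dataclass
class EvalResult:
    """Cohort accuracy for one quantification scheme.

    ``sem`` is the standard error of the mean of per-library squared errors,
    using the sample (n-1) standard deviation; it is None for a single
    library.
    """

    method_label: str
    per_library_squared_error: list[float]
    mse: float
    sem: float | None
    n_libraries: int


def count_reads_in_length_range(
    reads: Union[PathLike, Iterable[str]],
    min_len: int = 19,
    max_len: int = 23,
) -> int:
    """Count reads whose length is within [min_len, max_len], inclusive."""
    if isinstance(reads, (str,)) or hasattr(reads, "__fspath__"):
        seqs: Iterable[str] = (seq for _rid, seq in iter_fastq(reads))
    else:
        seqs = reads
    return sum(1 for s in seqs if min_len <= len(s) <= max_len)


def mse_and_sem(
    estimates: Sequence[float],
    totals: Sequence[float],
    method_label: str = "",
) -> EvalResult:
    """MSE between estimated input miRNA reads and output total counts.

    Inputs are paired by library and compared on raw (unnormalized) counts.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one library")
    if len(estimates) != len(totals):
        raise ValueError(
            f"pairing error: {len(estimates)} estimates vs {len(totals)} totals"
        )
    est = np.asarray(estimates, dtype=float)
    tot = np.asarray(totals, dtype=float)
    sq = (est - tot) ** 2
    n = len(sq)
    sem = float(np.std(sq, ddof=1) / np.sqrt(n)) if n > 1 else None
    return EvalResult(
        method_label=method_label,
        per_library_squared_error=sq.tolist(),
        mse=float(np.mean(sq)),
        sem=sem,
        n_libraries=n,
    )


def ratio_table(stats: list[LibraryStats]) -> pd.DataFrame:
    """Tabulate total-count-to-raw-read ratios, one row per library.

    A ratio of 0.8 means the scheme's total count was 0.8x the raw read
    count; ratios above 1.0 indicate double counting. Libraries with zero raw
    reads get a NaN ratio rather than an exception.
    """
    if not stats:
        raise ValueError("need at least one library")
    rows = [
        {
            "library_id": s.library_id,
            "n_raw_reads": s.n_raw_reads,
            "total_count": s.total_count,
            "ratio": s.ratio_total_to_raw,
        }
        for s in stats
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("library_id")
        .reset_index(drop=True)
    )


def length_fraction_in_range(
    mirnas: list[MatureMiRNA],
    min_len: int = 19,
    max_len: int = 23,
    unique_sequences: bool = False,
) -> float:
    """Fraction of reference matures whose length falls in [min_len, max_len].

    With ``unique_sequences=True`` the fraction is over distinct mature
    sequences; otherwise over all records (one per annotated locus product).
    """
    if not mirnas:
        raise ValueError("empty reference")
    if unique_sequences:
        lengths = [len(s) for s in {m.sequence for m in mirnas}]
    else:
        lengths = [m.length for m in mirnas]
    in_range = sum(1 for L in lengths if min_len <= L <= max_len)
    return in_range / len(lengths)
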