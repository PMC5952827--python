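# Methods

## Quantification model

Let a mature miRNA have sequence $s$ of length $L$ (DNA alphabet; RNA input
is mapped U→T on ingest). Its **core** under trim parameters $(t_5, t_3)$ is
the substring $s[t_5 : L - t_3]$. A mature whose core would be shorter than
`min_core_len` is excluded from the index with a warning — a short core would
match promiscuously, and stringency is the point of the method.

A read $r$ **matches** a functional group $g$ iff some member of $g$ has a
core that occurs verbatim as a substring of $r$, and
`min_read_len` ≤ |r| ≤ `max_read_len`. Matching is exact substring
containment — no mismatches, indels, seeds or alignment scores. Consequences:

- **5′/3′ isomiR tolerance.** A read formed by deleting up to $t_5$ bases at
  the 5′ end and/or $t_3$ bases at the 3′ end of a mature, or by extending
  either end with arbitrary bases (within the read-length gates), still
  contains the core and is counted with its parent.
- **Polymorphic rejection.** Any substitution at a core position destroys the
  match; the read is dropped unless another reference core happens to rescue
  it.
- Matching direction is core-in-read (not read-in-reference): read ends may
  carry untemplated additions or adapter remnants, so the trusted anchor is
  the reference core. Reads are matched as sequenced (stranded protocol); no
  reverse complement is taken. Cores containing N never match anything (N is
  not equal to any base, including N), a conservative choice under ambiguity.

**Counting.** Each read is matched once against the index; a read
contributes **at most once per functional group**. When a read matches $k>1$
groups, the policy decides: `all_groups` (default) adds 1 to each of the $k$
groups; `discard_ambiguous` drops the read; `fractional` adds $1/k$ to each.
The default is the literal reading of once-per-group counting; because no
cross-group tie-break is canonical, the alternatives are flags and the
ambiguous-read count is always reported. Count tables are dense over the
group universe (zero groups emitted) so per-library outputs align into a
matrix.

**Grouping schemes.** `none`: every miRNA is a singleton group. `mimat`:
group = accession substring before the first `_`; matures without an
accession stay singletons. `name`: group = (class, core number, letter, arm)
from the name grammar
`<species>-<class>-<number><letter?>(-<locus>)?(-<arm>)?` with class ∈
{miR/mir (case-folded), let}; the locus index and species prefix are dropped
from the group id. Unparseable names become singleton groups with a logged
warning rather than an error — reference databases contain irregular names
and quantification must not abort. `mimat`-vs-`name` give identical
partitions whenever duplicated loci share accession prefixes and locus-indexed
names; they differ only on references where paralog naming and accession
assignment disagree.

## Accuracy metric

For a cohort of libraries, the per-library miRNA input is estimated as the
number of adapter-clipped reads of 19–23 nt inclusive (the length band
containing the large majority of mature miRNAs). For estimates $e_i$ and
method totals $c_i$, the score is
$\mathrm{MSE} = \tfrac1n \sum_i (e_i - c_i)^2$, reported with the standard
error of the mean of the squared errors, $\mathrm{SEM} = sd(\{(e_i-c_i)^2\}) /
\sqrt n$ using the sample ($n-1$) standard deviation (undefined for $n=1$).
Errors are computed on raw counts, not per-million-scaled: the comparison is
of absolute totals to absolute input estimates. The ratio table reports
$c_i / \text{raw reads}_i$ per library (NaN for empty libraries); ratios
above 1.0 indicate double counting.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `trim5`, `trim3` | 2 nt, 2 nt | end bases removed to form each core; absorb the dominant ±2 nt end variation of isomiRs |
| `min_core_len` | 16 nt | matures with shorter cores are excluded from the index |
| `min_read_len`, `max_read_len` | 16 nt, 30 nt | reads outside the gates never match; the upper gate keeps long fragments containing a core from counting |
| policy | `all_groups` | cross-group handling of multi-matching reads |

Symmetric 2+2 trimming with a 16 nt floor was chosen so that typical
19–23 nt matures yield usable cores while ±2 nt end variation is absorbed;
note the arithmetic consequence that a 19 nt mature trims to 15 nt and is
excluded at the default floor. All values are exposed as CLI flags and
`CoreParams` fields.

## Synthetic-data generator

The simulator emulates the features of real small RNA-seq that make
quantification hard, with full per-read ground truth:

- **Reference.** `n_families` random matures with lengths uniform on
  `mirna_len_range` (default 19–23 nt, the band containing ~95% of real
  matures). With probability `p_duplicate_locus` a family has two
  sequence-identical loci, named with locus indices (`sim-miR-7-1-5p`,
  `sim-miR-7-2-5p`) and sharing an accession prefix with `_k` suffixes
  (`MIMAT0000007_1`, `MIMAT0000007_2`), so both the `name` and `mimat`
  schemes recover exactly the true families. Sequences are
  rejection-sampled so that every valid core is unique across families, no
  core occurs inside another family's mature, and generation fails loudly
  after bounded retries rather than emitting an ambiguous reference.
- **Abundances.** Per-library family weights are log-normal
  (`abundance_mu=3`, `abundance_sigma=1.5` on the natural-log scale) —
  right-skewed, so a handful of families dominate, as in real libraries.
  The values are declared defaults, not fitted to any dataset.
- **Read classes.** Each miRNA read is canonical, a 5′ isomiR, a 3′ isomiR,
  or a polymorphic isomiR with probabilities (`frac_5p_isomir=0.10`,
  `frac_3p_isomir=0.25`, `frac_polymorphic=0.05`); the defaults make 3′
  isomiRs the most common class, matching their observed dominance.
  End-shifted classes delete or extend (50/50) 1..`max_end_shift` bases at
  the respective end; polymorphic reads carry one substitution uniform over
  core positions, which guarantees rejection under exact matching. A flat
  per-base substitution error (`seq_error_rate`, default 0.001) is applied
  last.
- **Background.** `n_background_reads` non-miRNA fragments with lengths from
  a two-component mixture (a 19–23 nt miRNA-sized component with weight
  `background_mirna_sized_frac=0.2`, else uniform over
  `background_len_range=16–30 nt`), so both the length filter and the
  matcher gates are exercised. Background sequences are rejection-sampled to
  contain no reference core. `background_reads_for_fraction` solves for the
  background depth that puts the cohort's 19–23 nt read fraction at a
  requested value (e.g. anywhere in the 50–72% band observed in real brain
  libraries); the default mixture weight was set at 0.2 precisely so that
  band is reachable.
- **Ground truth.** Every read id encodes its source family and class. A
  read is **countable** iff its class is canonical/iso5p/iso3p, its end
  *deletions* are within the declared trims, its final length passes the
  declared read-length gates, and its source family yields a valid core
  under the declared `CoreParams`. This is the package's own completion of
  "end shifts within the trims": without the last two conditions, exact
  recovery would be arithmetically impossible for 19 nt matures at the
  default core floor. Countability assumes error-free sequencing; with
  `seq_error_rate > 0` the quantifier undercounts truth by reads whose error
  fell inside the core, which is the intended stringency/false-negative
  trade-off. To make per-read labels exact for *every* seed (not just almost
  surely), end extensions and polymorphic substitutions are also
  rejection-resampled if they would create a spurious match to another
  family's core — the same construction the background uses.
- **Determinism.** All randomness flows from one integer seed through
  `numpy.random.default_rng`; identical parameters give byte-identical
  FASTA/FASTQ/truth outputs.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: adapter sequences and trimming artifacts,
quality-score structure and platform-specific error profiles, templated
multi-nucleotide 3′ additions (e.g. poly-uridylation), genuine cross-family
sequence homology (real paralogous families differ by 1–2 bases; simulated
families are random and far apart, so real ambiguous multi-group matches are
rarer here than in miRBase), and expression correlation between samples.
Exact-recovery results on simulated data certify the bookkeeping of the
implementation, not the biological fidelity of exact core matching.

## Numerical and design choices

- Verification sizes: the randomized matcher-vs-oracle comparison uses
  ≥ 10,000 (read, reference) instances across trims 0–3; the exact-recovery
  cohort uses 20 libraries × 50 families at 4,000 miRNA + 1,200 background
  reads per library. Exactness is a per-read property, so cohort depth is a
  verification-cost choice, not a statistical one.
- The isomiR-recovery check uses 20–23 nt matures so that every family has a
  valid core under the default 2+2 trims and the expected recovery is exactly
  the read count.
- Identical reads are deduplicated internally (match once, multiply by
  multiplicity); this is observationally equivalent to per-read matching and
  is covered by the order-invariance test.
- Ties, degenerate inputs: empty libraries yield all-zero tables with a
  warning (not an error); an empty reference, a reference whose matures all
  lose their cores, and conflicting group tables are hard errors; zero raw
  reads yields a NaN ratio rather than an exception; SEM is reported as
  absent for single-library cohorts.
- Fractional counts are emitted with 6 decimal places; integer policies print
  integers.

## Limitations

- The tool produces counts only; normalization, differential expression and
  novel-miRNA discovery are out of scope by design.
- High stringency trades false positives for false negatives: sequencing
  errors or genetic variation inside a core cause missed assignments. The
  trims absorb end variation only; there is no mismatch tolerance anywhere.
- Grouping is identifier-based (accessions and name structure) plus
  user-supplied tables; no sequence-similarity (edit-distance) family
  merging is performed.
- The reference FASTA is taken as given: no species filtering, no
  hairpin/GFF parsing, no network retrieval.
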