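"""Core extraction, index construction, and exact-substring matching."""

import numpy as np
import pytest

from mirmagic import (
    CoreParams,
    MatureMiRNA,
    build_core_index,
    build_groups,
    extract_core,
    match_read,
    naive_match,
)
from mirmagic.errors import EmptyIndexError
from mirmagic.mirbase_io import GroupTable


def make_index(mirnas, scheme="none", **kw):
    return build_core_index(mirnas, build_groups(mirnas, scheme), CoreParams(**kw))


class TestExtractCore:
    def test_symmetric_trim(self):
        seq = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        assert extract_core(seq, CoreParams(trim5=2, trim3=2)) == seq[2:-2]
        assert len(extract_core(seq, CoreParams())) == 18

    def test_zero_trim_is_identity(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert extract_core(seq, CoreParams(trim5=0, trim3=0)) == seq

    def test_short_core_returns_none(self):
        seq = "ACGTACGTACGTACGTAC"  # 18 nt -> 14 nt core < 16
        assert extract_core(seq, CoreParams(trim5=2, trim3=2, min_core_len=16)) is None

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CoreParams(trim5=-1)
        with pytest.raises(ValueError):
            CoreParams(min_read_len=31, max_read_len=30)


class TestBuildCoreIndex:
    def test_identical_sequences_same_group_one_entry(self):
        seq = "TCTTTGGTTATCTAGCTGTATGA"
        mirnas = [MatureMiRNA("a-miR-9-1-5p", "M1_1", seq),
                  MatureMiRNA("a-miR-9-2-5p", "M1_2", seq)]
        index = make_index(mirnas, scheme="name")
        assert len(index.entries) == 1
        (groups,) = index.entries.values()
        assert groups == frozenset({"miR-9-5p"})
        assert index.n_ambiguous_cores == 0

    def test_identical_sequences_distinct_groups_share_core(self):
        seq = "TCTTTGGTTATCTAGCTGTATGA"
        mirnas = [MatureMiRNA("a-miR-9-1-5p", "M1_1", seq),
                  MatureMiRNA("a-miR-9-2-5p", "M1_2", seq)]
        index = make_index(mirnas, scheme="none")
        (groups,) = index.entries.values()
        assert groups == frozenset({"a-miR-9-1-5p", "a-miR-9-2-5p"})
        assert index.n_ambiguous_cores == 1

    def test_short_matures_excluded_and_counted(self, caplog):
        mirnas = [MatureMiRNA("a-miR-1-5p", "M1", "ACGTACGTACGTACGTAC"),  # 18 nt
                  MatureMiRNA("a-miR-2-5p", "M2", "TCTTTGGTTATCTAGCTGTATGA")]
        with caplog.at_level("WARNING"):
            index = make_index(mirnas)
        assert index.n_excluded == 1
        assert len(index.entries) == 1

    def test_all_excluded_raises(self):
        mirnas = [MatureMiRNA("a-miR-1-5p", "M1", "ACGTACGTACGTACGTAC")]
        with pytest.raises(EmptyIndexError):
            make_index(mirnas)

    def test_zero_count_group_universe_retained(self, tiny_reference):
        table = build_groups(tiny_reference, "name")
        index = build_core_index(tiny_reference, table)
        assert index.all_group_ids == frozenset(table.assignments.values())


class TestMatchRead:
    CORE = "GTACGTACGTACGTACGT"  # 18 nt core of the 22 nt mature below
    MATURE = "ACGTACGTACGTACGTACGTAC"

    @pytest.fixture
    def index(self):
        return make_index([MatureMiRNA("a-miR-1-5p", "M1", self.MATURE)])

    def test_end_shifted_read_matches(self, index):
        # 2 nt 5' truncation plus 2 nt untemplated 3' addition
        read = "TT" + self.CORE + "AA"
        assert match_read(read, index) == {"a-miR-1-5p"}

    def test_internal_substitution_rejected(self, index):
        read = list("TT" + self.CORE + "AA")
        read[10] = "A" if read[10] != "A" else "C"
        assert match_read("".join(read), index) == set()

    def test_exact_mature_read_matches(self, index):
        assert match_read(self.MATURE, index) == {"a-miR-1-5p"}

    def test_read_length_gates(self, index):
        assert match_read(self.CORE[:15], index) == set()  # below min_read_len
        long_read = "A" * 6 + self.CORE + "A" * 10  # 34 nt > max_read_len
        assert match_read(long_read, index) == set()

    def test_core_with_n_never_matches(self):
        with_n = "ACGTACGTACNTACGTACGTAC"
        mirnas = [MatureMiRNA("a-miR-1-5p", "M1", with_n)]
        index = make_index(mirnas)
        assert with_n[2:-2] in index.entries  # present in the index
        assert match_read(with_n, index) == set()  # but never matched


def random_reference(rng, n_mirnas):
    mirnas = []
    for k in range(n_mirnas):
        length = int(rng.integers(18, 26))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        mirnas.append(MatureMiRNA(f"sim-miR-{k + 1}-5p", f"M{k + 1}", seq))
    return mirnas


class TestOracleEquivalence:
    def test_matches_brute_force_across_trims(self):
        """Indexed matching equals the index-free scan on random instances."""
        rng = np.random.default_rng(2024)
        n_trials = 0
        for trim in (0, 1, 2, 3):
            params = CoreParams(trim5=trim, trim3=trim, min_core_len=14)
            for _ in range(30):
                mirnas = random_reference(rng, 6)
                groups = build_groups(mirnas, "none")
                try:
                    index = build_core_index(mirnas, groups, params)
                except EmptyIndexError:
                    continue
                reads = []
                # random reads plus reads derived from the reference
                for _ in range(15):
                    L = int(rng.integers(14, 33))
                    reads.append("".join(rng.choice(list("ACGT"), size=L)))
                for m in mirnas:
                    d5, d3 = int(rng.integers(0, 4)), int(rng.integers(0, 4))
                    reads.append(m.sequence[d5: len(m.sequence) - d3])
                    reads.append("TT" + m.sequence + "A")
                for read in reads:
                    assert match_read(read, index) == naive_match(
                        read, mirnas, groups, params
                    )
                    n_trials += 1
        assert n_trials >= 3000

    def test_empty_reference_naive(self):
        assert naive_match("ACGT" * 5, [], GroupTable("none", {})) == set()


class TestMatchingProperties:
    def test_monotone_in_trim_stringency(self):
        """Shorter cores (larger trims) can only grow the match set."""
        rng = np.random.default_rng(7)
        mirnas = random_reference(rng, 8)
        groups = build_groups(mirnas, "none")
        reads = ["TT" + m.sequence[1:-1] + "A" for m in mirnas]
        prev_sets = None
        for trim in (0, 1, 2, 3):
            params = CoreParams(trim5=trim, trim3=trim, min_core_len=12)
            index = build_core_index(mirnas, groups, params)
            cur = [match_read(r, index) for r in reads]
            if prev_sets is not None:
                for old, new in zip(prev_sets, cur):
                    assert old <= new
            prev_sets = cur

    def test_coarsening_shrinks_match_multiplicity(self, sim_reference):
        _params, reference, _truth = sim_reference
        fine = build_core_index(reference, build_groups(reference, "none"))
        coarse = build_core_index(reference, build_groups(reference, "name"))
        for m in reference:
            read = m.sequence
            assert len(match_read(read, coarse)) <= len(match_read(read, fine))

    def test_isomir_tolerance_within_trims(self, sim_reference):
        """Deletions <= trims and arbitrary extensions keep the match."""
        _params, reference, _truth = sim_reference
        groups = build_groups(reference, "name")
        params = CoreParams()
        index = build_core_index(reference, groups, params)
        for m in reference:
            core = extract_core(m.sequence, params)
            if core is None:
                continue
            gid = groups.assignments[m.mirna_id]
            for d5 in range(params.trim5 + 1):
                for d3 in range(params.trim3 + 1):
                    read = m.sequence[d5: len(m.sequence) - d3]
                    assert gid in match_read(read, index)
            assert gid in match_read("GG" + m.sequence, index)
            assert gid in match_read(m.sequence + "CC", index)

    def test_any_core_substitution_destroys_match(self, sim_reference):
        _params, reference, _truth = sim_reference
        groups = build_groups(reference, "name")
        params = CoreParams()
        index = build_core_index(reference, groups, params)
        swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for m in reference:
            if extract_core(m.sequence, params) is None:
                continue
            gid = groups.assignments[m.mirna_id]
            for pos in range(params.trim5, m.length - params.trim3):
                read = m.sequence[:pos] + swap[m.sequence[pos]] + m.sequence[pos + 1:]
                assert gid not in match_read(read, index)
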