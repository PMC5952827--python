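import pytest

from mirmagic import MatureMiRNA, SimParams, simulate_reference


@pytest.fixture
def tiny_reference():
    """Five matures: a duplicated-locus pair, two lettered paralogs, one let."""
    return [
        MatureMiRNA("mmu-miR-9-1-5p", "MIMAT0000142_1", "TCTTTGGTTATCTAGCTGTATGA"),
        MatureMiRNA("mmu-miR-9-2-5p", "MIMAT0000142_2", "TCTTTGGTTATCTAGCTGTATGA"),
        MatureMiRNA("mmu-miR-26a-5p", "MIMAT0000533", "TTCAAGTAATCCAGGATAGGCT"),
        MatureMiRNA("mmu-miR-26b-5p", "MIMAT0000534", "TTCAAGTAATTCAGGATAGGT"),
        MatureMiRNA("mmu-let-7a-5p", "MIMAT0000521", "TGAGGTAGTAGGTTGTATAGTT"),
    ]


@pytest.fixture
def sim_reference():
    """Small simulated reference with guaranteed duplicated loci."""
    params = SimParams(n_families=12, p_duplicate_locus=0.5, seed=11)
    reference, truth_groups = simulate_reference(params)
    return params, reference, truth_groups


def write_fasta(path, records):
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
    return path
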