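import pytest

from zfnkit import CodonUsageTable, HalfSite, HelixTable, make_random_cds

# The published NF-YA8 half-site pair (5'->3' as bound by each ZFP).
LEFT_SITE = "GCTCTACCC"
RIGHT_SITE = "AGGACGCTT"


@pytest.fixture(scope="session")
def left_half_site() -> HalfSite:
    return HalfSite(LEFT_SITE, side="left", strand_bound="bottom")


@pytest.fixture(scope="session")
def right_half_site() -> HalfSite:
    return HalfSite(RIGHT_SITE, side="right", strand_bound="top")


@pytest.fixture(scope="session")
def helix_table() -> HelixTable:
    return HelixTable()


@pytest.fixture(scope="session")
def flat_usage() -> CodonUsageTable:
    return CodonUsageTable.equal_usage()


@pytest.fixture(scope="session")
def skewed_usage() -> CodonUsageTable:
    """A deterministic non-flat usage table: frequency grows alphabetically."""
    from Bio.Data.CodonTable import standard_dna_table

    codons = sorted(standard_dna_table.forward_table) + standard_dna_table.stop_codons
    return CodonUsageTable({c: float(i + 1) for i, c in enumerate(sorted(codons))})


@pytest.fixture(scope="session")
def reference_cds() -> str:
    """A random 1020-nt CDS long enough for the default edit windows."""
    return make_random_cds(340, seed=2024)
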