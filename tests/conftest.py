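import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("default")

from tilevar.models import AmpliconConfig, GeneModel, NhejSimConfig
from tilevar.simulate import default_amplicon


@pytest.fixture(scope="session")
def syn_cfg() -> AmpliconConfig:
    """The packaged synthetic 62-nt amplicon configuration."""
    return default_amplicon()


@pytest.fixture(scope="session")
def toy_gene() -> GeneModel:
    """Single-exon 9-codon gene with 12-nt flanks on a 51-nt segment."""
    flank5 = "TTGACTGCAATC"
    cds = "ATGAAACATGGTCCAGTTCGAGACTAA"  # M K H G P V R D *
    flank3 = "GCCTTGAAGGTC"
    seq = flank5 + cds + flank3
    return GeneModel(
        name="toy",
        sequence=seq,
        cds_intervals=((len(flank5), len(flank5) + len(cds)),),
        intron_margin=5,
    )


@pytest.fixture()
def noiseless_sim(syn_cfg) -> NhejSimConfig:
    """Small error-free simulation used by exact round-trip tests."""
    return NhejSimConfig(
        cfg=syn_cfg, seq_error_rate=0.0, depth=20_000, n_edit_draws=2_000, seed=11
    )
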