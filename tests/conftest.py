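import numpy as np
import pytest

from sercodon import CodingSequence, SimulationConfig, gen_transcriptome


@pytest.fixture(scope="session")
def small_transcriptome():
    """Five short CDSs with known Ser content, plus truth table."""
    cfg = SimulationConfig(
        seed=42,
        n_genes=5,
        cds_length_range=(60, 90),
        reads_per_transcript=300,
    )
    cds_by_gene, truth = gen_transcriptome(cfg)
    return cfg, cds_by_gene, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_cds():
    # 120 nt / 40 codons: ATG + 38 interior + stop; Ser codons at known spots
    interior = ["GCT"] * 38
    interior[10] = "TCC"
    interior[20] = "AGT"
    interior[30] = "TCG"
    seq = "ATG" + "".join(interior) + "TAA"
    return CodingSequence("toy", "toy.t1", seq)
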