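import numpy as np
import pytest

from leaderless_scan import synthetic
from leaderless_scan.genome_io import Contig, GeneRecord


@pytest.fixture(scope="session")
def small_genome():
    """A dense 200-gene synthetic genome with planted promoter hexamers."""
    spec = synthetic.SyntheticSpec(n_genes=200, rng_seed=7)
    contigs, genes, truth = synthetic.gen_genome(spec)
    return spec, contigs, genes, truth


@pytest.fixture
def toy_contig():
    """A hand-built contig with one gene on each strand.

    Forward gene at [30, 60) starting ATG; reverse gene at [80, 110) whose
    forward-strand end carries CAT (= ATG on the coding strand).
    """
    seq = (
        "GATTACAGGG" "CCCCCCCCCC" "AACCGGTTAA"  # 0-30 upstream region
        + "ATG" + "C" * 24 + "TAA"              # 30-60 forward gene
        + "G" * 20                               # 60-80 gap
        + "TTA" + "G" * 24 + "CAT"              # 80-110 reverse gene
        + "C" * 30
    )
    contig = Contig("toy", seq)
    genes = [
        GeneRecord("fwd1", "toy", "+", 30, 60, "ATG"),
        GeneRecord("rev1", "toy", "-", 80, 110, "ATG"),
    ]
    return contig, genes
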