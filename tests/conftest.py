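import numpy as np
import pytest

from phagecharm.model import AnnotatedGenome, Feature


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def two_cds_genome():
    """A 60 bp genome with two short CDS features, one per strand."""
    seq = "ATGAAACCCGGGTTTTAAATTTTTTCATATGAAACCCGGGAAATAAGGGCCCTTTAAGGG"
    return AnnotatedGenome(
        "toy", seq, "linear",
        [Feature("CDS", 0, 18, "+", "g1"),
         Feature("CDS", 25, 46, "-", "g2")],
    )


@pytest.fixture
def two_cds_genbank(tmp_path, two_cds_genome):
    from phagecharm import genome_io
    path = tmp_path / "two_cds.gb"
    genome_io.write_genbank(two_cds_genome, path)
    return path
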