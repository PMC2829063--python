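import numpy as np
import pytest

from pangei.genome import AnnotatedGenome, GeneRecord, Replicon
from pangei.simulate import SimulationConfig, generate_reference_genome


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=20260926)


@pytest.fixture(scope="session")
def sim_genome(default_cfg):
    """Default simulated genome + truth, shared across the session."""
    return generate_reference_genome(default_cfg)


@pytest.fixture()
def tiny_genome() -> AnnotatedGenome:
    """Two genes on a 60 bp replicon, one per strand."""
    seq = "TT" + "ATGAAATAA" + "CCGGTTA" + "TTATTTCAT" + "G" * 33
    rep = Replicon("chr", len(seq), circular=False, seq=seq)
    plus = GeneRecord("gA", "chr", 2, 11, "+", "CDS")    # ATGAAATAA
    minus = GeneRecord("gB", "chr", 18, 27, "-", "CDS")  # revcomp = ATGAAATAA
    return AnnotatedGenome([rep], [plus, minus])


def random_small_genome(rng: np.random.Generator) -> AnnotatedGenome:
    """A few random genes for round-trip property tests."""
    n = int(rng.integers(1, 8))
    length = 400 + n * 120
    seq = "".join(rng.choice(list("ACGT"), size=length))
    genes = []
    pos = 5
    kinds = ["CDS", "tRNA", "miscRNA", "other"]
    products = ["", "hypothetical protein", "transposase", "phage integrase"]
    from pangei.genome import classify_mobility
    for i in range(n):
        glen = int(rng.integers(1, 20)) * 3
        product = products[int(rng.integers(4))]
        genes.append(GeneRecord(
            id=f"g{i}", replicon_id="r1", start=pos, end=pos + glen,
            strand="+-"[int(rng.integers(2))], kind=kinds[int(rng.integers(4))],
            mobility_class=classify_mobility(product), product=product))
        pos += glen + int(rng.integers(3, 30))
    return AnnotatedGenome([Replicon("r1", length, seq=seq)], genes)
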