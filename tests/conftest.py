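import numpy as np
import pytest

from mmseq.core import Genome, MethylationTruth, MotifRule
from mmseq.simdata import SimConfig, plant_methylation, simulate_genome

GATC = MotifRule("GATC", "GATC", 1, both_strands=True)
VATB = MotifRule("VATB", "VATB", 1, both_strands=True)


@pytest.fixture(scope="session")
def gatc_rule():
    return GATC


@pytest.fixture(scope="session")
def vatb_rule():
    return VATB


@pytest.fixture(scope="session")
def toy_genome():
    """10-kb single-contig random genome."""
    return simulate_genome(1, 10_000, 0.5, seed=42)


@pytest.fixture(scope="session")
def toy_truth(toy_genome, gatc_rule):
    """Every GATC duplex in the toy genome fully methylated."""
    return plant_methylation(toy_genome, gatc_rule, 1.0, seed=7)


@pytest.fixture
def oligo():
    """Synthetic 59-nt duplex with one plus-strand 6mA at 1-based position 25.

    The non-site bases avoid A so the modified adenine is the only one on
    the plus strand (mirrors a defined synthetic substrate).
    """
    rng = np.random.default_rng(11)
    seq = list(rng.choice(list("CGT"), 59))
    seq[24] = "A"
    genome = Genome({"oligo": "".join(seq)})
    truth = MethylationTruth()
    truth.add("oligo", 24, "+")
    return genome, truth


@pytest.fixture
def full_length_cfg():
    """One full-length fragment, guaranteed capture."""
    return SimConfig(
        n_fragments=1, capture_prob=1.0, frag_len_mean=59, frag_len_sd=0, seed=5
    )


def depth_to_fragments(genome, depth, frag_len):
    return int(round(depth * genome.total_length() / frag_len))
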