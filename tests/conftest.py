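import numpy as np
import pytest

from regmotif.core import Genome
from regmotif.fixtures import make_genome, planted_pwm
from regmotif.motif import Background, to_pssm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    return make_genome(2000, seed=11, sequence_ids=("chr1", "chr2"))


@pytest.fixture
def pwm():
    return planted_pwm()  # 10-column, ~16.3-bit palindrome-consensus motif


@pytest.fixture
def pssm(pwm):
    return to_pssm(pwm, Background.uniform())


def random_dna(rng, length, with_n=0.0):
    bases = np.array(list("ACGTN"))
    p = [(1 - with_n) / 4] * 4 + [with_n]
    return "".join(bases[rng.choice(5, size=length, p=p)])
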