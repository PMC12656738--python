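import numpy as np
import pytest

from phagekit.io import Genome, GenomeSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length, gc=0.5):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def mutate(rng, sequence, p):
    """Independent per-site substitution, uniform over the 3 alternatives."""
    bases = "ACGT"
    out = list(sequence)
    mask = rng.random(len(out)) < p
    for i in np.nonzero(mask)[0]:
        alternatives = [b for b in bases if b != out[i]]
        out[i] = alternatives[rng.integers(0, 3)]
    return "".join(out)


@pytest.fixture
def small_pair(rng):
    """A 9 kb genome and a copy with 30 substitutions in the first 3 kb."""
    ancestor = random_sequence(rng, 9000)
    positions = rng.choice(3000, size=30, replace=False)
    derived = list(ancestor)
    for i in positions:
        alternatives = [b for b in "ACGT" if b != derived[i]]
        derived[i] = alternatives[rng.integers(0, 3)]
    return Genome(id="anc", sequence=ancestor), Genome(id="der", sequence="".join(derived))


@pytest.fixture
def genome_set(rng):
    return GenomeSet(
        [
            Genome(id="A", sequence=random_sequence(rng, 4000)),
            Genome(id="B", sequence=random_sequence(rng, 4200)),
        ]
    )
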