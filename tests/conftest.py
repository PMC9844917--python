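import random

import pytest


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def random_sequences(rng):
    """A reusable batch of random DNA sequences of mixed lengths."""

    def make(n, min_len=1, max_len=400):
        return [
            "".join(rng.choice("ACGT") for _ in range(rng.randint(min_len, max_len)))
            for _ in range(n)
        ]

    return make


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">s1\nACGT\n>s2\nAC\nGT\n>s3\nAAATTTCCGG\n")
    return str(path)
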