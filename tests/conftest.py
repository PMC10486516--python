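import numpy as np
import pandas as pd
import pytest

from graphmer.debruijn import FeatureMatrix, feature_names
from graphmer.fastq_io import CleanSample


def write_fastq(path, records):
    """records: iterable of (ident, seq, plus, qual) tuples."""
    with open(path, "w") as fh:
        for ident, seq, plus, qual in records:
            fh.write(f"{ident}\n{seq}\n{plus}\n{qual}\n")


def random_sample(rng, sample_id="s", n_reads=20, min_len=0, max_len=50,
                  n_prob=0.0, label=None):
    """Random CleanSample; n_prob > 0 sprinkles N bases."""
    alphabet = np.array(list("ACGTN"))
    reads = []
    for _ in range(n_reads):
        length = int(rng.integers(min_len, max_len + 1))
        probs = np.array([1, 1, 1, 1, 0], dtype=float)
        if n_prob > 0:
            probs = np.array([(1 - n_prob) / 4] * 4 + [n_prob])
        probs = probs / probs.sum()
        reads.append("".join(rng.choice(alphabet, size=length, p=probs)))
    return CleanSample(sample_id=sample_id, reads=reads, label=label)


def labeled_matrix(rng, n0=75, n1=25, n_features=None, k=2):
    """A labeled FeatureMatrix of random nonnegative counts."""
    if n_features is None:
        n_features = 4 ** (k + 1)
    n = n0 + n1
    data = pd.DataFrame(
        rng.integers(0, 50, size=(n, n_features)),
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        columns=feature_names(k),
    )
    labels = pd.Series([0] * n0 + [1] * n1, index=data.index, name="label")
    return FeatureMatrix(k=k, data=data, labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
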