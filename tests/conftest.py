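import numpy as np
import pytest

from iddcomp.io import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_seqs(strings, prefix="s"):
    return [SequenceRecord(id=f"{prefix}{i}", residues=s) for i, s in enumerate(strings)]


def random_seqs(rng, n, min_len=5, max_len=60):
    letters = np.array(list(AA))
    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        p = rng.dirichlet(np.ones(20))
        out.append(
            SequenceRecord(id=f"r{i}", residues="".join(rng.choice(letters, size=length, p=p)))
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_synthetic():
    """Two tiny synthetic sets sharing the default four archetypes."""
    from iddcomp.synthetic import default_config, generate

    cfg = default_config(seed=7)
    cfg.n_per_archetype_a = 10
    cfg.n_per_archetype_b = 10
    cfg.length_mean = 120.0
    return generate(cfg)
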