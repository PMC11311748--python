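import numpy as np
import pytest

from formulanet.corpus_io import corpus_from_records


@pytest.fixture
def tiny_corpus():
    """Two small prescriptions sharing one herb and one indication."""
    return corpus_from_records(
        [
            ("P-1", "H1", "herb"),
            ("P-1", "H2", "herb"),
            ("P-1", "S13", "indication"),
            ("P-2", "H1", "herb"),
            ("P-2", "S13", "indication"),
            ("P-2", "S1", "indication"),
        ]
    )


def random_corpus(rng, n_prescriptions=10, n_herbs=12, n_indications=6, p=0.35):
    """Random corpus with non-empty herb sets; indications may be empty."""
    records = []
    for i in range(n_prescriptions):
        herbs = [f"H{j+1}" for j in range(n_herbs) if rng.random() < p]
        if not herbs:
            herbs = [f"H{int(rng.integers(n_herbs)) + 1}"]
        inds = [f"S{j+1}" for j in range(n_indications) if rng.random() < p]
        pid = f"P-{i+1}"
        records += [(pid, h, "herb") for h in herbs]
        records += [(pid, s, "indication") for s in inds]
    return corpus_from_records(records)


@pytest.fixture
def corpus_factory():
    return random_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(20240728)
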