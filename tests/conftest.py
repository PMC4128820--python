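import numpy as np
import pytest

import landbridge as lb


@pytest.fixture(scope="session")
def study_dataset():
    """One study-like synthetic dataset shared across the session."""
    cfg = lb.StudyConfig(tips_per_clade=10)
    aln, tree, truth = lb.generate_study_like_dataset(cfg, seed=1)
    return cfg, aln, tree, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_tip_tree():
    return lb.TimeTree(np.array([2, 2, -1]), np.array([0.0, 0.0, 5000.0]),
                       ["a", "b"])


@pytest.fixture()
def toy_alignment():
    # 4 sequences, hand-countable differences
    return lb.Alignment(
        ["s1", "s2", "s3", "s4"],
        ["ACGTACGTAC", "ACGTACGTAC", "ACGAACGTAC", "GCGAACTTAC"],
    )
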