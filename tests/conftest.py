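import numpy as np
import pytest

import trlocus as trl


@pytest.fixture(scope="session")
def small_locus():
    """A compact defect-free locus: 3 V, 2 D, 3 J, 1 C."""
    spec = trl.SyntheticLocusSpec(n_v=3, n_d=2, n_j=3, n_c=1, seed=1)
    genome, truth = trl.build_locus(spec)
    return spec, genome, truth


@pytest.fixture(scope="session")
def recovery_locus():
    """A 50-segment defect-free locus with its full annotation run."""
    spec = trl.SyntheticLocusSpec(n_v=25, n_d=5, n_j=15, n_c=5, seed=11)
    genome, truth = trl.build_locus(spec)
    refs = trl.reference_set(truth)
    ann = trl.annotate_genome(
        genome, refs, expression=trl.expression_from_truth(truth), locus_label="SYN"
    )
    return genome, truth, ann


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n: int, gc: float = 0.42) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
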