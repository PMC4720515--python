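import numpy as np
import pytest

from txdrift import ExpressionMatrix, SampleAnnotation, cpm_normalize


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def toy_counts():
    """3 genes x 4 samples, two ages x two replicates."""
    values = np.array(
        [
            [10.0, 12.0, 40.0, 44.0],
            [30.0, 28.0, 10.0, 9.0],
            [60.0, 60.0, 50.0, 47.0],
        ]
    )
    m = ExpressionMatrix(["g1", "g2", "g3"], ["y1", "y2", "o1", "o2"], values)
    anns = [
        SampleAnnotation("y1", age=1, treatment="water", replicate=1),
        SampleAnnotation("y2", age=1, treatment="water", replicate=2),
        SampleAnnotation("o1", age=10, treatment="water", replicate=1),
        SampleAnnotation("o2", age=10, treatment="water", replicate=2),
    ]
    return m, anns


@pytest.fixture
def toy_cpm(toy_counts):
    m, anns = toy_counts
    return cpm_normalize(m), anns
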