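import numpy as np
import pytest

from permaxt import ExpressionMatrix, Outcome


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    values = rng.standard_normal((5, 8))
    return ExpressionMatrix(
        values=values,
        feature_ids=[f"g{i}" for i in range(5)],
        sample_ids=[f"s{i}" for i in range(8)],
    )


@pytest.fixture
def binary_outcome():
    return Outcome.binary([0, 0, 0, 0, 1, 1, 1, 1])


@pytest.fixture
def quantitative_outcome():
    rng = np.random.default_rng(7)
    return Outcome.quantitative(rng.standard_normal(8))


@pytest.fixture
def survival_outcome():
    # 10 samples, 6 events, all event times distinct
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
    event = np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 0])
    return Outcome.survival(time, event)


def write_tsv(path, header, rows):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path
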