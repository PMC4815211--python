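import numpy as np
import pandas as pd
import pytest

from snvda.matrix import SnvMatrix


def make_matrix(values, labels=None, regions=None, genes=None, editing=None,
                coverage_threshold=10):
    """Build an SnvMatrix from a plain array (features x samples)."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    keys = [f"chr1:{1000 + 100 * i}:C>T" for i in range(p)]
    samples = [f"S{j:02d}" for j in range(n)]
    if labels is None:
        labels = ["group_A"] * (n // 2) + ["group_B"] * (n - n // 2)
    ann = pd.DataFrame(
        {
            "region": regions if regions is not None else ["exonic"] * p,
            "gene": genes if genes is not None else [f"G{i}" for i in range(p)],
            "dbsnp_id": [""] * p,
            "is_editing_site": editing if editing is not None else [False] * p,
        },
        index=pd.Index(keys, name="snv_key"),
    )
    return SnvMatrix(
        values=pd.DataFrame(values, index=ann.index, columns=samples),
        annotations=ann,
        labels=pd.Series(labels, index=pd.Index(samples, name="sample_id"), name="group"),
        coverage_threshold=coverage_threshold,
    )


@pytest.fixture
def separable_matrix():
    """One perfectly separating feature among pure-noise features."""
    rng = np.random.default_rng(42)
    p, n = 20, 16
    vals = rng.beta(5, 5, size=(p, n)) * (rng.random((p, n)) < 0.6)
    vals[0] = np.r_[np.full(8, 0.05), np.full(8, 0.95)]  # group_A low, group_B high
    return make_matrix(vals)


@pytest.fixture
def random_na_matrix():
    rng = np.random.default_rng(7)
    vals = rng.beta(2, 2, size=(30, 12))
    vals[rng.random((30, 12)) < 0.15] = np.nan
    return make_matrix(vals)
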