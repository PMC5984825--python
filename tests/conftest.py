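import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def toy_expr():
    """3 genes x 4 samples, hand-sized."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [2.0, 2.0, 2.0, 2.0]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["s1", "s2", "s3", "s4"])


def make_meta(sample_ids, diagnosis, region=None, subject=None, seed=0):
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    return pd.DataFrame({
        "subject_id": subject if subject is not None else [f"sub{i}" for i in range(n)],
        "diagnosis": diagnosis,
        "RIN": rng.uniform(6, 9, n).round(2),
        "PMI": rng.uniform(10, 30, n).round(2),
        "age": rng.uniform(5, 60, n).round(1),
        "sex": rng.choice(["M", "F"], n),
        "region": region if region is not None else rng.choice(["frontal", "temporal"], n),
    }, index=pd.Index(sample_ids, name="sample_id"))


@pytest.fixture
def toy_meta(toy_expr):
    return make_meta(list(toy_expr.columns), ["autism", "autism", "control", "control"])
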