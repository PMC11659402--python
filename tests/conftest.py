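import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_de():
    """The canonical 5-gene table: extremes map to +/-100, zero stays 0."""
    return pd.DataFrame(
        {"gene_id": list("ABCDE"), "log2fc": [2.0, 1.0, 0.0, -1.0, -3.0], "padj": np.nan}
    )


def percentile_oracle(gene_ids, log2fc):
    """Brute-force pool-ranking oracle for the regulatory-percentile transform.

    Mid-ranks computed by explicit counting, independent of scipy.
    """
    out = {}
    up = [(g, v) for g, v in zip(gene_ids, log2fc) if v > 0]
    down = [(g, v) for g, v in zip(gene_ids, log2fc) if v < 0]
    for g, v in zip(gene_ids, log2fc):
        if v == 0:
            out[g] = 0.0
        elif v > 0:
            less = sum(1 for _, w in up if w < v)
            equal = sum(1 for _, w in up if w == v)
            out[g] = (less + (equal + 1) / 2.0) / len(up) * 100.0
        else:
            less = sum(1 for _, w in down if abs(w) < abs(v))
            equal = sum(1 for _, w in down if abs(w) == abs(v))
            out[g] = -(less + (equal + 1) / 2.0) / len(down) * 100.0
    return out


def es_oracle(values_sorted, hit_positions, weight):
    """Exhaustive running-sum oracle for the weighted KS enrichment score."""
    n = len(values_sorted)
    hits = set(int(p) for p in hit_positions)
    nh = len(hits)
    if nh == n:
        return 0.0
    sumw = sum(abs(values_sorted[p]) ** weight for p in hits)
    if sumw == 0:
        weights = {p: 1.0 / nh for p in hits}
    else:
        weights = {p: abs(values_sorted[p]) ** weight / sumw for p in hits}
    rs = 0.0
    trace = []
    for i in range(n):
        rs += weights[i] if i in hits else -1.0 / (n - nh)
        trace.append(rs)
    mx, mn = max(trace), min(trace)
    return mx if abs(mx) >= abs(mn) - 1e-9 else mn
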