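import numpy as np
import pytest

from bluecall import make_benchmark


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark100():
    """The standard synthetic benchmark: 100 single-window scenes at 10 dB
    in-band SNR, generated once per session."""
    return make_benchmark(n_scenes=100, snr_db=10.0, seed=1)


@pytest.fixture(scope="session")
def benchmark_small():
    return make_benchmark(n_scenes=30, snr_db=10.0, seed=7)


def sampen_oracle(x, m, r, norm_mode="paper"):
    """Literal double-loop sample entropy: embeddings, Chebyshev matches at
    m and m+1, the probabilistic parameters under either normaliser, and
    -ln of their ratio.  Independent of the vectorized implementation."""
    x = list(map(float, x))
    n = len(x)

    def pair_count(dim):
        vecs = [x[i:i + dim] for i in range(n - dim + 1)]
        count = 0
        for i in range(len(vecs) - 1):
            for j in range(i + 1, len(vecs)):
                if max(abs(a - b) for a, b in zip(vecs[i], vecs[j])) <= r:
                    count += 1
        return count

    M = n - m + 1
    C_m = pair_count(m)
    C_m1 = pair_count(m + 1)
    if norm_mode == "paper":
        T_m = m * M / 2.0
        T_m1 = (m + 1) * (M - 1) / 2.0
    else:
        T_m = M * (M - 1) / 2.0
        T_m1 = (M - 1) * (M - 2) / 2.0
    if C_m == 0 or C_m1 == 0:
        return C_m, C_m1, float("nan")
    return C_m, C_m1, -np.log((C_m1 / T_m1) / (C_m / T_m))
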