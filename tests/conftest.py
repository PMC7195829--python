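import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

import ecmpredict as ep
from ecmpredict.synthetic import SimConfig, generate


@pytest.fixture(scope="session")
def catalog():
    return ep.read_domain_catalog()


@pytest.fixture(scope="session")
def aaindex():
    return ep.read_aaindex_table()


@pytest.fixture(scope="session")
def small_dataset(catalog):
    """Small signal-bearing dataset shared by feature/model/evaluation tests."""
    return generate(
        SimConfig(n_pos=15, n_neg=60, seq_len_range=(20, 40), seed=7),
        catalog=catalog,
    )


@pytest.fixture(scope="session")
def small_features(small_dataset, aaindex):
    return ep.extract_feature_table(
        small_dataset.records,
        small_dataset.annotations,
        small_dataset.pssms,
        small_dataset.catalog,
        aaindex,
    )


def gm21_oracle(x0):
    """Independent GM(2,1) estimate via explicit normal equations / pinv."""
    x0 = [float(v) for v in x0]
    L = len(x0)
    x1 = []
    total = 0.0
    for v in x0:
        total += v
        x1.append(total)
    B, Y = [], []
    for k in range(1, L):
        B.append([-x0[k], -0.5 * (x1[k] + x1[k - 1]), 1.0])
        Y.append(x0[k] - x0[k - 1])
    return np.linalg.pinv(np.array(B)) @ np.array(Y)


def mi_oracle(x, y):
    """Brute-force plug-in mutual information (bits) over the joint histogram."""
    n = len(x)
    pxy = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in pxy.items():
        p = c / n
        total += p * math.log2(p / ((px[a] / n) * (py[b] / n)))
    return total
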