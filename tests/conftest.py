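import itertools

import numpy as np
import pytest

from catapanel import CitationDataset, PanelSimConfig, simulate_panel


def make_dataset(indicators) -> CitationDataset:
    """Wrap a (J, P, R, A) binary array with generated labels."""
    arr = np.asarray(indicators, dtype=np.uint8)
    J, P, R, A = arr.shape
    return CitationDataset(
        tuple(f"J{j+1}" for j in range(J)),
        tuple(f"P{p+1}" for p in range(P)),
        tuple(f"R{r+1}" for r in range(R)),
        tuple(f"A{a+1}" for a in range(A)),
        arr,
    )


def random_dataset(rng, J=3, P=2, R=2, A=6, p=0.3) -> CitationDataset:
    return make_dataset((rng.random((J, P, R, A)) < p).astype(np.uint8))


def brute_force_pair_counts(dataset, panelist, product):
    """Set-based recomputation of the replicate 2x2 counts."""
    j = dataset.panelist_ids.index(panelist)
    p = dataset.product_ids.index(product)
    rep1 = {a for a, v in zip(dataset.attribute_ids, dataset.indicators[j, p, 0]) if v}
    rep2 = {a for a, v in zip(dataset.attribute_ids, dataset.indicators[j, p, 1]) if v}
    n11 = len(rep1 & rep2)
    n10 = len(rep1 - rep2)
    n01 = len(rep2 - rep1)
    n00 = dataset.n_attributes - n11 - n10 - n01
    return n11, n10, n01, n00


def brute_force_indices(dataset, panelist):
    """Per-product enumeration of the three indices for one panelist."""
    r_terms, p_terms, c_terms = [], [], []
    A = dataset.n_attributes
    for product in dataset.product_ids:
        n11, n10, n01, n00 = brute_force_pair_counts(dataset, panelist, product)
        n1, m1 = n11 + n10, n11 + n01
        n0, m0 = A - n1, A - m1
        if n1 + m1 > 0:
            r_terms.append(2 * n11 / (n1 + m1))
        if n1 > 0:
            p_terms.append(n11 / n1)
        if n1 * n0 * m1 * m0 > 0:
            c_terms.append(A * (n11 * n00 - n10 * n01) ** 2 / (n1 * n0 * m1 * m0))
    mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
    return mean(c_terms), mean(r_terms), mean(p_terms)


def permutation_p_cochran(x, statistic):
    """Exact within-block permutation p-values (raw, mid) for Cochran's Q, k=3.

    The permutation law is enumerated exhaustively by dynamic programming over
    the joint distribution of the first two column sums; the Q denominator is
    permutation-invariant, so Q is a deterministic function of the column sums.
    """
    from collections import defaultdict

    x = np.asarray(x)
    b, k = x.shape
    assert k == 3
    dist = {(0, 0): 1.0}
    for row in x:
        arrangements = sorted(set(itertools.permutations(row.tolist())))
        p_each = 1.0 / len(arrangements)
        new = defaultdict(float)
        for (c1, c2), pr in dist.items():
            for arr in arrangements:
                new[(c1 + arr[0], c2 + arr[1])] += pr * p_each
        dist = new
    N = int(x.sum())
    den = k * N - int((x.sum(axis=1) ** 2).sum())
    greater = equal = 0.0
    for (c1, c2), pr in dist.items():
        c3 = N - c1 - c2
        q = 0.0 if den == 0 else (k - 1) * (k * (c1**2 + c2**2 + c3**2) - N**2) / den
        if q > statistic + 1e-9:
            greater += pr
        elif abs(q - statistic) <= 1e-9:
            equal += pr
    return greater + equal, greater + 0.5 * equal


def permutation_p_friedman(x, statistic):
    """Exact within-block permutation p-values (raw, mid) for Friedman, k=3.

    Blocks contribute independent uniformly permuted rank vectors; the
    statistic depends only on the column rank sums, enumerated by DP.
    """
    from collections import defaultdict

    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    b, k = x.shape
    assert k == 3
    dist = {(0.0, 0.0): 1.0}
    for row in x:
        ranks = rankdata(row)
        arrangements = sorted(set(itertools.permutations(ranks.tolist())))
        p_each = 1.0 / len(arrangements)
        new = defaultdict(float)
        for (r1, r2), pr in dist.items():
            for arr in arrangements:
                new[(r1 + arr[0], r2 + arr[1])] += pr * p_each
        dist = new
    # tie-corrected statistic as a function of column rank sums
    ranks_all = np.apply_along_axis(rankdata, 1, x)
    den = (ranks_all**2).sum() - b * k * (k + 1) ** 2 / 4
    greater = equal = 0.0
    total = ranks_all.sum()
    for (r1, r2), pr in dist.items():
        r3 = total - r1 - r2
        cols = np.array([r1, r2, r3])
        s = 0.0 if den == 0 else (k - 1) * ((cols - b * (k + 1) / 2) ** 2).sum() / den
        if s > statistic + 1e-9:
            greater += pr
        elif abs(s - statistic) <= 1e-9:
            equal += pr
    return greater + equal, greater + 0.5 * equal


@pytest.fixture(scope="session")
def sim_default():
    """One study-scale simulated panel, shared across tests."""
    return simulate_panel(PanelSimConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
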