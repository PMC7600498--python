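"""Panel-level reproducibility and discrimination analysis.

Two nonparametric tests for complete block designs drive this module:

* Cochran's Q for binary responses — used per descriptor to test a
  *replicate* effect (blocks = panelist x product pairs, treatments = the two
  replicates; a significant Q means the panel cites the descriptor at
  different rates in the two sessions) and a *product* effect (blocks =
  panelist x replicate pairs, treatments = products; significance evidences
  discrimination ability).  A pooled "All attributes" row adds attribute as
  a further blocking factor, giving one overall Q.
* Friedman's rank test — used on the per-product single-wine index values
  (blocks = panelists, treatments = products) to ask whether reproducibility
  differs across products.

The module also computes the chi-square (correspondence-analysis row)
distances between the two replicate citation profiles of every product,
which feed the Sammon embedding in :mod:`catapanel.embedding`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import cochrans_q

from .dataset import (
    CatapanelWarning,
    CitationDataset,
    DegenerateDataError,
    frequency_table,
)
from .outliers import TestResult
from .panelist import per_product_index_values

__all__ = [
    "cochran_q",
    "friedman_test",
    "replicate_effect",
    "product_effect",
    "effect_table",
    "per_product_indices",
    "PerProductIndices",
    "replicate_profile_distances",
]


def cochran_q(block_matrix) -> TestResult:
    """Cochran's Q test for equal proportions across related binary treatments.

    ``block_matrix`` is blocks x treatments with entries in {0, 1}.  Blocks
    with constant response contribute nothing; if *all* blocks are constant
    the statistic is reported as 0 with p = 1 and a warning.  For k = 2 the
    statistic equals the uncorrected McNemar statistic.
    """
    x = np.asarray(block_matrix)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("block_matrix must be 2-D with at least 2 treatments")
    if not np.isin(x, (0, 1)).all():
        raise TypeError("Cochran's Q requires binary (0/1) entries")
    k = x.shape[1]
    row_sums = x.sum(axis=1)
    if ((row_sums == 0) | (row_sums == k)).all():
        warnings.warn(
            "Cochran's Q degenerate: all blocks constant; reporting Q=0, p=1",
            CatapanelWarning,
        )
        return TestResult(0.0, 1.0, "Cochran's Q test", df=k - 1, n=x.shape[0])
    res = cochrans_q(x, return_object=True)
    return TestResult(
        float(res.statistic), float(res.pvalue), "Cochran's Q test", df=k - 1, n=x.shape[0]
    )


def friedman_test(value_matrix) -> TestResult:
    """Friedman rank test for a complete block design, with tie correction.

    Ranks are assigned within blocks (average ranks for ties).  The
    chi-square statistic uses the general tie-corrected form
    ``(k-1) * sum_j (R_j - b(k+1)/2)^2 / (sum_ij r_ij^2 - b k (k+1)^2 / 4)``
    with df = k - 1.  An all-tied matrix yields statistic 0, p = 1 with a
    warning.  Unlike the scipy implementation this accepts k = 2.
    """
    x = np.asarray(value_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("value_matrix must be 2-D with >=2 blocks and >=2 treatments")
    if np.isnan(x).any():
        raise ValueError("value_matrix contains missing cells")
    b, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * ((col_sums - b * (k + 1) / 2) ** 2).sum()
    den = (ranks**2).sum() - b * k * (k + 1) ** 2 / 4
    if den == 0:
        warnings.warn(
            "Friedman test degenerate: all blocks fully tied; reporting 0, p=1",
            CatapanelWarning,
        )
        return TestResult(0.0, 1.0, "Friedman test", df=k - 1, n=b)
    statistic = num / den
    p = float(stats.chi2.sf(statistic, df=k - 1))
    return TestResult(float(statistic), p, "Friedman test", df=k - 1, n=b)


def replicate_effect(dataset: CitationDataset) -> pd.DataFrame:
    """Per-descriptor replicate effect (Cochran's Q) and citation proportions.

    Rows: a pooled "All attributes" row followed by every attribute.
    Columns: ``replicate_p`` plus one citation-proportion column per
    replicate.  Blocks are (panelist, product) pairs; the pooled row treats
    attribute as an extra blocking factor.
    """
    if dataset.n_replicates != 2:
        raise DegenerateDataError("replicate effect requires exactly 2 replicates")
    ind = dataset.indicators  # (J, P, R, A)
    J, P, R, A = ind.shape
    rows = {}
    pooled = ind.transpose(0, 1, 3, 2).reshape(J * P * A, R)
    rows["All attributes"] = cochran_q(pooled)
    for a, attr in enumerate(dataset.attribute_ids):
        block = ind[:, :, :, a].reshape(J * P, R)
        rows[attr] = cochran_q(block)
    props = ind.mean(axis=(0, 1))  # (R, A) -> proportion per replicate x attribute
    out = pd.DataFrame(
        {"replicate_p": {name: res.p_value for name, res in rows.items()}}
    )
    for r, rep in enumerate(dataset.replicate_ids):
        col = {"All attributes": float(ind[:, :, r, :].mean())}
        col.update({attr: float(props[r, a]) for a, attr in enumerate(dataset.attribute_ids)})
        out[f"proportion_{rep}"] = pd.Series(col)
    out.index.name = "attribute"
    return out.loc[["All attributes"] + list(dataset.attribute_ids)]


def product_effect(dataset: CitationDataset) -> pd.DataFrame:
    """Per-descriptor product effect (Cochran's Q; blocks = panelist x replicate)."""
    if dataset.n_products < 2:
        raise ValueError("product effect requires at least 2 products")
    ind = dataset.indicators
    J, P, R, A = ind.shape
    rows = {}
    pooled = ind.transpose(0, 2, 3, 1).reshape(J * R * A, P)
    rows["All attributes"] = cochran_q(pooled)
    for a, attr in enumerate(dataset.attribute_ids):
        block = ind[:, :, :, a].transpose(0, 2, 1).reshape(J * R, P)
        rows[attr] = cochran_q(block)
    out = pd.DataFrame({"product_p": {name: res.p_value for name, res in rows.items()}})
    out.index.name = "attribute"
    return out.loc[["All attributes"] + list(dataset.attribute_ids)]


def effect_table(dataset: CitationDataset) -> pd.DataFrame:
    """Combined replicate- and product-effect table (one row per attribute)."""
    return replicate_effect(dataset).join(product_effect(dataset))


@dataclass(frozen=True)
class PerProductIndices:
    """Per-product mean indices plus the Friedman test per index."""

    table: pd.DataFrame  # products x (chi2, R, p11)
    friedman: dict  # index name -> TestResult


def per_product_indices(dataset: CitationDataset) -> PerProductIndices:
    """Average the single-wine index values over panelists, per product.

    Degenerate (panelist, product) cells are skipped in the means with a
    warning; for the Friedman test (blocks = panelists, treatments =
    products, which needs a complete matrix) panelists with any degenerate
    cell are dropped, also with a warning.
    """
    values = per_product_index_values(dataset)
    table = pd.DataFrame(index=list(dataset.product_ids))
    table.index.name = "product"
    friedman: dict[str, TestResult] = {}
    for name, mat in values.items():
        if mat.isna().any().any():
            warnings.warn(
                f"per-product {name}: degenerate cells excluded from means",
                CatapanelWarning,
            )
        table[name] = [
            float(np.mean(mat[p].dropna().to_numpy())) for p in table.index
        ]
        complete = mat.dropna(axis=0)
        if len(complete) < len(mat):
            warnings.warn(
                f"Friedman on {name}: dropped {len(mat) - len(complete)} incomplete panelist(s)",
                CatapanelWarning,
            )
        if len(complete) >= 2:
            friedman[name] = friedman_test(complete.to_numpy())
        else:
            warnings.warn(
                f"Friedman on {name}: fewer than 2 complete panelists; test omitted",
                CatapanelWarning,
            )
            friedman[name] = TestResult(np.nan, 1.0, "Friedman test (omitted)")
    return PerProductIndices(table, friedman)


def replicate_profile_distances(dataset: CitationDataset) -> pd.DataFrame:
    """Chi-square row distances between product x replicate citation profiles.

    The per-replicate citation-count table (rows = product x replicate,
    columns = attributes) is treated as a correspondence table: with
    correspondence matrix P, row masses r and column masses c, the distance
    between rows i and i' is
    ``sqrt( sum_a (P_ia / r_i - P_i'a / r_i')^2 / c_a )``.
    Rows with zero mass (a product-replicate with no citations at all) are
    excluded with a warning.  Returns a symmetric labelled DataFrame.
    """
    freq = frequency_table(dataset, mode="per_replicate")
    counts = freq.counts.to_numpy(dtype=float)
    labels = list(freq.counts.index)
    mass = counts.sum()
    if mass == 0:
        raise DegenerateDataError("no citations at all: distances undefined")
    keep = counts.sum(axis=1) > 0
    if not keep.all():
        dropped = [labels[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropped zero-citation profiles: {dropped}", CatapanelWarning
        )
        counts = counts[keep]
        labels = [l for l, k in zip(labels, keep) if k]
    P = counts / counts.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep_cols = c > 0
    profiles = (P / r[:, None])[:, keep_cols]
    inv_c = 1.0 / c[keep_cols]
    diff = profiles[:, None, :] - profiles[None, :, :]
    d2 = (diff**2 * inv_c[None, None, :]).sum(axis=2)
    D = np.sqrt(np.maximum(d2, 0.0))
    np.fill_diagonal(D, 0.0)
    index = pd.MultiIndex.from_tuples(labels, names=["product", "replicate"])
    return pd.DataFrame(D, index=index, columns=index)
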