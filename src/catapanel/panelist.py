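"""Per-panelist reproducibility indices and outlier-based panel screening.

For each panelist and product, the two replicate citation sets are
cross-tabulated into a 2x2 table over the A descriptors:

====================  =================  =====================
                      chosen in rep 2    not chosen in rep 2
chosen in rep 1       n11                n10
not chosen in rep 1   n01                n00
====================  =================  =====================

with margins n1. = n11 + n10 (descriptors ticked in replicate 1) and
n.1 = n11 + n01 (ticked in replicate 2).  Three per-panelist indices average
over the n products evaluated:

* ``R``    = mean of 2 n11 / (n1. + n.1)  — Dice agreement of the two sets;
* ``p11``  = mean of n11 / n1.            — estimated probability of re-citing
  in replicate 2 a descriptor cited in replicate 1;
* ``chi2`` = mean of the (uncorrected) Pearson chi-square statistic of the
  2x2 table, A (n11 n00 - n10 n01)^2 / (n1. n0. n.1 n.0); large values
  indicate association between replicates, i.e. reproducibility.

Products whose 2x2 table is degenerate for an index (zero denominator or
zero margin) are excluded from that panelist's average with a warning: the
2-5-citation protocol makes them impossible in practice, but the library
must not crash on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CatapanelWarning, CitationDataset, DegenerateDataError
from .outliers import TestResult, chisq_outlier_test, dixon_test, grubbs_test

__all__ = [
    "ReplicatePairCounts",
    "ExclusionReport",
    "pair_counts",
    "index_R",
    "index_p11",
    "index_chi2",
    "reproducibility_indices",
    "summarize_indices",
    "screen_panelists",
]

_ALL_TESTS = ("grubbs", "dixon", "chisq")
_TEST_FUNCS = {"grubbs": grubbs_test, "dixon": dixon_test, "chisq": chisq_outlier_test}


@dataclass(frozen=True)
class ReplicatePairCounts:
    """2x2 agreement counts between the two replicate citation sets."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def A(self) -> int:
        """Total number of attributes in the table."""
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def n1_(self) -> int:
        return self.n11 + self.n10

    @property
    def n_1(self) -> int:
        return self.n11 + self.n01

    @property
    def n0_(self) -> int:
        return self.n01 + self.n00

    @property
    def n_0(self) -> int:
        return self.n10 + self.n00


def pair_counts(dataset: CitationDataset, panelist, product) -> ReplicatePairCounts:
    """Cross-tabulate one panelist's two replicate citation vectors for a product."""
    if dataset.n_replicates != 2:
        raise DegenerateDataError(
            f"reproducibility indices need exactly 2 replicates, got {dataset.n_replicates}"
        )
    j = dataset.panelist_ids.index(panelist)
    p = dataset.product_ids.index(product)
    r1 = dataset.indicators[j, p, 0].astype(bool)
    r2 = dataset.indicators[j, p, 1].astype(bool)
    return ReplicatePairCounts(
        int((r1 & r2).sum()),
        int((r1 & ~r2).sum()),
        int((~r1 & r2).sum()),
        int((~r1 & ~r2).sum()),
    )


def _counts_for_panelist(dataset: CitationDataset, panelist) -> list[ReplicatePairCounts]:
    return [pair_counts(dataset, panelist, p) for p in dataset.product_ids]


def index_R(counts: Sequence[ReplicatePairCounts]) -> float:
    """Mean Dice agreement 2 n11 / (n1. + n.1) over products.

    Products with both replicate sets empty are excluded with a warning;
    raises :class:`DegenerateDataError` if all products are degenerate.
    """
    terms = []
    skipped = 0
    for c in counts:
        denom = c.n1_ + c.n_1
        if denom == 0:
            skipped += 1
            continue
        terms.append(2 * c.n11 / denom)
    if skipped:
        warnings.warn(
            f"index R: excluded {skipped} product(s) with empty replicate sets",
            CatapanelWarning,
        )
    if not terms:
        raise DegenerateDataError("index R undefined: all products degenerate")
    return float(np.mean(terms))


def index_p11(counts: Sequence[ReplicatePairCounts]) -> float:
    """Mean re-citation probability n11 / n1. over products (n1. > 0)."""
    terms = []
    skipped = 0
    for c in counts:
        if c.n1_ == 0:
            skipped += 1
            continue
        terms.append(c.n11 / c.n1_)
    if skipped:
        warnings.warn(
            f"index p11: excluded {skipped} product(s) with empty first replicate",
            CatapanelWarning,
        )
    if not terms:
        raise DegenerateDataError("index p11 undefined: all products degenerate")
    return float(np.mean(terms))


def _chi2_2x2(c: ReplicatePairCounts) -> Optional[float]:
    denom = c.n1_ * c.n0_ * c.n_1 * c.n_0
    if denom == 0:
        return None
    return c.A * (c.n11 * c.n00 - c.n10 * c.n01) ** 2 / denom


def index_chi2(counts: Sequence[ReplicatePairCounts]) -> float:
    """Mean uncorrected Pearson chi-square of the per-product 2x2 tables."""
    terms = []
    skipped = 0
    for c in counts:
        value = _chi2_2x2(c)
        if value is None:
            skipped += 1
            continue
        terms.append(value)
    if skipped:
        warnings.warn(
            f"index chi2: excluded {skipped} product(s) with a zero margin",
            CatapanelWarning,
        )
    if not terms:
        raise DegenerateDataError("index chi2 undefined: all products degenerate")
    return float(np.mean(terms))


def per_product_index_values(dataset: CitationDataset) -> dict[str, pd.DataFrame]:
    """Panelist x product matrices of the three single-product index values.

    Vectorized over the whole design; degenerate cells are NaN.  This is the
    common kernel behind both the per-panelist and the per-product averages.
    """
    if dataset.n_replicates != 2:
        raise DegenerateDataError(
            f"reproducibility indices need exactly 2 replicates, got {dataset.n_replicates}"
        )
    r1 = dataset.indicators[:, :, 0, :].astype(np.int64)
    r2 = dataset.indicators[:, :, 1, :].astype(np.int64)
    n11 = (r1 & r2).sum(axis=2)
    n10 = (r1 & ~r2 & 1).sum(axis=2)
    n01 = (~r1 & 1 & r2).sum(axis=2)
    A = dataset.n_attributes
    n00 = A - n11 - n10 - n01
    n1_, n_1 = n11 + n10, n11 + n01
    n0_, n_0 = A - n1_, A - n_1

    with np.errstate(divide="ignore", invalid="ignore"):
        r_val = np.where(n1_ + n_1 > 0, 2 * n11 / np.maximum(n1_ + n_1, 1), np.nan)
        p11_val = np.where(n1_ > 0, n11 / np.maximum(n1_, 1), np.nan)
        denom = n1_ * n0_ * n_1 * n_0
        chi2_val = np.where(
            denom > 0,
            A * (n11 * n00 - n10 * n01) ** 2 / np.maximum(denom, 1),
            np.nan,
        )
    idx = list(dataset.panelist_ids)
    cols = list(dataset.product_ids)
    return {
        "chi2": pd.DataFrame(chi2_val, index=idx, columns=cols),
        "R": pd.DataFrame(r_val, index=idx, columns=cols),
        "p11": pd.DataFrame(p11_val, index=idx, columns=cols),
    }


def reproducibility_indices(dataset: CitationDataset) -> pd.DataFrame:
    """Per-panelist index table: columns chi2, R, p11 and products used per index."""
    values = per_product_index_values(dataset)
    out = pd.DataFrame(index=list(dataset.panelist_ids))
    out.index.name = "panelist"
    for name, mat in values.items():
        used = mat.notna().sum(axis=1)
        if (used == 0).any():
            bad = list(out.index[used == 0])
            raise DegenerateDataError(
                f"index {name} undefined for panelists {bad}: all products degenerate"
            )
        if (used < dataset.n_products).any():
            warnings.warn(
                f"index {name}: degenerate products excluded for some panelists",
                CatapanelWarning,
            )
        out[name] = [
            float(np.mean(mat.loc[j].dropna().to_numpy())) for j in out.index
        ]
        out[f"n_products_{name}"] = used
    return out[["chi2", "R", "p11", "n_products_chi2", "n_products_R", "n_products_p11"]]


def summarize_indices(indices: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Descriptive summary of the index table.

    Returns ``describe`` (mean, sample std, min, max, first quartile per
    index), ``correlations`` (Pearson, NaN where an index is constant) and
    ``normality`` (Shapiro-Wilk p-value per index; omitted with a warning
    below 3 panelists).
    """
    cols = ["chi2", "R", "p11"]
    data = indices[cols]
    describe = pd.DataFrame(
        {
            "Mean": data.mean(),
            "Std": data.std(ddof=1),
            "Min": data.min(),
            "Max": data.max(),
            "First quartile": data.quantile(0.25),
        }
    ).T
    correlations = data.corr(method="pearson")
    if len(data) >= 3:
        normality = pd.DataFrame(
            {c: [stats.shapiro(data[c]).pvalue] if data[c].nunique() > 1 else [np.nan] for c in cols},
            index=["shapiro_p"],
        )
    else:
        warnings.warn("fewer than 3 panelists: normality test omitted", CatapanelWarning)
        normality = pd.DataFrame({c: [np.nan] for c in cols}, index=["shapiro_p"])
    return {"describe": describe, "correlations": correlations, "normality": normality}


@dataclass(frozen=True)
class ExclusionReport:
    """Outcome of iterative outlier-based panelist screening."""

    excluded: tuple
    retained: tuple
    rounds: tuple  # one dict per round: {"tests": {(index, test): TestResult}, "removed": id|None}
    alpha: float

    def to_dict(self) -> dict:
        rounds = []
        for rnd in self.rounds:
            rounds.append(
                {
                    "removed": rnd["removed"],
                    "tests": {
                        f"{index}:{test}": {
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "method": res.method,
                        }
                        for (index, test), res in rnd["tests"].items()
                    },
                }
            )
        return {
            "alpha": self.alpha,
            "excluded": list(self.excluded),
            "retained": list(self.retained),
            "rounds": rounds,
        }


def _run_tests(indices: pd.DataFrame, screen_indices, tests) -> dict:
    out = {}
    for index_name in screen_indices:
        values = indices[index_name].to_numpy()
        for test in tests:
            try:
                out[(index_name, test)] = _TEST_FUNCS[test](values, alternative="min")
            except DegenerateDataError:
                out[(index_name, test)] = TestResult(
                    np.nan if np.isnan(values).any() else 0.0, 1.0, test, "min"
                )
    return out


def screen_panelists(
    indices: pd.DataFrame,
    alpha: float = 0.05,
    max_removals: int = 2,
    screen_indices: Sequence[str] = ("R", "p11"),
    decision_tests: Sequence[str] = ("grubbs", "dixon"),
    simultaneous: bool = False,
) -> ExclusionReport:
    """Iteratively remove low-reproducibility outlier panelists.

    Each round runs the Grubbs, Dixon and chi-square outlier tests on the
    lower tail of every index in ``screen_indices``.  All results are
    reported, but removal is triggered only when *every* test in
    ``decision_tests`` is significant at ``alpha`` on the same index
    (default: Grubbs and Dixon must agree).  The chi-square criterion is
    excluded from the default decision battery because it is
    anticonservative for sample extremes (see :mod:`catapanel.outliers`);
    requiring agreement of the two calibrated tests keeps the false-removal
    rate of the whole multi-index screen near the nominal level while a
    genuinely unreliable panelist is flagged by both tests essentially
    always.  While the trigger fires and fewer than ``max_removals``
    panelists have been removed, the panelist with the lowest R (ties:
    lowest p11) is dropped and the tests re-run.  With ``simultaneous=True``
    every panelist flagged as the current extreme of a triggering index is
    removed in one go.
    """
    if len(indices) < 4:
        raise ValueError("screening needs at least 4 panelists")
    if max_removals >= len(indices):
        raise ValueError("max_removals would empty the panel")
    unknown = set(decision_tests) - set(_ALL_TESTS)
    if unknown:
        raise ValueError(f"unknown decision tests: {sorted(unknown)}")

    current = indices.copy()
    excluded: list = []
    rounds: list[dict] = []
    while True:
        tests = _run_tests(current, screen_indices, _ALL_TESTS)
        flagged_indices = [
            i
            for i in screen_indices
            if all(tests[(i, t)].p_value < alpha for t in decision_tests)
        ]
        significant = bool(flagged_indices)
        if not significant or len(excluded) >= max_removals:
            rounds.append({"tests": tests, "removed": None})
            break
        if len(current) - 1 < 3:
            raise ValueError("removal would leave fewer than 3 panelists")
        order = current.sort_values(["R", "p11"], kind="mergesort")
        if simultaneous:
            # remove the current extreme of every index with a significant test
            budget = max_removals - len(excluded)
            flagged = dict.fromkeys(current[i].idxmin() for i in flagged_indices)
            victims = [v for v in order.index if v in flagged][:budget]
        else:
            victims = [order.index[0]]
        for victim in victims:
            excluded.append(victim)
        rounds.append({"tests": tests, "removed": victims[0] if len(victims) == 1 else list(victims)})
        current = current.drop(index=victims)
    return ExclusionReport(
        tuple(excluded), tuple(current.index), tuple(rounds), alpha
    )
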