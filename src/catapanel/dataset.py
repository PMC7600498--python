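"""Canonical data model and file I/O for replicated binary citation data.

A check-all-that-apply (CATA) evaluation is one panelist smelling/tasting one
product once (one replicate) and ticking every descriptor that applies.  The
canonical container is a dense 4-way binary array indexed by
(panelist, product, replicate, attribute); replicated designs are small
(a typical trained-panel study is ~23 x 17 x 2 x 25 cells) so density costs
nothing and makes every downstream cross-tabulation a reduction.

Two on-disk dialects are supported, both plain CSV:

* ``long``  — header ``panelist,product,replicate,attribute,cited`` with
  ``cited`` in {0, 1}; rows absent for an evaluation that appears at least
  once are read as 0.
* ``wide``  — header ``panelist,product,replicate,<attr1>,...,<attrK>``,
  one row per evaluation, binary cells.

Identifier order is the order of first appearance in the input and is
preserved in every output, so tables are reproducible.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CitationDataset",
    "FrequencyTable",
    "ValidationReport",
    "CatapanelError",
    "ParseError",
    "ConflictError",
    "CompletenessError",
    "DegenerateDataError",
    "CatapanelWarning",
    "read_citations",
    "write_citations",
    "validate_protocol",
    "frequency_table",
]


class CatapanelError(Exception):
    """Base class for all package errors."""


class ParseError(CatapanelError):
    """A file could not be parsed in the declared dialect."""


class ConflictError(CatapanelError):
    """The same (panelist, product, replicate, attribute) key carries both 0 and 1."""


class CompletenessError(CatapanelError):
    """The design is incomplete: some (panelist, product, replicate) cell is missing."""


class DegenerateDataError(CatapanelError):
    """An operation is undefined on the given (degenerate) data."""


class CatapanelWarning(UserWarning):
    """Advisory condition (degenerate cells skipped, zero-mass rows dropped...)."""


def _unique_in_order(values: Iterable) -> list:
    return list(dict.fromkeys(values))


@dataclass(frozen=True)
class CitationDataset:
    """Complete replicated binary citation data.

    Parameters
    ----------
    panelist_ids, product_ids, replicate_ids, attribute_ids
        Ordered unique labels for each axis.
    indicators
        Binary ``uint8`` array of shape ``(n_panelists, n_products,
        n_replicates, n_attributes)``; ``indicators[j, p, r, a] == 1`` iff
        panelist ``j`` cited attribute ``a`` for product ``p`` in replicate
        ``r``.
    """

    panelist_ids: tuple
    product_ids: tuple
    replicate_ids: tuple
    attribute_ids: tuple
    indicators: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "panelist_ids", tuple(self.panelist_ids))
        object.__setattr__(self, "product_ids", tuple(self.product_ids))
        object.__setattr__(self, "replicate_ids", tuple(self.replicate_ids))
        object.__setattr__(self, "attribute_ids", tuple(self.attribute_ids))
        for name in ("panelist_ids", "product_ids", "replicate_ids", "attribute_ids"):
            ids = getattr(self, name)
            if len(ids) == 0:
                raise ValueError(f"{name} must be non-empty")
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} contains duplicate labels")
        arr = np.asarray(self.indicators)
        expected = (
            len(self.panelist_ids),
            len(self.product_ids),
            len(self.replicate_ids),
            len(self.attribute_ids),
        )
        if arr.shape != expected:
            raise ValueError(f"indicators shape {arr.shape} != {expected}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("indicators must be binary (0/1)")
        object.__setattr__(self, "indicators", arr.astype(np.uint8))
        self.indicators.setflags(write=False)

    # -- shape helpers -------------------------------------------------
    @property
    def n_panelists(self) -> int:
        return len(self.panelist_ids)

    @property
    def n_products(self) -> int:
        return len(self.product_ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    @property
    def n_attributes(self) -> int:
        return len(self.attribute_ids)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CitationDataset):
            return NotImplemented
        return (
            self.panelist_ids == other.panelist_ids
            and self.product_ids == other.product_ids
            and self.replicate_ids == other.replicate_ids
            and self.attribute_ids == other.attribute_ids
            and np.array_equal(self.indicators, other.indicators)
        )

    def citation_counts(self) -> np.ndarray:
        """Number of cited attributes per evaluation, shape (J, P, R)."""
        return self.indicators.sum(axis=3)

    def to_long_frame(self) -> pd.DataFrame:
        """All cells as a long DataFrame with columns panelist/product/replicate/attribute/cited."""
        j, p, r, a = np.meshgrid(
            np.arange(self.n_panelists),
            np.arange(self.n_products),
            np.arange(self.n_replicates),
            np.arange(self.n_attributes),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "panelist": np.asarray(self.panelist_ids, dtype=object)[j.ravel()],
                "product": np.asarray(self.product_ids, dtype=object)[p.ravel()],
                "replicate": np.asarray(self.replicate_ids, dtype=object)[r.ravel()],
                "attribute": np.asarray(self.attribute_ids, dtype=object)[a.ravel()],
                "cited": self.indicators.ravel().astype(int),
            }
        )

    def subset_panelists(self, keep: Sequence) -> "CitationDataset":
        """Dataset restricted to the given panelists (order preserved from ``keep``)."""
        missing = [k for k in keep if k not in self.panelist_ids]
        if missing:
            raise KeyError(f"unknown panelists: {missing}")
        idx = [self.panelist_ids.index(k) for k in keep]
        return CitationDataset(
            tuple(keep),
            self.product_ids,
            self.replicate_ids,
            self.attribute_ids,
            self.indicators[idx],
        )


@dataclass(frozen=True)
class FrequencyTable:
    """Citation counts per product (optionally per replicate) and attribute.

    ``counts`` is a DataFrame whose rows are products (``averaged`` mode) or a
    (product, replicate) MultiIndex (``per_replicate`` mode) and whose columns
    are attributes.  ``denominators`` gives the number of evaluations behind
    each row; ``proportions`` = counts / denominators row-wise.
    """

    counts: pd.DataFrame
    denominators: pd.Series

    def __post_init__(self):
        c = self.counts.to_numpy(dtype=float)
        d = self.denominators.to_numpy(dtype=float)
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if (c > d[:, None] + 1e-9).any():
            raise ValueError("counts exceed denominators")

    @property
    def product_ids(self) -> tuple:
        idx = self.counts.index
        if isinstance(idx, pd.MultiIndex):
            return tuple(_unique_in_order(idx.get_level_values(0)))
        return tuple(idx)

    @property
    def attribute_ids(self) -> tuple:
        return tuple(self.counts.columns)

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts.div(self.denominators, axis=0)

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of protocol validation; ``is_valid`` iff no violations."""

    violations: tuple

    @property
    def is_valid(self) -> bool:
        return len(self.violations) == 0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["panelist", "product", "replicate", "attribute", "cited"]
_WIDE_KEY = ["panelist", "product", "replicate"]

Dialect = Literal["long", "wide"]


def _check_complete(frame: pd.DataFrame, panelists, products, replicates, path):
    have = set(map(tuple, frame[_WIDE_KEY].itertuples(index=False)))
    missing = [
        (j, p, r)
        for j in panelists
        for p in products
        for r in replicates
        if (j, p, r) not in have
    ]
    if missing:
        raise CompletenessError(
            f"{path}: incomplete design, missing evaluations: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )


def read_citations(path, dialect: Dialect = "long") -> CitationDataset:
    """Read a CitationDataset from a CSV file in the given dialect.

    Raises
    ------
    ParseError
        Malformed file (wrong header, non-binary cells, missing values).
    ConflictError
        The same key appears with both values 0 and 1.
    CompletenessError
        Some (panelist, product, replicate) evaluation is absent.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if dialect == "long":
        return _read_long(frame, path)
    if dialect == "wide":
        return _read_wide(frame, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_binary(series: pd.Series, path, context: str) -> np.ndarray:
    values = series.to_numpy()
    ok = np.isin(values, ("0", "1"))
    if not ok.all():
        bad = int(np.flatnonzero(~ok)[0])
        raise ParseError(
            f"{path}: non-binary value {values[bad]!r} in {context} (data line {bad + 2})"
        )
    return values.astype(np.uint8)


def _read_long(frame: pd.DataFrame, path) -> CitationDataset:
    if list(frame.columns) != _LONG_COLUMNS:
        raise ParseError(
            f"{path}: expected header {','.join(_LONG_COLUMNS)}, got {','.join(frame.columns)}"
        )
    cited = _parse_binary(frame["cited"], path, "column 'cited'")
    frame = frame.assign(cited=cited)
    conflicts = frame.groupby(
        ["panelist", "product", "replicate", "attribute"], sort=False
    )["cited"].nunique()
    if (conflicts > 1).any():
        key = conflicts[conflicts > 1].index[0]
        raise ConflictError(f"{path}: conflicting duplicate rows for key {key}")
    frame = frame.drop_duplicates(["panelist", "product", "replicate", "attribute"])

    panelists = _unique_in_order(frame["panelist"])
    products = _unique_in_order(frame["product"])
    replicates = _unique_in_order(frame["replicate"])
    attributes = _unique_in_order(frame["attribute"])
    _check_complete(frame, panelists, products, replicates, path)

    arr = np.zeros((len(panelists), len(products), len(replicates), len(attributes)), np.uint8)
    jix = frame["panelist"].map({k: i for i, k in enumerate(panelists)})
    pix = frame["product"].map({k: i for i, k in enumerate(products)})
    rix = frame["replicate"].map({k: i for i, k in enumerate(replicates)})
    aix = frame["attribute"].map({k: i for i, k in enumerate(attributes)})
    arr[jix, pix, rix, aix] = frame["cited"]
    return CitationDataset(panelists, products, replicates, attributes, arr)


def _read_wide(frame: pd.DataFrame, path) -> CitationDataset:
    if list(frame.columns[:3]) != _WIDE_KEY or frame.shape[1] < 4:
        raise ParseError(
            f"{path}: expected header panelist,product,replicate,<attributes...>"
        )
    attributes = list(frame.columns[3:])
    dup = frame.duplicated(_WIDE_KEY, keep=False)
    if dup.any():
        sub = frame[dup]
        if sub.duplicated(keep=False).all():
            frame = frame.drop_duplicates()
        else:
            key = tuple(sub.iloc[0][_WIDE_KEY])
            raise ConflictError(f"{path}: conflicting duplicate rows for evaluation {key}")
    data = np.column_stack(
        [_parse_binary(frame[a], path, f"column {a!r}") for a in attributes]
    )
    panelists = _unique_in_order(frame["panelist"])
    products = _unique_in_order(frame["product"])
    replicates = _unique_in_order(frame["replicate"])
    _check_complete(frame, panelists, products, replicates, path)
    arr = np.zeros((len(panelists), len(products), len(replicates), len(attributes)), np.uint8)
    jix = frame["panelist"].map({k: i for i, k in enumerate(panelists)})
    pix = frame["product"].map({k: i for i, k in enumerate(products)})
    rix = frame["replicate"].map({k: i for i, k in enumerate(replicates)})
    arr[jix, pix, rix, :] = data
    return CitationDataset(panelists, products, replicates, attributes, arr)


def write_citations(dataset: CitationDataset, path, dialect: Dialect = "long") -> None:
    """Write ``dataset`` so that :func:`read_citations` round-trips it exactly."""
    path = Path(path)
    if dialect == "long":
        dataset.to_long_frame().to_csv(path, index=False)
    elif dialect == "wide":
        j, p, r = np.meshgrid(
            np.arange(dataset.n_panelists),
            np.arange(dataset.n_products),
            np.arange(dataset.n_replicates),
            indexing="ij",
        )
        frame = pd.DataFrame(
            {
                "panelist": np.asarray(dataset.panelist_ids, dtype=object)[j.ravel()],
                "product": np.asarray(dataset.product_ids, dtype=object)[p.ravel()],
                "replicate": np.asarray(dataset.replicate_ids, dtype=object)[r.ravel()],
            }
        )
        block = dataset.indicators.reshape(-1, dataset.n_attributes).astype(int)
        for k, a in enumerate(dataset.attribute_ids):
            frame[a] = block[:, k]
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Protocol validation and frequency tables
# ---------------------------------------------------------------------------


def validate_protocol(
    dataset: CitationDataset, min_citations: int = 2, max_citations: int = 5
) -> ValidationReport:
    """Flag evaluations whose citation count falls outside the protocol bounds.

    The evaluation protocol asks panelists to tick between ``min_citations``
    and ``max_citations`` descriptors (2–5 by default).  Violations are
    advisory: downstream operations accept flagged data, and degenerate
    zero-citation evaluations are simply excluded from per-panelist index
    averages with a warning.
    """
    if min_citations > max_citations:
        raise ValueError("min_citations must be <= max_citations")
    counts = dataset.citation_counts()
    violations = []
    for j, jp in enumerate(dataset.panelist_ids):
        for p, pp in enumerate(dataset.product_ids):
            for r, rr in enumerate(dataset.replicate_ids):
                c = int(counts[j, p, r])
                if c < min_citations:
                    violations.append(
                        (jp, pp, rr, "below_min_citations", f"cited {c} < {min_citations}")
                    )
                elif c > max_citations:
                    violations.append(
                        (jp, pp, rr, "above_max_citations", f"cited {c} > {max_citations}")
                    )
    return ValidationReport(tuple(violations))


def frequency_table(
    dataset: CitationDataset, mode: Literal["per_replicate", "averaged"] = "averaged"
) -> FrequencyTable:
    """Citation-frequency contingency table.

    ``averaged`` sums citations over panelists and replicates and divides by
    the number of replicates, i.e. the mean citation count per replicate; the
    denominator is the number of panelists, so proportions are the fraction of
    evaluations citing the attribute.  ``per_replicate`` keeps replicates as
    separate rows.
    """
    ind = dataset.indicators
    if mode == "averaged":
        counts = ind.sum(axis=(0, 2)) / dataset.n_replicates
        frame = pd.DataFrame(
            counts, index=list(dataset.product_ids), columns=list(dataset.attribute_ids)
        )
        frame.index.name = "product"
        denom = pd.Series(float(dataset.n_panelists), index=frame.index)
        return FrequencyTable(frame, denom)
    if mode == "per_replicate":
        counts = ind.sum(axis=0)  # (P, R, A)
        rows = pd.MultiIndex.from_product(
            [list(dataset.product_ids), list(dataset.replicate_ids)],
            names=["product", "replicate"],
        )
        frame = pd.DataFrame(
            counts.reshape(-1, dataset.n_attributes),
            index=rows,
            columns=list(dataset.attribute_ids),
        )
        denom = pd.Series(float(dataset.n_panelists), index=frame.index)
        return FrequencyTable(frame, denom)
    raise ValueError(f"unknown mode {mode!r}")
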