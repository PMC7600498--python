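"""Product characterization: citation ranking, correspondence analysis,
consensus cluster-count selection and cluster odor profiles.

Correspondence analysis (CA) decomposes a non-negative contingency table
``N`` through the SVD of its standardized residuals.  With correspondence
matrix ``P = N / n`` (``n`` the grand total), row masses ``r`` and column
masses ``c``, the residual matrix is

    S_ij = (P_ij - r_i c_j) / sqrt(r_i c_j),    S = U Sigma V'.

Principal coordinates are ``F = diag(1/sqrt(r)) U Sigma`` for rows and
``G = diag(1/sqrt(c)) V Sigma`` for columns; the squared singular values are
the principal inertias, summing to the total inertia chi^2 / n.  The
symmetric map plots rows and columns both in principal coordinates.  SVD
sign indeterminacy is resolved by making the largest-magnitude row
coordinate on each dimension positive.

The consensus cluster count mirrors the vote-over-combinations idea of the
NbClust approach: every (distance measure, clustering method) pair — k-means
restricted to Euclidean — is fitted for each candidate k, scored by a
battery of validity indices (silhouette, Calinski-Harabasz, Dunn), each
index casts one vote for its best k, and the modal k wins (ties: smallest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .dataset import CatapanelWarning, DegenerateDataError, FrequencyTable

__all__ = [
    "CAResult",
    "ClusterVote",
    "ClusterProfile",
    "top_descriptors",
    "select_ca_attributes",
    "correspondence_analysis",
    "ca_cell_contributions",
    "consensus_cluster_count",
    "cluster_products",
    "cluster_profile",
    "spider_data",
]

DISTANCES = ("euclidean", "manhattan", "maximum", "canberra", "minkowski")
METHODS = ("kmeans", "ward.D", "ward.D2", "single", "complete", "average")
VALIDITY_INDICES = ("silhouette", "calinski", "dunn")

_SCIPY_METRIC = {
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "maximum": "chebyshev",
    "canberra": "canberra",
    "minkowski": "minkowski",
}


# ---------------------------------------------------------------------------
# descriptor ranking
# ---------------------------------------------------------------------------


def top_descriptors(freq: FrequencyTable, k: int = 6) -> dict:
    """The k most-cited attributes per product, with citation proportions.

    Zero-proportion attributes are never listed; ties at rank k are broken
    alphabetically on the attribute label.
    """
    props = freq.proportions
    if k > props.shape[1]:
        raise ValueError(f"k={k} exceeds the {props.shape[1]} attributes")
    out = {}
    for product, row in props.iterrows():
        ranked = sorted(row.items(), key=lambda item: (-item[1], item[0]))
        out[product] = [(a, float(v)) for a, v in ranked[:k] if v > 0]
    return out


def select_ca_attributes(
    freq: FrequencyTable,
    top_n: int = 3,
    include: Sequence[str] = (),
    exclude: Sequence[str] = (),
) -> list:
    """Attribute subset for the CA table.

    Union over products of each product's ``top_n`` most-cited attributes,
    plus ``include``, minus ``exclude``; ordered by overall citation rank.
    The ``include`` list is the hook for descriptors that are cited many
    times overall without entering any product's top ``top_n`` (an earthy
    note like Mushroom often behaves this way) and should still appear on
    the map.
    """
    attributes = set(freq.attribute_ids)
    for label in list(include) + list(exclude):
        if label not in attributes:
            raise ValueError(f"unknown attribute label {label!r}")
    chosen = set(include)
    for _, entries in top_descriptors(freq, k=top_n).items():
        chosen.update(a for a, _ in entries)
    chosen -= set(exclude)
    totals = freq.counts.sum(axis=0)
    return sorted(chosen, key=lambda a: (-totals[a], a))


# ---------------------------------------------------------------------------
# correspondence analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CAResult:
    """Correspondence-analysis decomposition of a contingency table."""

    row_labels: tuple
    col_labels: tuple
    row_masses: np.ndarray
    col_masses: np.ndarray
    correspondence: np.ndarray  # P = table / total
    standardized_residuals: np.ndarray
    eigenvalues: np.ndarray  # principal inertias, non-increasing
    explained_inertia: np.ndarray  # percentages summing to 100 (or 0 if degenerate)
    row_coordinates: np.ndarray  # principal coordinates
    col_coordinates: np.ndarray
    total_inertia: float
    chi2: float
    chi2_p: float
    table_total: float

    @property
    def n_dimensions(self) -> int:
        return len(self.eigenvalues)

    def row_frame(self) -> pd.DataFrame:
        cols = [f"Dim{i + 1}" for i in range(self.n_dimensions)]
        return pd.DataFrame(self.row_coordinates, index=list(self.row_labels), columns=cols)

    def col_frame(self) -> pd.DataFrame:
        cols = [f"Dim{i + 1}" for i in range(self.n_dimensions)]
        return pd.DataFrame(self.col_coordinates, index=list(self.col_labels), columns=cols)


def correspondence_analysis(table: pd.DataFrame) -> CAResult:
    """CA of a non-negative product x attribute (or any contingency) table.

    All-zero rows or columns are dropped with a warning.  The chi-square
    test of independence of the (cleaned) table is computed without
    continuity correction; the sum of the principal inertias equals
    chi^2 / n exactly.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table, dtype=float))
    N = table.to_numpy(dtype=float)
    if (N < 0).any():
        raise ValueError("contingency table must be non-negative")
    keep_r = N.sum(axis=1) > 0
    keep_c = N.sum(axis=0) > 0
    if not (keep_r.all() and keep_c.all()):
        warnings.warn("dropped all-zero rows/columns from the CA table", CatapanelWarning)
        table = table.loc[table.index[keep_r], table.columns[keep_c]]
        N = table.to_numpy(dtype=float)
    if N.shape[0] < 2 or N.shape[1] < 2:
        raise DegenerateDataError("CA needs at least a 2x2 table after cleaning")

    n = N.sum()
    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)
    K = min(N.shape) - 1
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    U, sv, Vt = U[:, :K], sv[:K], Vt[:K]

    F = (U * sv) / np.sqrt(r)[:, None]
    G = (Vt.T * sv) / np.sqrt(c)[:, None]
    # sign convention: largest-|.| row coordinate positive per dimension
    for d in range(K):
        i = np.argmax(np.abs(F[:, d]))
        if F[i, d] < 0:
            F[:, d] *= -1
            G[:, d] *= -1
            U[:, d] *= -1
            Vt[d] *= -1

    eigenvalues = sv**2
    total_inertia = float((S**2).sum())
    chi2 = total_inertia * n
    dof = (N.shape[0] - 1) * (N.shape[1] - 1)
    chi2_p = float(stats.chi2.sf(chi2, df=dof))
    if total_inertia > 1e-12:
        explained = 100.0 * eigenvalues / eigenvalues.sum()
    else:
        warnings.warn("table is exactly independent: zero inertia", CatapanelWarning)
        explained = np.zeros(K)
    return CAResult(
        tuple(table.index),
        tuple(table.columns),
        r,
        c,
        P,
        S,
        eigenvalues,
        explained,
        F,
        G,
        total_inertia,
        float(chi2),
        chi2_p,
        float(n),
    )


def ca_cell_contributions(ca: CAResult) -> pd.DataFrame:
    """Percent contribution of every cell to the total inertia (sums to 100)."""
    if ca.total_inertia <= 1e-12:
        warnings.warn("zero total inertia: all contributions are 0", CatapanelWarning)
        contrib = np.zeros_like(ca.standardized_residuals)
    else:
        contrib = 100.0 * ca.standardized_residuals**2 / ca.total_inertia
    return pd.DataFrame(contrib, index=list(ca.row_labels), columns=list(ca.col_labels))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _condensed(points: np.ndarray, distance: str, minkowski_p: float) -> np.ndarray:
    metric = _SCIPY_METRIC[distance]
    if metric == "minkowski":
        return pdist(points, metric=metric, p=minkowski_p)
    return pdist(points, metric=metric)


def _hier_labels(condensed: np.ndarray, method: str, k: int) -> np.ndarray:
    if method == "ward.D":
        # R's ward.D applies the Ward update to raw distances; feeding the
        # square roots to scipy's ward (which squares internally) matches it.
        Z = linkage(np.sqrt(condensed), method="ward")
    elif method == "ward.D2":
        Z = linkage(condensed, method="ward")
    else:
        Z = linkage(condensed, method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def _dunn(square: np.ndarray, labels: np.ndarray) -> float:
    unique = np.unique(labels)
    intra = 0.0
    for u in unique:
        members = labels == u
        if members.sum() > 1:
            intra = max(intra, square[np.ix_(members, members)].max())
    inter = np.inf
    for i, u in enumerate(unique):
        for v in unique[i + 1 :]:
            inter = min(inter, square[np.ix_(labels == u, labels == v)].min())
    if intra == 0:
        return np.inf if inter > 0 else 0.0
    return inter / intra


def choose_modal_k(tally: dict) -> int:
    """Modal cluster count from a vote tally; ties resolved toward smallest k."""
    if not tally:
        raise ValueError("empty vote tally")
    max_votes = max(tally.values())
    return min(k for k, v in tally.items() if v == max_votes)


@dataclass(frozen=True)
class ClusterVote:
    """Vote tally of the consensus cluster-count selection."""

    votes: pd.DataFrame  # rows = (distance, method, index), column "best_k"
    tally: dict  # k -> number of votes
    chosen_k: int


def consensus_cluster_count(
    points,
    kmin: int = 2,
    kmax: int = 10,
    distances: Sequence[str] = DISTANCES,
    methods: Sequence[str] = METHODS,
    indices: Sequence[str] = VALIDITY_INDICES,
    seed: Optional[int] = None,
    minkowski_p: float = 2.0,
) -> ClusterVote:
    """Choose the cluster count proposed by the most (distance, method, index) votes.

    k-means is paired only with the Euclidean distance; hierarchical methods
    accept all five distance measures.  For every combination and every k in
    [kmin, kmax], the partition is scored by each validity index; each index
    votes for its best k (ties: smallest).  The chosen k is the modal vote,
    ties again resolved toward the smallest k.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be a 2-D coordinate matrix")
    n = X.shape[0]
    if kmax >= n:
        raise ValueError(f"kmax={kmax} must be < number of points ({n})")
    if kmin < 2:
        raise ValueError("kmin must be >= 2")
    for d in distances:
        if d not in DISTANCES:
            raise ValueError(f"unknown distance {d!r}")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")

    rng_seed = 0 if seed is None else int(seed)
    records = []
    ks = list(range(kmin, kmax + 1))
    for method in methods:
        method_distances = ("euclidean",) if method == "kmeans" else distances
        for distance in method_distances:
            if distance not in distances:
                continue
            cd = _condensed(X, distance, minkowski_p)
            sq = squareform(cd)
            labelings = {}
            for k in ks:
                if method == "kmeans":
                    km = KMeans(n_clusters=k, n_init=10, random_state=rng_seed)
                    labelings[k] = km.fit_predict(X)
                else:
                    labelings[k] = _hier_labels(cd, method, k)
            for index in indices:
                best_k, best_score = None, -np.inf
                for k in ks:
                    labels = labelings[k]
                    if len(np.unique(labels)) < 2:
                        continue
                    if index == "silhouette":
                        score = silhouette_score(sq, labels, metric="precomputed")
                    elif index == "calinski":
                        score = calinski_harabasz_score(X, labels)
                    elif index == "dunn":
                        score = _dunn(sq, labels)
                    else:
                        raise ValueError(f"unknown validity index {index!r}")
                    if score > best_score:
                        best_k, best_score = k, score
                if best_k is not None:
                    records.append(
                        {"distance": distance, "method": method, "index": index, "best_k": best_k}
                    )
    votes = pd.DataFrame.from_records(records)
    tally_series = votes["best_k"].value_counts()
    tally = {int(k): int(v) for k, v in tally_series.items()}
    return ClusterVote(votes, tally, choose_modal_k(tally))


def cluster_products(
    points, k: int, method: str = "ward.D2", seed: Optional[int] = None
) -> np.ndarray:
    """Cluster coordinate rows into k groups; returns labels 1..k.

    Default is Ward linkage on Euclidean distances; ``seed`` only affects
    k-means.  Labels are renumbered by first appearance so they are
    deterministic for hierarchical methods and, given a seed, for k-means.
    """
    X = np.asarray(points, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of points")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=0 if seed is None else int(seed))
        raw = km.fit_predict(X)
    elif method in METHODS:
        raw = _hier_labels(_condensed(X, "euclidean", 2.0), method, k)
    else:
        raise ValueError(f"unknown method {method!r}")
    # renumber by first appearance -> stable 1-based labels
    mapping = {}
    labels = np.empty(len(raw), dtype=int)
    for i, value in enumerate(raw):
        if value not in mapping:
            mapping[value] = len(mapping) + 1
        labels[i] = mapping[value]
    return labels


# ---------------------------------------------------------------------------
# cluster profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterProfile:
    """Descriptor x cluster citation profile with Pearson residuals."""

    counts: pd.DataFrame  # attributes x clusters
    residuals: pd.DataFrame  # (observed - expected) / sqrt(expected)
    chi2: float
    chi2_p: float
    proportions: pd.DataFrame  # clusters x attributes, mean citation proportions


def _labels_by_product(freq: FrequencyTable, labels) -> pd.Series:
    products = list(freq.counts.index)
    labels = np.asarray(labels)
    if len(labels) != len(products):
        raise ValueError("labels must cover every product in the frequency table")
    return pd.Series(labels, index=products)


def cluster_profile(
    freq: FrequencyTable, labels, attributes: Optional[Sequence[str]] = None
) -> ClusterProfile:
    """Descriptor x cluster contingency table, residuals and spider data.

    Counts are citation counts summed over the member products of each
    cluster, restricted to ``attributes`` (default: all).  Pearson residuals
    are (observed - expected)/sqrt(expected) with expected from the row and
    column margins; the chi-square p-value tests independence of descriptor
    and cluster.
    """
    by_product = _labels_by_product(freq, labels)
    unique = sorted(pd.unique(by_product))
    for u in unique:
        if not (by_product == u).any():  # pragma: no cover - defensive
            raise ValueError(f"empty cluster {u}")
    attrs = list(attributes) if attributes is not None else list(freq.attribute_ids)
    unknown = set(attrs) - set(freq.attribute_ids)
    if unknown:
        raise ValueError(f"unknown attributes: {sorted(unknown)}")
    counts = pd.DataFrame(
        {
            f"Cluster {u}": freq.counts.loc[by_product[by_product == u].index, attrs].sum()
            for u in unique
        }
    )
    observed = counts.to_numpy(dtype=float)
    if observed.sum() == 0:
        raise DegenerateDataError("cluster profile undefined: no citations")
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / observed.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        residuals = np.where(expected > 0, (observed - expected) / np.sqrt(expected), 0.0)
    chi2 = float((residuals**2).sum())
    dof = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    chi2_p = float(stats.chi2.sf(chi2, df=dof))
    residual_frame = pd.DataFrame(residuals, index=counts.index, columns=counts.columns)
    props = spider_data(freq, labels)
    return ClusterProfile(counts, residual_frame, chi2, chi2_p, props)


def spider_data(freq: FrequencyTable, labels) -> pd.DataFrame:
    """Cluster x attribute mean citation proportions (spider-diagram data).

    The unweighted mean over member products of each product's citation
    proportion; every cluster must be non-empty.
    """
    by_product = _labels_by_product(freq, labels)
    props = freq.proportions
    rows = {}
    for u in sorted(pd.unique(by_product)):
        members = by_product[by_product == u].index
        if len(members) == 0:  # pragma: no cover - defensive
            raise ValueError(f"empty cluster {u}")
        rows[f"Cluster {u}"] = props.loc[members].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "cluster"
    return out
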