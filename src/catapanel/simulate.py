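"""Synthetic replicated CATA panels with known ground truth.

The generator emulates the structure a trained-panel citation study assumes:

* latent product *citation-propensity* profiles ``theta[p, a]`` in (0, 1),
  optionally organised into product clusters with disjoint signature
  attribute subsets;
* a per-panelist *reliability* ``rho[j]``: the probability of re-keeping, in
  replicate 2, a descriptor ticked in replicate 1 (this maps directly onto
  the p11 reproducibility index);
* a per-panelist *discrimination* exponent ``lambda[j]``: replicate-1 choices
  are drawn with probability proportional to ``theta[p, ·] ** lambda[j]``,
  so large lambda sharpens attribute preference and lambda = 0 makes a
  panelist pick uniformly at random;
* the protocol constraint that each evaluation ticks between
  ``min_citations`` and ``max_citations`` descriptors (2–5 by default).

Replicate 2 uses a *keep-then-refill* mechanism: each replicate-1 choice is
independently kept with probability ``rho[j]``; a fresh citation count ``m2``
is drawn; if more attributes were kept than ``m2`` a uniform random subset of
size ``m2`` is retained, otherwise the remaining slots are filled by the same
weighted sampling over the not-yet-chosen attributes.

The exact draw order is fixed so output is bit-stable under a seed: for each
panelist (outer) and product (inner): replicate-1 count, replicate-1
sequential weighted picks, one keep-uniform per replicate-1 choice in
ascending attribute order, replicate-2 count, then either the subset draw or
the sequential refill picks.  Weighted sampling without replacement is
sequential with renormalization (draw one index from the normalized weights,
zero its weight, repeat).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataset import CitationDataset

__all__ = ["PanelSimConfig", "SimTruth", "make_profiles", "simulate_panel"]

# Study-scale defaults: 23 panelists x 17 products x 2 replicates x
# 25 descriptors, 2-5 citations per evaluation, 4 latent product clusters.
_DEFAULT_N_PANELISTS = 23
_DEFAULT_N_PRODUCTS = 17
_DEFAULT_N_ATTRIBUTES = 25
_DEFAULT_RHO = 0.25
_DEFAULT_BASE_RATE = 0.08
_DEFAULT_SEPARATION = 0.35
_DEFAULT_N_CLUSTERS = 4


def make_profiles(
    n_products: int,
    n_attributes: int,
    n_clusters: int,
    separation: float,
    base_rate: float,
    seed: int,
    jitter: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build clustered citation-propensity profiles.

    Each cluster owns a disjoint *signature* subset of
    ``n_attributes // n_clusters`` attributes; signature propensities are
    ``base_rate + separation``, all others ``base_rate``.  Products are
    assigned to clusters in contiguous, maximally even blocks.  ``jitter``
    adds seeded uniform noise of that amplitude per product row (clipped to
    (0, 1)); with the default 0 all rows within a cluster are identical.

    Returns
    -------
    theta : (n_products, n_attributes) array in (0, 1)
    cluster_labels : (n_products,) int array in [0, n_clusters)
    """
    if not 0 < base_rate < 1:
        raise ValueError("base_rate must be in (0, 1)")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if base_rate + separation >= 1:
        raise ValueError("base_rate + separation must be < 1")
    if not 1 <= n_clusters <= n_products:
        raise ValueError("need 1 <= n_clusters <= n_products")
    if n_clusters > n_attributes:
        raise ValueError("each cluster needs at least one signature attribute")

    rng = np.random.default_rng(seed)
    sig_size = n_attributes // n_clusters
    # even contiguous blocks of products per cluster
    block = np.array_split(np.arange(n_products), n_clusters)
    labels = np.empty(n_products, dtype=int)
    theta = np.full((n_products, n_attributes), base_rate, dtype=float)
    for c, members in enumerate(block):
        labels[members] = c
        sig = slice(c * sig_size, (c + 1) * sig_size)
        theta[members, sig] = base_rate + separation
    if jitter > 0:
        theta = theta + rng.uniform(-jitter, jitter, size=theta.shape)
        theta = np.clip(theta, 1e-3, 1 - 1e-3)
    return theta, labels


@dataclass
class PanelSimConfig:
    """Parameters of a simulated replicated CATA panel.

    ``theta``, ``rho`` and ``lambda_`` default to a typical trained-panel
    wine-profiling design:
    clustered profiles from :func:`make_profiles` (4 clusters, base rate 0.08,
    separation 0.35), homogeneous reliability 0.25 (which puts the simulated
    p11 index in the ~0.3 regime typical of a trained wine panel) and
    discrimination 1.
    """

    n_panelists: int = _DEFAULT_N_PANELISTS
    n_products: int = _DEFAULT_N_PRODUCTS
    n_attributes: int = _DEFAULT_N_ATTRIBUTES
    theta: Optional[np.ndarray] = None
    rho: Optional[np.ndarray] = None
    lambda_: Optional[np.ndarray] = None
    min_citations: int = 2
    max_citations: int = 5
    seed: int = 0
    n_clusters: int = _DEFAULT_N_CLUSTERS
    base_rate: float = _DEFAULT_BASE_RATE
    separation: float = _DEFAULT_SEPARATION
    cluster_labels: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        if self.theta is None:
            self.theta, self.cluster_labels = make_profiles(
                self.n_products,
                self.n_attributes,
                min(self.n_clusters, self.n_products),
                self.separation,
                self.base_rate,
                seed=self.seed,
            )
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (self.n_products, self.n_attributes):
            raise ValueError("theta must have shape (n_products, n_attributes)")
        if not ((self.theta > 0) & (self.theta < 1)).all():
            raise ValueError("theta values must lie in (0, 1)")
        if self.rho is None:
            self.rho = np.full(self.n_panelists, _DEFAULT_RHO)
        self.rho = np.broadcast_to(
            np.asarray(self.rho, dtype=float), (self.n_panelists,)
        ).copy()
        if ((self.rho < 0) | (self.rho > 1)).any():
            raise ValueError("rho must lie in [0, 1]")
        if self.lambda_ is None:
            self.lambda_ = np.ones(self.n_panelists)
        self.lambda_ = np.broadcast_to(
            np.asarray(self.lambda_, dtype=float), (self.n_panelists,)
        ).copy()
        if (self.lambda_ < 0).any():
            raise ValueError("lambda_ must be >= 0")
        if not 1 <= self.min_citations <= self.max_citations <= self.n_attributes:
            raise ValueError("need 1 <= min_citations <= max_citations <= n_attributes")

    def to_json(self) -> str:
        payload = {
            "n_panelists": self.n_panelists,
            "n_products": self.n_products,
            "n_attributes": self.n_attributes,
            "theta": self.theta.tolist(),
            "rho": self.rho.tolist(),
            "lambda": self.lambda_.tolist(),
            "min_citations": self.min_citations,
            "max_citations": self.max_citations,
            "seed": self.seed,
            "cluster_labels": None
            if self.cluster_labels is None
            else np.asarray(self.cluster_labels).tolist(),
        }
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth behind a simulated dataset."""

    config: PanelSimConfig
    cluster_labels: Optional[np.ndarray]

    def to_json(self) -> str:
        return self.config.to_json()


def _weighted_draw_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, m: int
) -> list[int]:
    """Sequential weighted sampling with renormalization (documented seed contract)."""
    w = weights.astype(float).copy()
    out: list[int] = []
    for _ in range(m):
        total = w.sum()
        if total <= 0:
            raise ValueError("not enough attributes with positive weight to sample")
        idx = int(rng.choice(len(w), p=w / total))
        out.append(idx)
        w[idx] = 0.0
    return out


def simulate_panel(config: PanelSimConfig) -> tuple[CitationDataset, SimTruth]:
    """Simulate a complete replicated panel under ``config``.

    Deterministic under ``config.seed``; see the module docstring for the
    exact draw order and the keep-then-refill replicate-2 mechanism.
    """
    rng = np.random.default_rng(config.seed)
    J, P, A = config.n_panelists, config.n_products, config.n_attributes
    ind = np.zeros((J, P, 2, A), dtype=np.uint8)
    for j in range(J):
        lam = config.lambda_[j]
        rho = config.rho[j]
        for p in range(P):
            weights = config.theta[p] ** lam
            m1 = int(rng.integers(config.min_citations, config.max_citations + 1))
            rep1 = _weighted_draw_without_replacement(rng, weights, m1)
            ind[j, p, 0, rep1] = 1
            keep_u = rng.random(len(rep1))
            kept = [a for a, u in zip(sorted(rep1), keep_u) if u < rho]
            m2 = int(rng.integers(config.min_citations, config.max_citations + 1))
            if len(kept) > m2:
                rep2 = list(rng.choice(kept, size=m2, replace=False))
            else:
                w2 = weights.copy()
                w2[kept] = 0.0
                fill = _weighted_draw_without_replacement(rng, w2, m2 - len(kept))
                rep2 = kept + fill
            ind[j, p, 1, rep2] = 1

    dataset = CitationDataset(
        tuple(f"J{j + 1}" for j in range(J)),
        tuple(f"P{p + 1}" for p in range(P)),
        ("R1", "R2"),
        tuple(f"A{a + 1}" for a in range(A)),
        ind,
    )
    return dataset, SimTruth(config, config.cluster_labels)
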