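"""Sammon non-linear mapping of a distance matrix into low dimension.

Sammon's stress weights each pairwise error by the inverse of the target
distance, so small distances (here: the two replicates of the same product,
which should sit close together) dominate the fit:

    E(Y) = (1 / sum_{i<j} d_ij) * sum_{i<j} (d_ij - ||y_i - y_j||)^2 / d_ij

Minimization is iterative gradient descent from a deterministic classical
(metric) MDS initialization, with step-halving whenever a step would
increase the stress; the recorded stress trace is therefore non-increasing.
Exact zero target distances off the diagonal are replaced by a small epsilon
(1e-8 x the maximum distance) so the stress stays defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SammonEmbedding", "sammon_map", "classical_mds"]


@dataclass(frozen=True)
class SammonEmbedding:
    """Result of a Sammon mapping."""

    coordinates: np.ndarray  # (n, dim)
    stress: float
    n_iter: int
    trace: np.ndarray  # stress after init and after each accepted step

    def __post_init__(self):
        if self.stress < 0:
            raise ValueError("stress must be non-negative")


def classical_mds(distances: np.ndarray, dim: int) -> np.ndarray:
    """Deterministic classical (Torgerson) metric MDS coordinates."""
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dim]
    vals = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(vals)
    return coords


def _stress_and_grad(Y: np.ndarray, delta: np.ndarray, c: float):
    diff = Y[:, None, :] - Y[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 1.0)
    delta_safe = delta.copy()
    np.fill_diagonal(delta_safe, 1.0)
    err = delta - d
    off = ~np.eye(len(Y), dtype=bool)
    stress = (err[off] ** 2 / delta[off]).sum() / (2 * c)
    w = err / (delta_safe * np.maximum(d, 1e-30))
    np.fill_diagonal(w, 0.0)
    grad = (-2.0 / c) * (w[:, :, None] * diff).sum(axis=1)
    return stress, grad


def sammon_map(
    distances,
    dim: int = 2,
    max_iter: int = 500,
    tol: float = 1e-12,
    seed: int | None = None,
    init: np.ndarray | None = None,
) -> SammonEmbedding:
    """Embed a symmetric distance matrix by minimizing Sammon stress.

    ``seed`` is accepted for interface stability but the default
    initialization (classical MDS) is deterministic, so it is unused unless
    a random ``init`` is supplied by the caller.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    delta = D.copy()
    np.fill_diagonal(delta, 0.0)
    dmax = delta.max()
    if dmax == 0:
        raise ValueError("all distances are zero")
    eps = 1e-8 * dmax
    off = ~np.eye(n, dtype=bool)
    delta[off & (delta < eps)] = eps

    Y = classical_mds(delta, dim) if init is None else np.array(init, dtype=float)
    c = delta[off].sum() / 2
    stress, grad = _stress_and_grad(Y, delta, c)
    trace = [stress]
    lr = 0.1 * dmax / max(np.abs(grad).max(), 1e-30)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        improved = False
        for _ in range(40):
            Y_new = Y - lr * grad
            new_stress, new_grad = _stress_and_grad(Y_new, delta, c)
            if new_stress < stress:
                improved = True
                break
            lr *= 0.5
        if not improved:
            n_iter -= 1
            break
        gain = stress - new_stress
        Y, stress, grad = Y_new, new_stress, new_grad
        trace.append(stress)
        lr *= 1.2
        if gain < tol * max(stress, 1e-30) or stress < 1e-30:
            break
    return SammonEmbedding(Y, float(stress), n_iter, np.asarray(trace))
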