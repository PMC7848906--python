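"""Nonmetric multidimensional scaling (NMDS) with Kruskal stress-1.

Optimization uses nonmetric SMACOF (scikit-learn) restarted from multiple
initializations; the first start is the classical (metric) scaling solution,
which makes exactly embeddable configurations converge to ~zero stress, and
the rest are random.  The reported stress is Kruskal stress-1,

    stress1 = sqrt( sum (dhat_ij - dstar_ij)^2 / sum dhat_ij^2 )

with ``dhat`` the configuration distances and ``dstar`` their isotonic
(rank-preserving) regression on the input dissimilarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .diversity import DistanceMatrix


@dataclass
class Ordination:
    ids: list[str]
    coordinates: np.ndarray  # (n_samples, k), column-centered
    stress: float
    n_starts: int
    converged: bool


def stress1(coordinates: np.ndarray, dissimilarities: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    dhat = pdist(coordinates)
    dcond = dissimilarities[np.triu_indices(len(dissimilarities), k=1)]
    denom = float(np.sum(dhat ** 2))
    if denom == 0:
        return 0.0
    dstar = IsotonicRegression().fit_transform(dcond, dhat)
    return float(np.sqrt(np.sum((dhat - dstar) ** 2) / denom))


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling used as a deterministic warm start."""
    n = len(d)
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> Ordination:
    """Best-of-``n_starts`` NMDS embedding of ``dm`` into ``k`` dimensions.

    Degenerate inputs (all off-diagonal dissimilarities equal) return a
    result flagged ``converged=False`` rather than raising.
    """
    n = dm.n
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for a {k}-D embedding")
    d = dm.values
    off = d[np.triu_indices(n, k=1)]
    degenerate = off.size > 0 and np.ptp(off) == 0.0

    rng = np.random.default_rng(seed)
    best_coords: np.ndarray | None = None
    best_stress = np.inf
    any_converged = False
    inits: list[np.ndarray | None] = [_classical_scaling(d, k)]
    inits += [rng.standard_normal((n, k)) for _ in range(max(0, n_starts - 1))]
    for init in inits[:n_starts]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # smacof's eps criterion tracks raw squared-error stress;
            # tol refers to stress-1 (its square root), hence eps = tol**2
            coords, _, n_iter = smacof(
                d, metric=False, n_components=k, init=init, n_init=1,
                max_iter=max_iter, eps=tol ** 2, random_state=0,
                normalized_stress=True, return_n_iter=True,
            )
        s = stress1(coords, d)
        if n_iter < max_iter:
            any_converged = True
        if s < best_stress:
            best_stress = s
            best_coords = coords
    assert best_coords is not None
    best_coords = best_coords - best_coords.mean(axis=0, keepdims=True)
    return Ordination(
        ids=list(dm.ids),
        coordinates=best_coords,
        stress=best_stress,
        n_starts=min(n_starts, len(inits)),
        converged=any_converged and not degenerate,
    )
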