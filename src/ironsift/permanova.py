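"""One-factor PERMANOVA: pseudo-F on a distance matrix with permutation p-values.

Sums of squares follow the classical distance-based partition:

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_between = SS_total - SS_within
    F = (SS_between / (a - 1)) / (SS_within / (N - a))

The p-value uses free permutation of group labels with the add-one
convention ``p = (#{F_perm >= F_obs} + 1) / (n_permutations + 1)``; ties
count as exceeding.  An exact variant enumerates all distinct labelings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _itertools_permutations
from typing import Sequence

import numpy as np

from .diversity import DistanceMatrix


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    df_between: int
    df_within: int
    ss_total: float
    ss_between: float
    ss_within: float
    n_permutations: int
    seed: int | None = None
    method: str = "permutation"

    def as_dict(self) -> dict:
        return {
            "pseudo_f": self.pseudo_f,
            "p_value": self.p_value,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "ss_total": self.ss_total,
            "ss_between": self.ss_between,
            "ss_within": self.ss_within,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "method": self.method,
        }


def _as_codes(grouping: Sequence[str]) -> tuple[np.ndarray, int]:
    labels = np.asarray(grouping)
    uniq, codes = np.unique(labels, return_inverse=True)
    return codes, len(uniq)


def _ss_partition(d2: np.ndarray, codes: np.ndarray, n_groups: int
                  ) -> tuple[float, float, float]:
    n = len(codes)
    ss_total = float(np.triu(d2, k=1).sum() / n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += float(np.triu(sub, k=1).sum() / len(idx))
    return ss_total, ss_total - ss_within, ss_within


def _pseudo_f(ss_between: float, ss_within: float, a: int, n: int) -> float:
    if ss_within == 0.0:
        return float("inf") if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _ge(f_perm: float, f_obs: float) -> bool:
    """Ties count as exceeding; tolerate floating-point jitter in exact ties
    arising from different summation orders of the same partition."""
    if np.isinf(f_obs):
        return np.isinf(f_perm)
    return f_perm >= f_obs - max(1e-12, 1e-12 * abs(f_obs))


def permanova(
    dm: DistanceMatrix,
    grouping: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
    strata: Sequence[str] | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on ``dm`` with per-sample group labels.

    Parameters
    ----------
    dm
        Distance matrix; ids define sample order.
    grouping
        One label per sample, aligned with ``dm.ids``; at least 2 groups.
    n_permutations
        Number of random label permutations for the p-value.
    seed
        Seed for the permutation stream (identical seed, identical p).
    strata
        Optional per-sample stratum labels; when given, labels are permuted
        only within strata.  Off by default (free permutation).
    """
    if len(grouping) != dm.n:
        raise ValueError(f"{len(grouping)} labels for {dm.n} samples")
    codes, a = _as_codes(grouping)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    n = dm.n
    if n - a < 1:
        raise ValueError("no within-group degrees of freedom (N - a < 1)")
    d2 = dm.values ** 2
    ss_total, ss_between, ss_within = _ss_partition(d2, codes, a)
    f_obs = _pseudo_f(ss_between, ss_within, a, n)

    rng = np.random.default_rng(seed)
    if strata is not None:
        if len(strata) != n:
            raise ValueError("strata length must match number of samples")
        strata_arr = np.asarray(strata)
        strata_idx = [np.flatnonzero(strata_arr == s) for s in np.unique(strata_arr)]

    exceed = 0
    for _ in range(n_permutations):
        if strata is None:
            perm = rng.permutation(codes)
        else:
            perm = codes.copy()
            for idx in strata_idx:
                perm[idx] = perm[idx[rng.permutation(len(idx))]]
        _, ssb, ssw = _ss_partition(d2, perm, a)
        if _ge(_pseudo_f(ssb, ssw, a, n), f_obs):
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=f_obs, p_value=p, df_between=a - 1, df_within=n - a,
        ss_total=ss_total, ss_between=ss_between, ss_within=ss_within,
        n_permutations=n_permutations, seed=seed,
    )


def _distinct_labelings(codes: np.ndarray):
    seen: set[tuple[int, ...]] = set()
    for perm in _itertools_permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)


def permanova_exact(dm: DistanceMatrix, grouping: Sequence[str]) -> PermanovaResult:
    """PERMANOVA with the exact p-value over all distinct label arrangements.

    The observed labeling is a member of the enumeration, so
    ``p = #{F >= F_obs} / #labelings`` (no add-one term).  Only feasible for
    small N (the enumeration is N! before deduplication).
    """
    if len(grouping) != dm.n:
        raise ValueError(f"{len(grouping)} labels for {dm.n} samples")
    codes, a = _as_codes(grouping)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    n = dm.n
    d2 = dm.values ** 2
    ss_total, ss_between, ss_within = _ss_partition(d2, codes, a)
    f_obs = _pseudo_f(ss_between, ss_within, a, n)
    total = 0
    exceed = 0
    for perm in _distinct_labelings(codes):
        total += 1
        _, ssb, ssw = _ss_partition(d2, perm, a)
        if _ge(_pseudo_f(ssb, ssw, a, n), f_obs):
            exceed += 1
    return PermanovaResult(
        pseudo_f=f_obs, p_value=exceed / total, df_between=a - 1, df_within=n - a,
        ss_total=ss_total, ss_between=ss_between, ss_within=ss_within,
        n_permutations=total, method="exact",
    )
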