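"""Four techniques for selecting the OTUs most affected by a treatment
transition: random forest, indicator value (IndVal), presence-absence, and
multiple t-testing.

All techniques operate on relative abundances of a (typically rarefied)
table and compare exactly two classes of samples — the two time points of a
transition.  Each returns a :class:`SelectionResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

from .stats import ADJUSTMENTS
from .tables import OTUTable


@dataclass
class SelectionResult:
    """OTUs chosen by one technique at one transition."""

    method: str
    selected_otus: list[str]
    scores: dict[str, float]  # per selected OTU: importance, IndVal, |prevalence delta| or adjusted p
    transition: tuple[str, str] | None = None
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [o for o in self.selected_otus if o not in self.scores]
        if missing:
            raise ValueError(f"selected OTUs without scores: {missing}")

    @property
    def n_selected(self) -> int:
        return len(self.selected_otus)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "transition": list(self.transition) if self.transition else None,
            "n_selected": self.n_selected,
            "selected_otus": list(self.selected_otus),
            "scores": {k: float(v) for k, v in self.scores.items()},
            "params": self.params,
            "seed": self.seed,
        }


def _two_classes(table: OTUTable, labels: Sequence[str]) -> np.ndarray:
    if len(labels) != table.n_samples:
        raise ValueError(f"{len(labels)} labels for {table.n_samples} samples")
    uniq, codes = np.unique(np.asarray(labels), return_inverse=True)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 classes, got {list(uniq)}")
    return codes


# ---------------------------------------------------------------------------
# random forest with null-calibrated permutation importance
# ---------------------------------------------------------------------------

def _proba_importance(
    rf: RandomForestClassifier,
    X: np.ndarray,
    codes: np.ndarray,
    rng: np.random.Generator,
    n_repeats: int,
) -> np.ndarray:
    """Permutation importance scored as the drop in mean true-class
    probability when one feature is shuffled.

    Probability scoring (rather than accuracy) keeps importances informative
    when several features carry a redundant signal.
    """
    n, p = X.shape
    rows = np.arange(n)
    base = rf.predict_proba(X)[rows, codes].mean()
    imp = np.zeros(p)
    for _ in range(n_repeats):
        big = np.repeat(X[None, :, :], p, axis=0)
        for j in range(p):
            big[j, :, j] = X[rng.permutation(n), j]
        proba = rf.predict_proba(big.reshape(p * n, p)).reshape(p, n, -1)
        imp += base - proba[:, rows, codes].mean(axis=1)
    return imp / n_repeats


def select_random_forest(
    table: OTUTable,
    labels: Sequence[str],
    n_trees: int = 100,
    importance_null_reps: int = 50,
    alpha: float = 0.05,
    seed: int | None = None,
    n_repeats: int = 3,
    top_k: int | None = None,
    transition: tuple[str, str] | None = None,
) -> SelectionResult:
    """Random-forest selection of discriminating OTUs.

    A classifier of samples into the two classes is trained on relative
    abundances and per-OTU permutation importances are computed.  The
    selection threshold is the ``1 - alpha`` quantile of the maximum
    importance across ``importance_null_reps`` label-shuffled refits; OTUs
    exceeding it are selected, ranked by importance.  ``top_k`` switches to
    a fixed-size selection of the most important OTUs instead.
    """
    codes = _two_classes(table, labels)
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    X = table.relative_abundance()
    rng = np.random.default_rng(seed)

    def fit(y: np.ndarray) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_trees, n_jobs=1,
            random_state=int(rng.integers(2 ** 31 - 1)),
        ).fit(X, y)

    importance = _proba_importance(fit(codes), X, codes, rng, n_repeats)

    params = {"n_trees": n_trees, "importance_null_reps": importance_null_reps,
              "alpha": alpha, "n_repeats": n_repeats, "top_k": top_k}
    order = np.argsort(importance)[::-1]
    if top_k is not None:
        chosen = order[:top_k]
    else:
        null_max = np.empty(importance_null_reps)
        for r in range(importance_null_reps):
            y_null = rng.permutation(codes)
            null_max[r] = _proba_importance(fit(y_null), X, y_null, rng, n_repeats).max()
        threshold = float(np.quantile(null_max, 1.0 - alpha))
        params["threshold"] = threshold
        chosen = [j for j in order if importance[j] > threshold]
    selected = [table.otu_ids[j] for j in chosen]
    return SelectionResult(
        method="random_forest", selected_otus=selected,
        scores={table.otu_ids[j]: float(importance[j]) for j in chosen},
        transition=transition, params=params, seed=seed,
    )


# ---------------------------------------------------------------------------
# indicator value (IndVal)
# ---------------------------------------------------------------------------

def _indval(X: np.ndarray, presence: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Max-over-groups IndVal (specificity x fidelity x 100) per OTU."""
    means = np.stack([X[codes == g].mean(axis=0) for g in (0, 1)])
    prev = np.stack([presence[codes == g].mean(axis=0) for g in (0, 1)])
    total = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, means / total, 0.0)
    return (a * prev * 100.0).max(axis=0)


def select_indval(
    table: OTUTable,
    labels: Sequence[str],
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    exact: bool = False,
    transition: tuple[str, str] | None = None,
) -> SelectionResult:
    """IndVal selection: per-OTU indicator value with a label-permutation
    test (add-one convention) and BH adjustment within the technique.

    ``exact=True`` enumerates all distinct labelings instead of sampling
    (``p = #{IndVal_perm >= IndVal_obs} / #labelings``, observed labeling
    included); only feasible for small sample counts.
    """
    codes = _two_classes(table, labels)
    X = table.relative_abundance()
    presence = (table.counts >= 1).astype(float)
    obs = _indval(X, presence, codes)
    exceed = np.zeros(table.n_otus, dtype=np.int64)
    if exact:
        from .permanova import _distinct_labelings

        total = 0
        for perm in _distinct_labelings(codes):
            exceed += _indval(X, presence, perm) >= obs
            total += 1
        p = exceed / total
        n_permutations = total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            perm = rng.permutation(codes)
            exceed += _indval(X, presence, perm) >= obs
        p = (exceed + 1) / (n_permutations + 1)
    adjusted = ADJUSTMENTS["bh"](p)
    chosen = np.flatnonzero(adjusted < alpha)
    chosen = chosen[np.argsort(obs[chosen])[::-1]]
    selected = [table.otu_ids[j] for j in chosen]
    return SelectionResult(
        method="indval", selected_otus=selected,
        scores={table.otu_ids[j]: float(obs[j]) for j in chosen},
        transition=transition,
        params={"n_permutations": n_permutations, "alpha": alpha, "exact": exact},
        seed=seed,
    )


def indval_scores(table: OTUTable, labels: Sequence[str]) -> np.ndarray:
    """Per-OTU IndVal values in [0, 100] (no test), in table OTU order."""
    codes = _two_classes(table, labels)
    return _indval(table.relative_abundance(), (table.counts >= 1).astype(float), codes)


# ---------------------------------------------------------------------------
# presence-absence
# ---------------------------------------------------------------------------

def select_presence_absence(
    table: OTUTable,
    labels: Sequence[str],
    prevalence_high: float = 0.5,
    prevalence_zero: float = 0.0,
    transition: tuple[str, str] | None = None,
) -> SelectionResult:
    """Select OTUs detected in more than ``prevalence_high`` of samples at
    one time point and in at most ``prevalence_zero`` at the other (either
    direction).  Detection means count >= 1.  Score = |prevalence delta|."""
    codes = _two_classes(table, labels)
    presence = (table.counts >= 1).astype(float)
    prev0 = presence[codes == 0].mean(axis=0)
    prev1 = presence[codes == 1].mean(axis=0)
    hit = ((prev0 > prevalence_high) & (prev1 <= prevalence_zero)) | \
          ((prev1 > prevalence_high) & (prev0 <= prevalence_zero))
    delta = np.abs(prev0 - prev1)
    chosen = np.flatnonzero(hit)
    chosen = chosen[np.argsort(delta[chosen])[::-1]]
    selected = [table.otu_ids[j] for j in chosen]
    return SelectionResult(
        method="presence_absence", selected_otus=selected,
        scores={table.otu_ids[j]: float(delta[j]) for j in chosen},
        transition=transition,
        params={"prevalence_high": prevalence_high, "prevalence_zero": prevalence_zero},
    )


# ---------------------------------------------------------------------------
# multiple t-testing
# ---------------------------------------------------------------------------

def select_multiple_ttest(
    table: OTUTable,
    labels: Sequence[str],
    correction: str = "bonferroni",
    alpha: float = 0.05,
    paired: bool = False,
    subjects: Sequence[str] | None = None,
    transition: tuple[str, str] | None = None,
) -> SelectionResult:
    """Per-OTU t-tests on relative abundances with multiplicity correction.

    With ``paired=True``, ``subjects`` pairs samples across the two classes
    (subjects with one sample per class); otherwise a Welch two-sample test
    is used.  OTUs constant across all samples are skipped (never selected).
    Score = adjusted p-value; selected where adjusted p < ``alpha``.
    """
    if correction not in ADJUSTMENTS:
        raise ValueError(f"correction must be one of {sorted(ADJUSTMENTS)}")
    codes = _two_classes(table, labels)
    X = table.relative_abundance()
    if paired:
        if subjects is None:
            raise ValueError("paired=True requires subjects")
        subj = np.asarray(subjects)
        a_rows, b_rows = [], []
        for s in dict.fromkeys(subj):
            ia = np.flatnonzero((subj == s) & (codes == 0))
            ib = np.flatnonzero((subj == s) & (codes == 1))
            if len(ia) == 1 and len(ib) == 1:
                a_rows.append(ia[0])
                b_rows.append(ib[0])
        if len(a_rows) < 2:
            raise ValueError("need at least 2 complete pairs for a paired t-test")
        A, B = X[a_rows], X[b_rows]
        n_eff = len(a_rows)
    else:
        A, B = X[codes == 0], X[codes == 1]
        if min(len(A), len(B)) < 2:
            raise ValueError("each class needs at least 2 samples")
        n_eff = min(len(A), len(B))

    constant = np.ptp(X, axis=0) == 0.0
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if paired:
            res = sps.ttest_rel(A, B, axis=0)
        else:
            res = sps.ttest_ind(A, B, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance but non-constant OTUs: deterministic difference or equality
    mean_gap = np.abs(A.mean(axis=0) - B.mean(axis=0))
    undefined = np.isnan(p) & ~constant
    p[undefined & (mean_gap > 0)] = 0.0
    p[undefined & (mean_gap == 0)] = 1.0
    testable = np.flatnonzero(~constant)
    adjusted = np.full(table.n_otus, np.nan)
    if testable.size:
        adjusted[testable] = ADJUSTMENTS[correction](p[testable])
    chosen = np.flatnonzero(~np.isnan(adjusted) & (adjusted < alpha))
    chosen = chosen[np.argsort(adjusted[chosen], kind="stable")]
    selected = [table.otu_ids[j] for j in chosen]
    return SelectionResult(
        method="ttest", selected_otus=selected,
        scores={table.otu_ids[j]: float(adjusted[j]) for j in chosen},
        transition=transition,
        params={"correction": correction, "alpha": alpha, "paired": paired,
                "n_pairs_or_min_class": int(n_eff)},
    )


SELECTORS = {
    "rf": select_random_forest,
    "indval": select_indval,
    "presence": select_presence_absence,
    "ttest": select_multiple_ttest,
}
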