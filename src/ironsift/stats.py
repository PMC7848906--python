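"""Paired nonparametric time-point comparisons, multiplicity correction and
comparative-Ct gene-expression analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import SampleMetadata


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank ("paired Wilcoxon")
# ---------------------------------------------------------------------------

def paired_wilcoxon(
    values_a: Sequence[float] | Mapping[str, float],
    values_b: Sequence[float] | Mapping[str, float],
    subjects: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on within-subject differences.

    ``values_a`` / ``values_b`` are either equal-length sequences (aligned by
    position or by ``subjects``) or mappings from subject id to value, in
    which case pairing is by key intersection.  Pairs with a missing member
    (NaN) are dropped; zero differences are dropped before ranking.  The
    exact sign-enumeration null is used when n <= 25 and the absolute
    differences are tie-free, otherwise a normal approximation with
    continuity correction and tie-corrected variance.

    Returns ``(W_plus, p)`` where ``W_plus`` is the sum of ranks of the
    positive differences.
    """
    if isinstance(values_a, Mapping) or isinstance(values_b, Mapping):
        if not (isinstance(values_a, Mapping) and isinstance(values_b, Mapping)):
            raise TypeError("values_a and values_b must both be mappings or both sequences")
        common = [s for s in values_a if s in values_b]
        missing = sorted(set(values_a) ^ set(values_b))
        a = np.array([values_a[s] for s in common], dtype=float)
        b = np.array([values_b[s] for s in common], dtype=float)
    else:
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("values_a and values_b must have equal length")
        missing = []
    ok = ~(np.isnan(a) | np.isnan(b))
    d = (a - b)[ok]
    d = d[d != 0.0]
    if d.size == 0:
        detail = f" (unpaired subjects: {missing})" if missing else ""
        raise ValueError("no complete non-zero pairs for paired Wilcoxon" + detail)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       alternative="two-sided", method=method)
    return w_plus, float(res.pvalue)


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------

def _validate_p(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = _validate_p(p_values)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjusted p-values ``min(1, p * m)``."""
    p = _validate_p(p_values)
    return np.minimum(p * p.size, 1.0) if p.size else p


ADJUSTMENTS = {"bh": bh_adjust, "bonferroni": bonferroni_adjust}


# ---------------------------------------------------------------------------
# sequential paired comparisons of a per-sample measurement
# ---------------------------------------------------------------------------

@dataclass
class PairedComparison:
    timepoint_a: str
    timepoint_b: str
    n_pairs: int
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    method: str = "wilcoxon_signed_rank"


def sequential_paired_comparisons(
    values: Mapping[str, float],
    metadata: SampleMetadata,
    timepoints: Sequence[str] | None = None,
    adjust: str = "bh",
) -> list[PairedComparison]:
    """Paired Wilcoxon tests between consecutive time points of a per-sample
    measurement, BH-corrected within the family of sequential comparisons.

    ``values`` maps sample id to the measured quantity (e.g. inverse
    Simpson); pairing is by mouse.
    """
    if timepoints is None:
        timepoints = metadata.timepoints_present()
    df = metadata.df.set_index("sample_id")
    by_tp: dict[str, dict[str, float]] = {}
    for tp in timepoints:
        by_tp[tp] = {
            df.loc[s, "mouse_id"]: values[s]
            for s in metadata.samples_at(tp)
            if s in values
        }
    comparisons: list[PairedComparison] = []
    for tp_a, tp_b in zip(timepoints[:-1], timepoints[1:]):
        a, b = by_tp[tp_a], by_tp[tp_b]
        common = [m for m in a if m in b]
        try:
            stat, p = paired_wilcoxon(a, b)
        except ValueError:
            stat, p = float("nan"), float("nan")
        comparisons.append(PairedComparison(tp_a, tp_b, len(common), stat, p))
    raw = [c.p_value for c in comparisons]
    finite = [i for i, p in enumerate(raw) if not np.isnan(p)]
    if finite:
        adjusted = ADJUSTMENTS[adjust]([raw[i] for i in finite])
        for i, q in zip(finite, adjusted):
            comparisons[i].p_adjusted = float(q)
            comparisons[i].method = f"wilcoxon_signed_rank+{adjust}"
    return comparisons


def comparisons_table(comparisons: Iterable[PairedComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])


# ---------------------------------------------------------------------------
# comparative Ct (delta-delta-Ct) gene expression
# ---------------------------------------------------------------------------

@dataclass
class CtRecord:
    animal: str
    tissue: str
    gene: str
    ct: float
    role: str  # "target" | "reference"
    arm: str   # "treatment" | "control"

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"Ct must be finite and positive, got {self.ct}")
        if self.role not in ("target", "reference"):
            raise ValueError(f"role must be 'target' or 'reference', got {self.role!r}")


@dataclass
class ExpressionResult:
    gene: str
    tissue: str
    fold_change: float
    ddct: float
    mean_dct_treatment: float
    mean_dct_control: float
    n_treatment: int
    n_control: int
    t_statistic: float
    p_value: float


def ddct_fold_change(
    ct_records: Sequence[CtRecord], gene: str, tissue: str
) -> ExpressionResult:
    """Comparative-Ct relative expression of ``gene`` in ``tissue``.

    Per animal, ``dCt = Ct_target - Ct_reference``; ``ddCt`` is the mean dCt
    of the treatment arm minus the mean dCt of the control arm, and the fold
    change is ``2 ** (-ddCt)``.  A Welch t-test on the per-animal dCt values
    between arms accompanies the estimate.
    """
    per_arm: dict[str, list[float]] = {"treatment": [], "control": []}
    for arm in per_arm:
        targets = {
            r.animal: r.ct for r in ct_records
            if r.arm == arm and r.tissue == tissue and r.role == "target" and r.gene == gene
        }
        refs = {
            r.animal: r.ct for r in ct_records
            if r.arm == arm and r.tissue == tissue and r.role == "reference"
        }
        if targets and not refs:
            raise ValueError(f"no reference-gene Ct records in {arm} arm for tissue {tissue!r}")
        per_arm[arm] = [targets[a] - refs[a] for a in targets if a in refs]
    dct_t, dct_c = per_arm["treatment"], per_arm["control"]
    if not dct_t or not dct_c:
        raise ValueError(
            f"need target and reference Ct in both arms for gene {gene!r}, tissue {tissue!r}"
        )
    ddct = float(np.mean(dct_t) - np.mean(dct_c))
    if len(dct_t) > 1 and len(dct_c) > 1:
        if np.ptp(dct_t) == 0 and np.ptp(dct_c) == 0:
            t_stat, p = (0.0, 1.0) if np.mean(dct_t) == np.mean(dct_c) else (float("inf"), 0.0)
        else:
            res = sps.ttest_ind(dct_t, dct_c, equal_var=False)
            t_stat, p = float(res.statistic), float(res.pvalue)
    else:
        t_stat, p = float("nan"), float("nan")
    return ExpressionResult(
        gene=gene, tissue=tissue, fold_change=float(2.0 ** (-ddct)), ddct=ddct,
        mean_dct_treatment=float(np.mean(dct_t)), mean_dct_control=float(np.mean(dct_c)),
        n_treatment=len(dct_t), n_control=len(dct_c),
        t_statistic=t_stat, p_value=p,
    )
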