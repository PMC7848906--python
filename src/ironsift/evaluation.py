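"""Benchmarking OTU-selection techniques by PERMANOVA pseudo-F reduction.

A technique is scored at a treatment transition by how much deleting its
selected OTUs from the community table lowers the PERMANOVA pseudo-F
between the two time points (distances recomputed on the remaining counts,
same samples, no re-rarefaction), and by how few OTUs it needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diversity import distance_matrix
from .permanova import permanova
from .selection import SelectionResult
from .tables import OTUTable, SampleMetadata


@dataclass
class EvaluationRecord:
    method: str
    group: str
    transition: tuple[str, str]
    n_selected: int
    f_full: float
    f_reduced: float
    p_full: float
    p_reduced: float

    @property
    def delta_f(self) -> float:
        return self.f_full - self.f_reduced

    def as_dict(self) -> dict:
        return {
            "method": self.method, "group": self.group,
            "transition": "->".join(self.transition),
            "n_selected": self.n_selected,
            "f_full": self.f_full, "f_reduced": self.f_reduced,
            "delta_f": self.delta_f,
            "p_full": self.p_full, "p_reduced": self.p_reduced,
        }


def evaluate_selection(
    table: OTUTable,
    metadata: SampleMetadata,
    transition: tuple[str, str],
    selection: SelectionResult,
    n_permutations: int = 999,
    seed: int | None = None,
    group: str | None = None,
) -> EvaluationRecord:
    """Pseudo-F reduction achieved by removing ``selection``'s OTUs.

    ``F_full`` is the PERMANOVA pseudo-F on Bray-Curtis distances between
    the samples of the two time points; ``F_reduced`` is the same statistic
    after deleting the selected OTU columns (identical sample set, same
    permutation seed, counts not re-rarefied).  An empty selection yields
    ``F_reduced == F_full``.
    """
    tp_a, tp_b = transition
    samples = metadata.samples_at(tp_a, group) + metadata.samples_at(tp_b, group)
    if not samples:
        raise ValueError(f"no samples at transition {tp_a}->{tp_b}"
                         + (f" in group {group!r}" if group else ""))
    sub = table.select_samples(samples)
    labels = metadata.column_for(samples, "timepoint")

    full = permanova(distance_matrix(sub), labels,
                     n_permutations=n_permutations, seed=seed)
    to_drop = [o for o in selection.selected_otus if o in sub.otu_ids]
    if len(to_drop) == sub.n_otus:
        raise ValueError("selection removes every OTU in the table")
    if to_drop:
        reduced_table = sub.drop_otus(to_drop)
        reduced = permanova(distance_matrix(reduced_table), labels,
                            n_permutations=n_permutations, seed=seed)
        f_reduced, p_reduced = reduced.pseudo_f, reduced.p_value
    else:
        f_reduced, p_reduced = full.pseudo_f, full.p_value

    groups = metadata.for_samples(samples).groups()
    group_id = group if group is not None else "+".join(groups)
    return EvaluationRecord(
        method=selection.method, group=group_id, transition=(tp_a, tp_b),
        n_selected=selection.n_selected,
        f_full=full.pseudo_f, f_reduced=f_reduced,
        p_full=full.p_value, p_reduced=p_reduced,
    )


def records_table(records: Iterable[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_techniques(records: Sequence[EvaluationRecord]) -> dict:
    """Pairwise paired t-tests between techniques on delta-F and n_selected.

    Records are paired by ``(group, transition)``; unmatched pairs are
    dropped.  The summary ranks techniques by median delta-F (descending)
    and median n_selected (ascending).  Output is invariant to record order.
    """
    df = records_table(records)
    if df.empty:
        raise ValueError("no evaluation records")
    methods = sorted(df["method"].unique())
    keyed = df.set_index(["method", "group", "transition"]).sort_index()

    pairwise = []
    for m1, m2 in combinations(methods, 2):
        k1 = keyed.loc[m1]
        k2 = keyed.loc[m2]
        common = sorted(set(k1.index) & set(k2.index))
        if len(common) < 2:
            continue
        d1 = k1.loc[common, "delta_f"].to_numpy(dtype=float)
        d2 = k2.loc[common, "delta_f"].to_numpy(dtype=float)
        n1 = k1.loc[common, "n_selected"].to_numpy(dtype=float)
        n2 = k2.loc[common, "n_selected"].to_numpy(dtype=float)
        t_df, p_df = _paired_t(d1, d2)
        t_n, p_n = _paired_t(n1, n2)
        pairwise.append({
            "method_a": m1, "method_b": m2, "n_pairs": len(common),
            "delta_f_t": t_df, "delta_f_p": p_df,
            "n_selected_t": t_n, "n_selected_p": p_n,
        })

    summary = (
        df.groupby("method")
        .agg(median_delta_f=("delta_f", "median"),
             median_n_selected=("n_selected", "median"),
             n_records=("delta_f", "size"))
        .reset_index()
        .sort_values(["median_delta_f", "method"], ascending=[False, True])
        .reset_index(drop=True)
    )
    summary["rank_by_delta_f"] = np.arange(1, len(summary) + 1)
    by_n = summary.sort_values(["median_n_selected", "method"]).reset_index(drop=True)
    rank_n = {m: i + 1 for i, m in enumerate(by_n["method"])}
    summary["rank_by_n_selected"] = summary["method"].map(rank_n)
    return {
        "pairwise": pairwise,
        "summary": summary.to_dict(orient="records"),
    }
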