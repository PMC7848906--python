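"""Iron-sensitivity and recovery classification of OTUs.

An OTU is *iron-sensitive* when it is present at appreciable levels at
baseline (joint prevalence and mean-relative-abundance floor) and becomes
undetectable — zero reads at every challenge time point sampled for that
mouse — in more than half of the mice.  A sensitive OTU is *recovered* when
it is detected again in at least half of the mice at any repletion time
point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables import OTUTable, SampleMetadata

STATUS_SENSITIVE_RECOVERED = "sensitive_recovered"
STATUS_SENSITIVE_NOT_RECOVERED = "sensitive_not_recovered"
STATUS_SENSITIVE = "sensitive"  # when no repletion time points are available
STATUS_UNAFFECTED = "unaffected"


@dataclass
class SensitivityCall:
    otu_id: str
    status: str
    baseline_prevalence: float
    baseline_mean_relabund: float
    li_undetectable_fraction: float
    repletion_prevalence: float | None  # None when no repletion time points


def _mouse_sample_map(metadata: SampleMetadata, table: OTUTable,
                      timepoints: Sequence[str]) -> dict[str, list[int]]:
    """mouse id -> row indices of that mouse's samples at ``timepoints``."""
    present = set(table.sample_ids)
    out: dict[str, list[int]] = {}
    for tp in timepoints:
        for sid in metadata.samples_at(tp):
            if sid in present:
                out.setdefault(metadata.column_for([sid], "mouse_id")[0], []) \
                   .append(table.sample_index(sid))
    return out


def classify_sensitivity(
    table: OTUTable,
    metadata: SampleMetadata,
    baseline_tps: Sequence[str],
    li_tps: Sequence[str],
    repletion_tps: Sequence[str] = (),
    appreciable_min_prevalence: float = 0.5,
    appreciable_min_relabund: float = 0.001,
    undetectable_frac: float = 0.5,
    recovery_min_prevalence: float = 0.5,
) -> list[SensitivityCall]:
    """Classify every OTU of a rarefied table as sensitive (recovered / not
    recovered) or unaffected.

    Per mouse, an OTU is "undetectable during LI" when it has zero reads in
    every challenge-phase sample of that mouse; mice with no challenge
    samples are excluded from the denominator.  Sensitivity requires the
    baseline criteria (prevalence across mice and mean relative abundance)
    plus undetectability in strictly more than ``undetectable_frac`` of
    mice.  Recovery requires detection in at least
    ``recovery_min_prevalence`` of mice at any repletion time point.  With
    no repletion time points, sensitive OTUs get status ``"sensitive"`` and
    ``repletion_prevalence`` is ``None``.
    """
    for name, tps in (("baseline_tps", baseline_tps), ("li_tps", li_tps)):
        if not list(tps):
            raise ValueError(f"{name} must be non-empty")
    sets = [set(baseline_tps), set(li_tps), set(repletion_tps)]
    for i in range(3):
        for j in range(i + 1, 3):
            overlap = sets[i] & sets[j]
            if overlap:
                raise ValueError(f"time-point sets overlap: {sorted(overlap)}")

    rel = table.relative_abundance()
    detected = table.counts >= 1

    base_rows = _mouse_sample_map(metadata, table, baseline_tps)
    li_rows = _mouse_sample_map(metadata, table, li_tps)
    rep_rows = _mouse_sample_map(metadata, table, repletion_tps)
    if not base_rows:
        raise ValueError("no baseline samples found in the table")
    if not li_rows:
        raise ValueError("no challenge (LI) samples found in the table")

    all_base_idx = [i for rows in base_rows.values() for i in rows]
    baseline_mean_ra = rel[all_base_idx].mean(axis=0)
    # per-mouse baseline detection: detected in any baseline sample
    base_det = np.stack([detected[rows].any(axis=0) for rows in base_rows.values()])
    baseline_prev = base_det.mean(axis=0)

    # per-mouse LI undetectability: zero in every LI sample of that mouse
    li_undet = np.stack([~detected[rows].any(axis=0) for rows in li_rows.values()])
    li_undet_frac = li_undet.mean(axis=0)

    if rep_rows:
        rep_det = np.stack([detected[rows].any(axis=0) for rows in rep_rows.values()])
        rep_prev = rep_det.mean(axis=0)
    else:
        rep_prev = None

    calls: list[SensitivityCall] = []
    for j, otu in enumerate(table.otu_ids):
        appreciable = (baseline_prev[j] >= appreciable_min_prevalence
                       and baseline_mean_ra[j] >= appreciable_min_relabund)
        sensitive = appreciable and li_undet_frac[j] > undetectable_frac
        if not sensitive:
            status = STATUS_UNAFFECTED
        elif rep_prev is None:
            status = STATUS_SENSITIVE
        elif rep_prev[j] >= recovery_min_prevalence:
            status = STATUS_SENSITIVE_RECOVERED
        else:
            status = STATUS_SENSITIVE_NOT_RECOVERED
        calls.append(SensitivityCall(
            otu_id=otu, status=status,
            baseline_prevalence=float(baseline_prev[j]),
            baseline_mean_relabund=float(baseline_mean_ra[j]),
            li_undetectable_fraction=float(li_undet_frac[j]),
            repletion_prevalence=float(rep_prev[j]) if rep_prev is not None else None,
        ))
    return calls


def calls_table(calls: Iterable[SensitivityCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def sensitive_set(calls: Iterable[SensitivityCall]) -> set[str]:
    return {c.otu_id for c in calls if c.status.startswith("sensitive")}


def recovered_set(calls: Iterable[SensitivityCall]) -> set[str]:
    return {c.otu_id for c in calls if c.status == STATUS_SENSITIVE_RECOVERED}
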