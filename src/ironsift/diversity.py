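"""Alpha diversity (inverse Simpson, richness) and Bray-Curtis beta diversity."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import OTUTable


def inverse_simpson(counts: Sequence[float], unbiased: bool = False) -> float:
    """Inverse Simpson index ``1 / sum(p_i^2)`` of one sample.

    With ``unbiased=True`` the finite-sample form
    ``1 / sum(n_i (n_i - 1) / (N (N - 1)))`` is used instead of the plug-in
    estimator.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single sample (1-D counts)")
    if x.size and x.min() < 0:
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("inverse Simpson undefined for an all-zero sample")
    if unbiased:
        n = x.sum()
        denom = (x * (x - 1)).sum() / (n * (n - 1))
        if denom == 0:
            raise ValueError("unbiased inverse Simpson undefined: all singletons")
        return float(1.0 / denom)
    p = x / total
    return float(1.0 / np.sum(p * p))


def richness(counts: Sequence[float]) -> int:
    """Number of OTUs observed (count >= 1)."""
    x = np.asarray(counts, dtype=float)
    return int(np.count_nonzero(x >= 1))


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity ``sum|x - y| / sum(x + y)`` in [0, 1]."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if (a.size and a.min() < 0) or (b.size and b.min() < 0):
        raise ValueError("abundances must be non-negative")
    denom = float(np.sum(a) + np.sum(b))
    if denom == 0:
        raise ValueError("Bray-Curtis undefined when both samples are all-zero")
    return float(np.sum(np.abs(a - b)) / denom)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(map(str, self.ids))
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.array_equal(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.size and v.min() < 0:
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def distance_matrix(table: OTUTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis over the rows of ``table``.

    Raises with the offending sample id if any sample is all-zero.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    X = table.counts.astype(float)
    totals = X.sum(axis=1)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"Bray-Curtis undefined for all-zero samples: {zero}")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = totals[:, None] + totals[None, :]
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = np.minimum(d, d.T)  # exact symmetry irrespective of fp summation order
    return DistanceMatrix(list(table.sample_ids), d)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def diversity_table(table: OTUTable) -> pd.DataFrame:
    """Per-sample inverse Simpson and richness as a tidy DataFrame."""
    rows = [
        {
            "sample_id": sid,
            "inverse_simpson": inverse_simpson(row),
            "richness": richness(row),
        }
        for sid, row in zip(table.sample_ids, table.counts)
    ]
    return pd.DataFrame(rows)


def write_diversity_tsv(table: OTUTable, path: str | Path) -> None:
    diversity_table(table).to_csv(path, sep="\t", index=False)


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids).rename_axis("sample_id") \
        .to_csv(path, sep="\t")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy())


def write_phylip_lower(dm: DistanceMatrix, path: str | Path) -> None:
    """Lower-triangle PHYLIP-style distance matrix writer."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for i, sid in enumerate(dm.ids):
            row = "\t".join(f"{dm.values[i, j]:.10g}" for j in range(i))
            fh.write(sid + ("\t" + row if row else "") + "\n")
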