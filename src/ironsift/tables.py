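"""Community tables, sample metadata and taxonomy: types, parsers and writers.

The central objects of the package:

* :class:`OTUTable` — an integer count matrix (samples x OTUs).
* :class:`SampleMetadata` — per-sample mouse / group / cage / sex / time point.
* :class:`TaxonomyMap` — OTU id -> ranked lineage with per-rank confidence.

File formats supported are the mothur ``.shared`` table, the mothur
``.cons.taxonomy`` table, plain sample-by-OTU TSV, and a metadata TSV with
required columns ``sample_id, mouse_id, group, cage, sex, timepoint``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical ordering of the study's time points.  T0 is the conventional-chow
#: start, B* the post-diet-shift baseline, LI* the low-iron challenge and R*
#: the iron repletion phase.
TIMEPOINT_ORDER: tuple[str, ...] = ("T0", "B7", "B14", "LI7", "LI14", "R7", "R14")

METADATA_COLUMNS = ("sample_id", "mouse_id", "group", "cage", "sex", "timepoint")


def phase_of(timepoint: str) -> str:
    """Map a time-point label to its dietary phase.

    ``T0`` -> ``"conventional"``, ``B*`` -> ``"baseline"``, ``LI*`` ->
    ``"challenge"``, ``R*`` -> ``"repletion"``.
    """
    if timepoint == "T0":
        return "conventional"
    if timepoint.startswith("LI"):
        return "challenge"
    if timepoint.startswith("B"):
        return "baseline"
    if timepoint.startswith("R"):
        return "repletion"
    raise ValueError(f"unrecognized time-point label: {timepoint!r}")


class ParseError(ValueError):
    """Raised for malformed input files; names the offending line."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class OTUTable:
    """Integer count matrix of samples (rows) by OTUs (columns).

    Parameters
    ----------
    sample_ids, otu_ids
        Row / column labels; must be unique.
    counts
        Non-negative integer matrix of shape ``(len(sample_ids), len(otu_ids))``.
    rarefied_depth
        If set, every row must sum to exactly this depth (enforced).
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    rarefied_depth: int | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.otu_ids = list(map(str, self.otu_ids))
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integral")
        counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts = counts
        if self.rarefied_depth is not None:
            sums = counts.sum(axis=1)
            if not np.all(sums == self.rarefied_depth):
                bad = [s for s, t in zip(self.sample_ids, sums) if t != self.rarefied_depth]
                raise ValueError(
                    f"rarefied_depth={self.rarefied_depth} but samples {bad} "
                    "do not sum to it"
                )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_index(sample_id)]

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized counts. Rows with zero total raise."""
        totals = self.counts.sum(axis=1)
        if np.any(totals == 0):
            bad = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValueError(f"samples with zero total reads: {bad}")
        return self.counts / totals[:, None]

    # -- subsetting (never mutates counts of survivors) --------------------
    def select_samples(self, sample_ids: Iterable[str]) -> "OTUTable":
        wanted = list(sample_ids)
        idx = [self.sample_index(s) for s in wanted]
        return OTUTable(wanted, list(self.otu_ids), self.counts[idx],
                        rarefied_depth=self.rarefied_depth)

    def select_otus(self, otu_ids: Iterable[str]) -> "OTUTable":
        wanted = list(otu_ids)
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        missing = [o for o in wanted if o not in pos]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        idx = [pos[o] for o in wanted]
        # column subsetting breaks the equal-row-sum guarantee
        return OTUTable(list(self.sample_ids), wanted, self.counts[:, idx])

    def drop_otus(self, otu_ids: Iterable[str]) -> "OTUTable":
        drop = set(otu_ids)
        keep = [o for o in self.otu_ids if o not in drop]
        return self.select_otus(keep)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OTUTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
            and self.rarefied_depth == other.rarefied_depth
        )


@dataclass
class SampleMetadata:
    """Per-sample experimental annotations.

    Wraps a DataFrame with columns ``sample_id, mouse_id, group, cage, sex,
    timepoint``.  Sample ids are unique and each ``(mouse_id, timepoint)``
    pair occurs at most once.
    """

    df: pd.DataFrame
    timepoint_order: tuple[str, ...] = TIMEPOINT_ORDER

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        df = df[list(METADATA_COLUMNS)].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dup}")
        pairs = df[["mouse_id", "timepoint"]]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].itertuples(index=False)
            raise ValueError(
                "duplicate (mouse_id, timepoint) pairs: "
                + ", ".join(f"({m}, {t})" for m, t in dup)
            )
        unknown = sorted(set(df["timepoint"]) - set(self.timepoint_order))
        if unknown:
            raise ValueError(f"unknown time points {unknown}; expected one of "
                             f"{list(self.timepoint_order)}")
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def timepoints_present(self) -> list[str]:
        present = set(self.df["timepoint"])
        return [t for t in self.timepoint_order if t in present]

    def samples_at(self, timepoint: str, group: str | None = None) -> list[str]:
        sel = self.df["timepoint"] == timepoint
        if group is not None:
            sel &= self.df["group"] == group
        return self.df.loc[sel, "sample_id"].tolist()

    def for_samples(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        wanted = list(sample_ids)
        sub = self.df.set_index("sample_id").loc[wanted].reset_index()
        return SampleMetadata(sub, timepoint_order=self.timepoint_order)

    def column_for(self, sample_ids: Iterable[str], column: str) -> list[str]:
        lut = self.df.set_index("sample_id")[column]
        return [lut[s] for s in sample_ids]

    def groups(self) -> list[str]:
        return sorted(set(self.df["group"]))


@dataclass
class TaxonomyMap:
    """OTU id -> ranked lineage ``[(taxon, confidence), ...]`` from domain down."""

    lineages: dict[str, list[tuple[str, float | None]]] = field(default_factory=dict)

    def domain(self, otu_id: str) -> str | None:
        lin = self.lineages.get(otu_id)
        if not lin:
            return None
        return lin[0][0]

    def is_unclassified_at_domain(self, otu_id: str) -> bool:
        dom = self.domain(otu_id)
        if dom is None:
            return True
        return dom.lower() in {"unknown", "unclassified", "unknown_domain"}

    def lineage_contains(self, otu_id: str, name: str) -> bool:
        lin = self.lineages.get(otu_id, [])
        target = name.lower()
        return any(taxon.lower() == target for taxon, _ in lin)


# ---------------------------------------------------------------------------
# mothur shared format
# ---------------------------------------------------------------------------

def read_shared(path: str | Path) -> OTUTable:
    """Read a mothur ``.shared`` table (``label Group numOtus Otu...``)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "label" or header[1] != "Group" or header[2] != "numOtus":
        raise ParseError(
            f"{path}:1: expected header starting with 'label\\tGroup\\tnumOtus', "
            f"got {header[:3]}"
        )
    otu_ids = header[3:]
    _check_unique(otu_ids, "OTU")
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3 + len(otu_ids):
            raise ParseError(
                f"{path}:{lineno}: expected {3 + len(otu_ids)} fields, got {len(fields)}"
            )
        group = fields[1]
        if group in seen:
            raise ParseError(f"{path}:{lineno}: duplicate Group {group!r}")
        seen.add(group)
        try:
            num_otus = int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: numOtus {fields[2]!r} is not an integer") from None
        if num_otus != len(otu_ids):
            raise ParseError(
                f"{path}:{lineno}: numOtus={num_otus} inconsistent with "
                f"{len(otu_ids)} OTU columns"
            )
        try:
            row = [int(x) for x in fields[3:]]
        except ValueError:
            bad = next(x for x in fields[3:] if not re.fullmatch(r"[+-]?\d+", x))
            raise ParseError(f"{path}:{lineno}: non-integer count {bad!r}") from None
        if any(x < 0 for x in row):
            raise ParseError(f"{path}:{lineno}: negative count")
        sample_ids.append(group)
        rows.append(row)
    if not sample_ids:
        raise ParseError(f"{path}: no sample rows")
    return OTUTable(sample_ids, otu_ids, np.array(rows, dtype=np.int64))


def write_shared(table: OTUTable, path: str | Path, label: str = "0.03") -> None:
    """Write an :class:`OTUTable` as a mothur ``.shared`` file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(["label", "Group", "numOtus", *table.otu_ids]) + "\n")
        for sid, row in zip(table.sample_ids, table.counts):
            fh.write("\t".join([label, sid, str(table.n_otus),
                                *(str(int(x)) for x in row)]) + "\n")


# ---------------------------------------------------------------------------
# plain TSV / metadata / taxonomy
# ---------------------------------------------------------------------------

def read_table_tsv(path: str | Path) -> OTUTable:
    """Read a plain samples-by-OTUs TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OTUTable(list(df.index.astype(str)), list(df.columns.astype(str)),
                    df.to_numpy())


def write_table_tsv(table: OTUTable, path: str | Path) -> None:
    table.to_dataframe().rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path,
                  timepoint_order: tuple[str, ...] = TIMEPOINT_ORDER) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df, timepoint_order=timepoint_order)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.df.to_csv(path, sep="\t", index=False)


_TAXON_RE = re.compile(r"^(?P<name>.*?)(?:\((?P<conf>\d+(?:\.\d+)?)\))?$")


def parse_lineage(text: str) -> list[tuple[str, float | None]]:
    """Parse ``Bacteria(100);Firmicutes(98);...;`` into (taxon, confidence) pairs."""
    out: list[tuple[str, float | None]] = []
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        m = _TAXON_RE.match(part)
        assert m is not None
        conf = m.group("conf")
        out.append((m.group("name"), float(conf) if conf is not None else None))
    return out


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a mothur ``.cons.taxonomy`` TSV (``OTU  Size  Taxonomy``)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if header[:1] != ["otu"] or "taxonomy" not in header:
        raise ParseError(f"{path}:1: expected 'OTU\\tSize\\tTaxonomy' header")
    tax_col = header.index("taxonomy")
    lineages: dict[str, list[tuple[str, float | None]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) <= tax_col:
            raise ParseError(f"{path}:{lineno}: too few fields")
        otu = fields[0]
        if otu in lineages:
            raise ParseError(f"{path}:{lineno}: duplicate OTU {otu!r}")
        lineages[otu] = parse_lineage(fields[tax_col])
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("OTU\tSize\tTaxonomy\n")
        for otu, lin in taxonomy.lineages.items():
            text = ";".join(
                f"{name}({conf:g})" if conf is not None else name for name, conf in lin
            )
            fh.write(f"{otu}\t0\t{text};\n")
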