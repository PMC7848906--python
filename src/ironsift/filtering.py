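"""Post-clustering table filtering and rarefaction.

Order of operations in the canonical pipeline is fixed: unwanted-taxon
removal, then rare-OTU filtering, then rarefaction.  Filtering steps only
change membership — counts of surviving entries are never altered.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .tables import OTUTable, TaxonomyMap

logger = logging.getLogger(__name__)

#: Lineage names whose presence anywhere in an OTU's classification flags it
#: for removal (host organellar and non-bacterial signal).
UNWANTED_TAXA = ("Mitochondria", "Chloroplast", "Eukaryota")


def remove_unwanted_taxa(table: OTUTable, taxonomy: TaxonomyMap) -> OTUTable:
    """Drop OTUs classified to mitochondria, chloroplasts or Eukaryota, or
    left unclassified at the domain level.

    OTUs absent from ``taxonomy`` are treated as unclassified at the domain
    level and removed.  An empty result is permitted.
    """
    keep = []
    for otu in table.otu_ids:
        if taxonomy.is_unclassified_at_domain(otu):
            continue
        if any(taxonomy.lineage_contains(otu, name) for name in UNWANTED_TAXA):
            continue
        keep.append(otu)
    dropped = table.n_otus - len(keep)
    if dropped:
        logger.info("remove_unwanted_taxa: dropped %d of %d OTUs", dropped, table.n_otus)
    return table.select_otus(keep)


def filter_rare_otus(table: OTUTable, min_total_reads: int = 100) -> OTUTable:
    """Drop OTUs whose dataset-wide total is below ``min_total_reads``.

    Totals exactly at the threshold are retained ("fewer than" is strict).
    """
    totals = table.counts.sum(axis=0)
    keep = [otu for otu, t in zip(table.otu_ids, totals) if t >= min_total_reads]
    return table.select_otus(keep)


def rarefy(
    table: OTUTable,
    depth: int = 10_000,
    seed: int | np.random.Generator | None = None,
    return_dropped: bool = False,
) -> OTUTable | tuple[OTUTable, list[str]]:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Each retained row is a single multivariate-hypergeometric draw from the
    sample's reads.  Samples with fewer than ``depth`` total reads are
    dropped (and logged); if all samples fall below depth an error is raised.
    Identical seeds give identical output.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    kept_ids: list[str] = []
    dropped: list[str] = []
    rows: list[np.ndarray] = []
    for sid, row, total in zip(table.sample_ids, table.counts, totals):
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth, method="marginals"))
        kept_ids.append(sid)
    if not kept_ids:
        raise ValueError(
            f"all {table.n_samples} samples have fewer than {depth} reads; "
            "nothing to rarefy"
        )
    if dropped:
        logger.warning("rarefy: dropped %d samples below depth %d: %s",
                       len(dropped), depth, ", ".join(dropped))
    out = OTUTable(kept_ids, list(table.otu_ids),
                   np.vstack(rows), rarefied_depth=depth)
    if return_dropped:
        return out, dropped
    return out
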