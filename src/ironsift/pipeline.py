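"""End-to-end pipeline: filter -> rarefy -> diversity -> paired stats ->
PERMANOVA/NMDS per transition -> four selections -> pseudo-F-reduction
evaluation -> sensitivity classification, with a provenance manifest.

The pipeline is a pure function of (inputs, config, seeds): identical
configurations produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import calls_table, classify_sensitivity
from .diversity import distance_matrix, diversity_table, write_distance_tsv
from .evaluation import EvaluationRecord, compare_techniques, evaluate_selection, records_table
from .filtering import filter_rare_otus, rarefy, remove_unwanted_taxa
from .nmds import nmds
from .permanova import permanova
from .selection import (select_indval, select_multiple_ttest,
                        select_presence_absence, select_random_forest)
from .simulate import GroundTruth, SimulationConfig, generate_cohort
from .stats import comparisons_table, sequential_paired_comparisons
from .tables import (OTUTable, SampleMetadata, TIMEPOINT_ORDER, phase_of,
                     read_metadata, read_shared, read_table_tsv, read_taxonomy,
                     write_metadata, write_shared, write_table_tsv)

DEFAULT_TRANSITIONS = (("T0", "B7"), ("B14", "LI7"), ("LI14", "R7"))


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def simulate_groups(
    sim_config: Mapping[str, Any] | Sequence[Mapping[str, Any]],
) -> tuple[OTUTable, SampleMetadata, dict[str, GroundTruth]]:
    """Simulate one or several experimental groups and merge them.

    ``sim_config`` is a config dict for :class:`SimulationConfig`, or a list
    of them (one per group; each should set ``group_label`` and ``seed``).
    """
    cfgs = [sim_config] if isinstance(sim_config, Mapping) else list(sim_config)
    tables, metas, truths = [], [], {}
    for raw in cfgs:
        cfg = SimulationConfig(**{k: tuple(v) if k == "timepoints" else v
                                  for k, v in dict(raw).items()})
        table, meta, truth = generate_cohort(cfg)
        tables.append(table)
        metas.append(meta)
        truths[cfg.group_label] = truth
    if len(tables) == 1:
        table, meta = tables[0], metas[0]
    else:
        otu_ids = tables[0].otu_ids
        for t in tables[1:]:
            if t.otu_ids != otu_ids:
                raise ValueError("all simulated groups must share the same OTU set")
        table = OTUTable(
            [s for t in tables for s in t.sample_ids], list(otu_ids),
            np.vstack([t.counts for t in tables]),
        )
        meta = SampleMetadata(pd.concat([m.df for m in metas], ignore_index=True))
    return table, meta, truths


def _load_inputs(inputs: Mapping[str, Any]) -> tuple[OTUTable, SampleMetadata, Any]:
    path = Path(inputs["table"])
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("label\tGroup\tnumOtus"):
        table = read_shared(path)
    else:
        table = read_table_tsv(path)
    metadata = read_metadata(inputs["metadata"])
    taxonomy = read_taxonomy(inputs["taxonomy"]) if inputs.get("taxonomy") else None
    return table, metadata, taxonomy


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict:
    """Execute the full analysis described by ``config`` into ``out_dir``.

    ``config`` contains either a ``simulation`` block (dict or list of
    dicts) or an ``inputs`` block (``table``, ``metadata``, optional
    ``taxonomy`` paths), plus optional ``filtering``, ``rarefaction``,
    ``transitions``, ``permanova``, ``nmds``, ``selection`` and
    ``classification`` blocks.  Returns the report bundle (also written to
    disk, including a ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"version": __version__, "config": _jsonable(config),
                               "stages": []}

    # -- input / simulation ------------------------------------------------
    @_stage("input")
    def load():
        if "simulation" in config:
            table, meta, truths = simulate_groups(config["simulation"])
            for label, truth in truths.items():
                truth.to_json(out / f"ground_truth_{label}.json")
            return table, meta, None
        if "inputs" in config:
            table, meta, taxonomy = _load_inputs(config["inputs"])
            return table, meta, taxonomy
        raise ValueError("config needs a 'simulation' or 'inputs' block")

    table, metadata, taxonomy = load()
    manifest["stages"].append({"stage": "input", "n_samples": table.n_samples,
                               "n_otus": table.n_otus})

    # -- filtering ---------------------------------------------------------
    @_stage("filtering")
    def do_filter(table: OTUTable) -> OTUTable:
        if taxonomy is not None:
            table = remove_unwanted_taxa(table, taxonomy)
        min_reads = int(config.get("filtering", {}).get("min_total_reads", 100))
        return filter_rare_otus(table, min_total_reads=min_reads)

    table = do_filter(table)
    manifest["stages"].append({"stage": "filtering", "n_otus": table.n_otus})

    # -- rarefaction -------------------------------------------------------
    rare_cfg = config.get("rarefaction", {})
    depth = int(rare_cfg.get("depth", 10_000))
    rare_seed = rare_cfg.get("seed", 0)

    @_stage("rarefaction")
    def do_rarefy(table: OTUTable):
        return rarefy(table, depth=depth, seed=rare_seed, return_dropped=True)

    table, dropped = do_rarefy(table)
    metadata = metadata.for_samples(table.sample_ids)
    write_shared(table, out / "otu_table.shared")
    write_table_tsv(table, out / "otu_table.tsv")
    write_metadata(metadata, out / "metadata.tsv")
    manifest["stages"].append({"stage": "rarefaction", "depth": depth,
                               "seed": rare_seed, "dropped_samples": dropped,
                               "n_samples": table.n_samples})

    # -- alpha diversity + sequential paired tests -------------------------
    @_stage("diversity")
    def do_diversity():
        div = diversity_table(table)
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)
        values = dict(zip(div["sample_id"], div["inverse_simpson"]))
        comps = sequential_paired_comparisons(values, metadata)
        comparisons_table(comps).to_csv(out / "alpha_comparisons.tsv",
                                        sep="\t", index=False)
        return div

    do_diversity()
    manifest["stages"].append({"stage": "diversity"})

    # -- transitions: PERMANOVA + NMDS -------------------------------------
    present = set(metadata.timepoints_present())
    transitions = [tuple(t) for t in config.get("transitions", DEFAULT_TRANSITIONS)]
    transitions = [t for t in transitions if set(t) <= present]
    perm_cfg = config.get("permanova", {})
    n_perm = int(perm_cfg.get("permutations", 999))
    perm_seed = perm_cfg.get("seed", 0)
    nmds_cfg = config.get("nmds", {})

    @_stage("ordination_permanova")
    def do_ordination():
        results = {}
        for tp_a, tp_b in transitions:
            samples = metadata.samples_at(tp_a) + metadata.samples_at(tp_b)
            sub = table.select_samples(samples)
            dm = distance_matrix(sub)
            labels = metadata.column_for(samples, "timepoint")
            res = permanova(dm, labels, n_permutations=n_perm, seed=perm_seed)
            ord_ = nmds(dm, k=int(nmds_cfg.get("k", 2)),
                        n_starts=int(nmds_cfg.get("n_starts", 20)),
                        seed=nmds_cfg.get("seed", 0))
            key = f"{tp_a}-{tp_b}"
            results[key] = {"permanova": res.as_dict(), "nmds_stress": ord_.stress}
            coords = pd.DataFrame(ord_.coordinates, index=ord_.ids,
                                  columns=[f"NMDS{i+1}" for i in range(ord_.coordinates.shape[1])])
            coords.rename_axis("sample_id").to_csv(out / f"nmds_{key}.tsv", sep="\t")
        (out / "permanova.json").write_text(
            json.dumps(results, indent=2, sort_keys=True) + "\n")
        return results

    permanova_results = do_ordination()
    manifest["stages"].append({"stage": "ordination_permanova",
                               "transitions": ["->".join(t) for t in transitions],
                               "permutations": n_perm, "seed": perm_seed})

    # -- OTU selection + evaluation ----------------------------------------
    sel_cfg = config.get("selection", {})
    alpha = float(sel_cfg.get("alpha", 0.05))
    sel_seed = sel_cfg.get("seed", 0)
    rf_cfg = sel_cfg.get("rf", {})
    iv_cfg = sel_cfg.get("indval", {})
    tt_cfg = sel_cfg.get("ttest", {})

    @_stage("selection")
    def do_selection():
        selections = []
        records: list[EvaluationRecord] = []
        for group in metadata.groups():
            for tp_a, tp_b in transitions:
                samples = (metadata.samples_at(tp_a, group)
                           + metadata.samples_at(tp_b, group))
                if not samples:
                    continue
                sub = table.select_samples(samples)
                labels = metadata.column_for(samples, "timepoint")
                subjects = metadata.column_for(samples, "mouse_id")
                tr = (tp_a, tp_b)
                sels = [
                    select_random_forest(
                        sub, labels, n_trees=int(rf_cfg.get("n_trees", 100)),
                        importance_null_reps=int(rf_cfg.get("importance_null_reps", 50)),
                        n_repeats=int(rf_cfg.get("n_repeats", 3)),
                        alpha=alpha, seed=sel_seed, transition=tr),
                    select_indval(
                        sub, labels,
                        n_permutations=int(iv_cfg.get("n_permutations", 999)),
                        alpha=alpha, seed=sel_seed, transition=tr),
                    select_presence_absence(sub, labels, transition=tr),
                    select_multiple_ttest(
                        sub, labels,
                        correction=tt_cfg.get("correction", "bonferroni"),
                        alpha=alpha, paired=bool(tt_cfg.get("paired", True)),
                        subjects=subjects, transition=tr),
                ]
                for sel in sels:
                    selections.append({"group": group, **sel.as_dict()})
                    try:
                        rec = evaluate_selection(
                            table, metadata, tr, sel, n_permutations=n_perm,
                            seed=perm_seed, group=group)
                    except ValueError:
                        continue
                    records.append(rec)
        (out / "selections.json").write_text(
            json.dumps(selections, indent=2, sort_keys=True) + "\n")
        records_table(records).to_csv(out / "evaluation.tsv", sep="\t", index=False)
        comparison = compare_techniques(records) if records else {"pairwise": [], "summary": []}
        (out / "technique_comparison.json").write_text(
            json.dumps(comparison, indent=2, sort_keys=True) + "\n")
        return selections, records, comparison

    selections, records, comparison = do_selection()
    manifest["stages"].append({"stage": "selection", "alpha": alpha,
                               "seed": sel_seed, "n_selections": len(selections)})

    # -- sensitivity classification ----------------------------------------
    cls_cfg = config.get("classification", {})
    baseline_tps = [t for t in cls_cfg.get("baseline", ("B7", "B14")) if t in present]
    li_tps = [t for t in cls_cfg.get("challenge", ("LI7", "LI14")) if t in present]
    repletion_tps = [t for t in cls_cfg.get("repletion", ("R7", "R14")) if t in present]

    @_stage("classification")
    def do_classification():
        calls = classify_sensitivity(
            table, metadata, baseline_tps, li_tps, repletion_tps,
            appreciable_min_prevalence=float(cls_cfg.get("appreciable_min_prevalence", 0.5)),
            appreciable_min_relabund=float(cls_cfg.get("appreciable_min_relabund", 0.001)),
            undetectable_frac=float(cls_cfg.get("undetectable_frac", 0.5)),
            recovery_min_prevalence=float(cls_cfg.get("recovery_min_prevalence", 0.5)),
        )
        calls_table(calls).to_csv(out / "sensitivity_calls.tsv", sep="\t", index=False)
        return calls

    calls = do_classification()
    manifest["stages"].append({
        "stage": "classification",
        "baseline": baseline_tps, "challenge": li_tps, "repletion": repletion_tps,
        "n_sensitive": sum(1 for c in calls if c.status.startswith("sensitive")),
    })

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "table": table, "metadata": metadata,
        "permanova": permanova_results, "selections": selections,
        "evaluation": records, "comparison": comparison, "calls": calls,
        "manifest": manifest,
    }


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
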