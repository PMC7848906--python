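"""Synthetic longitudinal cohorts with planted ground truth.

Counts are Dirichlet-multinomial draws around per-mouse expected
compositions: log-normal baseline OTU abundances with additive mouse and
cage random effects on the log scale, a diet-shift log-fold-change applied
from the first post-T0 time point onward, and a sensitivity log-fold-change
applied to planted iron-sensitive OTUs during the challenge phase (and kept
through repletion for the non-recovering subset).  All randomness flows
from a single seeded generator, so identical configurations give identical
cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import OTUTable, SampleMetadata, phase_of
from .stats import CtRecord


@dataclass
class SimulationConfig:
    """Parameters of a simulated cohort; see module docstring for the model."""

    n_otus: int = 300
    n_mice: int = 10
    n_cages: int = 2
    timepoints: tuple[str, ...] = ("T0", "B7", "B14", "LI7", "LI14", "R7", "R14")
    library_size_mean: float = 20_000.0
    library_size_dispersion: float = 0.0  # log-normal sigma of library sizes
    base_abundance_logmean: float = 0.0
    base_abundance_logsd: float = 1.5
    diet_shift_fraction: float = 0.0
    diet_shift_logfc_sd: float = 1.0
    n_sensitive: int = 0
    n_recovering: int = 0
    sensitivity_logfc: float = -15.0
    sensitive_abundance_quantile: float = 0.5  # plant sensitives above this base-abundance quantile
    mouse_effect_sd: float = 0.3
    cage_effect_sd: float = 0.15
    overdispersion: float = 200.0  # Dirichlet concentration; inf = multinomial
    group_label: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.n_recovering <= self.n_sensitive <= self.n_otus):
            raise ValueError("need 0 <= n_recovering <= n_sensitive <= n_otus")
        if self.n_otus < 1 or self.n_mice < 1 or self.n_cages < 1:
            raise ValueError("n_otus, n_mice and n_cages must be positive")
        if self.n_cages > self.n_mice:
            raise ValueError("more cages than mice")
        tps = tuple(self.timepoints)
        if not tps or len(set(tps)) != len(tps):
            raise ValueError("timepoints must be non-empty and unique")
        for tp in tps:
            phase_of(tp)  # raises on unknown labels
        for name in ("library_size_dispersion", "base_abundance_logsd",
                     "diet_shift_logfc_sd", "mouse_effect_sd", "cage_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.diet_shift_fraction <= 1.0):
            raise ValueError("diet_shift_fraction must be in [0, 1]")
        if not (0.0 <= self.sensitive_abundance_quantile < 1.0):
            raise ValueError("sensitive_abundance_quantile must be in [0, 1)")
        if not (self.overdispersion > 0):
            raise ValueError("overdispersion must be positive (inf for multinomial)")
        if self.library_size_mean < 1:
            raise ValueError("library_size_mean must be >= 1")
        if self.n_sensitive > 0 and not any(phase_of(t) == "challenge" for t in tps):
            raise ValueError(
                "config plants sensitive OTUs but timepoints contain no "
                "challenge (LI) time point"
            )


@dataclass
class GroundTruth:
    """Planted effect sets and per-phase true log-fold-changes."""

    sensitive_otus: set[str] = field(default_factory=set)
    recovering_otus: set[str] = field(default_factory=set)
    diet_shift_otus: set[str] = field(default_factory=set)
    #: phase name -> {otu_id -> log-fold-change}; phases "diet_shift"
    #: (post-T0, persistent), "challenge" and "repletion".
    log_fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.recovering_otus <= self.sensitive_otus:
            raise ValueError("recovering_otus must be a subset of sensitive_otus")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sensitive_otus": sorted(self.sensitive_otus),
            "recovering_otus": sorted(self.recovering_otus),
            "diet_shift_otus": sorted(self.diet_shift_otus),
            "log_fold_changes": self.log_fold_changes,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            sensitive_otus=set(payload["sensitive_otus"]),
            recovering_otus=set(payload["recovering_otus"]),
            diet_shift_otus=set(payload["diet_shift_otus"]),
            log_fold_changes=payload["log_fold_changes"],
        )


def _otu_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"Otu{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(
    config: SimulationConfig,
) -> tuple[OTUTable, SampleMetadata, GroundTruth]:
    """Simulate one experimental group: one sample per mouse per time point."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_otus, n_mice = config.n_otus, config.n_mice
    otu_ids = _otu_ids(n_otus)

    base = rng.normal(config.base_abundance_logmean, config.base_abundance_logsd, n_otus)

    # planted sensitive OTUs come from the upper part of the base-abundance
    # distribution so they are appreciable at baseline
    sens_idx = np.array([], dtype=int)
    if config.n_sensitive:
        cutoff = np.quantile(base, config.sensitive_abundance_quantile)
        candidates = np.flatnonzero(base >= cutoff)
        sens_idx = rng.choice(candidates, size=config.n_sensitive, replace=False)
    recov_idx = sens_idx[: config.n_recovering]

    n_shift = int(round(config.diet_shift_fraction * n_otus))
    pool = np.setdiff1d(np.arange(n_otus), sens_idx)
    n_shift = min(n_shift, len(pool))
    shift_idx = rng.choice(pool, size=n_shift, replace=False) if n_shift else np.array([], dtype=int)
    shift_lfc = np.zeros(n_otus)
    shift_lfc[shift_idx] = rng.normal(0.0, config.diet_shift_logfc_sd, n_shift)

    mouse_eff = rng.normal(0.0, config.mouse_effect_sd, (n_mice, n_otus))
    cage_eff = rng.normal(0.0, config.cage_effect_sd, (config.n_cages, n_otus))
    cage_of_mouse = np.array([i * config.n_cages // n_mice for i in range(n_mice)])

    sens_lfc = np.zeros(n_otus)
    sens_lfc[sens_idx] = config.sensitivity_logfc
    repl_lfc = np.zeros(n_otus)
    non_recovering = np.setdiff1d(sens_idx, recov_idx)
    repl_lfc[non_recovering] = config.sensitivity_logfc

    mouse_ids = [f"{config.group_label}_M{i + 1:02d}" for i in range(n_mice)]
    sexes = ["F" if cage_of_mouse[i] % 2 == 0 else "M" for i in range(n_mice)]

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    counts = np.zeros((n_mice * len(config.timepoints), n_otus), dtype=np.int64)
    row = 0
    for m in range(n_mice):
        for tp in config.timepoints:
            phase = phase_of(tp)
            log_theta = base + mouse_eff[m] + cage_eff[cage_of_mouse[m]]
            if tp != "T0":
                log_theta = log_theta + shift_lfc
            if phase == "challenge":
                log_theta = log_theta + sens_lfc
            elif phase == "repletion":
                log_theta = log_theta + repl_lfc
            p = np.exp(log_theta - log_theta.max())
            p /= p.sum()
            if config.library_size_dispersion == 0:
                lib = int(round(config.library_size_mean))
            else:
                sigma = config.library_size_dispersion
                mu = np.log(config.library_size_mean) - 0.5 * sigma ** 2
                lib = max(1, int(round(rng.lognormal(mu, sigma))))
            if np.isinf(config.overdispersion):
                theta = p
            else:
                theta = rng.dirichlet(p * config.overdispersion)
                total = theta.sum()
                theta = p if total <= 0 else theta / total
            counts[row] = rng.multinomial(lib, theta)
            sid = f"{mouse_ids[m]}_{tp}"
            sample_ids.append(sid)
            meta_rows.append({
                "sample_id": sid,
                "mouse_id": mouse_ids[m],
                "group": config.group_label,
                "cage": f"{config.group_label}_C{cage_of_mouse[m] + 1}",
                "sex": sexes[m],
                "timepoint": tp,
            })
            row += 1

    table = OTUTable(sample_ids, otu_ids, counts)
    metadata = SampleMetadata(pd.DataFrame(meta_rows),
                              timepoint_order=tuple(config.timepoints))
    truth = GroundTruth(
        sensitive_otus={otu_ids[i] for i in sens_idx},
        recovering_otus={otu_ids[i] for i in recov_idx},
        diet_shift_otus={otu_ids[i] for i in shift_idx},
        log_fold_changes={
            "diet_shift": {otu_ids[i]: float(shift_lfc[i]) for i in shift_idx},
            "challenge": {otu_ids[i]: config.sensitivity_logfc for i in sens_idx},
            "repletion": {otu_ids[i]: config.sensitivity_logfc for i in non_recovering},
        },
    )
    return table, metadata, truth


# ---------------------------------------------------------------------------
# auxiliary measurements
# ---------------------------------------------------------------------------

def generate_iron_measurements(
    metadata: SampleMetadata,
    phase_means: Mapping[str, tuple[float, float]],
    seed: int | None = None,
) -> pd.DataFrame:
    """Log-normal per-sample iron measurements with phase-specific means.

    ``phase_means`` maps a phase name (``conventional``, ``baseline``,
    ``challenge``, ``repletion``) to ``(log10_mean, log10_sd)``; the value
    drawn for a sample is ``10 ** Normal(log10_mean, log10_sd)``, so with
    ``sd == 0`` every sample takes the phase mean exactly.
    """
    if metadata.df.empty:
        raise ValueError("metadata is empty")
    for phase, (_, sd) in phase_means.items():
        if sd < 0:
            raise ValueError(f"negative sd for phase {phase!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in metadata.df.itertuples(index=False):
        phase = phase_of(rec.timepoint)
        if phase not in phase_means:
            raise KeyError(f"phase_means lacks an entry for phase {phase!r}")
        mean, sd = phase_means[phase]
        rows.append({
            "sample_id": rec.sample_id,
            "mouse_id": rec.mouse_id,
            "timepoint": rec.timepoint,
            "phase": phase,
            "iron": float(10.0 ** rng.normal(mean, sd)),
        })
    return pd.DataFrame(rows)


def generate_ct_records(
    groups: Mapping[str, Sequence[str]],
    true_fold_changes: Mapping[tuple[str, str], float],
    noise_sd: float,
    seed: int | None = None,
    reference_gene: str = "Actb",
    target_base_ct: float = 24.0,
    reference_base_ct: float = 18.0,
) -> list[CtRecord]:
    """Simulate qPCR Ct values so the comparative-Ct estimator is unbiased.

    ``groups`` maps arm name (``treatment`` / ``control``) to animal ids;
    ``true_fold_changes`` maps ``(gene, tissue)`` to the fold change of the
    treatment arm relative to control (> 0).  Treatment-arm target Ct values
    are shifted down by ``log2(fold_change)`` so that
    ``2 ** (-ddCt) == fold_change`` when ``noise_sd == 0``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for key in ("treatment", "control"):
        if key not in groups:
            raise ValueError(f"groups must contain arm {key!r}")
    for (gene, tissue), fc in true_fold_changes.items():
        if not fc > 0:
            raise ValueError(f"fold change for ({gene}, {tissue}) must be > 0, got {fc}")
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    tissues = sorted({tissue for _, tissue in true_fold_changes})
    for arm, animals in groups.items():
        for animal in animals:
            for tissue in tissues:
                records.append(CtRecord(
                    animal=str(animal), tissue=tissue, gene=reference_gene,
                    ct=float(reference_base_ct + rng.normal(0.0, noise_sd)),
                    role="reference", arm=arm,
                ))
            for (gene, tissue), fc in true_fold_changes.items():
                shift = -np.log2(fc) if arm == "treatment" else 0.0
                records.append(CtRecord(
                    animal=str(animal), tissue=tissue, gene=gene,
                    ct=float(target_base_ct + shift + rng.normal(0.0, noise_sd)),
                    role="target", arm=arm,
                ))
    return records


def ct_records_table(records: Sequence[CtRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
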