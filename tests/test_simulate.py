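import numpy as np
import pytest

from ironsift.filtering import rarefy
from ironsift.simulate import (GroundTruth, SimulationConfig, generate_cohort,
                               generate_ct_records, generate_iron_measurements)
from ironsift.stats import ddct_fold_change, paired_wilcoxon


class TestConfigValidation:
    def test_recovering_exceeds_sensitive(self):
        with pytest.raises(ValueError, match="n_recovering"):
            SimulationConfig(n_sensitive=2, n_recovering=3,
                             timepoints=("B14", "LI7")).validate()

    def test_sensitive_without_li_timepoint(self):
        with pytest.raises(ValueError, match="challenge"):
            SimulationConfig(n_sensitive=1, timepoints=("T0", "B7")).validate()

    def test_negative_sd(self):
        with pytest.raises(ValueError, match=">= 0"):
            SimulationConfig(mouse_effect_sd=-0.1).validate()

    def test_duplicate_timepoints(self):
        with pytest.raises(ValueError, match="unique"):
            SimulationConfig(timepoints=("B7", "B7")).validate()

    def test_ground_truth_subset_invariant(self):
        with pytest.raises(ValueError, match="subset"):
            GroundTruth(sensitive_otus={"a"}, recovering_otus={"a", "b"})


class TestGenerateCohort:
    def test_deterministic(self):
        cfg = SimulationConfig(n_otus=50, n_mice=4, n_sensitive=2,
                               n_recovering=1, seed=9)
        t1, m1, g1 = generate_cohort(cfg)
        t2, m2, g2 = generate_cohort(cfg)
        assert t1 == t2
        assert m1.df.equals(m2.df)
        assert g1.sensitive_otus == g2.sensitive_otus
        assert g1.log_fold_changes == g2.log_fold_changes

    def test_one_sample_per_mouse_per_timepoint(self):
        cfg = SimulationConfig(n_otus=30, n_mice=5, seed=0)
        t, m, _ = generate_cohort(cfg)
        assert t.n_samples == 5 * 7
        counts = m.df.groupby(["mouse_id", "timepoint"]).size()
        assert (counts == 1).all()

    def test_row_sums_match_drawn_library_sizes(self):
        cfg = SimulationConfig(n_otus=40, n_mice=3, library_size_mean=5000,
                               library_size_dispersion=0.0, seed=1)
        t, _, _ = generate_cohort(cfg)
        assert np.all(t.counts.sum(axis=1) == 5000)

    def test_cage_structure(self):
        cfg = SimulationConfig(n_otus=20, n_mice=10, n_cages=2, seed=0)
        _, m, _ = generate_cohort(cfg)
        per_cage = m.df.groupby("cage")["mouse_id"].nunique()
        assert sorted(per_cage) == [5, 5]

    def test_extreme_logfc_undetectable_at_li(self):
        cfg = SimulationConfig(n_otus=100, n_mice=6, n_sensitive=3,
                               sensitivity_logfc=-20.0,
                               sensitive_abundance_quantile=0.7,
                               library_size_mean=10_000, seed=2)
        t, m, g = generate_cohort(cfg)
        li_samples = m.samples_at("LI7") + m.samples_at("LI14")
        sub = t.select_samples(li_samples).select_otus(sorted(g.sensitive_otus))
        assert sub.counts.sum() == 0

    def test_null_config_exchangeable_across_timepoints(self):
        # with all effects zero, per-OTU pooled relative abundance differs
        # across time points only by sampling error (binomial CI check)
        cfg = SimulationConfig(
            n_otus=30, n_mice=12, timepoints=("B14", "LI7"),
            diet_shift_fraction=0.0, n_sensitive=0, mouse_effect_sd=0.0,
            cage_effect_sd=0.0, overdispersion=np.inf,
            library_size_mean=20_000, seed=3)
        t, m, _ = generate_cohort(cfg)
        for tp in ("B14", "LI7"):
            assert len(m.samples_at(tp)) == 12
        tot_a = t.select_samples(m.samples_at("B14")).counts.sum(axis=0)
        tot_b = t.select_samples(m.samples_at("LI7")).counts.sum(axis=0)
        n_a, n_b = tot_a.sum(), tot_b.sum()
        p_hat = (tot_a + tot_b) / (n_a + n_b)
        se = np.sqrt(p_hat * (1 - p_hat) * (1 / n_a + 1 / n_b))
        z = np.abs(tot_a / n_a - tot_b / n_b) / np.maximum(se, 1e-12)
        # 30 OTUs, ~4-sigma family bound
        assert np.max(z) < 4.5

    def test_recovering_vs_nonrecovering_at_repletion(self):
        cfg = SimulationConfig(n_otus=100, n_mice=8, n_sensitive=4,
                               n_recovering=2, sensitivity_logfc=-20.0,
                               sensitive_abundance_quantile=0.7, seed=4)
        t, m, g = generate_cohort(cfg)
        r_samples = m.samples_at("R7") + m.samples_at("R14")
        recovering = sorted(g.recovering_otus)
        lost = sorted(g.sensitive_otus - g.recovering_otus)
        rec_counts = t.select_samples(r_samples).select_otus(recovering).counts
        lost_counts = t.select_samples(r_samples).select_otus(lost).counts
        assert rec_counts.sum() > 0
        assert lost_counts.sum() == 0

    def test_mean_realized_logfc_matches_planted(self):
        # Monte-Carlo oracle over 50 replicate cohorts: the realized B->LI
        # log-fold-change of planted OTUs is an (almost) unbiased estimate
        # of sensitivity_logfc; a small positive renormalization offset is
        # absorbed by keeping the planted mass small.
        target = -1.0
        reps = 50
        estimates = []
        for r in range(reps):
            cfg = SimulationConfig(
                n_otus=300, n_mice=10, timepoints=("B14", "LI7"),
                n_sensitive=3, n_recovering=0, sensitivity_logfc=target,
                sensitive_abundance_quantile=0.5, overdispersion=5000.0,
                mouse_effect_sd=0.25, library_size_mean=50_000, seed=1000 + r)
            t, m, g = generate_cohort(cfg)
            rel = t.relative_abundance()
            idx = [t.otu_ids.index(o) for o in sorted(g.sensitive_otus)]
            rows_b = [t.sample_index(s) for s in m.samples_at("B14")]
            rows_l = [t.sample_index(s) for s in m.samples_at("LI7")]
            ra_b = rel[np.ix_(rows_b, idx)].mean(axis=0)
            ra_l = rel[np.ix_(rows_l, idx)].mean(axis=0)
            estimates.append(np.mean(np.log(ra_l / ra_b)))
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(reps)
        assert abs(estimates.mean() - target) < 2 * mc_se

    def test_deep_suppression_undetectable_in_most_mice(self):
        # planted logfc <= -10 => zero counts in > 50% of mice at LI
        for seed in range(10):
            cfg = SimulationConfig(n_otus=200, n_mice=10, n_sensitive=4,
                                   sensitivity_logfc=-10.0,
                                   sensitive_abundance_quantile=0.6,
                                   library_size_mean=10_000, seed=seed)
            t, m, g = generate_cohort(cfg)
            tr = rarefy(t, depth=10_000, seed=seed)
            li_tps = ("LI7", "LI14")
            for otu in g.sensitive_otus:
                j = tr.otu_ids.index(otu)
                undet = 0
                mice = sorted(set(m.df["mouse_id"]))
                for mouse in mice:
                    rows = [tr.sample_index(s) for tp in li_tps
                            for s in m.samples_at(tp)
                            if m.column_for([s], "mouse_id")[0] == mouse
                            and s in tr.sample_ids]
                    if rows and all(tr.counts[r, j] == 0 for r in rows):
                        undet += 1
                assert undet > len(mice) / 2


class TestIronMeasurements:
    PHASES = {"conventional": (2.0, 0.0), "baseline": (2.0, 0.0),
              "challenge": (1.0, 0.0), "repletion": (2.0, 0.0)}

    def test_zero_sd_exact_phase_means(self, metadata_factory):
        md = metadata_factory(["a", "b"], ["m1", "m1"], ["B14", "LI7"])
        df = generate_iron_measurements(md, self.PHASES, seed=0)
        assert df.loc[df.timepoint == "B14", "iron"].iloc[0] == pytest.approx(100.0)
        assert df.loc[df.timepoint == "LI7", "iron"].iloc[0] == pytest.approx(10.0)

    def test_deterministic(self, metadata_factory):
        md = metadata_factory(["a", "b"], ["m1", "m1"], ["B14", "LI7"])
        phases = {k: (v[0], 0.3) for k, v in self.PHASES.items()}
        d1 = generate_iron_measurements(md, phases, seed=5)
        d2 = generate_iron_measurements(md, phases, seed=5)
        assert d1.equals(d2)

    def test_negative_sd_rejected(self, metadata_factory):
        md = metadata_factory(["a"], ["m1"], ["B14"])
        with pytest.raises(ValueError, match="negative sd"):
            generate_iron_measurements(md, {"baseline": (2.0, -0.1)}, seed=0)

    def test_wilcoxon_power_on_separated_phases(self, metadata_factory):
        mice = [f"m{i}" for i in range(10)]
        sample_ids = [f"{m}_{tp}" for m in mice for tp in ("B14", "LI14")]
        md = metadata_factory(sample_ids, [m for m in mice for _ in range(2)],
                              ["B14", "LI14"] * 10)
        phases = {"baseline": (2.0, 0.2), "challenge": (1.0, 0.2)}
        rejections = 0
        reps = 200
        for r in range(reps):
            df = generate_iron_measurements(md, phases, seed=r)
            vals = df.set_index("sample_id")["iron"]
            a = {m: np.log10(vals[f"{m}_B14"]) for m in mice}
            b = {m: np.log10(vals[f"{m}_LI14"]) for m in mice}
            _, p = paired_wilcoxon(a, b)
            rejections += p < 0.05
        assert rejections / reps > 0.9


class TestCtRecords:
    def test_fold_one_noise_free(self):
        recs = generate_ct_records({"treatment": ["t1"], "control": ["c1"]},
                                   {("Dcytb", "duodenum"): 1.0}, 0.0, seed=0)
        res = ddct_fold_change(recs, "Dcytb", "duodenum")
        assert res.fold_change == pytest.approx(1.0)

    def test_fold_four_gives_ddct_minus_two(self):
        recs = generate_ct_records({"treatment": ["t1"], "control": ["c1"]},
                                   {("Fpn", "duodenum"): 4.0}, 0.0, seed=0)
        res = ddct_fold_change(recs, "Fpn", "duodenum")
        assert res.ddct == pytest.approx(-2.0)
        assert res.fold_change == pytest.approx(4.0)

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            generate_ct_records({"treatment": ["t"], "control": ["c"]},
                                {("g", "t"): 0.0}, 0.1, seed=0)

    def test_estimator_nearly_unbiased_with_noise(self):
        # 500-rep simulation oracle: mean recovered FC within 5% of 2
        animals = [f"a{i}" for i in range(5)]
        controls = [f"c{i}" for i in range(5)]
        fcs = []
        for r in range(500):
            recs = generate_ct_records(
                {"treatment": animals, "control": controls},
                {("Dmt1", "duodenum"): 2.0}, noise_sd=0.1, seed=r)
            fcs.append(ddct_fold_change(recs, "Dmt1", "duodenum").fold_change)
        assert abs(np.mean(fcs) - 2.0) / 2.0 < 0.05

    def test_deterministic(self):
        kw = dict(groups={"treatment": ["t"], "control": ["c"]},
                  true_fold_changes={("g", "x"): 2.0}, noise_sd=0.5, seed=3)
        r1 = generate_ct_records(**kw)
        r2 = generate_ct_records(**kw)
        assert [(a.animal, a.ct) for a in r1] == [(a.animal, a.ct) for a in r2]


def test_ground_truth_json_round_trip(tmp_path):
    g = GroundTruth(sensitive_otus={"a", "b"}, recovering_otus={"a"},
                    diet_shift_otus={"c"},
                    log_fold_changes={"challenge": {"a": -15.0, "b": -15.0}})
    path = tmp_path / "truth.json"
    g.to_json(path)
    back = GroundTruth.from_json(path)
    assert back.sensitive_otus == g.sensitive_otus
    assert back.recovering_otus == g.recovering_otus
    assert back.log_fold_changes == g.log_fold_changes
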