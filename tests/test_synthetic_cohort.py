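import math

import numpy as np
import pandas as pd
import pytest

from icpnet import synthetic_cohort as sc
from icpnet.preprocess import FilterRule, filter_by_flags


def _design(n_genes=50):
    return sc.CohortDesign(n_genes=n_genes)


class TestDesignInvariants:
    def test_pooling_arithmetic_enforced(self):
        with pytest.raises(ValueError, match="pool_size"):
            sc.CohortDesign(individuals_per_group=9)

    def test_strata_ordering_enforced(self):
        with pytest.raises(ValueError, match="strata"):
            sc.CohortDesign(
                bile_acid_strata={
                    "healthy": (0, 20),
                    "mild": (10, 40),
                    "severe": (40, math.inf),
                }
            )

    def test_planted_fc_below_min_rejected(self):
        with pytest.raises(ValueError, match="log2"):
            sc.PlantedEffects(de_genes={"mild_vs_healthy": {"g00001": 0.2}})

    def test_overlapping_modules_rejected(self):
        m1 = sc.Module(genes=("g00001",), loadings={"g00001": 0.8})
        m2 = sc.Module(genes=("g00001",), loadings={"g00001": 0.9})
        with pytest.raises(ValueError, match="overlap"):
            sc.PlantedEffects(modules=[m1, m2])


class TestSimulateIndividuals:
    def test_degenerate_noise_gives_baseline(self):
        d = _design()
        e = sc.PlantedEffects(seed=0, individual_sd=0.0, baseline_gene_sd=0.0)
        ind = sc.simulate_individuals(d, e)
        assert np.allclose(ind.to_numpy(), e.baseline_log2_mean)

    def test_planted_lfc_recovered_in_group_means(self):
        # Monte-Carlo: 200 individuals per group, lfc=1 in severe
        d = sc.CohortDesign(
            n_genes=50, individuals_per_group=200, pool_size=100, arrays_per_group=2
        )
        e = sc.PlantedEffects(
            seed=5, de_genes={"severe_vs_healthy": {"g00007": 1.0}}, individual_sd=0.5
        )
        ind = sc.simulate_individuals(d, e)
        grp = np.array(d.individual_groups())
        row = ind.loc["g00007"].to_numpy()
        diff = row[grp == "severe"].mean() - row[grp == "healthy"].mean()
        se = 0.5 * math.sqrt(2 / 200)
        assert abs(diff - 1.0) < 3 * se

    def test_same_seed_bitwise_identical(self):
        d = _design()
        e = sc.make_standard_effects(d, seed=3, n_de_mild=5, n_de_severe=5, module_size=5)
        a = sc.simulate_individuals(d, e)
        b = sc.simulate_individuals(d, e)
        assert a.equals(b)

    def test_unknown_planted_gene_named_in_error(self):
        d = _design()
        e = sc.PlantedEffects(de_genes={"severe_vs_healthy": {"gXXXXX": 1.0}})
        with pytest.raises(ValueError, match="gXXXXX"):
            sc.simulate_individuals(d, e)


class TestPooling:
    def test_identical_individuals_pool_to_themselves(self):
        d = _design()
        e = sc.PlantedEffects(seed=0, individual_sd=0.0, baseline_gene_sd=1.0)
        ind = sc.simulate_individuals(d, e)
        m = sc.pool_samples(ind, d, measurement_sd=0.0)
        assert np.allclose(m.values.to_numpy(), ind.to_numpy()[:, :1])

    def test_linear_scale_mean(self):
        # linear values {2, 4} pool to linear 3 -> log2(3)
        d = sc.CohortDesign(
            n_genes=1, group_labels=("healthy",), individuals_per_group=2,
            pool_size=2, arrays_per_group=1,
            bile_acid_strata={"healthy": (0, 10)},
        )
        ind = pd.DataFrame(
            [[1.0, 2.0]], index=["g00000"], columns=["healthy_01", "healthy_02"]
        )
        m = sc.pool_samples(ind, d, measurement_sd=0.0)
        assert m.values.iloc[0, 0] == pytest.approx(math.log2(3.0), abs=1e-12)

    def test_pooled_group_mean_tracks_planted_lfc(self):
        # over 50 seeds the severe-vs-healthy pooled-array difference ~ 1
        diffs = []
        d = _design(n_genes=20)
        for seed in range(50):
            e = sc.PlantedEffects(
                seed=seed, de_genes={"severe_vs_healthy": {"g00003": 1.0}}
            )
            ind = sc.simulate_individuals(d, e)
            m = sc.pool_samples(ind, d, measurement_sd=e.measurement_sd, seed=seed)
            g = m.values.loc["g00003"]
            arrays = m.groups()
            diffs.append(g[arrays["severe"]].mean() - g[arrays["healthy"]].mean())
        # per-seed sd ~ sqrt(2*(0.5^2/5 + 0.2^2)) ~ 0.42 -> SE over 50 seeds
        assert abs(np.mean(diffs) - 1.0) < 3 * 0.42 / math.sqrt(50)

    def test_bad_partition_rejected(self):
        d = _design()
        e = sc.PlantedEffects(seed=0)
        ind = sc.simulate_individuals(d, e).drop(columns=["healthy_01"])
        with pytest.raises(ValueError, match="partition"):
            sc.pool_samples(ind, d)


class TestFlags:
    def _matrix(self, n_genes=1000, seed=0):
        d = _design(n_genes)
        e = sc.PlantedEffects(seed=seed)
        return sc.pool_samples(sc.simulate_individuals(d, e), d)

    def test_prob_one_all_detected(self):
        m = self._matrix(100)
        flags = sc.simulate_flags(m, {1.0: 1.0})
        assert flags.all().all()

    def test_prob_zero_none_detected_and_filter_empty(self):
        m = self._matrix(100)
        m.flags = sc.simulate_flags(m, {1.0: 0.0})
        assert not m.flags.any().any()
        kept = filter_by_flags(m, FilterRule(2, 6))
        assert kept.n_genes == 0

    def test_binomial_tail_at_half(self):
        # P(>=2 detections of 6 at p=0.5) = 1 - 0.5^6 - 6*0.5^6 = 0.890625
        m = self._matrix(1000, seed=7)
        flags = sc.simulate_flags(m, {1.0: 0.5}, seed=7)
        frac = (flags.sum(axis=1) >= 2).mean()
        expected = 0.890625
        se = math.sqrt(expected * (1 - expected) / 1000)
        assert abs(frac - expected) < 3 * se

    def test_malformed_probability_rejected(self):
        m = self._matrix(10)
        with pytest.raises(ValueError, match="malformed"):
            sc.simulate_flags(m, {1.0: 1.5})


class TestAnnotation:
    def test_full_fraction_forces_de_count(self):
        d = _design(10_000)
        e = sc.make_standard_effects(
            d, seed=2, n_de_mild=50, n_de_severe=100, frac_shared=0.5,
            n_modules=0, plant_hub=False, n_enriched_terms=1, enriched_fraction=1.0,
        )
        ann = sc.simulate_annotation(d, e, planted_term_size=20)
        planted = set(ann.loc[ann["term"] == "PT000", "gene"])
        assert len(planted) == 20
        assert planted <= e.de_union()

    def test_no_planted_terms_empty_truth(self):
        d = _design(200)
        e = sc.PlantedEffects(seed=1)
        ann = sc.simulate_annotation(d, e, n_background_terms=0)
        assert ann.empty

    def test_fraction_exceeding_de_pool_rejected(self):
        d = _design(200)
        e = sc.PlantedEffects(seed=1, enriched_terms={"PT000": 1.0})
        with pytest.raises(ValueError, match="PT000"):
            sc.simulate_annotation(d, e, planted_term_size=50)


class TestQpcr:
    def test_zero_noise_inverts_to_planted_fold(self):
        from icpnet.validation_stats import ddct_fold_change

        d = _design()
        truth = sc.CohortTruth(true_de={"mild_vs_healthy": {"g00001": 1.0}})
        q = sc.simulate_qpcr(truth, d, genes=["g00001"], ct_sd=0.0)
        res = ddct_fold_change(q, run_anova=False)
        mild = res.per_individual.query("group == 'mild'")["fold"]
        assert np.allclose(mild, 2.0)

    def test_zero_effect_all_folds_one(self):
        from icpnet.validation_stats import ddct_fold_change

        d = _design()
        truth = sc.CohortTruth(true_de={})
        q = sc.simulate_qpcr(truth, d, genes=["g00001"], ct_sd=0.0)
        res = ddct_fold_change(q, run_anova=False)
        assert np.allclose(res.per_individual["fold"], 1.0)

    def test_noisy_estimate_within_3se_of_planted(self):
        from icpnet.validation_stats import ddct_fold_change

        d = _design()
        truth = sc.CohortTruth(true_de={"mild_vs_healthy": {"g00001": 1.0}})
        folds = []
        for seed in range(20):
            q = sc.simulate_qpcr(truth, d, genes=["g00001"], ct_sd=0.2, seed=seed)
            res = ddct_fold_change(q, run_anova=False)
            folds.append(
                res.per_group.query("group == 'mild'")["mean_fold"].iloc[0]
            )
        se = np.std(folds, ddof=1) / math.sqrt(len(folds))
        assert abs(np.mean(folds) - 2.0) < 3 * se


class TestMorphometry:
    def test_zero_mean_all_zero(self):
        d = _design()
        means = {g: {m: 0.0 for m in ("capillaries", "villi", "cd45", "cd3", "cd19")}
                 for g in d.group_labels}
        tab = sc.simulate_morphometry(d, means)
        assert (tab[["capillaries", "villi", "cd45", "cd3", "cd19"]] == 0).all().all()

    def test_negative_mean_rejected(self):
        d = _design()
        with pytest.raises(ValueError, match="negative"):
            sc.simulate_morphometry(d, {"healthy": {"capillaries": -1.0}})

    def test_same_seed_identical(self):
        d = _design()
        assert sc.simulate_morphometry(d, seed=4).equals(
            sc.simulate_morphometry(d, seed=4)
        )

    def test_poisson_ratio_centers_on_mean_ratio(self):
        from icpnet.validation_stats import capillaries_per_villus

        d = _design()
        ratios = []
        for seed in range(20):
            tab = sc.simulate_morphometry(d, seed=seed)
            res = capillaries_per_villus(tab, run_anova=False)
            ratios.append(
                res.per_placenta.query("group == 'healthy'")["value"].mean()
            )
        se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 3.0) < 3 * se


class TestTruthRoundTrip:
    def test_json_lossless(self, tmp_path):
        from icpnet import io_formats as io

        d = _design(300)
        e = sc.make_standard_effects(d, seed=9, n_de_mild=10, n_de_severe=10, module_size=5)
        truth = sc.truth_from_effects(e)
        io.write_json(truth.to_dict(), tmp_path / "t.json")
        back = sc.CohortTruth.from_dict(io.read_json(tmp_path / "t.json"))
        assert back.to_dict() == truth.to_dict()
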