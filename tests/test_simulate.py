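"""Generator correctness: determinism, planted structure, closed forms."""

import numpy as np
import pandas as pd
import pytest

import oncohub as oh
from oncohub.config import ConfigError
from oncohub.simulate import loewe_combo_fa, logistic_curve, median_effect_fa


class TestDeterminism:
    def test_identical_seed_and_config_bit_identical(self, small_config):
        a = oh.simulate_all(small_config.sim)
        b = oh.simulate_all(small_config.sim)
        pd.testing.assert_frame_equal(a.compendium.values, b.compendium.values)
        pd.testing.assert_frame_equal(a.sga, b.sga)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        pd.testing.assert_frame_equal(a.dose_response, b.dose_response)
        assert a.truth.hub_genes == b.truth.hub_genes
        assert a.truth.regulated_genes == b.truth.regulated_genes

    def test_different_seeds_differ(self, small_config):
        import dataclasses
        a = oh.generate_compendium(small_config.sim)[0]
        other = dataclasses.replace(small_config.sim, seed=99)
        b = oh.generate_compendium(other)[0]
        assert not np.allclose(a.values, b.values)


class TestCompendium:
    def test_noiseless_factor_model_perfect_within_module_correlation(self):
        cfg = oh.SimConfig(seed=5, noise_sd=0.0, batch_sd=0.0, n_genes=300,
                           n_modules=2, module_sizes=(40, 40),
                           trait_effect=(0.5, 0.0))
        comp, _, truth = oh.generate_compendium(cfg)
        genes = [g for g, m in truth.module_of_gene.items() if m == 1]
        corr = np.corrcoef(comp.values.loc[genes].to_numpy())
        np.testing.assert_allclose(np.abs(corr), 1.0, atol=1e-9)

    def test_within_module_correlation_exceeds_between(self, default_study):
        comp = default_study.compendium
        truth = default_study.truth
        m1 = [g for g, m in truth.module_of_gene.items() if m == 1][:30]
        m2 = [g for g, m in truth.module_of_gene.items() if m == 2][:30]
        x1 = comp.values.loc[m1].to_numpy()
        x2 = comp.values.loc[m2].to_numpy()
        within = np.abs(np.corrcoef(x1)[np.triu_indices(30, 1)]).mean()
        between = np.abs(np.corrcoef(x1, x2)[:30, 30:]).mean()
        assert within > between
        # regression guard for the planted-correlation gap at the default seed
        assert within - between > 0.3

    def test_null_trait_config_has_no_trait_correlation(self):
        cfg = oh.SimConfig(seed=11, n_genes=300, n_modules=2,
                           module_sizes=(40, 40), trait_effect=(0.0, 0.0),
                           samples_per_phenotype={p: 20 for p in
                                                  oh.SimConfig().phenotypes})
        comp, traits, truth = oh.generate_compendium(cfg)
        assert truth.disease_modules == frozenset()
        labels = pd.Series(truth.module_of_gene)
        me = oh.module_eigengenes(comp, oh.ModulePartition(labels))
        out = oh.module_trait_correlation(me, traits[["phenotype_rank"]])
        assert (out["p"] > 0.01).all()  # no module beats chance

    def test_oversized_modules_rejected(self):
        with pytest.raises(ConfigError):
            oh.SimConfig(n_genes=100, n_modules=2, module_sizes=(80, 40),
                         trait_effect=(0.5, 0.0))

    def test_sample_and_dataset_layout(self, default_study):
        comp = default_study.compendium
        assert comp.n_samples == 300
        assert comp.sample_meta["dataset"].nunique() == 8
        assert comp.sample_meta["phenotype"].value_counts().eq(50).all()


class TestPerturbationGenerator:
    def test_regulated_set_structure(self, default_study):
        truth = default_study.truth
        target_label = default_study.config.perturb_module + 1
        module_genes = {g for g, m in truth.module_of_gene.items()
                        if m == target_label}
        in_module = {g for g in truth.regulated_genes if g in module_genes}
        # 75% of the 80-gene module is regulated, all downward upon depletion
        assert len(in_module) == 60
        assert all(truth.regulated_genes[g] == "down" for g in in_module)
        assert not (truth.control_artifact_genes & set(truth.regulated_genes))

    def test_replicate_count_below_two_rejected(self, small_config):
        import dataclasses
        with pytest.raises(ConfigError):
            dataclasses.replace(small_config.sim, perturb_replicates=1)

    def test_null_effect_yields_alpha_level_hits(self):
        import dataclasses
        cfg = dataclasses.replace(oh.SimConfig(seed=21, n_genes=1000,
                                               n_modules=1, module_sizes=(40,),
                                               trait_effect=(0.5,)),
                                  perturb_effect=0.0, extra_regulated_count=0,
                                  control_artifact_count=0)
        _, _, truth = oh.generate_compendium(cfg)
        pert = oh.generate_perturbation(truth, cfg)
        res = oh.differential_expression(pert.target_induced,
                                         pert.target_noninduced, alpha=0.05)
        rate = len(res.significant_set) / 1000
        assert 0.03 < rate < 0.07  # binomial 95% band around alpha

    def test_zero_artifacts_leave_control_filter_idle(self):
        import dataclasses
        cfg = dataclasses.replace(oh.SimConfig(seed=22, n_genes=500,
                                               n_modules=1, module_sizes=(40,),
                                               trait_effect=(0.5,)),
                                  control_artifact_count=0)
        _, _, truth = oh.generate_compendium(cfg)
        pert = oh.generate_perturbation(truth, cfg)
        assert truth.control_artifact_genes == set()
        delta = (pert.control_induced.mean(axis=1)
                 - pert.control_noninduced.mean(axis=1))
        assert abs(delta).max() < 5 * cfg.perturb_noise_sd


class TestSgaGenerator:
    def test_null_interaction_effect_balances_conditions(self):
        import dataclasses
        cfg = dataclasses.replace(oh.SimConfig(seed=31, n_genes=200,
                                               n_modules=1, module_sizes=(40,),
                                               trait_effect=(0.5,)),
                                  n_strains=40, n_interactors=10,
                                  interaction_effect=1.0)
        truth = oh.PlantedTruth()
        sga = oh.generate_sga(truth, cfg)
        hits = oh.call_hits(sga, alpha=0.05)
        assert (hits["category"] != "").mean() < 0.2

    def test_noiseless_suppressor_reduces_fitness(self):
        import dataclasses
        cfg = dataclasses.replace(oh.SimConfig(seed=32, n_genes=200,
                                               n_modules=1, module_sizes=(40,),
                                               trait_effect=(0.5,)),
                                  n_strains=20, n_interactors=10,
                                  interaction_effect=0.5, sga_noise_sd=0.0)
        truth = oh.PlantedTruth()
        sga = oh.generate_sga(truth, cfg)
        fit = oh.growth_fitness(sga)
        for strain, kind in truth.interaction_genes.items():
            grp = fit[fit["strain"] == strain]
            ind = grp.loc[grp["condition"] == "induced", "fitness"].mean()
            non = grp.loc[grp["condition"] == "non_induced", "fitness"].mean()
            if kind == "suppressor":
                assert ind < non
            else:
                assert ind > non

    def test_essentials_absent_from_strain_list(self, default_study):
        strains = set(default_study.sga["strain"])
        assert not (default_study.truth.essential_interactors & strains)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ConfigError):
            oh.SimConfig(interaction_effect=0.0)


class TestPpiGenerator:
    def test_planted_essentials_wired_above_threshold(self, default_study):
        truth = default_study.truth
        net = default_study.network
        primary = set(truth.interaction_genes)
        strong = net[net["confidence"] >= 0.7]
        for e in truth.essential_interactors:
            nbrs = set(strong.loc[strong["geneA"] == e, "geneB"]) \
                 | set(strong.loc[strong["geneB"] == e, "geneA"])
            assert len(nbrs & primary) >= 2

    def test_hub_identity_holds(self, default_study):
        default_study.truth.assert_hub_identity()

    def test_ortholog_map_has_many_to_one_and_unmapped(self, default_study):
        truth = default_study.truth
        ortho = default_study.orthologs
        humans = [h for hs in ortho.values() for h in hs]
        assert len(humans) > len(set(humans))  # many-to-one present
        unmapped = [y for y in truth.interaction_genes if y not in ortho]
        assert unmapped  # some yeast hits have no human ortholog


class TestSurvivalGenerator:
    def test_no_censoring_when_rate_zero(self):
        import dataclasses
        cfg = dataclasses.replace(oh.SimConfig(seed=41), censoring_rate=0.0)
        truth = oh.PlantedTruth(hub_genes={"A", "B"})
        cohort = oh.generate_survival(truth, cfg)
        assert (cohort["event"] == 1).all()

    def test_censoring_rate_approximately_respected(self):
        cfg = oh.SimConfig(seed=42, n_patients=2000)
        truth = oh.PlantedTruth(hub_genes={"A"})
        cohort = oh.generate_survival(truth, cfg)
        censored = 1 - cohort["event"].mean()
        assert censored == pytest.approx(cfg.censoring_rate, abs=0.05)

    def test_altered_patients_recorded_and_shifted(self, default_study):
        truth = default_study.truth
        cohort = default_study.survival.set_index("patient")
        hubs = sorted(truth.hub_genes)
        alt = cohort.loc[sorted(truth.survival_altered_patients), hubs]
        normal = cohort.drop(index=truth.survival_altered_patients)[hubs]
        assert (alt.mean() - normal.mean() > 4).all()

    def test_invalid_hazard_ratio_rejected(self):
        with pytest.raises(ConfigError):
            oh.SimConfig(hazard_ratio=0.0)


class TestDoseResponseGenerator:
    def test_median_effect_closed_form(self):
        assert median_effect_fa(100.0, m=2.0, dm=100.0) == pytest.approx(0.5)
        assert median_effect_fa(200.0, m=2.0, dm=100.0) == pytest.approx(0.8)

    def test_single_agent_rows_follow_median_effect(self, default_study):
        table = default_study.dose_response
        (m1, dm1) = default_study.config.drug_params["drug1"]
        single = table[(table["drug1_dose"] > 0) & (table["drug2_dose"] == 0)]
        expected = median_effect_fa(single["drug1_dose"].to_numpy(), m1, dm1)
        np.testing.assert_allclose(single["fraction_affected"], expected,
                                   atol=1e-12)

    def test_loewe_solution_satisfies_additivity_equation(self):
        fa = loewe_combo_fa(30.0, 120.0, 1.5, 50.0, 2.0, 200.0, alpha=1.0)
        ratio = fa / (1 - fa)
        dx1 = 50.0 * ratio ** (1 / 1.5)
        dx2 = 200.0 * ratio ** (1 / 2.0)
        assert 30.0 / dx1 + 120.0 / dx2 == pytest.approx(1.0, abs=1e-9)

    def test_invalid_combo_alpha_rejected(self):
        with pytest.raises(ConfigError):
            oh.SimConfig(combo_alpha=0.0)
        with pytest.raises(ValueError):
            loewe_combo_fa(1, 1, 1, 1, 1, 1, alpha=-1.0)


class TestLogisticCurve:
    def test_monotone_in_time_and_rate(self):
        t = np.linspace(0, 72, 13)
        slow = logistic_curve(t, 0.05)
        fast = logistic_curve(t, 0.15)
        assert (np.diff(slow) > 0).all()
        assert (fast[1:] > slow[1:]).all()
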