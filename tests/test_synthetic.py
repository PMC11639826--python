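"""Fixture exactness, generator calibration and the planted-partition tool."""

import numpy as np
import pytest
from scipy import stats

import psncohort as pc
from psncohort.synthetic import (
    NS_PATHWAY_COUNTS,
    PLANTED_BLOCK_TEMPLATES,
    S_PATHWAY_COUNTS,
)


class TestRealworldFixture:
    def test_stratum_sizes(self, realworld):
        patients = realworld["cohort"].patients
        assert len(patients) == 142
        ns = [p for p in patients if p.smoking_status is pc.SmokingStatus.NEVER]
        assert len(ns) == 31

    def test_all_22_pathway_count_cells_exact(self, realworld):
        table = pc.pathway_summary(realworld["profiles"], realworld["strata"])
        assert tuple(table["S_count"]) == S_PATHWAY_COUNTS
        assert tuple(table["NS_count"]) == NS_PATHWAY_COUNTS

    def test_ns_high_subgroup_composition(self, realworld):
        fx = realworld["fixture"]
        strata = realworld["strata_by_id"]
        assert len(fx.ns_htmb_ids) == 11
        assert all(strata[pid].subgroup == "NS/H" for pid in fx.ns_htmb_ids)
        ddr = sum(realworld["profiles_by_id"][pid]["ddr"] for pid in fx.ns_htmb_ids)
        assert ddr == 8
        responses = {
            realworld["patients_by_id"][pid].best_response for pid in fx.ns_htmb_ids
        }
        assert responses <= {pc.BestResponse.CR, pc.BestResponse.PR}

    def test_stratum_tmb_medians_match_published(self, realworld):
        patients = realworld["cohort"].patients
        s = [p.tmb for p in patients if p.smoking_status is not pc.SmokingStatus.NEVER]
        ns = [p.tmb for p in patients if p.smoking_status is pc.SmokingStatus.NEVER]
        assert np.median(s) == 8.0
        assert np.median(ns) == 4.0
        nsh = [realworld["patients_by_id"][pid].tmb for pid in realworld["fixture"].ns_htmb_ids]
        assert np.median(nsh) == 16.39

    def test_construction_is_deterministic(self, realworld):
        again = pc.build_realworld_fixture()
        assert again.cohort == realworld["cohort"]
        assert again.ns_htmb_ids == realworld["fixture"].ns_htmb_ids

    def test_profiles_rebuild_from_written_files(self, tmp_path, realworld):
        cohort = realworld["cohort"]
        pc.write_mutations(cohort.mutations, tmp_path / "m.tsv")
        pc.write_clinical(cohort.patients, tmp_path / "c.tsv")
        pc.write_gmt(cohort.catalog, tmp_path / "p.gmt")
        back = pc.Cohort(
            patients=tuple(pc.read_clinical(tmp_path / "c.tsv")),
            mutations=tuple(pc.read_mutations(tmp_path / "m.tsv")),
            catalog=pc.read_gmt(tmp_path / "p.gmt"),
        )
        assert pc.build_pathway_profiles(back) == realworld["profiles"]


class TestGenerateCohort:
    def test_same_seed_identical_output(self):
        cfg = pc.GeneratorConfig(seed=5)
        assert pc.generate_cohort(cfg) == pc.generate_cohort(cfg)

    def test_different_seed_differs(self):
        a = pc.generate_cohort(pc.GeneratorConfig(seed=1))
        b = pc.generate_cohort(pc.GeneratorConfig(seed=2))
        assert a != b

    def test_stratum_sizes_within_binomial_bounds(self):
        cfg = pc.GeneratorConfig(seed=1)
        cohort = pc.generate_cohort(cfg)
        n_s = sum(
            p.smoking_status is not pc.SmokingStatus.NEVER for p in cohort.patients
        )
        lo, hi = stats.binom.ppf([0.005, 0.995], 142, 111 / 142)
        assert lo <= n_s <= hi

    def test_ns_tmb_median_near_configured(self):
        cfg = pc.GeneratorConfig(
            n_patients=1000,
            seed=3,
            planted=pc.PlantedSubgroupConfig(size=0, boosted_probs={}),
        )
        cohort = pc.generate_cohort(cfg)
        ns = [
            p.tmb
            for p in cohort.patients
            if p.smoking_status is pc.SmokingStatus.NEVER
        ]
        assert 2.5 < np.median(ns) < 6.0

    def test_planted_patients_are_exactly_ns_high(self):
        cohort = pc.generate_cohort(pc.GeneratorConfig(seed=9))
        strata = pc.stratify(cohort.patients)
        nsh = [s for s in strata if s.subgroup == "NS/H"]
        assert len(nsh) == 11

    def test_profiles_roundtrip_through_mutation_table(self):
        cohort = pc.generate_cohort(pc.GeneratorConfig(seed=2))
        profiles = pc.build_pathway_profiles(cohort)
        # every sampled pathway bit is backed by >= 1 pathogenic call and
        # benign extras never set bits
        deleterious = pc.filter_deleterious(cohort.mutations)
        by_pid = {}
        for m in deleterious:
            by_pid.setdefault(m.patient_id, set()).update(
                cohort.catalog.pathways_of(m.gene)
            )
        for p in profiles:
            expected = by_pid.get(p.patient_id, set())
            assert {pc.PATHWAY_ORDER[j] for j, b in enumerate(p.x) if b} == expected

    def test_marginal_calibration_over_seeds(self):
        """Empirical smoker pathway frequencies track configured probabilities."""
        cfg0 = pc.GeneratorConfig()
        sums = np.zeros(11)
        total = 0
        no_plant = pc.PlantedSubgroupConfig(size=0, boosted_probs={})
        for seed in range(200):
            cohort = pc.generate_cohort(
                pc.GeneratorConfig(seed=seed, n_patients=40, planted=no_plant)
            )
            profiles = pc.build_pathway_profiles(cohort)
            strata = {s.patient_id: s for s in pc.stratify(cohort.patients)}
            xs = np.array(
                [
                    p.x
                    for p in profiles
                    if strata[p.patient_id].smoking_class == "S"
                ]
            )
            sums += xs.sum(axis=0)
            total += len(xs)
        freq = sums / total
        expected = np.array(cfg0.pathway_probs_s)
        se = np.sqrt(expected * (1 - expected) / total)
        assert (np.abs(freq - expected) <= 3 * se + 1e-9).all()

    def test_infeasible_planted_size_rejected(self):
        cfg = pc.GeneratorConfig(
            n_patients=20,
            smoker_fraction=0.95,
            seed=0,
            planted=pc.PlantedSubgroupConfig(size=11),
        )
        with pytest.raises(ValueError, match="planted"):
            pc.generate_cohort(cfg)

    def test_byte_identical_files_for_same_config(self, tmp_path):
        for sub in ("a", "b"):
            cohort = pc.generate_cohort(pc.GeneratorConfig(seed=4))
            d = tmp_path / sub
            d.mkdir()
            pc.write_mutations(cohort.mutations, d / "m.tsv")
            pc.write_clinical(cohort.patients, d / "c.tsv")
        assert (tmp_path / "a/m.tsv").read_bytes() == (tmp_path / "b/m.tsv").read_bytes()
        assert (tmp_path / "a/c.tsv").read_bytes() == (tmp_path / "b/c.tsv").read_bytes()


class TestPlantedPartition:
    def test_zero_noise_reproduces_templates(self):
        cohort, labels = pc.generate_planted_partition(
            (3, 2, 2, 2), PLANTED_BLOCK_TEMPLATES, 0.0, seed=0
        )
        profiles = pc.build_pathway_profiles(cohort)
        for profile, label in zip(profiles, labels):
            assert profile.x == PLANTED_BLOCK_TEMPLATES[label]

    def test_noise_boundary_rejected(self):
        with pytest.raises(ValueError):
            pc.generate_planted_partition(
                (2, 2, 2, 2), PLANTED_BLOCK_TEMPLATES, 0.5, seed=0
            )

    def test_duplicate_templates_rejected(self):
        templates = (PLANTED_BLOCK_TEMPLATES[0],) * 2
        with pytest.raises(ValueError, match="distinct"):
            pc.generate_planted_partition((2, 2), templates, 0.1, seed=0)

    def test_strong_separation_recovered_end_to_end(self):
        from sklearn.metrics import adjusted_rand_score

        cohort, labels = pc.generate_planted_partition(
            (8, 4, 7, 12), PLANTED_BLOCK_TEMPLATES, 0.05, seed=7
        )
        profiles = pc.build_pathway_profiles(cohort)
        net = pc.build_network(profiles, pc.KernelParams(mu=0.6))
        part = pc.detect_communities(net, seed=7, n_restarts=10)
        pred = [part.assignment[p.patient_id] for p in profiles]
        assert adjusted_rand_score(labels, pred) == 1.0


def test_calibration_targets_are_flagged_irreproducible():
    """External-cohort and patient-level published values are calibration
    inputs only and must never be marked as reproducible claims."""
    assert pc.CALIBRATION_TARGETS  # non-empty
    for name, target in pc.CALIBRATION_TARGETS.items():
        assert target["reproducible"] is False, name
        assert "value" in target and "reason" in target
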