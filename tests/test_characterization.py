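"""Community profiles, TMB contrasts, H-TMB enrichment, profile correlation."""

import numpy as np
import pytest

import psncohort as pc
from tests.test_enrichment import brute_force_upper_tail


def make_partition(assignment):
    return pc.CommunityPartition(
        assignment=assignment, modularity=0.3, resolution=1.0, seed=0, n_restarts=1
    )


def patient(pid, tmb, status=pc.SmokingStatus.NEVER, os_months=10.0, os_event=False):
    return pc.PatientRecord(
        patient_id=pid,
        smoking_status=status,
        tmb=tmb,
        os_months=os_months,
        os_event=os_event,
        pfs_months=os_months / 2,
        pfs_event=os_event,
        best_response=pc.BestResponse.SD,
    )


class TestCommunityProfiles:
    def test_six_of_eight_ddr_is_75_percent(self):
        ddr_idx = pc.PATHWAY_ORDER.index("ddr")
        profiles = []
        for i in range(8):
            bits = [0] * 11
            if i < 6:
                bits[ddr_idx] = 1
            profiles.append(pc.PathwayProfile(f"P{i}", tuple(bits)))
        partition = make_partition({f"P{i}": 0 for i in range(8)})
        (community,) = pc.community_profiles(partition, profiles)
        assert community["ddr"] == 75.0

    def test_singleton_zero_profile(self):
        partition = make_partition({"P0": 0, "P1": 1})
        profiles = [
            pc.PathwayProfile("P0", (0,) * 11),
            pc.PathwayProfile("P1", (1,) * 11),
        ]
        c0, c1 = pc.community_profiles(partition, profiles)
        assert c0.pct_mutated == (0.0,) * 11
        assert c1.pct_mutated == (100.0,) * 11

    def test_whole_ns_community_matches_summary_percentages(self, realworld):
        ns = [
            p
            for p in realworld["profiles"]
            if realworld["strata_by_id"][p.patient_id].smoking_class == "NS"
        ]
        partition = make_partition({p.patient_id: 0 for p in ns})
        (community,) = pc.community_profiles(partition, ns)
        table = pc.pathway_summary(realworld["profiles"], realworld["strata"])
        for j, pathway in enumerate(pc.PATHWAY_ORDER):
            assert community.pct_mutated[j] == pytest.approx(
                table.loc[pathway, "NS_pct"], abs=0.06  # table is rounded to 0.1
            )

    def test_size_weighted_profiles_aggregate_to_cohort(self, realworld):
        ns = realworld["profiles"][:40]
        labels = {p.patient_id: (0 if i < 25 else 1) for i, p in enumerate(ns)}
        communities = pc.community_profiles(make_partition(labels), ns)
        agg = sum(
            np.array(c.pct_mutated) * c.size for c in communities
        ) / sum(c.size for c in communities)
        overall = 100.0 * np.array([p.x for p in ns]).mean(axis=0)
        assert agg == pytest.approx(overall, abs=1e-9)

    def test_mismatched_patients_rejected(self):
        partition = make_partition({"P0": 0})
        with pytest.raises(ValueError):
            pc.community_profiles(partition, [pc.PathwayProfile("P1", (0,) * 11)])


class TestCompareTmb:
    def test_hand_computed_two_group_example(self):
        partition = make_partition(
            {"A0": 0, "A1": 0, "A2": 0, "B0": 1, "B1": 1, "B2": 1}
        )
        patients = [patient(f"A{i}", t) for i, t in enumerate((1, 2, 3))] + [
            patient(f"B{i}", t) for i, t in enumerate((10, 11, 12))
        ]
        result = pc.compare_tmb(partition, patients)
        # ranks 1-3 vs 4-6, no ties: H = 12/42 * (3*1.5^2 + 3*1.5^2) = 27/7
        assert result.statistic == pytest.approx(27 / 7, abs=1e-10)
        assert result.p_value == pytest.approx(0.0495, abs=5e-4)

    def test_identical_groups_give_h_zero(self):
        partition = make_partition(
            {"A0": 0, "A1": 0, "A2": 0, "B0": 1, "B1": 1, "B2": 1}
        )
        patients = [patient(f"A{i}", t) for i, t in enumerate((1, 2, 3))] + [
            patient(f"B{i}", t) for i, t in enumerate((1, 2, 3))
        ]
        result = pc.compare_tmb(partition, patients)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_all_identical_values_degenerate(self):
        partition = make_partition({"A0": 0, "A1": 0, "B0": 1, "B1": 1})
        patients = [patient(p, 5.0) for p in ("A0", "A1", "B0", "B1")]
        result = pc.compare_tmb(partition, patients)
        assert result.degenerate
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_rank_based_invariance_to_monotone_transform(self, realworld):
        ns = [
            p
            for p in realworld["cohort"].patients
            if p.smoking_status is pc.SmokingStatus.NEVER
        ]
        labels = {p.patient_id: (0 if i < 15 else 1) for i, p in enumerate(ns)}
        partition = make_partition(labels)
        raw = pc.compare_tmb(partition, ns)
        transformed = [
            patient(p.patient_id, np.exp(p.tmb / 10.0)) for p in ns
        ]
        assert pc.compare_tmb(partition, transformed).statistic == pytest.approx(
            raw.statistic, abs=1e-10
        )

    def test_single_community_rejected(self):
        partition = make_partition({"A0": 0, "A1": 0})
        with pytest.raises(ValueError):
            pc.compare_tmb(partition, [patient("A0", 1), patient("A1", 2)])


class TestHtmbEnrichment:
    def test_validation_scale_counts_match_oracle(self):
        # community of 57 capturing 14 of 18 high-TMB patients among 140
        assignment = {}
        strata = []
        for i in range(140):
            pid = f"P{i}"
            in_comm = i < 57
            assignment[pid] = 0 if in_comm else 1 + (i % 3)
            high = (i < 14) or (57 <= i < 61)  # 14 inside, 4 outside
            strata.append(
                pc.PatientStratum(patient_id=pid, tmb_class="H" if high else "L", smoking_class="NS")
            )
        result = pc.htmb_enrichment(make_partition(assignment), strata, community=0)
        assert (result.N, result.K, result.n, result.k) == (140, 18, 57, 14)
        assert result.p_value == pytest.approx(
            brute_force_upper_tail(140, 18, 57, 14), abs=1e-12
        )

    def test_zero_high_tmb_in_community_gives_p_one(self, realworld):
        ns_ids = [
            s.patient_id for s in realworld["strata"] if s.smoking_class == "NS"
        ]
        low_ids = [
            s.patient_id
            for s in realworld["strata"]
            if s.smoking_class == "NS" and s.tmb_class == "L"
        ]
        assignment = {pid: (0 if pid in low_ids[:5] else 1) for pid in ns_ids}
        result = pc.htmb_enrichment(
            make_partition(assignment), realworld["strata"], community=0
        )
        assert result.k == 0 and result.p_value == 1.0

    def test_community_of_all_high_tmb_is_minimal_p(self, realworld):
        ns_ids = [
            s.patient_id for s in realworld["strata"] if s.smoking_class == "NS"
        ]
        high_ids = {
            s.patient_id
            for s in realworld["strata"]
            if s.subgroup == "NS/H"
        }
        assignment = {pid: (0 if pid in high_ids else 1) for pid in ns_ids}
        result = pc.htmb_enrichment(
            make_partition(assignment), realworld["strata"], community=0
        )
        assert result.k == result.n == result.K
        # k = K = n is the most extreme possible observation
        assert result.p_value == pytest.approx(
            brute_force_upper_tail(31, 11, 11, 11), abs=1e-15
        )


class TestProfileCorrelation:
    def test_identical_profiles_rho_one(self):
        a = tuple(float(v) for v in range(11))
        result = pc.profile_correlation(a, a, n_permutations=2000, seed=0)
        assert result.rho == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        a = tuple(float(v) for v in range(11))
        b = tuple(reversed(a))
        result = pc.profile_correlation(a, b, n_permutations=2000, seed=0)
        assert result.rho == pytest.approx(-1.0)

    def test_hand_computed_length_four_example(self):
        result = pc.profile_correlation(
            (10, 20, 30, 40), (1, 3, 2, 4), n_permutations=50_000, seed=0
        )
        assert result.rho == pytest.approx(0.8, abs=1e-12)
        # exact permutation null at n=4: P(|rho| >= 0.8) = 8/24
        assert result.p_value == pytest.approx(8 / 24, abs=0.01)

    def test_symmetric(self):
        a = (10.0, 40.0, 20.0, 90.0, 5.0, 0.0, 70.0, 30.0, 60.0, 50.0, 80.0)
        b = (1.0, 5.0, 2.0, 10.0, 0.0, 3.0, 8.0, 4.0, 6.0, 7.0, 9.0)
        ra = pc.profile_correlation(a, b, n_permutations=2000, seed=1)
        rb = pc.profile_correlation(b, a, n_permutations=2000, seed=1)
        assert ra.rho == pytest.approx(rb.rho, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pc.profile_correlation((1.0,) * 11, tuple(float(v) for v in range(11)))
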