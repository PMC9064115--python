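"""Differential abundance/presence testing, FDR control and concordance."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from presabs.diff_features import (
    DiffFeatureRecord,
    bh_fdr,
    concordance,
    fisher_presence_test,
    mannwhitney_test,
    per_disease_aggregation,
    significant_taxa,
)
from presabs.profiles_io import LabeledCohort, ProfileError, ProfileTable
from presabs.synthetic_data import (
    PrevalenceSignal,
    ReadDepth,
    SyntheticSpec,
    simulate_cohort,
    synthetic_taxonomy,
)


def enumerate_mwu_p(case, control):
    """Exact two-sided MWU p by full enumeration of rank assignments."""
    pooled = sorted(case) + sorted(control)
    n1, n2 = len(case), len(control)

    def u_stat(group1):
        u = 0.0
        rest = list(pooled)
        for v in group1:
            rest.remove(v)
        for a in group1:
            for b in rest:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    u_obs = u_stat(list(case))
    center = n1 * n2 / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        group1 = [pooled[i] for i in combo]
        total += 1
        if abs(u_stat(group1) - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


def enumerate_fisher_p(a, n1, b, n2):
    """Two-sided Fisher p by summing hypergeometric masses <= the observed."""
    successes = a + b
    lo = max(0, successes - n2)
    hi = min(n1, successes)

    def mass(x):
        return (
            math.comb(n1, x) * math.comb(n2, successes - x) / math.comb(n1 + n2, successes)
        )

    observed = mass(a)
    return sum(mass(x) for x in range(lo, hi + 1) if mass(x) <= observed * (1 + 1e-9))


def literal_bh(p):
    """Independent literal step-up implementation of Benjamini-Hochberg."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        # cases above all controls: the two most extreme of C(6,3)=20 splits
        assert mannwhitney_test([4, 5, 6], [1, 2, 3]) == pytest.approx(2 / 20)

    def test_identical_multisets_give_one(self):
        assert mannwhitney_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(size=rng.integers(3, 12))
            assert mannwhitney_test(a, b) == pytest.approx(
                mannwhitney_test(b, a), abs=1e-12
            )

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            case, control = pooled[:n1], pooled[n1:]
            assert mannwhitney_test(case, control) == pytest.approx(
                enumerate_mwu_p(case, control), abs=1e-12
            )

    def test_exact_and_asymptotic_agree_where_both_apply(self):
        rng = np.random.default_rng(8)
        from scipy.stats import mannwhitneyu

        for _ in range(20):
            case = rng.normal(size=8)
            control = rng.normal(size=8)
            exact = mannwhitney_test(case, control)
            approx = mannwhitneyu(
                case, control, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(exact - approx) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_test([], [1.0])

    def test_constant_taxon_gives_one(self):
        assert mannwhitney_test([0.0, 0.0], [0.0, 0.0, 0.0]) == 1.0


class TestFisher:
    def test_identical_prevalence_gives_one(self):
        assert fisher_presence_test(5, 10, 5, 10) == pytest.approx(1.0)

    def test_maximal_separation(self):
        # only 2 of the C(20,10) tables are as extreme as 10/10 vs 0/10
        expected = 2 / math.comb(20, 10)
        assert fisher_presence_test(10, 10, 0, 10) == pytest.approx(
            expected, rel=1e-9
        )

    def test_group_and_row_swap_symmetries(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n1, n2 = int(rng.integers(2, 15)), int(rng.integers(2, 15))
            a, b = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            p = fisher_presence_test(a, n1, b, n2)
            assert p == pytest.approx(fisher_presence_test(b, n2, a, n1), rel=1e-9)
            assert p == pytest.approx(
                fisher_presence_test(n1 - a, n1, n2 - b, n2), rel=1e-9
            )

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(40):
            n1, n2 = int(rng.integers(1, 12)), int(rng.integers(1, 12))
            a, b = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            assert fisher_presence_test(a, n1, b, n2) == pytest.approx(
                enumerate_fisher_p(a, n1, b, n2), rel=1e-7, abs=1e-12
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_presence_test(5, 4, 0, 10)


class TestBHFDR:
    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_textbook_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_literal_step_up_and_invariants(self, p):
        q = bh_fdr(p)
        np.testing.assert_allclose(q, literal_bh(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone along sorted p

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        p = rng.random(25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-12)


def make_cohort(values, labels):
    n, k = np.asarray(values).shape
    profile = ProfileTable(
        sample_ids=[f"S{i}" for i in range(n)],
        taxa=synthetic_taxonomy(k),
        values=values,
        rank="species",
    )
    return LabeledCohort(profile=profile, labels=np.asarray(labels), study_id="toy")


class TestSignificantTaxa:
    def test_maximal_separation_significant_in_both_modes(self):
        rng = np.random.default_rng(12)
        n = 40
        labels = np.array([0] * 20 + [1] * 20)
        values = rng.random((n, 6)) * 0.01
        values[:20, 0] = 0.0  # taxon 0: all cases, no controls
        values[20:, 0] = 0.05
        cohort = make_cohort(values / values.sum(1, keepdims=True), labels)
        for mode in ("abundance", "presence"):
            records = significant_taxa(cohort, mode)
            assert records[0].q < 0.05
            assert records[0].direction == "case-enriched"

    def test_constant_zero_taxon_flagged_never_significant(self):
        labels = np.array([0] * 6 + [1] * 6)
        values = np.full((12, 3), 0.5)
        values[:, 2] = 0.0
        cohort = make_cohort(values, labels)
        for mode in ("abundance", "presence"):
            rec = significant_taxa(cohort, mode)[2]
            assert rec.flagged and rec.p_raw == 1.0 and rec.direction == "none"

    def test_null_cohort_has_few_discoveries(self):
        spec = SyntheticSpec(
            n_control=50, n_case=50, n_taxa=300,
            read_depth=ReadDepth(mean_depth=100_000), seed=21,
        )
        cohort = simulate_cohort(spec).cohort
        for mode in ("abundance", "presence"):
            n_sig = sum(r.q < 0.05 for r in significant_taxa(cohort, mode))
            assert n_sig <= 5

    def test_recovers_planted_prevalence_signal(self):
        spec = SyntheticSpec(
            n_control=100, n_case=100, n_taxa=80,
            prevalence_signal=PrevalenceSignal(indices=tuple(range(10)), delta=0.5),
            read_depth=ReadDepth(mean_depth=100_000), seed=22,
        )
        cohort = simulate_cohort(spec).cohort
        records = significant_taxa(cohort, "presence")
        hits = sum(records[j].q < 0.05 for j in range(10))
        assert hits >= 8
        for j in range(10):
            if records[j].q < 0.05:
                assert records[j].direction == "case-enriched"

    def test_significance_sets_shrink_with_alpha(self):
        spec = SyntheticSpec(
            n_control=40, n_case=40, n_taxa=60,
            prevalence_signal=PrevalenceSignal(indices=tuple(range(10)), delta=0.5),
            read_depth=ReadDepth(mean_depth=50_000), seed=23,
        )
        cohort = simulate_cohort(spec).cohort
        sets = []
        for alpha in (0.1, 0.05, 0.01):
            records = significant_taxa(cohort, "presence", alpha=alpha)
            sets.append({r.taxon.source_string for r in records if r.q < alpha})
        assert sets[2] <= sets[1] <= sets[0]


class TestConcordance:
    @staticmethod
    def record(taxon, mode, q, direction):
        return DiffFeatureRecord(
            taxon=taxon, mode=mode, p_raw=q / 2, q=q, direction=direction
        )

    def test_identical_sets_and_directions(self):
        taxa = synthetic_taxonomy(4)
        rec_a = [self.record(t, "abundance", 0.01, "case-enriched") for t in taxa]
        rec_p = [self.record(t, "presence", 0.01, "case-enriched") for t in taxa]
        report = concordance(rec_a, rec_p)
        assert report.shared_fraction == 1.0
        assert report.direction_discrepancy_fraction == 0.0

    def test_disjoint_sets(self):
        taxa = synthetic_taxonomy(4)
        rec_a = [
            self.record(t, "abundance", 0.01 if j < 2 else 0.5, "case-enriched")
            for j, t in enumerate(taxa)
        ]
        rec_p = [
            self.record(t, "presence", 0.01 if j >= 2 else 0.5, "case-enriched")
            for j, t in enumerate(taxa)
        ]
        assert concordance(rec_a, rec_p).shared_fraction == 0.0

    def test_hand_built_counts(self):
        """10 taxa: 6 significant in both, 2 abundance-only, 2 presence-only,
        1 direction flip among the shared -> shared 6/10, discrepancy 1/10."""
        taxa = synthetic_taxonomy(10)
        sig_a = set(range(8))  # 6 shared + 2 abundance-only
        sig_p = set(range(6)) | {8, 9}  # 6 shared + 2 presence-only
        rec_a, rec_p = [], []
        for j, t in enumerate(taxa):
            qa = 0.01 if j in sig_a else 0.5
            qp = 0.01 if j in sig_p else 0.5
            da = "case-enriched"
            dp = "control-enriched" if j == 0 else "case-enriched"  # one flip
            rec_a.append(self.record(t, "abundance", qa, da if qa < 0.05 else "none"))
            rec_p.append(self.record(t, "presence", qp, dp if qp < 0.05 else "none"))
        report = concordance(rec_a, rec_p)
        assert report.n_sig_abundance == 8 and report.n_sig_presence == 8
        assert report.shared_fraction == pytest.approx(6 / 10)
        assert report.direction_discrepancy_fraction == pytest.approx(1 / 10)

    def test_mismatched_universes_rejected(self):
        taxa = synthetic_taxonomy(4)
        rec_a = [self.record(t, "abundance", 0.5, "none") for t in taxa[:3]]
        rec_p = [self.record(t, "presence", 0.5, "none") for t in taxa]
        with pytest.raises(ProfileError):
            concordance(rec_a, rec_p)


class TestPerDiseaseAggregation:
    def test_single_disease_single_dataset(self):
        out = per_disease_aggregation({"CRC": [{"taxonA"}]})
        assert out["taxonA"] == 1.0

    def test_seven_of_nine_diseases(self):
        mapping = {
            f"disease{i}": [{"taxonA"} if i < 7 else {"taxonB"}] for i in range(9)
        }
        out = per_disease_aggregation(mapping)
        assert out["taxonA"] == pytest.approx(7 / 9)

    def test_hit_means_significant_in_at_least_one_dataset(self):
        mapping = {
            "d1": [{"taxonA"}, set(), set()],  # one of three datasets is enough
            "d2": [set(), set()],
            "d3": [{"taxonA", "taxonB"}],
        }
        out = per_disease_aggregation(mapping)
        assert out["taxonA"] == pytest.approx(2 / 3)
        assert out["taxonB"] == pytest.approx(1 / 3)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            per_disease_aggregation({})
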