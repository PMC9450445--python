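"""Carrier 2x2 association tests and phenotype t-tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bavscreen.assoc import (
    DegenerateTableError,
    InsufficientDataError,
    TwoByTwo,
    auto_test,
    carrier_2x2,
    chi2_2x2,
    compare_phenotype_by_gene,
    fisher_2x2,
    gene_panel_association,
    split_by_carrier,
    ttest_from_summary,
)
from bavscreen.cohort_model import (
    GenotypeMatrix,
    PhenotypeRecord,
    PipelineConfig,
    SummaryStat,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration (math.comb)."""
    r1, r2 = a + b, c + d
    k = a + c  # first-column margin
    n = r1 + r2
    denom = math.comb(n, k)

    def prob(x):
        if x < 0 or x > r1 or k - x < 0 or k - x > r2:
            return 0.0
        return math.comb(r1, x) * math.comb(r2, k - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, k) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def gene_matrix(dosage_rows, genes, sample_ids=None):
    dosage = np.array(dosage_rows, dtype=np.int8)
    ids = sample_ids or [f"S{i}" for i in range(dosage.shape[0])]
    keys = [f"1:{100 + j}:C:T" for j in range(dosage.shape[1])]
    return GenotypeMatrix(ids, keys, dosage, genes)


class TestCarrier2x2:
    def test_published_esrrb_counts(self, fixture_cohort, fx):
        g, phenotypes = fixture_cohort
        case_ids = [p.sample_id for p in phenotypes if p.cohort == "validation"]
        control_ids = [p.sample_id for p in phenotypes if p.cohort == "control"]
        t = carrier_2x2(g, "ESRRB", case_ids, control_ids)
        assert (t.a, t.b, t.c, t.d) == (25, 112, 4, 126)

    def test_gene_without_variants_gives_zero_carriers(self):
        g = gene_matrix([[1], [0]], ["GENEA"])
        t = carrier_2x2(g, "GENEB", ["S0"], ["S1"])
        assert (t.a, t.b, t.c, t.d) == (0, 1, 0, 1)

    def test_multivariant_gene_counts_patient_once(self):
        # S0 carries two variants of the same gene: still one carrier
        g = gene_matrix([[1, 1], [0, 1], [0, 0]], ["GX", "GX"])
        t = carrier_2x2(g, "GX", ["S0", "S1"], ["S2"])
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 1)

    def test_all_missing_dosage_is_noncarrier(self):
        g = gene_matrix([[-1], [1]], ["GX"])
        t = carrier_2x2(g, "GX", ["S0", "S1"], [])
        assert (t.a, t.b) == (1, 1)

    def test_unknown_sample_id_raises(self):
        g = gene_matrix([[1]], ["GX"])
        with pytest.raises(KeyError, match="nope"):
            carrier_2x2(g, "GX", ["nope"], [])


class TestChi2:
    @pytest.mark.parametrize(
        "table,p3",
        [
            ((11, 126, 1, 129), 0.004),   # published S100A1 row
            ((14, 123, 2, 128), 0.003),   # published LGR4 row
            ((14, 123, 1, 129), 0.001),   # published WWOX row
        ],
    )
    def test_published_p_values_uncorrected(self, table, p3):
        res = chi2_2x2(TwoByTwo(*table), continuity_correction=False)
        assert round(res.p_value, 3) == p3
        assert res.test_used == "chi2"

    def test_identical_proportions_give_zero_statistic(self):
        res = chi2_2x2(TwoByTwo(5, 5, 5, 5))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi2_2x2(TwoByTwo(0, 10, 0, 10))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30), st.integers(1, 30))
    def test_transpose_and_label_swap_invariance(self, a, b, c, d):
        base = chi2_2x2(TwoByTwo(a, b, c, d))
        transposed = chi2_2x2(TwoByTwo(a, c, b, d))
        swapped = chi2_2x2(TwoByTwo(d, c, b, a))
        assert base.statistic == pytest.approx(transposed.statistic, rel=1e-12)
        assert base.statistic == pytest.approx(swapped.statistic, rel=1e-12)
        assert 0.0 <= base.p_value <= 1.0


class TestFisher:
    def test_enumeration_example_three_tables(self):
        # margins (2,2)x(2,2): tables (2,0,0,2),(1,1,1,1),(0,2,2,0) with
        # probabilities 1/6, 4/6, 1/6 -> p(observed extreme) = 2/6... the
        # two-sided minimum-likelihood sum for the observed (2,0,0,2) is 1/3.
        res = fisher_2x2(TwoByTwo(2, 0, 0, 2))
        assert res.p_value == pytest.approx(1 / 3, rel=1e-7)
        assert res.statistic is None

    def test_degenerate_margin_gives_p_one(self):
        assert fisher_2x2(TwoByTwo(0, 10, 0, 10)).p_value == 1.0

    def test_cohort_scale_table_matches_enumeration(self):
        res = fisher_2x2(TwoByTwo(12, 125, 3, 127))
        assert res.p_value == pytest.approx(fisher_oracle(12, 125, 3, 127), rel=1e-7)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        res = fisher_2x2(TwoByTwo(a, b, c, d))
        assert res.p_value == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12)

    def test_asymptotic_agreement_with_chi2_in_significant_tail(self):
        """For well-populated tables (all expected counts >= 20) the exact and
        asymptotic tests agree closely wherever they reject: the minimum-
        likelihood two-sided Fisher p and the Pearson p differ by at most
        0.02 whenever either is below 0.05.  (Outside the tail the two
        two-sided constructions can legitimately differ by more.)"""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 200:
            a, b, c, d = (int(x) for x in rng.integers(25, 160, size=4))
            t = TwoByTwo(a, b, c, d)
            if t.expected().min() < 20:
                continue
            checked += 1
            p_chi2 = chi2_2x2(t).p_value
            p_fisher = fisher_2x2(t).p_value
            if min(p_chi2, p_fisher) < 0.05:
                assert abs(p_chi2 - p_fisher) <= 0.02


class TestAutoSelection:
    def test_adequate_expected_counts_choose_chi2(self):
        # 12 carriers over 267 patients: min expected 12*130/267 = 5.84
        res = auto_test(TwoByTwo(11, 126, 1, 129), PipelineConfig())
        assert res.test_used == "chi2"

    def test_sparse_table_chooses_fisher(self):
        res = auto_test(TwoByTwo(2, 135, 1, 129), PipelineConfig())
        assert res.test_used == "fisher"

    def test_degenerate_table_takes_fisher_path(self):
        res = auto_test(TwoByTwo(0, 137, 0, 130), PipelineConfig())
        assert res.test_used == "fisher" and res.p_value == 1.0

    def test_threshold_follows_config(self):
        t = TwoByTwo(11, 126, 1, 129)  # min expected 5.84
        assert auto_test(t, PipelineConfig(expected_count_min=6.0)).test_used == "fisher"


class TestTTestFromSummary:
    def test_published_lvef_comparison_significant(self):
        res = ttest_from_summary(
            SummaryStat(50, 63.8, 7.5), SummaryStat(87, 58.4, 5.2), method="welch"
        )
        assert res.p_value < 0.001
        assert res.t > 0

    def test_published_calcification_comparison_significant(self):
        for method in ("welch", "pooled"):
            res = ttest_from_summary(
                SummaryStat(50, 1129.3, 154.0), SummaryStat(87, 1261.8, 123.0), method=method
            )
            assert res.p_value < 0.001
            assert res.t < 0

    def test_identical_groups_give_t_zero_p_one(self):
        s = SummaryStat(30, 5.0, 2.0)
        res = ttest_from_summary(s, s)
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_conventions(self):
        a, b = SummaryStat(5, 1.0, 0.0), SummaryStat(5, 2.0, 0.0)
        res = ttest_from_summary(a, b)
        assert math.isinf(res.t) and res.p_value == 0.0
        same = ttest_from_summary(a, SummaryStat(5, 1.0, 0.0))
        assert same.t == 0.0 and same.p_value == 1.0

    def test_welch_symmetry_under_group_swap(self):
        x, y = SummaryStat(50, 63.8, 7.5), SummaryStat(87, 58.4, 5.2)
        fwd, rev = ttest_from_summary(x, y), ttest_from_summary(y, x)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.df == pytest.approx(rev.df)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 9999),
        n1=st.integers(3, 40),
        n2=st.integers(3, 40),
        shift=st.floats(-3, 3),
    )
    def test_pooled_summary_equals_raw_data_ttest(self, seed, n1, n2, shift):
        """Affine-rescale arbitrary samples to exact n/mean/sd and compare
        the summary-based statistic with scipy on the raw values."""
        from scipy import stats

        rng = np.random.default_rng(seed)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        x = 10.0 + 2.5 * (x - x.mean()) / x.std(ddof=1)
        y = (10.0 + shift) + 1.5 * (y - y.mean()) / y.std(ddof=1)
        raw = stats.ttest_ind(x, y, equal_var=True)
        summ = ttest_from_summary(
            SummaryStat(n1, float(x.mean()), float(x.std(ddof=1))),
            SummaryStat(n2, float(y.mean()), float(y.std(ddof=1))),
            method="pooled",
        )
        assert summ.t == pytest.approx(raw.statistic, rel=1e-9)
        assert summ.p_value == pytest.approx(raw.pvalue, rel=1e-9)


def _patients(n, prefix="V", cohort="validation", lvef=None, calc=None):
    return [
        PhenotypeRecord(
            sample_id=f"{prefix}{i}", cohort=cohort,
            lvef=None if lvef is None else lvef[i],
            calc_volume=None if calc is None else calc[i],
        )
        for i in range(n)
    ]


class TestCarrierStratification:
    def test_fixture_cohort_split_sizes(self, fixture_cohort, fx):
        g, phenotypes = fixture_cohort
        validation = [p for p in phenotypes if p.cohort == "validation"]
        panel = [row.gene for row in fx.table4]
        carriers, noncarriers = split_by_carrier(g, panel, validation)
        assert (len(carriers), len(noncarriers)) == (87, 50)
        assert {p.sample_id for p in carriers}.isdisjoint(
            {p.sample_id for p in noncarriers}
        )

    def test_all_reference_matrix_gives_no_carriers(self):
        g = gene_matrix([[0], [0], [0]], ["GX"])
        patients = _patients(3, prefix="S")
        # sample ids must match the matrix
        patients = [
            PhenotypeRecord(sample_id=f"S{i}", cohort="validation") for i in range(3)
        ]
        carriers, noncarriers = split_by_carrier(g, ["GX"], patients)
        assert (len(carriers), len(noncarriers)) == (0, 3)

    def test_planted_phenotype_shift_detected_only_in_shifted_phenotype(self):
        rng = np.random.default_rng(1)
        n = 120
        carrier = np.zeros(n, dtype=np.int8)
        carrier[:40] = 1
        g = gene_matrix(carrier.reshape(-1, 1), ["TTN"],
                        sample_ids=[f"V{i}" for i in range(n)])
        lvef = np.where(carrier == 1, rng.normal(58.4, 5.2, n), rng.normal(63.8, 7.5, n))
        calc = rng.normal(1200.0, 130.0, n)  # no carrier effect
        patients = _patients(n, lvef=lvef, calc=np.abs(calc))
        shifted = compare_phenotype_by_gene(g, "TTN", patients, "lvef")
        assert shifted.p_value < 0.05
        unshifted = compare_phenotype_by_gene(g, "TTN", patients, "calc_volume")
        assert unshifted.p_value > 0.05

    def test_missing_phenotypes_excluded(self):
        g = gene_matrix([[1], [1], [1], [0], [0], [0]], ["GX"],
                        sample_ids=[f"V{i}" for i in range(6)])
        lvef = [50.0, 51.0, None, 60.0, None, 61.0]
        patients = _patients(6, lvef=lvef)
        res = compare_phenotype_by_gene(g, "GX", patients, "lvef")
        assert res.df == pytest.approx(2, abs=1.0)  # 2+2 usable values

    def test_zero_carriers_is_insufficient_data(self):
        g = gene_matrix([[0], [0], [0], [0]], ["GX"],
                        sample_ids=[f"V{i}" for i in range(4)])
        patients = _patients(4, lvef=[60.0, 61.0, 62.0, 63.0])
        with pytest.raises(InsufficientDataError):
            compare_phenotype_by_gene(g, "GX", patients, "lvef")


class TestGenePanelAssociation:
    def test_published_panel_all_significant(self, fixture_cohort, fx):
        g, phenotypes = fixture_cohort
        panel = [row.gene for row in fx.table4]
        case_ids = [p.sample_id for p in phenotypes if p.cohort == "validation"]
        control_ids = [p.sample_id for p in phenotypes if p.cohort == "control"]
        results = gene_panel_association(g, panel, case_ids, control_ids, PipelineConfig())
        assert [r.gene for r in results] == panel
        for r, row in zip(results, fx.table4):
            assert (r.table.a, r.table.c) == (row.validation_carriers, row.control_carriers)
            assert r.p_value < 0.05

    def test_equal_proportions_give_p_near_one(self):
        rows = [[1]] * 10 + [[0]] * 10 + [[1]] * 10 + [[0]] * 10
        g = gene_matrix(rows, ["GX"], sample_ids=[f"S{i}" for i in range(40)])
        case_ids = [f"S{i}" for i in range(20)]
        control_ids = [f"S{i}" for i in range(20, 40)]
        (res,) = gene_panel_association(g, ["GX"], case_ids, control_ids)
        assert res.p_value > 0.9

    def test_composition_equals_per_gene_calls(self, fixture_cohort, fx):
        g, phenotypes = fixture_cohort
        panel = [row.gene for row in fx.table4]
        case_ids = [p.sample_id for p in phenotypes if p.cohort == "validation"]
        control_ids = [p.sample_id for p in phenotypes if p.cohort == "control"]
        cfg = PipelineConfig(test_policy="fisher")
        results = gene_panel_association(g, panel, case_ids, control_ids, cfg)
        for r in results:
            solo = fisher_2x2(carrier_2x2(g, r.gene, case_ids, control_ids))
            assert r.p_value == pytest.approx(solo.p_value, rel=1e-12)
            assert r.test_used == "fisher"

    def test_bh_adjustment_appended_on_request(self, fixture_cohort, fx):
        g, phenotypes = fixture_cohort
        panel = [row.gene for row in fx.table4]
        case_ids = [p.sample_id for p in phenotypes if p.cohort == "validation"]
        control_ids = [p.sample_id for p in phenotypes if p.cohort == "control"]
        plain = gene_panel_association(g, panel, case_ids, control_ids, PipelineConfig())
        assert all(r.p_adjusted is None for r in plain)
        adjusted = gene_panel_association(
            g, panel, case_ids, control_ids, PipelineConfig(adjust_bh=True)
        )
        for r in adjusted:
            assert r.p_adjusted is not None and r.p_adjusted >= r.p_value - 1e-12
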