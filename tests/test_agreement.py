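"""Lin's CCC, Pearson, Bland-Altman, Cohen's kappa, and the magnitude scale."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from strokeperf.agreement import (
    ContingencyTable,
    PlatformAgreement,
    bland_altman,
    ccc,
    cohens_kappa,
    magnitude_label,
    pearson,
)
from strokeperf.phantom import make_paired_cohort

paired_floats = st.lists(
    st.tuples(st.floats(-100, 100), st.floats(-100, 100)), min_size=3, max_size=40
)


class TestCcc:
    def test_identity_gives_one(self):
        assert ccc([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]).estimate == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_offset_example(self):
        # means 2 and 3, all 1/n variances 2/3, covariance 2/3:
        # ccc = 2*(2/3) / (2/3 + 2/3 + 1) = 4/7
        assert ccc([1, 2, 3], [2, 3, 4]).estimate == pytest.approx(4 / 7, abs=1e-12)

    def test_perfect_anticoncordance(self):
        x, y = [-1.0, 1.0, -1.0, 1.0], [1.0, -1.0, 1.0, -1.0]
        assert ccc(x, y).estimate == pytest.approx(-1.0, abs=1e-12)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="undefined"):
            ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(3, 1, 100)
        y = x * rng.lognormal(0, 0.3, 100)
        est = ccc(x, y)
        assert est.ci_low < est.estimate < est.ci_high
        assert est.ci_high <= 1.0

    @given(paired_floats)
    @settings(max_examples=80, deadline=None)
    def test_ccc_never_exceeds_pearson_magnitude(self, pairs):
        """Precision-accuracy decomposition: |rho_c| <= |r|."""
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if (x == x[0]).all() or (y == y[0]).all():
            return
        assert abs(ccc(x, y).estimate) <= abs(pearson(x, y)) + 1e-9

    def test_symmetric_in_platforms(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert ccc(x, y).estimate == pytest.approx(ccc(y, x).estimate, abs=1e-14)


class TestPearson:
    def test_affine_relation_gives_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(2 * y + 1, y) == pytest.approx(1.0)

    def test_offset_example_contrasts_with_ccc(self):
        assert pearson([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0)

    def test_orthogonal_vectors_zero(self):
        assert pearson([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_inputs(self):
        bias, (lo, hi), _ = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert bias == 0.0 and lo == 0.0 and hi == 0.0

    def test_unit_sd_differences(self):
        # differences (-1, 0, 1): sample SD exactly 1
        bias, (lo, hi), _ = bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert bias == pytest.approx(0.0)
        assert (lo, hi) == (pytest.approx(-1.96), pytest.approx(1.96))

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0]) + 5
        bias, (lo, hi), _ = bland_altman(x, x - 5)
        assert bias == pytest.approx(5.0) and lo == pytest.approx(5.0) and hi == pytest.approx(5.0)

    def test_loa_symmetric_about_bias(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=50), rng.normal(size=50)
        bias, (lo, hi), _ = bland_altman(x, y)
        assert hi - bias == pytest.approx(bias - lo)


class TestKappa:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ([[88, 2], [4, 29]], 0.873),
            ([[28, 0], [2, 7]], 0.841),
            ([[55, 2], [1, 18]], 0.897),
            ([[5, 0], [1, 4]], 0.800),
            ([[86, 15], [4, 58]], 0.761),
        ],
    )
    def test_eligibility_tables_to_three_decimals(self, cells, expected):
        assert round(cohens_kappa(ContingencyTable(cells)).kappa, 3) == expected

    def test_diagonal_table_is_one(self):
        res = cohens_kappa(ContingencyTable([[10, 0], [0, 10]]))
        assert res.kappa == pytest.approx(1.0)

    def test_marginal_independence_gives_zero(self):
        assert cohens_kappa(ContingencyTable([[50, 50], [50, 50]])).kappa == pytest.approx(0.0)

    def test_transpose_symmetry(self):
        t = ContingencyTable([[30, 7], [2, 19]])
        assert cohens_kappa(t).kappa == pytest.approx(cohens_kappa(t.transpose()).kappa)

    def test_ci_truncated_at_one(self):
        res = cohens_kappa(ContingencyTable([[28, 0], [2, 7]]))
        assert res.ci_high == 1.0

    def test_degenerate_marginals_error(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_kappa(ContingencyTable([[10, 0], [0, 0]]))

    @given(st.lists(st.integers(0, 60), min_size=4, max_size=4))
    @settings(max_examples=80, deadline=None)
    def test_matches_reference_implementation(self, cells):
        """Cross-check against scikit-learn on label vectors."""
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        table = ContingencyTable([[a, b], [c, d]])
        y1 = [0] * (a + b) + [1] * (c + d)
        y2 = [0] * a + [1] * b + [0] * c + [1] * d
        if len(set(y1)) < 2 and len(set(y2)) < 2:
            return
        try:
            mine = cohens_kappa(table).kappa
        except ValueError:
            return
        ref = cohen_kappa_score(y1, y2)
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_percent_agreement(self):
        res = cohens_kappa(ContingencyTable([[88, 2], [4, 29]]))
        assert res.percent_agreement == pytest.approx(100 * 117 / 123)


class TestMagnitudeScale:
    @pytest.mark.parametrize(
        "value, label",
        [
            (0.87, "excellent"),
            (0.761, "substantial"),
            (0.20, "poor"),
            (0.80, "substantial"),
            (0.81, "excellent"),
            (0.205, "poor"),  # rounds to 0.20
            (0.50, "moderate"),
            (0.30, "fair"),
            (-0.3, "poor"),
            (1.0, "excellent"),
        ],
    )
    def test_banding(self, value, label):
        assert magnitude_label(value) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            magnitude_label(1.5)


class TestPlatformAgreementModel:
    def test_zero_error_cohort_perfect_statistics(self):
        df = make_paired_cohort(n=50, seed=3, error_log_sd=0.0)
        res = PlatformAgreement(df, measures=("core_ml", "hypoperfused_ml")).fit()
        for rep in res.reports.values():
            assert rep.ccc.estimate == pytest.approx(1.0, abs=1e-12)
            assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)
            assert rep.ba_bias == pytest.approx(0.0, abs=1e-9)

    def test_summary_names_platform_order(self):
        df = make_paired_cohort(n=30, seed=4)
        res = PlatformAgreement(df).fit()
        assert "rapid vs jlk" in res.summary()

    def test_missing_column_rejected(self):
        df = make_paired_cohort(n=30, seed=5)
        with pytest.raises(ValueError, match="missing column"):
            PlatformAgreement(df, measures=("nonexistent",))

    def test_bland_altman_plot_smoke(self):
        import matplotlib

        matplotlib.use("Agg")
        df = make_paired_cohort(n=30, seed=6)
        ax = PlatformAgreement(df).fit().plot_bland_altman("core_ml")
        assert ax.get_title() == "Bland-Altman: core_ml"
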