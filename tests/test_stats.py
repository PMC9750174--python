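"""Reliability, agreement and pooling statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from indentmap.stats import (
    bland_altman,
    compare_groups,
    dataset_accounting,
    icc_absolute_single,
    intra_assay_cv,
    pearson_r,
    percent_change,
    pool_regions,
    site_cv,
)


class TestSiteCV:
    def test_identical_triplicate_zero(self):
        assert site_cv([0.10, 0.10, 0.10]) == pytest.approx(0.0, abs=1e-9)

    def test_one_two_three_is_fifty_percent(self):
        assert site_cv([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_multiplicative_noise_recovers_sigma(self):
        """Triplicates at 5% multiplicative noise average to ~5% CV."""
        rng = np.random.default_rng(2)
        cvs = [site_cv(0.2 * (1 + 0.05 * rng.standard_normal(3)))
               for _ in range(1000)]
        # E[CV] of 3 normal draws is c4-biased: ~0.886 sigma
        assert np.mean(cvs) == pytest.approx(5.0 * 0.886, rel=0.05)

    def test_nonpositive_mean_flagged_undefined(self):
        assert np.isnan(site_cv([-1.0, 0.5, 0.2]))

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            site_cv([0.1])


class TestIntraAssayCV:
    def test_identical_repeats_zero(self):
        tab = pd.DataFrame({"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [1.0, 2.0]})
        assert intra_assay_cv(tab) == 0.0

    def test_generator_three_percent_noise(self):
        """Repeat-level noise of 3% in the study generator shows up as an
        intra-assay CV of about 3%."""
        from indentmap.simulate import GroundTruth, StudyConfig, make_study
        from indentmap.study import IndentationStudy

        gt = GroundTruth(force_noise=0.03, atypical_rate=0.0, np_failure_rate=0.0)
        study = make_study(StudyConfig(n_control=3, n_knockout=0, seed=21), truth=gt)
        res = IndentationStudy.from_simulation(study).fit()
        # c4 small-sample bias of the SD estimator at k=3 is ~0.886
        assert res.reliability["intra_assay_cv_pct"] == pytest.approx(
            3.0 * 0.886, rel=0.12)


class TestICC:
    def test_identical_columns_unity(self):
        X = np.tile(np.arange(1.0, 9.0)[:, None], (1, 3))
        res = icc_absolute_single(X)
        assert res.icc == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        res = icc_absolute_single(rng.standard_normal((500, 3)))
        assert res.ci_low < 0.0 < res.ci_high or abs(res.icc) < 0.1

    def test_six_by_three_longhand_oracle(self):
        """Frozen from an independent two-way ANOVA decomposition computed
        longhand (and agreeing with pingouin's ICC2 row)."""
        X = np.array([[9.0, 2.0, 5.0], [6.0, 1.0, 7.0], [8.0, 4.0, 6.0],
                      [7.0, 1.0, 2.0], [10.0, 5.0, 6.0], [6.0, 2.0, 4.0]])
        res = icc_absolute_single(X)
        assert res.icc == pytest.approx(0.13669064748201437, abs=1e-12)
        assert res.ci_low == pytest.approx(-0.0342, abs=5e-3)
        assert res.ci_high == pytest.approx(0.6043, abs=5e-3)

    def test_matches_pingouin_on_random_matrices(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        for _ in range(3):
            n, k = 12, 3
            X = (rng.normal(5, 2, (n, 1)) + 0.4 * rng.standard_normal((n, k))
                 + rng.normal(0, 0.3, (1, k)))
            df = pd.DataFrame({
                "t": np.repeat(np.arange(n), k),
                "r": list("ABC") * n,
                "s": X.ravel(),
            })
            want = pg.intraclass_corr(df, targets="t", raters="r", ratings="s")
            want = float(want.loc[want.Type == "ICC(A,1)", "ICC"].iloc[0])
            assert icc_absolute_single(X).icc == pytest.approx(want, abs=1e-9)

    def test_incomplete_rows_dropped_listwise(self):
        X = np.array([[1.0, 1.1, 0.9], [2.0, np.nan, 2.1], [3.0, 3.1, 2.9],
                      [4.0, 4.2, 3.8], [5.0, 4.9, 5.1]])
        res = icc_absolute_single(X)
        assert res.n == 4

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            icc_absolute_single(np.ones((2, 3)))


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.loa_high - res.loa_low == 0.0

    def test_constant_offset(self):
        a = np.array([10.0, 20.0, 30.0])
        res = bland_altman(a, a + 5.0)
        assert res.bias == pytest.approx(5.0)
        assert res.loa_high - res.loa_low == pytest.approx(0.0, abs=1e-12)

    def test_simulated_offset_and_limits(self):
        """Offset 6.8 um with 3 um SD at n=300 recovers bias ~6.8 and
        LoA ~ 6.8 +/- 5.88 within Monte-Carlo error."""
        rng = np.random.default_rng(9)
        a = rng.uniform(30, 80, 300)
        b = a + 6.8 + 3.0 * rng.standard_normal(300)
        res = bland_altman(a, b)
        assert res.bias == pytest.approx(6.8, abs=3 * 3.0 / np.sqrt(300))
        assert res.loa_high == pytest.approx(6.8 + 1.96 * 3.0, abs=0.8)
        assert res.loa_low == pytest.approx(6.8 - 1.96 * 3.0, abs=0.8)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 3 * x + 1)
        assert r == pytest.approx(1.0)

    def test_anti_linear(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, -2 * x)
        assert r == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(4)
        r, _ = pearson_r(rng.standard_normal(1000), rng.standard_normal(1000))
        assert abs(r) < 0.1


class TestScaleInvariance:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3))
    def test_cv_scale_invariant(self, scale):
        vals = np.array([0.08, 0.11, 0.10])
        assert site_cv(vals * scale) == pytest.approx(site_cv(vals), rel=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3))
    def test_icc_scale_invariant(self, scale):
        X = np.array([[9.0, 2.0, 5.0], [6.0, 1.0, 7.0], [8.0, 4.0, 6.0],
                      [7.0, 1.0, 2.0], [10.0, 5.0, 6.0], [6.0, 2.0, 4.0]])
        assert icc_absolute_single(X * scale).icc == pytest.approx(
            icc_absolute_single(X).icc, rel=1e-9)


class TestPooling:
    def _table(self, grid):
        rng = np.random.default_rng(3)
        rows = []
        for spec in ("S1", "S2", "S3"):
            for s in grid.sites:
                rows.append((spec, s.site_id,
                             0.1 + (0.1 if s.condyle == "medial" else 0.0)
                             + 0.01 * rng.standard_normal()))
        return pd.DataFrame(rows, columns=["specimen", "site_id", "value"])

    def test_single_site_region_equals_site_value(self, grid):
        tab = pd.DataFrame({"specimen": ["S1"], "site_id": ["L1"], "value": [0.42]})
        rs = pool_regions(tab, grid)
        assert rs.specimen_means.loc["S1", "lateral"] == pytest.approx(0.42)
        assert rs.specimen_means.loc["S1", "lateral/anterior"] == pytest.approx(0.42)

    def test_counts_preserved_and_missing_excluded(self, grid):
        tab = self._table(grid)
        tab.loc[(tab.specimen == "S2") & (tab.site_id == "M1"), "value"] = np.nan
        rs = pool_regions(tab, grid)
        assert len(rs.specimen_means) == 3
        # S2 medial mean over 16 available sites only
        manual = tab[(tab.specimen == "S2")
                     & tab.site_id.str.startswith("M")]["value"].dropna().mean()
        assert rs.specimen_means.loc["S2", "medial"] == pytest.approx(manual)

    def test_condyle_contrast_detected(self, grid):
        rs = pool_regions(self._table(grid), grid)
        row = rs.comparisons[rs.comparisons.contrast == "lateral vs medial"]
        assert row["p"].iloc[0] < 0.01

    def test_bonferroni_never_below_raw_p(self, grid):
        rs = pool_regions(self._table(grid), grid)
        pairwise = rs.comparisons[rs.comparisons.contrast.str.contains(" vs ")]
        assert (pairwise.p_adjusted >= pairwise.p - 1e-15).all()

    def test_empty_table_rejected(self, grid):
        tab = pd.DataFrame({"specimen": ["S1"], "site_id": ["L1"],
                            "value": [np.nan]})
        with pytest.raises(ValueError):
            pool_regions(tab, grid)


def test_compare_groups_direction(grid):
    rng = np.random.default_rng(6)
    def tab(shift):
        rows = [(f"S{i}", s.site_id,
                 50 + shift * (s.condyle == "medial") + rng.standard_normal())
                for i in range(5) for s in grid.sites]
        return pd.DataFrame(rows, columns=["specimen", "site_id", "value"])

    a = pool_regions(tab(0.0), grid)
    b = pool_regions(tab(15.0), grid)
    out = compare_groups(a, b)
    med = out[out.region == "medial"].iloc[0]
    assert med.difference > 10
    assert med.p_adjusted < 0.05


def test_percent_change_printed_contrasts():
    assert percent_change(60.3, 67.9) == pytest.approx(12.6, abs=0.05)
    assert round(percent_change(39.8, 56.3)) == 41


def test_accounting_rates():
    acc = dataset_accounting(["pass"] * 909 + ["atypical"] * 21)
    assert acc["total"] == 930 and acc["flagged"] == 21
    assert acc["rate_percent"] == pytest.approx(2.258, abs=0.01)
    assert dataset_accounting(["pass"] * 5)["rate_percent"] == 0.0
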