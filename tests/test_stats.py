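"""Point-wise regression, FDR control, effect sizes, summaries and rankings."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tractometry.extraction import SubjectTractProfile
from tractometry.reference import load_reference_summaries
from tractometry.stats import (
    bh_fdr,
    effect_size,
    expected_direction,
    mmse_association,
    percent_tract_affected,
    pointwise_regression,
    rank_from_summary,
    summarize,
    validate_design,
)
from tractometry.tensor import METRICS

N_SLOTS, K = 2, 5


def _make_design(n_disease=8, n_control=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_control):
        rows.append(("c%02d" % i, "control"))
    for i in range(n_disease):
        rows.append(("d%02d" % i, "bvFTD"))
    df = pd.DataFrame(rows, columns=["id", "group"])
    df["age"] = rng.normal(60, 8, len(df)).round(1)
    df["sex"] = rng.choice(["M", "F"], len(df))
    df["brain_volume"] = rng.normal(1.1e6, 1e5, len(df)).round()
    df["mmse"] = rng.integers(20, 30, len(df))
    return df


def _make_profiles(design, values_fn, bundles=("B1",)):
    """values_fn(row, bundle) -> (N_SLOTS, K, 4) array."""
    profiles = {}
    for _, row in design.iterrows():
        prof = SubjectTractProfile(subject_id=row["id"])
        for b in bundles:
            prof.values[b] = values_fn(row, b)
            prof.fallback[b] = np.zeros((N_SLOTS, K), dtype=bool)
        profiles[row["id"]] = prof
    return profiles


def _ols_oracle(y, x, j):
    """Explicit normal-equations OLS with the classical t test for beta_j."""
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = x.shape[0] - x.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(s2 * xtx_inv[j, j])
    t = beta[j] / se
    p = 2 * sps.t.sf(abs(t), dof)
    return beta[j], t, p


def _bh_oracle(p, q):
    """Literal step-up definition: largest i with p_(i) <= i q / m."""
    m = len(p)
    order = np.argsort(p)
    sorted_p = np.asarray(p)[order]
    kmax = 0
    for i in range(1, m + 1):
        if sorted_p[i - 1] <= i * q / m:
            kmax = i
    reject = np.zeros(m, dtype=bool)
    if kmax:
        reject[order[:kmax]] = True
    return reject


class TestPointwiseRegression:
    def test_constant_metric_gives_null_statistics(self):
        design = _make_design()
        profiles = _make_profiles(design, lambda row, b: np.full((N_SLOTS, K, 4), 0.5))
        res = pointwise_regression(profiles, design, "FA", ("bvFTD", "control"), q=None)
        assert np.allclose(res.t, 0.0)
        assert np.allclose(res.p, 1.0)

    def test_noiseless_disease_shift_recovered_exactly(self):
        design = _make_design()

        def values(row, b):
            v = np.full((N_SLOTS, K, 4), 1.0)
            if row["group"] == "bvFTD":
                v += 0.5
            return v

        profiles = _make_profiles(design, values)
        res = pointwise_regression(profiles, design, "MD", ("bvFTD", "control"), q=None)
        assert np.allclose(res.coef, 0.5, atol=1e-10)

    def test_sign_convention_positive_means_higher_in_disease(self):
        design = _make_design()

        def values(row, b):
            v = np.full((N_SLOTS, K, 4), 1.0)
            if row["group"] == "bvFTD":
                v -= 0.3  # lower in disease
            return v

        profiles = _make_profiles(design, values)
        res = pointwise_regression(profiles, design, "FA", ("bvFTD", "control"), q=None)
        assert np.all(res.coef < 0)

    def test_matches_independent_ols_oracle(self):
        design = _make_design(seed=4)
        rng = np.random.default_rng(7)
        profiles = _make_profiles(design, lambda row, b: rng.normal(0.7, 0.1, (N_SLOTS, K, 4)))
        res = pointwise_regression(profiles, design, "RD", ("bvFTD", "control"), q=None)
        rows = design.reset_index(drop=True)
        x = np.column_stack(
            [
                np.ones(len(rows)),
                (rows["group"] == "bvFTD").to_numpy(float),
                rows["age"].to_numpy(float),
                (rows["sex"] == "M").to_numpy(float),
                rows["brain_volume"].to_numpy(float),
            ]
        )
        mi = METRICS.index("RD")
        for point in (0, 7, res.n_points - 1):
            y = np.array(
                [profiles[s].values["B1"][:, :, mi].ravel()[point] for s in rows["id"]]
            )
            coef, t, p = _ols_oracle(y, x, 1)
            assert res.coef[point] == pytest.approx(coef, rel=1e-9)
            assert res.t[point] == pytest.approx(t, rel=1e-9)
            assert res.p[point] == pytest.approx(p, rel=1e-9)

    def test_effect_size_df_uses_n_minus_2(self):
        design = _make_design(n_disease=20, n_control=33)
        rng = np.random.default_rng(8)
        profiles = _make_profiles(design, lambda row, b: rng.normal(0.7, 0.1, (N_SLOTS, K, 4)))
        res = pointwise_regression(profiles, design, "MD", ("bvFTD", "control"), q=None)
        assert res.df == 51
        assert np.allclose(res.r, np.sqrt(res.t**2 / (res.t**2 + 51)))

    def test_collinear_design_reports_columns(self):
        design = _make_design()
        design["brain_volume"] = design["age"] * 1000.0
        profiles = _make_profiles(design, lambda row, b: np.random.default_rng(0).normal(size=(N_SLOTS, K, 4)))
        with pytest.raises(ValueError, match="collinear"):
            pointwise_regression(profiles, design, "FA", ("bvFTD", "control"))

    def test_too_few_subjects_rejected(self):
        design = _make_design(n_disease=2, n_control=3)
        profiles = _make_profiles(design, lambda row, b: np.zeros((N_SLOTS, K, 4)))
        with pytest.raises(ValueError, match="regressors"):
            pointwise_regression(profiles, design, "FA", ("bvFTD", "control"))

    def test_design_validation(self):
        design = _make_design()
        bad = design.copy()
        bad.loc[0, "group"] = "LOAD"
        with pytest.raises(ValueError, match="unknown groups"):
            validate_design(bad)
        dup = pd.concat([design, design.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            validate_design(dup)


class TestBhFdr:
    def test_all_ones_no_rejection(self):
        flags, crit = bh_fdr(np.ones(50), q=0.05)
        assert not flags.any()
        assert crit == 0.0

    def test_hand_worked_step_up(self):
        # p_(3) = 0.03 <= 3/4 * 0.05 = 0.0375 -> first three rejected.
        flags, crit = bh_fdr(np.array([0.01, 0.02, 0.03, 0.9]), q=0.05)
        assert flags.tolist() == [True, True, True, False]
        assert crit == pytest.approx(0.03)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 60))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            q = float(rng.uniform(0.01, 0.2))
            flags, crit = bh_fdr(p, q)
            oracle = _bh_oracle(p, q)
            assert np.array_equal(flags, oracle)
            if flags.any():
                assert crit == pytest.approx(p[flags].max())
                assert np.array_equal(flags, p <= crit)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            bh_fdr(np.array([]))
        with pytest.raises(ValueError, match="0, 1"):
            bh_fdr(np.array([0.5, 1.5]))
        with pytest.raises(ValueError, match="q"):
            bh_fdr(np.array([0.5]), q=1.5)


class TestEffectSize:
    def test_zero_t_zero_r(self):
        assert effect_size(0.0, 10) == 0.0

    def test_symmetric_case(self):
        assert effect_size(1.0, 1) == pytest.approx(np.sqrt(0.5))

    def test_direct_evaluation(self):
        assert effect_size(2.0, 51) == pytest.approx(np.sqrt(4 / 55), abs=1e-12)
        assert effect_size(2.0, 51) == pytest.approx(0.2697, abs=1e-4)

    def test_monotone_in_abs_t_and_decreasing_in_df(self):
        ts = np.linspace(0, 10, 40)
        rs = effect_size(ts, 20)
        assert np.all(np.diff(rs) > 0)
        dfs = np.arange(1, 50)
        rs_df = effect_size(2.0, dfs)
        assert np.all(np.diff(rs_df) < 0)
        assert effect_size(-3.0, 9) == effect_size(3.0, 9)

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError, match="df"):
            effect_size(1.0, 0)


class TestPercentTract:
    def test_definition_cases(self):
        sig = np.zeros(100, dtype=bool)
        coef = np.ones(100)
        assert percent_tract_affected(sig, coef, +1) == 0.0
        sig[:] = True
        assert percent_tract_affected(sig, coef, +1) == 100.0
        sig[:] = False
        sig[:43] = True
        assert percent_tract_affected(sig, coef, +1) == pytest.approx(43.0)

    def test_direction_mask_filters_wrong_sign(self):
        sig = np.ones(10, dtype=bool)
        coef = np.array([1.0] * 6 + [-1.0] * 4)
        assert percent_tract_affected(sig, coef, +1) == pytest.approx(60.0)
        assert percent_tract_affected(sig, coef, -1) == pytest.approx(40.0)

    def test_invariant_to_point_ordering(self, rng):
        sig = rng.random(60) < 0.3
        coef = rng.normal(size=60)
        perm = rng.permutation(60)
        assert percent_tract_affected(sig, coef, +1) == pytest.approx(
            percent_tract_affected(sig[perm], coef[perm], +1)
        )

    def test_fiber_unit_counts_majority_affected_fibers(self):
        slots = np.repeat([0, 1], 10)
        sig = np.zeros(20, dtype=bool)
        sig[:6] = True  # fiber 0: 6/10 points -> affected; fiber 1: none
        assert percent_tract_affected(sig, np.ones(20), +1, slots=slots, unit="fibers") == 50.0

    def test_empty_bundle_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            percent_tract_affected(np.array([], dtype=bool), np.array([]), +1)

    def test_expected_directions(self):
        assert expected_direction("FA") == -1
        assert all(expected_direction(m) == +1 for m in ("MD", "RD", "AX"))


class TestRankingLayer:
    def test_reference_bvftd_md_mean_rounds_to_69(self):
        ref = load_reference_summaries()
        ranking = rank_from_summary(ref, "bvFTD_vs_control")
        assert round(ranking.mean_percent_tract["MD"]) == 69

    def test_known_tract_order(self):
        ref = load_reference_summaries()
        ranking = rank_from_summary(ref, "bvFTD_vs_control")
        order = ranking.tract_ranking
        assert order.index("L-UNC") < order.index("CC-OCC")
        assert order[0] == "L-UNC"

    def test_all_zero_summary_keeps_registry_order(self):
        bundles = ["B%d" % i for i in range(5)]
        rows = [
            {"comparison": "x_vs_y", "metric": m, "bundle": b, "percent_tract": 0.0, "mean_r": 0.0}
            for m in METRICS
            for b in bundles
        ]
        ranking = rank_from_summary(pd.DataFrame(rows))
        assert ranking.tract_ranking == bundles
        assert set(ranking.mean_percent_tract.values()) == {0.0}

    def test_missing_bundle_named_in_error(self):
        ref = load_reference_summaries()
        broken = ref[~((ref["metric"] == "MD") & (ref["bundle"] == "L-UNC"))]
        with pytest.raises(ValueError, match="L-UNC"):
            rank_from_summary(broken, "bvFTD_vs_control")

    def test_summarize_requires_fdr_flags(self):
        design = _make_design()
        profiles = _make_profiles(design, lambda row, b: np.full((N_SLOTS, K, 4), 0.5))
        res = pointwise_regression(profiles, design, "FA", ("bvFTD", "control"), q=None)
        with pytest.raises(ValueError, match="FDR"):
            summarize({"FA": res})


class TestMmseAssociation:
    def test_constant_mmse_is_collinear_with_intercept(self):
        design = _make_design()
        design["mmse"] = 25
        profiles = _make_profiles(design, lambda row, b: np.random.default_rng(1).normal(size=(N_SLOTS, K, 4)))
        with pytest.raises(ValueError, match="collinear"):
            mmse_association(profiles, design, "MD")

    def test_planted_noiseless_slope_recovered(self):
        design = _make_design(seed=5)

        def values(row, b):
            return np.full((N_SLOTS, K, 4), 1.0 + 0.02 * row["mmse"])

        profiles = _make_profiles(design, values)
        res = mmse_association(profiles, design, "MD", q=None)
        assert np.allclose(res.coef, 0.02, atol=1e-10)

    def test_missing_mmse_lists_subjects(self):
        design = _make_design()
        design.loc[design.index[:2], "mmse"] = np.nan
        profiles = _make_profiles(design, lambda row, b: np.zeros((N_SLOTS, K, 4)))
        with pytest.raises(ValueError, match="c00"):
            mmse_association(profiles, design, "MD")

    def test_matches_ols_oracle(self):
        design = _make_design(seed=6)
        rng = np.random.default_rng(3)
        profiles = _make_profiles(design, lambda row, b: rng.normal(0.7, 0.1, (N_SLOTS, K, 4)))
        res = mmse_association(profiles, design, "AX", q=None)
        rows = design.reset_index(drop=True)
        x = np.column_stack(
            [
                np.ones(len(rows)),
                rows["mmse"].to_numpy(float),
                rows["age"].to_numpy(float),
                (rows["sex"] == "M").to_numpy(float),
                rows["brain_volume"].to_numpy(float),
            ]
        )
        mi = METRICS.index("AX")
        y = np.array([profiles[s].values["B1"][:, :, mi].ravel()[3] for s in rows["id"]])
        coef, t, p = _ols_oracle(y, x, 1)
        assert res.coef[3] == pytest.approx(coef, rel=1e-9)
        assert res.p[3] == pytest.approx(p, rel=1e-9)
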