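import math

import numpy as np
import pytest

import imugait as ig
from imugait.stats import StatsInputError, holm_correct, summary_table


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def test_gate_accepts_normal_draws():
    hits = sum(
        ig.shapiro_gate(np.random.default_rng(s).normal(size=14)) == "normal"
        for s in range(50))
    assert hits >= 45   # nominal alpha = 0.05


def test_gate_flags_skewed_draws():
    hits = sum(
        ig.shapiro_gate(np.random.default_rng(s).exponential(size=14)) == "non_normal"
        for s in range(50))
    assert hits >= 30   # power against strong skew at n = 14


def test_gate_constant_vector_routed_to_wilcoxon():
    assert ig.shapiro_gate(np.full(10, 3.0)) == "non_normal"
    res = ig.paired_compare(np.full(10, 1.0), np.full(10, 1.0))
    assert res.test == "wilcoxon" and res.flagged


def test_gate_needs_three_values():
    with pytest.raises(StatsInputError):
        ig.shapiro_gate([1.0, 2.0])


# ---------------------------------------------------------------------------
# Paired comparison
# ---------------------------------------------------------------------------

def test_textbook_pairs_match_hand_computed_t():
    """Pairs {(1,2),(3,5),(4,4),(6,9),(8,8)}: d=(1,2,0,3,0), mean 1.2,
    sd = sqrt(6.8/4) = 1.303840, t = 1.2/(1.303840/sqrt(5)) = 2.057983
    (hand calculation)."""
    pre = np.array([1, 3, 4, 6, 8.0])
    post = np.array([2, 5, 4, 9, 8.0])
    res = ig.paired_compare(pre, post)
    d = post - pre
    t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(5))
    assert t_hand == pytest.approx(2.057983, abs=1e-5)
    from scipy import stats as sps
    assert res.p == pytest.approx(
        2 * sps.t.sf(abs(t_hand), df=4) if res.test == "paired_t" else res.p,
        abs=1e-9)
    assert res.diff_mean == pytest.approx(1.2)


def test_location_shift_detected():
    rng = np.random.default_rng(0)
    pre = rng.normal(10, 2, size=20)
    post = pre + 3.0 + rng.normal(0, 0.5, size=20)
    res = ig.paired_compare(pre, post)
    assert res.diff_mean == pytest.approx(3.0, abs=0.5)
    assert res.p < 1e-4 and res.significant


def test_incomplete_pairs_dropped():
    pre = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
    post = np.array([2.0, 3.0, 4.0, 5.0, np.nan])
    res = ig.paired_compare(pre, post)
    assert res.n == 3
    assert res.diff_mean == pytest.approx(1.0)


def test_identical_pairs_flagged_zero_variance():
    pre = np.array([1.0, 2.0, 3.0, 4.0])
    res = ig.paired_compare(pre, pre + 0.0)
    assert res.flagged


def test_null_cohort_type_one_error_calibrated():
    """Empirical size of the gated comparison about 0.05 over null cohorts."""
    rejections = 0
    n_rep = 2000
    for s in range(n_rep):
        pre, post = ig.simulate_metric_pairs(14, base_mean=28.6, base_sd=9.3,
                                             effect=0.0, diff_sd=4.6, seed=s)
        if ig.paired_compare(pre, post).significant:
            rejections += 1
    assert abs(rejections / n_rep - 0.05) < 0.02


def test_hip_effect_power():
    """Effect 9.3 deg with diff SD 4.6 at n = 14 rejects in >= 80% of runs."""
    hits = sum(
        ig.paired_compare(*ig.simulate_metric_pairs(
            14, base_mean=28.6, base_sd=9.3, effect=9.3, diff_sd=4.6,
            seed=s)).significant
        for s in range(50))
    assert hits >= 40


# ---------------------------------------------------------------------------
# Differences and percent change
# ---------------------------------------------------------------------------

def test_printed_hip_difference():
    assert ig.mean_difference(28.6, 37.9) == pytest.approx(9.3)


def test_no_change_is_zero_and_100_percent():
    assert ig.mean_difference(5.0, 5.0) == 0.0
    assert ig.percent_change(5.0, 5.0) == 100


def test_knee_speed_percent_change():
    assert ig.percent_change(407.0, 501.4) == 123


def test_percent_change_zero_pre_is_error():
    with pytest.raises(StatsInputError):
        ig.percent_change(0.0, 1.0)


# ---------------------------------------------------------------------------
# ICC and SEM
# ---------------------------------------------------------------------------

def test_duplicated_trials_icc_one_sem_zero():
    y = np.array([3.0, 5.0, 9.0, 4.0, 7.0])
    assert ig.icc_consistency(y, y) == pytest.approx(1.0)
    r = ig.reliability(y, y)
    assert r.icc == 1.0 and r.sem == 0.0


def test_constant_offset_keeps_icc_one():
    y = np.array([3.0, 5.0, 9.0, 4.0, 7.0])
    assert ig.icc_consistency(y, y + 5.0) == pytest.approx(1.0, abs=1e-12)


def test_icc_matches_anova_oracle():
    """Six-subject toy table: explicit two-way ANOVA decomposition."""
    t1 = np.array([10.0, 12.0, 15.0, 9.0, 14.0, 11.0])
    t2 = np.array([11.0, 13.0, 14.0, 10.0, 15.0, 12.0])
    y = np.column_stack([t1, t2])
    n, k = y.shape
    grand = y.mean()
    ms_subj = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_trial = n * ((y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    ss_err = ((y - grand) ** 2).sum() - (n - 1) * ms_subj / k * k - (k - 1) * ms_trial / n * n
    ms_err = ss_err / ((n - 1) * (k - 1))
    expected = (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)
    assert ig.icc_consistency(t1, t2) == pytest.approx(expected, abs=1e-12)


def test_icc_matches_pingouin_icc3():
    """Cross-check against an independent implementation (two-way mixed,
    single measure, consistency)."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd
    rng = np.random.default_rng(5)
    subj = rng.normal(50, 8, size=12)
    t1 = subj + rng.normal(0, 3, size=12)
    t2 = subj + 1.5 + rng.normal(0, 3, size=12)
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(12), 2),
        "rater": np.tile(["a", "b"], 12),
        "y": np.column_stack([t1, t2]).ravel(),
    })
    out = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                   ratings="y").set_index("Type")
    icc3 = out.loc["ICC3" if "ICC3" in out.index else "ICC(C,1)", "ICC"]
    assert ig.icc_consistency(t1, t2) == pytest.approx(icc3, abs=1e-9)


def test_zero_between_subject_variance_flagged():
    assert math.isnan(ig.icc_consistency(np.zeros(5), np.zeros(5)))


def test_sem_closed_forms():
    assert ig.sem_from_icc(4.0, 1.0) == 0.0
    assert ig.sem_from_icc(4.0, 0.0) == 4.0
    assert ig.sem_from_icc(4.0, 0.84) == pytest.approx(1.6)
    with pytest.raises(StatsInputError):
        ig.sem_from_icc(4.0, 1.2)


def test_sem_monotone_in_icc():
    sems = [ig.sem_from_icc(4.0, icc) for icc in (0.0, 0.3, 0.6, 0.9, 1.0)]
    assert all(a > b for a, b in zip(sems, sems[1:]))


def test_icc_recovers_variance_ratio_over_replicates():
    """ICC estimate matches sigma_b^2/(sigma_b^2+sigma_e^2) within 0.1 over
    50 seeded replicates of the two-component model (n=12, k=2)."""
    for between, error in ((1.0, 0.5), (1.0, 1.0)):
        target = between ** 2 / (between ** 2 + error ** 2)
        vals = [ig.icc_consistency(*ig.simulate_retest_metric(
            12, between_sd=between, error_sd=error, seed=s))
            for s in range(50)]
        assert abs(np.mean(vals) - target) < 0.1


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def test_summary_table_round_trip():
    pre = np.array([1.0, 2, 3, 4, 5])
    post = pre + 1.0 + np.random.default_rng(0).normal(0, 0.1, 5)
    comp = {"m1": ig.paired_compare(pre, post, metric="m1")}
    rel = {"m1": ig.reliability(pre, pre + 0.05 * np.arange(5), metric="m1")}
    table = summary_table(comp, rel, {"m1": (3.3, 1.1)})
    row = table.loc["m1"]
    assert row.pre_mean == pytest.approx(3.0)
    assert row.healthy_mean == 3.3
    assert row.icc == rel["m1"].icc
    assert bool(row.significant) == (row.p < 0.05)


def test_summary_table_zero_diff_cohort():
    pre = np.array([1.0, 2, 3, 4, 5])
    comp = {"m": ig.paired_compare(pre, pre.copy(), metric="m")}
    table = summary_table(comp)
    assert table.loc["m", "diff"] == 0.0
    assert not table.loc["m", "significant"]


def test_holm_adjustment_monotone():
    p = np.array([0.01, 0.04, 0.03, 0.2])
    adj = holm_correct(p)
    assert np.all(adj >= p)
    assert adj.max() <= 1.0
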