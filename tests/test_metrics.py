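import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icatk import metrics, simulate
from icatk.session import TrialRecord


def brute_force_auc(scores, labels, positive="pos"):
    """Exhaustive pair counting with ties at 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def test_roc_auc_examples():
    assert metrics.roc_auc([0.1, 0.4, 0.35, 0.8], ["neg", "neg", "pos", "pos"]) == 0.75
    assert metrics.roc_auc([0, 0, 1, 1], ["neg", "neg", "pos", "pos"]) == 1.0
    assert metrics.roc_auc([0.5] * 6, ["neg"] * 3 + ["pos"] * 3) == 0.5
    with pytest.raises(ValueError):
        metrics.roc_auc([1, 2, 3], ["pos", "pos", "pos"])


def test_roc_auc_equals_pair_counting_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(500):
        n = rng.integers(4, 21)
        labels = np.array(["neg", "pos"])[rng.integers(0, 2, n)]
        if len(set(labels)) < 2:
            labels[0], labels[1] = "neg", "pos"
        scores = np.round(rng.random(n), 2)  # coarse grid to exercise ties
        assert metrics.roc_auc(scores, labels, positive_label="pos") == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def test_roc_auc_complement_symmetry():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(4, 30))
        labels = np.array(["neg"] * (n // 2) + ["pos"] * (n - n // 2))
        scores = rng.normal(size=n)  # continuous, tie-free
        a = metrics.roc_auc(scores, labels, positive_label="pos")
        b = metrics.roc_auc(-scores, labels, positive_label="pos")
        assert a + b == pytest.approx(1.0)


@pytest.mark.parametrize(
    "successes, n, expected",
    [
        (71, 95, (66.0, 83.5)),
        (53, 55, (91.4, 100.0)),
        (170, 230, (68.2, 79.6)),
    ],
)
def test_wald_ci_reproduces_published_rows(successes, n, expected):
    lo, hi = metrics.wald_ci(successes, n)
    assert round(lo, 1) == expected[0]
    assert round(hi, 1) == expected[1]


def test_wald_ci_boundaries():
    assert metrics.wald_ci(0, 10) == (0.0, 0.0)
    assert metrics.wald_ci(10, 10) == (100.0, 100.0)
    with pytest.raises(ValueError):
        metrics.wald_ci(5, 0)
    with pytest.raises(ValueError):
        metrics.wald_ci(11, 10)


def test_sensitivity_specificity_counts():
    """TP=107 FN=28 TN=71 FP=24 reproduces the published 79.3 / 74.7."""
    labels = np.array(["impaired"] * 135 + ["healthy"] * 95)
    preds = np.array(["impaired"] * 107 + ["healthy"] * 28 + ["healthy"] * 71 + ["impaired"] * 24)
    bm = metrics.sensitivity_specificity(preds, labels)
    assert bm.sensitivity_pct == pytest.approx(79.3, abs=0.05)
    assert bm.specificity_pct == pytest.approx(74.7, abs=0.05)
    assert bm.specificity_ci == pytest.approx((66.0, 83.5), abs=0.05)
    assert bm.n_positive == 135 and bm.n_negative == 95
    # order invariance
    perm = np.random.default_rng(0).permutation(230)
    bm2 = metrics.sensitivity_specificity(preds[perm], labels[perm])
    assert bm2.sensitivity_pct == bm.sensitivity_pct
    assert bm2.specificity_pct == bm.specificity_pct


def test_sensitivity_specificity_degenerate_predictor():
    labels = ["impaired"] * 5 + ["healthy"] * 5
    all_impaired = ["impaired"] * 10
    bm = metrics.sensitivity_specificity(all_impaired, labels)
    assert bm.sensitivity_pct == 100.0 and bm.specificity_pct == 0.0
    correct = list(labels)
    bm = metrics.sensitivity_specificity(correct, labels)
    assert bm.sensitivity_pct == 100.0 and bm.specificity_pct == 100.0
    with pytest.raises(ValueError):
        metrics.sensitivity_specificity(all_impaired, ["impaired"] * 10)


@pytest.mark.parametrize(
    "score, test, expected",
    [
        (26, "moca", "healthy"),
        (25, "moca", "impaired"),
        (90, "ace", "healthy"),
        (89, "ace", "impaired"),
    ],
)
def test_comparator_cutoffs(score, test, expected):
    assert metrics.comparator_prediction(score, test) == expected


def test_comparator_validation():
    with pytest.raises(ValueError):
        metrics.comparator_prediction(31, "moca")
    with pytest.raises(ValueError):
        metrics.comparator_prediction(50, "mmse")


def test_percent_agreement_cells():
    a = ["impaired"] * 10 + ["impaired"] * 5 + ["healthy"] * 5 + ["healthy"] * 10
    b = ["impaired"] * 10 + ["healthy"] * 5 + ["impaired"] * 5 + ["healthy"] * 10
    res = metrics.percent_agreement(a, b)
    assert res.opa_pct == pytest.approx(66.7, abs=0.05)
    assert res.ppa_pct == pytest.approx(100 * 10 / 15, abs=1e-9)
    assert res.npa_pct == pytest.approx(100 * 10 / 15, abs=1e-9)
    # OPA is symmetric in the two tests, PPA/NPA are reference-directional
    swapped = metrics.percent_agreement(b, a)
    assert swapped.opa_pct == res.opa_pct


def test_percent_agreement_boundaries():
    same = ["impaired", "healthy", "impaired"]
    res = metrics.percent_agreement(same, same)
    assert res.ppa_pct == res.npa_pct == res.opa_pct == 100.0
    opposite = ["healthy", "impaired", "healthy"]
    assert metrics.percent_agreement(opposite, same).opa_pct == 0.0
    with pytest.raises(ValueError):
        metrics.percent_agreement(same, same[:2])


def test_cohens_d_values():
    res = metrics.cohens_d([1, 2, 3], [3, 4, 5])
    assert res.cohens_d == pytest.approx(-2.0)
    assert metrics.cohens_d([1, 2, 3], [1, 2, 3]).cohens_d == 0.0
    rng = np.random.default_rng(2)
    big = metrics.cohens_d(rng.normal(1, 1, 10_000), rng.normal(0, 1, 10_000))
    assert big.cohens_d == pytest.approx(1.0, abs=0.05)
    assert big.p_value < 1e-10
    with pytest.raises(ValueError):
        metrics.cohens_d([1, 1], [1, 1])


def test_pearson_correlation():
    x = np.arange(10.0)
    r, p = metrics.pearson_correlation(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r, _ = metrics.pearson_correlation(x, -x)
    assert r == pytest.approx(-1.0)
    # small fixed table against the direct formula
    xs = np.array([1.0, 4.0, 2.0, 7.0, 5.0])
    ys = np.array([2.0, 3.0, 1.0, 9.0, 4.0])
    r, _ = metrics.pearson_correlation(xs, ys)
    manual = np.sum((xs - xs.mean()) * (ys - ys.mean())) / np.sqrt(
        np.sum((xs - xs.mean()) ** 2) * np.sum((ys - ys.mean()) ** 2)
    )
    assert r == pytest.approx(manual, abs=1e-12)
    with pytest.raises(ValueError):
        metrics.pearson_correlation([1, 1, 1], [1, 2, 3])


def test_anova_two_groups_equals_squared_t():
    rng = np.random.default_rng(3)
    table = pd.DataFrame(
        {
            "session_index": [1] * 12 + [2] * 12,
            "ica_index": np.concatenate([rng.normal(60, 5, 12), rng.normal(63, 5, 12)]),
        }
    )
    f, p_f = metrics.practice_effect_anova(table)
    g1 = table[table.session_index == 1]["ica_index"]
    g2 = table[table.session_index == 2]["ica_index"]
    t, p_t = stats.ttest_ind(g1, g2)
    assert f == pytest.approx(t**2)
    assert p_f == pytest.approx(p_t)


def test_anova_validation():
    flat = pd.DataFrame({"session_index": [1, 1, 2, 2], "ica_index": [5.0, 5.0, 5.0, 5.0]})
    with pytest.raises(ValueError, match="variance"):
        metrics.practice_effect_anova(flat)
    single = pd.DataFrame({"session_index": [1, 1], "ica_index": [1.0, 2.0]})
    with pytest.raises(ValueError, match="two session groups"):
        metrics.practice_effect_anova(single)


def test_delong_ci_brackets_auc():
    rng = np.random.default_rng(4)
    scores = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 60)])
    labels = np.array(["pos"] * 60 + ["neg"] * 60)
    auc, (lo, hi) = metrics.auc_delong_ci(scores, labels, positive_label="pos")
    assert lo < auc < hi
    assert auc == pytest.approx(metrics.roc_auc(scores, labels, positive_label="pos"))
    assert 0 <= lo and hi <= 1


def _mini_logs(params, bank):
    res = simulate.simulate_study(rng_seed=3, return_logs=True)
    return res


def test_image_performance_matrix(params):
    res = simulate.simulate_study(rng_seed=3, return_logs=True)
    diagnoses = dict(zip(res.participants.participant_id, res.participants.diagnosis))
    mat = metrics.image_performance_matrix(res.logs, diagnoses, bank=res.bank)
    assert mat.accuracy.shape == (3, 100)
    assert mat.rt_ms.shape == (3, 100)
    # animal block first
    assert all(c.startswith("animal") for c in mat.accuracy.columns[:50])
    assert mat.accuracy.notna().all().all()
    assert ((mat.accuracy >= 0) & (mat.accuracy <= 1)).all().all()
    # healthy participants outperform mild AD on average
    assert mat.accuracy.loc["healthy"].mean() > mat.accuracy.loc["mild_ad"].mean()


def test_image_performance_matrix_single_session_and_missing_group(bank):
    records = [
        TrialRecord(it.item_id, it.category, it.category, True, 500.0, "main", i)
        for i, it in enumerate(bank)
    ]
    mat = metrics.image_performance_matrix({"p1": records}, {"p1": "healthy"}, bank=bank)
    assert (mat.accuracy.loc["healthy"] == 1.0).all()
    assert mat.accuracy.loc["mci"].isna().all()  # missing, not zero
    with pytest.raises(ValueError, match="not in the bank"):
        metrics.image_performance_matrix({"p1": records}, {"p1": "healthy"}, bank=bank[:50])
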