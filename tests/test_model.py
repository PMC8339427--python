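import numpy as np
import pytest
from sklearn.linear_model import SGDClassifier
from sklearn.preprocessing import StandardScaler

from icatk import metrics, model, simulate


def toy_separable(n=40, seed=0):
    """Linearly separable features: impaired indices well below healthy ones."""
    rng = np.random.default_rng(seed)
    healthy = np.column_stack(
        [rng.normal(85, 3, n), rng.normal(80, 3, n), rng.normal(68, 3, n), rng.normal(65, 5, n)]
    )
    impaired = np.column_stack(
        [rng.normal(60, 3, n), rng.normal(60, 3, n), rng.normal(36, 3, n), rng.normal(72, 5, n)]
    )
    X = np.vstack([healthy, impaired])
    y = np.array(["healthy"] * n + ["impaired"] * n)
    return X, y


def study_features(seed, spec=None, n=None):
    res = simulate.simulate_study(spec, rng_seed=seed)
    t = res.participants.dropna(subset=["speed"])
    if n is not None:  # balanced subsample (participant rows are group-ordered)
        t = t.sample(n=n, random_state=seed).sort_index()
    return model.feature_matrix(t), model.impairment_labels(t["diagnosis"]), t


def test_fit_separates_toy_data():
    X, y = toy_separable()
    est = model.ImpairmentClassifier(random_state=0).fit(X, y)
    assert (est.predict(X) == y).mean() >= 0.95
    assert est.classes_.tolist() == ["healthy", "impaired"]
    assert est.standardization_scale_.min() > 0


def test_fit_rejects_single_class():
    X, y = toy_separable()
    with pytest.raises(ValueError, match="two classes"):
        model.ImpairmentClassifier(random_state=0).fit(X[y == "healthy"], y[y == "healthy"])


def test_fit_is_seed_deterministic():
    X, y = toy_separable()
    a = model.ImpairmentClassifier(random_state=3).fit(X, y)
    b = model.ImpairmentClassifier(random_state=3).fit(X, y)
    assert np.array_equal(a.coef_, b.coef_)
    assert np.array_equal(a.intercept_, b.intercept_)


def test_zero_weights_give_half_probability_and_impaired_label():
    """logistic(0) = 0.5, and the 0.5 threshold is inclusive on the impaired side."""
    X, y = toy_separable()
    est = model.ImpairmentClassifier(random_state=0).fit(X, y)
    est.sgd_.coef_ = np.zeros_like(est.sgd_.coef_)
    est.sgd_.intercept_ = np.zeros_like(est.sgd_.intercept_)
    pred = est.predict_one(X[0])
    assert pred.ai_probability == pytest.approx(0.5)
    assert pred.predicted_label == "impaired"
    assert pred.ica_score == pytest.approx(50.0)


def test_probability_monotone_in_index():
    """With healthy-direction weights, raising the index lowers the probability."""
    X, y = toy_separable()
    est = model.ImpairmentClassifier(random_state=0).fit(X, y)
    base = X[0].copy()
    worse = base.copy()
    worse[2] -= 20  # drop the index
    p_base = est.predict_proba([base])[0, 1]
    p_worse = est.predict_proba([worse])[0, 1]
    assert p_worse > p_base


def test_loocv_matches_bruteforce_refit():
    """Package LOOCV equals an independent from-scratch refit loop (n=30)."""
    X, y, _ = study_features(seed=11, n=30)
    assert np.unique(y).size == 2
    probs = model.loocv(X, y, rng_seed=5)
    assert probs.shape == (30,)
    for i in range(30):
        mask = np.ones(30, bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        keys = tuple(X_tr[:, j] for j in range(X_tr.shape[1] - 1, -1, -1))
        order = np.lexsort((y_tr.astype(str),) + keys)
        sc = StandardScaler().fit(X_tr[order])
        clf = SGDClassifier(
            loss="log_loss", penalty="l2", alpha=1e-4, max_iter=1000, tol=1e-4,
            learning_rate="adaptive", eta0=0.01, average=True, random_state=5,
        ).fit(sc.transform(X_tr[order]), y_tr[order])
        expected = clf.predict_proba(sc.transform(X[i : i + 1]))[0, list(clf.classes_).index("impaired")]
        assert probs[i] == pytest.approx(expected, abs=1e-12)


def test_loocv_order_invariant():
    X, y, _ = study_features(seed=12, n=40)
    probs = model.loocv(X, y, rng_seed=1)
    rng = np.random.default_rng(0)
    perm = rng.permutation(40)
    probs_perm = model.loocv(X[perm], y[perm], rng_seed=1)
    assert probs_perm == pytest.approx(probs[perm], abs=1e-12)


def test_loocv_standardization_ignores_held_out_point():
    """An extreme held-out outlier cannot leak into its fold's statistics."""
    X, y, _ = study_features(seed=13, n=30)
    X = X.copy()
    k = 4
    X[k] = [1e6, 1e6, 1e6, 1e6]
    probs = model.loocv(X, y, rng_seed=2)
    mask = np.ones(30, bool)
    mask[k] = False
    X_tr, y_tr = X[mask], y[mask]
    keys = tuple(X_tr[:, j] for j in range(X_tr.shape[1] - 1, -1, -1))
    order = np.lexsort((y_tr.astype(str),) + keys)
    est = model.ImpairmentClassifier(random_state=2).fit(X_tr[order], y_tr[order])
    assert est.standardization_mean_ == pytest.approx(X_tr.mean(axis=0))
    assert probs[k] == pytest.approx(est.predict_proba(X[k : k + 1])[0, 1], abs=1e-12)


def test_loocv_requires_two_per_class():
    X, y = toy_separable(n=10)
    with pytest.raises(ValueError):
        model.loocv(X[:11], y[:11])  # one impaired example only


def test_cross_cohort_close_to_within_cohort_for_identical_generators():
    """Exchangeable cohorts: transfer AUC tracks within-cohort LOOCV AUC."""
    import dataclasses

    spec = simulate.default_cohort_spec()
    # two cohorts with identical generative parameters, 150 participants each
    g = spec.groups
    groups = {
        (1, "healthy"): dataclasses.replace(g[(2, "healthy")], n=62),
        (1, "mci"): dataclasses.replace(g[(2, "mci")], n=53),
        (1, "mild_ad"): dataclasses.replace(g[(2, "mild_ad")], n=42),
        (2, "healthy"): g[(2, "healthy")],
        (2, "mci"): g[(2, "mci")],
        (2, "mild_ad"): g[(2, "mild_ad")],
    }
    X, y, t = study_features(seed=21, spec=simulate.CohortSpec(groups=groups))
    in1 = (t["cohort"] == 1).to_numpy()
    res = model.cross_cohort_evaluate(X[in1], y[in1], X[~in1], y[~in1], rng_seed=0)
    probs = model.loocv(X[~in1], y[~in1], rng_seed=0)
    auc_within = metrics.roc_auc(probs, y[~in1], positive_label="impaired")
    assert res["auc"] == pytest.approx(auc_within, abs=0.05)


def test_train_on_self_is_optimistic():
    """Apparent (train=test) AUC is at least the transfer AUC on average."""
    diffs = []
    for seed in range(10):
        X, y, t = study_features(seed=100 + seed)
        in1 = (t["cohort"] == 1).to_numpy()
        self_eval = model.cross_cohort_evaluate(X[in1], y[in1], X[in1], y[in1], rng_seed=seed)
        cross = model.cross_cohort_evaluate(X[in1], y[in1], X[~in1], y[~in1], rng_seed=seed)
        diffs.append(self_eval["auc"] - cross["auc"])
    assert np.mean(diffs) >= -0.005


def test_cross_cohort_validation_errors():
    X, y = toy_separable()
    with pytest.raises(ValueError, match="empty"):
        model.cross_cohort_evaluate(X, y, X[:0], y[:0])
    with pytest.raises(ValueError, match="two classes"):
        model.cross_cohort_evaluate(X[y == "healthy"], y[y == "healthy"], X, y)


def test_learning_curve_shape_and_degenerate_full_size():
    X, y = toy_separable(n=30)
    lc = model.learning_curve(X, y, X, y, sizes=[3, 10, 60], n_repetitions=20, rng_seed=0)
    assert lc.sizes == (3, 10, 60)
    assert lc.n_repetitions == 20
    # full-size subsets are all identical, so the CI collapses
    assert lc.ci_low[-1] == pytest.approx(lc.mean_auc[-1])
    assert lc.ci_high[-1] == pytest.approx(lc.mean_auc[-1])
    with pytest.raises(ValueError, match=">= 3"):
        model.learning_curve(X, y, X, y, sizes=[2, 10])


def test_model_json_roundtrip(tmp_path):
    X, y = toy_separable()
    est = model.ImpairmentClassifier(random_state=0).fit(X, y)
    path = tmp_path / "model.json"
    model.save_model(est, path)
    loaded = model.load_model(path)
    assert loaded.predict_proba(X) == pytest.approx(est.predict_proba(X))
    assert (loaded.predict(X) == est.predict(X)).all()
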