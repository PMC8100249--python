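"""The discriminant: oracle equivalence, symmetry cases, shrinkage limits,
invariances and error handling."""

import numpy as np
import pytest

from locomode import DiscriminantModel, discriminant_score, discriminant_scores, fit_lda, predict
from locomode.lda import canonical_class_order


def random_instance(rng, n_classes=None, n_features=None, n=None, spread=3.0):
    K = n_classes or int(rng.integers(2, 6))
    p = n_features or int(rng.integers(1, 11))
    n = n or int(rng.integers(K * 5, 120))
    means = rng.normal(scale=spread, size=(K, p))
    y = rng.integers(0, K, size=n)
    # ensure every class has at least 2 rows
    y[: 2 * K] = np.repeat(np.arange(K), 2)
    X = means[y] + rng.normal(size=(n, p))
    return X, np.array([f"c{int(k)}" for k in y], dtype=object)


def brute_force_gaussian_argmax(X_train, y_train, X_test, shrinkage):
    """Independent shared-covariance Gaussian classifier: standardize,
    pool, shrink, then full quadratic log-posteriors per row."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X_train - mu) / sd
    Zt = (X_test - mu) / sd
    classes = canonical_class_order(y_train)
    K = len(classes)
    means = np.stack([Z[y_train == c].mean(axis=0) for c in classes])
    scatter = sum(
        (Z[y_train == c] - means[i]).T @ (Z[y_train == c] - means[i])
        for i, c in enumerate(classes)
    )
    cov = scatter / (len(Z) - K)
    cov = (1 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    out = []
    for x in Zt:
        logp = [
            -0.5 * (x - m) @ np.linalg.solve(cov, x - m) + np.log(1.0 / K)
            for m in means
        ]
        out.append(classes[int(np.argmax(logp))])
    return np.array(out, dtype=object)


def test_two_point_classes_boundary_at_midpoint():
    X = np.array([[0.0], [0.0], [2.0], [2.0]])
    y = np.array(["a", "a", "b", "b"], dtype=object)
    model = fit_lda(X, y, shrinkage=1.0)
    s_lo = discriminant_scores(model, [[0.9]])[0]
    s_hi = discriminant_scores(model, [[1.1]])[0]
    assert predict(model, [[0.9]])[0] == "a"
    assert predict(model, [[1.1]])[0] == "b"
    # exactly on the midpoint the two scores coincide
    s_mid = discriminant_scores(model, [[1.0]])[0]
    assert s_mid[0] == pytest.approx(s_mid[1])
    assert s_lo[0] > s_lo[1] and s_hi[1] > s_hi[0]


def test_centroids_classify_as_their_own_class(rng):
    X, y = random_instance(rng, n_classes=5, n_features=6, n=300, spread=6.0)
    model = fit_lda(X, y, shrinkage=0.05)
    classes = model.classes
    centroids_raw = np.stack([X[y == c].mean(axis=0) for c in classes])
    assert list(predict(model, centroids_raw)) == list(classes)


def test_bisector_symmetry():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(size=(40, 3)) - 2, rng.normal(size=(40, 3)) + 2])
    y = np.array(["a"] * 40 + ["b"] * 40, dtype=object)
    model = fit_lda(X, y, shrinkage=0.0)
    mid = 0.5 * (X[:40].mean(axis=0) + X[40:].mean(axis=0))
    sa = discriminant_score(model, mid, "a")
    sb = discriminant_score(model, mid, "b")
    assert sa == pytest.approx(sb, rel=1e-9)


def test_matches_brute_force_oracle(rng):
    for _ in range(25):
        X, y = random_instance(rng)
        lam = float(rng.choice([0.0, 0.01, 0.1, 0.5]))
        try:
            model = fit_lda(X, y, shrinkage=lam)
        except np.linalg.LinAlgError:
            assert lam == 0.0
            continue
        Xt = rng.normal(scale=2.0, size=(40, X.shape[1])) + X.mean(axis=0)
        np.testing.assert_array_equal(
            predict(model, Xt), brute_force_gaussian_argmax(X, y, Xt, lam)
        )


def test_matches_sklearn_reference():
    """Independent library cross-check at zero shrinkage, matched priors."""
    sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
    rng = np.random.default_rng(11)
    # balanced classes: the reference pools covariance prior-weighted per
    # class, which coincides with the N-K pooled estimate up to a scalar
    # (argmax-invariant under equal priors) only when counts are equal
    means = rng.normal(scale=2.0, size=(5, 8))
    y = np.repeat([f"c{k}" for k in range(5)], 80).astype(object)
    X = means[np.repeat(np.arange(5), 80)] + rng.normal(size=(400, 8))
    model = fit_lda(X, y, shrinkage=0.0)
    ref = sklearn_lda.LinearDiscriminantAnalysis(
        solver="lsqr", priors=np.full(5, 0.2)
    ).fit(X, y.astype(str))
    Xt = rng.normal(scale=2.5, size=(200, 8)) + X.mean(axis=0)
    ours = predict(model, Xt).astype(str)
    theirs = ref.predict(Xt)
    assert (ours == theirs).mean() == 1.0


def test_permuted_labels_give_chance_accuracy(rng):
    X, _ = random_instance(rng, n_classes=4, n_features=5, n=1000, spread=4.0)
    y_perm = np.array([f"c{k}" for k in rng.integers(0, 4, size=1000)], dtype=object)
    model = fit_lda(X, y_perm, shrinkage=0.05)
    acc = (predict(model, X) == y_perm).mean()
    # binomial 3-sigma band around 1/K
    assert abs(acc - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 1000) + 0.02


def test_full_shrinkage_is_diagonal_classifier(rng):
    """At lambda = 1 the model must agree with an independently coded
    diagonal-covariance Gaussian classifier."""
    X, y = random_instance(rng, n_classes=3, n_features=4, n=200)
    model = fit_lda(X, y, shrinkage=1.0)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = (X - mu) / sd
    classes = model.classes
    means = np.stack([Z[y == c].mean(axis=0) for c in classes])
    var = np.zeros(X.shape[1])
    for i, c in enumerate(classes):
        R = Z[y == c] - means[i]
        var += (R**2).sum(axis=0)
    var /= len(Z) - len(classes)
    Xt = rng.normal(size=(60, 4)) + mu
    Zt = (Xt - mu) / sd
    logp = np.stack(
        [-0.5 * (((Zt - m) ** 2) / var).sum(axis=1) for m in means], axis=1
    )
    expected = [classes[i] for i in logp.argmax(axis=1)]
    np.testing.assert_array_equal(predict(model, Xt), np.array(expected, dtype=object))


def test_affine_rescaling_invariance(rng):
    X, y = random_instance(rng, n_classes=3, n_features=6, n=250)
    scale = rng.uniform(0.1, 40.0, size=6)
    shift = rng.normal(scale=30.0, size=6)
    Xt = rng.normal(size=(80, 6)) + X.mean(axis=0)
    p1 = predict(fit_lda(X, y, shrinkage=0.05), Xt)
    p2 = predict(fit_lda(X * scale + shift, y, shrinkage=0.05), Xt * scale + shift)
    np.testing.assert_array_equal(p1, p2)


def test_single_and_multi_row_predictions_agree(rng):
    X, y = random_instance(rng, n_classes=3, n_features=4, n=120)
    model = fit_lda(X, y)
    Xt = rng.normal(size=(15, 4))
    batch = predict(model, Xt)
    rows = [predict(model, Xt[i : i + 1])[0] for i in range(15)]
    np.testing.assert_array_equal(batch, np.array(rows, dtype=object))


def test_canonical_order_and_tie_break():
    assert canonical_class_order(["SS", "W", "COS", "CO"]) == ["W", "CO", "SS", "COS"]
    assert canonical_class_order(["b", "a", "W"]) == ["W", "a", "b"]


def test_error_small_class_named():
    X = np.random.default_rng(0).normal(size=(5, 2))
    y = np.array(["a", "a", "a", "a", "b"], dtype=object)
    with pytest.raises(ValueError, match="'b'"):
        fit_lda(X, y)


def test_error_singular_without_shrinkage():
    rng = np.random.default_rng(0)
    X = np.column_stack([rng.normal(size=20), np.zeros(20)])
    y = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
    with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
        fit_lda(X, y, shrinkage=0.0)
    fit_lda(X, y, shrinkage=0.01)  # regularized fit succeeds


def test_dimension_mismatch_error(rng):
    X, y = random_instance(rng, n_classes=2, n_features=3, n=40)
    model = fit_lda(X, y)
    with pytest.raises(ValueError, match="dimension"):
        predict(model, np.zeros((4, 5)))


def test_json_roundtrip(tmp_path, rng):
    X, y = random_instance(rng, n_classes=3, n_features=5, n=150)
    model = fit_lda(X, y, shrinkage=0.02)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = DiscriminantModel.from_json(path)
    Xt = rng.normal(size=(30, 5))
    np.testing.assert_array_equal(predict(model, Xt), predict(back, Xt))
    np.testing.assert_allclose(back.means, model.means)


def test_fit_is_deterministic(rng):
    X, y = random_instance(rng, n_classes=3, n_features=6, n=200)
    m1, m2 = fit_lda(X, y), fit_lda(X, y)
    np.testing.assert_array_equal(m1.means, m2.means)
    np.testing.assert_array_equal(m1.pooled_cov, m2.pooled_cov)
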