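"""CPT estimation on fixed DAGs, log-likelihood scoring, and naive-Bayes
scheme classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from emrcost.bayesnet import (
    DiscreteDAG,
    classify,
    discretize_features,
    fit_cpts,
    fit_naive_bayes,
    log_likelihood,
    naive_bayes_dag,
)
from emrcost.errors import ConfigError, DomainError, UndefinedCPTError
from tests.conftest import make_matrix


def test_dag_rejects_cycles_and_unknown_nodes():
    with pytest.raises(ConfigError, match="cycle"):
        DiscreteDAG(nodes=("a", "b"), edges=(("a", "b"), ("b", "a")))
    with pytest.raises(ConfigError):
        DiscreteDAG(nodes=("a",), edges=(("a", "z"),))


def test_dag_edge_file_round_trip(tmp_path):
    path = tmp_path / "net.dag"
    path.write_text("scheme\tchemo\nscheme\tradio\n# comment\n")
    dag = DiscreteDAG.from_edge_file(path)
    assert dag.parents("chemo") == ("scheme",)
    assert dag.parents("scheme") == ()


def test_discretize_keeps_finite_grids_and_bins_numerics():
    rng = np.random.default_rng(0)
    age = rng.uniform(0, 100, size=100)
    binary = rng.integers(0, 2, size=100).astype(float)
    degree = rng.choice([0.0, 2 / 3, 5 / 6, 1.0], size=100)
    fm = make_matrix(
        np.column_stack([age, binary, degree]),
        kinds=["numeric", "binary", "degree"],
        names=["age", "flag", "sev"],
    )
    disc, dmap = discretize_features(fm, bins_for_numeric=4)
    # binary column unchanged (2 states); degree column keeps its 4-value grid
    assert set(disc["flag"]) == {0.0, 1.0}
    assert set(disc["sev"]) == {0.0, np.round(2 / 3, 12), np.round(5 / 6, 12), 1.0}
    # quantile bins on ~uniform draws are near-balanced
    counts = disc["age"].value_counts()
    assert len(counts) == 4
    assert counts.min() >= 15
    # the recorded edges reproduce the same binning on the same data
    again = dmap.transform(fm)
    pd.testing.assert_frame_equal(again, disc)


def test_fit_cpts_frequency_and_laplace():
    # single node, data (A, A, B), alpha=0 -> (2/3, 1/3)
    data = pd.DataFrame({"n": ["A", "A", "B"]})
    dag = DiscreteDAG(nodes=("n",), edges=())
    cpts = fit_cpts(data, dag, alpha=0.0)
    np.testing.assert_allclose(cpts.nodes["n"].table[()], [2 / 3, 1 / 3])
    # child with one parent state, counts (3, 1), alpha=1 -> (4/6, 2/6)
    data2 = pd.DataFrame({"p": ["u"] * 4, "c": ["x", "x", "x", "y"]})
    dag2 = DiscreteDAG(nodes=("p", "c"), edges=(("p", "c"),))
    cpts2 = fit_cpts(data2, dag2, alpha=1.0)
    np.testing.assert_allclose(cpts2.nodes["c"].table[("u",)], [4 / 6, 2 / 6])


def test_unseen_parent_configuration_with_alpha_zero_raises():
    data = pd.DataFrame({"p": ["u", "v"], "q": ["a", "b"], "c": ["x", "y"]})
    dag = DiscreteDAG(nodes=("p", "q", "c"), edges=(("p", "c"), ("q", "c")))
    with pytest.raises(UndefinedCPTError):
        fit_cpts(data, dag, alpha=0.0)  # e.g. (u, a) x c never co-observed both ways
    # with smoothing the same fit succeeds and every distribution normalizes
    cpts = fit_cpts(data, dag, alpha=1.0)
    for combo, probs in cpts.nodes["c"].table.items():
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


def test_ml_estimate_maximizes_likelihood():
    """Perturbing the alpha=0 frequency table in any direction cannot
    increase the data log-likelihood."""
    rng = np.random.default_rng(1)
    data = pd.DataFrame({"n": rng.choice(["A", "B", "C"], size=30)})
    dag = DiscreteDAG(nodes=("n",), edges=())
    cpts = fit_cpts(data, dag, alpha=0.0)
    base = log_likelihood(data, cpts)
    probs = cpts.nodes["n"].table[()]
    for i, j in itertools.permutations(range(3), 2):
        perturbed = probs.copy()
        perturbed[i] += 0.01
        perturbed[j] -= 0.01
        if (perturbed <= 0).any():
            continue
        cpts.nodes["n"].table[()] = perturbed
        assert log_likelihood(data, cpts) < base
    cpts.nodes["n"].table[()] = probs


def test_log_likelihood_hand_oracle_on_chain():
    """Three-node chain, four records: the score equals the sum of
    hand-read CPT entries."""
    data = pd.DataFrame(
        {"a": [0, 0, 1, 1], "b": [0, 1, 1, 1], "c": [0, 1, 1, 0]}
    )
    dag = DiscreteDAG(nodes=("a", "b", "c"), edges=(("a", "b"), ("b", "c")))
    cpts = fit_cpts(data, dag, alpha=0.0)
    expected = 6 * np.log(0.5) + 2 * np.log(2 / 3) + np.log(1 / 3)
    assert log_likelihood(data, cpts) == pytest.approx(expected, abs=1e-12)
    # deterministic tables score exactly zero
    det = pd.DataFrame({"a": [0, 0], "b": [1, 1], "c": [0, 0]})
    cpts_det = fit_cpts(det, dag, alpha=0.0)
    assert log_likelihood(det, cpts_det) == 0.0


def test_log_likelihood_zero_probability_warns_minus_inf():
    train = pd.DataFrame({"n": ["A", "A"]})
    dag = DiscreteDAG(nodes=("n",), edges=())
    cpts = fit_cpts(train, dag, alpha=0.0)
    with pytest.warns(UserWarning, match="zero probability"):
        assert log_likelihood(pd.DataFrame({"n": ["B"]}), cpts) == -np.inf


def test_two_class_bayes_rule_by_hand():
    """Uniform priors, one feature with P(x=1|y1)=0.9, P(x=1|y2)=0.1:
    posterior is (0.9, 0.1) and class y1 wins."""
    data = pd.DataFrame(
        {
            "x": [1] * 9 + [0] + [1] + [0] * 9,
            "y": ["y1"] * 10 + ["y2"] * 10,
        }
    )
    cpts = fit_naive_bayes(data, class_col="y", alpha=0.0)
    label, post = classify({"x": 1}, cpts)
    assert label == "y1"
    np.testing.assert_allclose(post, [0.9, 0.1], atol=1e-12)


def test_classifier_matches_bruteforce_enumeration():
    """Over every combination of 4 binary features, the log-space classifier
    equals direct enumeration of prior x product-of-conditionals computed
    from raw counts, for 3 classes."""
    rng = np.random.default_rng(5)
    n = 120
    data = pd.DataFrame({f"x{i}": rng.integers(0, 2, n) for i in range(4)})
    data["y"] = rng.choice(["c1", "c2", "c3"], size=n, p=[0.5, 0.3, 0.2])
    alpha = 1.0
    cpts = fit_naive_bayes(data, class_col="y", alpha=alpha)
    classes = sorted(data["y"].unique())

    def brute_posterior(record):
        joint = []
        for c in classes:
            sub = data[data["y"] == c]
            p = (len(sub) + alpha) / (len(data) + alpha * len(classes))
            for f, v in record.items():
                p *= ((sub[f] == v).sum() + alpha) / (len(sub) + alpha * 2)
            joint.append(p)
        joint = np.array(joint)
        return joint / joint.sum()

    grid = pd.DataFrame(
        [dict(zip([f"x{i}" for i in range(4)], combo))
         for combo in itertools.product([0, 1], repeat=4)]
    )
    labels, post = classify(grid, cpts)
    for i, (_, rec) in enumerate(grid.iterrows()):
        expected = brute_posterior(rec.to_dict())
        np.testing.assert_allclose(post[i], expected, atol=1e-12)
        assert labels[i] == classes[int(np.argmax(expected))]
        assert post[i].sum() == pytest.approx(1.0, abs=1e-12)


def test_classification_invariant_to_column_order():
    rng = np.random.default_rng(8)
    data = pd.DataFrame({f"x{i}": rng.integers(0, 3, 80) for i in range(3)})
    data["y"] = rng.choice(["a", "b"], size=80)
    cpts = fit_naive_bayes(data, class_col="y", alpha=1.0)
    query = data.drop(columns="y").head(10)
    l1, p1 = classify(query, cpts)
    l2, p2 = classify(query[["x2", "x0", "x1"]], cpts)
    assert l1 == l2
    np.testing.assert_allclose(p1, p2)


def test_alpha_shrinks_posterior_toward_prior():
    rng = np.random.default_rng(3)
    data = pd.DataFrame({"x": rng.integers(0, 2, 40)})
    data["y"] = np.where(data["x"] == 1,
                         rng.choice(["a", "b"], 40, p=[0.85, 0.15]),
                         rng.choice(["a", "b"], 40, p=[0.2, 0.8]))
    dists = []
    for alpha in (0.0, 1.0, 10.0, 1000.0):
        cpts = fit_naive_bayes(data, class_col="y", alpha=alpha)
        _, post = classify({"x": 1}, cpts)
        dists.append(np.abs(post - cpts.class_priors).max())
    assert all(d2 < d1 + 1e-12 for d1, d2 in zip(dists, dists[1:]))
    assert dists[-1] < 0.01


def test_single_class_training_data():
    data = pd.DataFrame({"x": [0, 1, 0], "y": ["only"] * 3})
    cpts = fit_naive_bayes(data, class_col="y", alpha=0.0)
    label, post = classify({"x": 0}, cpts)
    assert label == "only"
    np.testing.assert_allclose(post, [1.0])


def test_unseen_state_with_alpha_zero_is_an_error():
    data = pd.DataFrame({"x": [0, 0, 1, 1], "y": ["a", "a", "b", "b"]})
    cpts = fit_naive_bayes(data, class_col="y", alpha=0.0)
    with pytest.raises(DomainError, match="zero likelihood"):
        classify({"x": 7}, cpts)


def test_discretize_rejects_missing_or_nonfinite(matrix_factory):
    fm = matrix_factory([[1.0], [np.nan]])
    with pytest.raises(DomainError):
        discretize_features(fm, bins_for_numeric=2)
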