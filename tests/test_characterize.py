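"""Wilks-lambda selection, tree distillation and association tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micalung import (
    associate,
    fit_tree,
    stepwise_forward_wilks,
    summarize_clusters,
    wilks_lambda,
)
from micalung.characterize import upper_lower_ratios
from micalung.pipeline import TREE_CANDIDATES

from _oracles import brute_wilks

# ---------------------------------------------------------------- Wilks' lambda


def test_wilks_no_separation_is_one():
    X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
    labels = np.array([0, 0, 0, 1, 1, 1])
    assert wilks_lambda(X, labels) == pytest.approx(1.0)


def test_wilks_perfect_separation_is_zero():
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    labels = np.array([0, 0, 1, 1])
    assert wilks_lambda(X, labels) == pytest.approx(0.0)


def test_wilks_matches_brute_force_determinant_ratio():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.standard_normal((4, 2)), rng.standard_normal((4, 2)) + 1.5])
    labels = np.repeat([0, 1], 4)
    assert wilks_lambda(X, labels) == pytest.approx(brute_wilks(X, labels), abs=1e-12)


@given(scale=st.floats(0.01, 100.0), shift=st.floats(-50.0, 50.0))
@settings(max_examples=50, deadline=None)
def test_wilks_affine_invariance(scale, shift):
    """Lambda is unchanged by rescaling/shifting any selected variable."""
    rng = np.random.default_rng(1)
    X = np.vstack([rng.standard_normal((6, 3)), rng.standard_normal((6, 3)) + 1.0])
    labels = np.repeat([0, 1], 6)
    lam = wilks_lambda(X, labels)
    X2 = X.copy()
    X2[:, 1] = X2[:, 1] * scale + shift
    assert wilks_lambda(X2, labels) == pytest.approx(lam, rel=1e-8)


def test_wilks_rejects_degenerate_groups():
    with pytest.raises(ValueError):
        wilks_lambda(np.ones((3, 1)), np.array([0, 0, 0]))
    with pytest.raises(ValueError):
        wilks_lambda(np.arange(4.0).reshape(4, 1), np.array([0, 0, 0, 1]))


# ---------------------------------------------------------------- stepwise


def test_perfect_separator_enters_first():
    rng = np.random.default_rng(2)
    n = 20
    labels = np.repeat([0, 1], n // 2)
    X = pd.DataFrame({
        "noise_a": rng.standard_normal(n),
        "separator": labels * 10.0 + 0.01 * rng.standard_normal(n),
        "noise_b": rng.standard_normal(n),
    })
    path = stepwise_forward_wilks(X, labels, max_vars=3)
    assert path.variables[0] == "separator"


def test_stepwise_path_is_monotone_and_bounded(smokers, fitted):
    path = stepwise_forward_wilks(smokers.data, fitted.labels_, max_vars=10)
    lams = path.lambdas
    assert len(lams) <= 10
    assert all(0.0 < lam <= 1.0 for lam in lams)
    assert all(a > b for a, b in zip(lams, lams[1:]))  # strictly decreasing


def test_fsad_total_leads_the_selection_path(smokers, fitted):
    """The total small-airways-disease burden is the strongest discriminant
    of the four imaging clusters."""
    path = stepwise_forward_wilks(smokers.data, fitted.labels_, max_vars=3)
    assert path.variables[0] == "fSAD% Total"
    assert path.lambdas[0] == pytest.approx(0.28, abs=0.05)


# ---------------------------------------------------------------- tree


def test_tree_depth_one_on_separable_toy():
    X = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)]})
    y = np.repeat([0, 1], 10)
    tree = fit_tree(X, y)
    assert tree.accuracy_ == 1.0
    assert tree.variables_used_ == ["x"]
    assert tree.tree_.get_depth() == 1


def test_tree_respects_variable_budget_and_beats_single_variable(smokers, fitted):
    full = fit_tree(smokers.data, fitted.labels_, candidate_variables=TREE_CANDIDATES,
                    random_state=0)
    assert len(full.variables_used_) <= 7
    single = fit_tree(smokers.data, fitted.labels_,
                      candidate_variables=["fSAD% Total"], random_state=0)
    assert single.accuracy_ < full.accuracy_


def test_tree_accuracy_monotone_in_complexity(smokers, fitted):
    loose = fit_tree(smokers.data, fitted.labels_, candidate_variables=TREE_CANDIDATES,
                     max_distinct_vars=7, random_state=0)
    tight = fit_tree(smokers.data, fitted.labels_, candidate_variables=TREE_CANDIDATES,
                     max_distinct_vars=2, random_state=0)
    assert len(tight.variables_used_) <= 2
    assert tight.accuracy_ <= loose.accuracy_


def test_tree_rejects_single_class():
    with pytest.raises(ValueError):
        fit_tree(pd.DataFrame({"x": [1.0, 2.0]}), np.zeros(2))


def test_tree_serialization_roundtrip(tmp_path, smokers, fitted):
    tree = fit_tree(smokers.data, fitted.labels_, candidate_variables=TREE_CANDIDATES,
                    random_state=0)
    d = tree.to_dict()
    assert set(d) == {"variables", "resubstitution_accuracy", "root"}
    rules = tree.to_rules()
    assert "fSAD% Total" in rules or "Jacobian Total" in rules
    tree.to_json(tmp_path / "tree.json")
    assert (tmp_path / "tree.json").exists()


# ---------------------------------------------------------------- associations


def test_chi_square_hand_computed_2x2():
    labels = np.repeat([0, 1], 30)
    var = pd.Series(["a"] * 20 + ["b"] * 10 + ["a"] * 10 + ["b"] * 20)
    out = associate(labels, pd.DataFrame({"v": var}))
    assert out.loc["v", "statistic"] == pytest.approx(20 / 3, abs=1e-9)
    assert out.loc["v", "test"].startswith("chi-square")


def test_identical_distribution_gives_large_p():
    labels = np.repeat([0, 1, 2], 20)
    clin = pd.DataFrame({"v": np.tile(np.arange(20.0), 3)})
    out = associate(labels, clin)
    assert out.loc["v", "p_value"] > 0.95


def test_association_invariance_to_relabeling(smokers, fitted, cohort):
    _, clinical = cohort
    clin = clinical.loc[smokers.data.index].drop(columns="true_cluster")
    a = associate(fitted.labels_, clin)
    b = associate((fitted.labels_ + 1) % 4, clin)
    assert np.allclose(a["p_value"].to_numpy(), b["p_value"].to_numpy())


def test_clinical_directional_regimes(smokers, fitted, cohort):
    """BMI peaks in the obese airway-thickening cluster; age increases toward
    the severe emphysema-fSAD cluster."""
    _, clinical = cohort
    clin = clinical.loc[smokers.data.index]
    truth = smokers.true_cluster.to_numpy()
    bmi = [clin["bmi"][truth == g].mean() for g in (1, 2, 3, 4)]
    assert np.argmax(bmi) == 1  # cluster 2
    age = [clin["age"][truth == g].mean() for g in (1, 2, 3, 4)]
    assert age == sorted(age)
    out = associate(fitted.labels_, clin.drop(columns="true_cluster"))
    assert out.loc["bmi", "p_value"] < 0.05
    assert out.loc["gold_stage", "test"].startswith("chi-square")


# ---------------------------------------------------------------- summaries


def test_summary_equals_global_means_for_single_cluster():
    rng = np.random.default_rng(6)
    data = pd.DataFrame({"a": rng.standard_normal(10)})
    table = summarize_clusters(data, np.zeros(10, dtype=int), include_ratios=False)
    expected = f"{data['a'].mean():.3g} ({data['a'].std(ddof=1):.3g})"
    assert table.loc["a", "cluster_0"] == expected


def test_upper_lower_ratio_arithmetic():
    cols = {f"fSAD% {lb}": [3.0] for lb in ("RUL", "LUL", "RML", "RLL", "LLL")}
    cols.update({f"Emph% {lb}": [2.0] for lb in ("RUL", "LUL", "RML", "RLL", "LLL")})
    cols["fSAD% Total"] = [3.0]
    cols["Emph% Total"] = [2.0]
    df = pd.DataFrame(cols)
    ratios = upper_lower_ratios(df)
    # equal lobar burden: upper 2 lobes over lower 3 lobes = 2/3
    assert ratios["fSAD% U/L"].iloc[0] == pytest.approx(2.0 / 3.0)
    assert ratios["Emph% U/L"].iloc[0] == pytest.approx(2.0 / 3.0)
    assert ratios["fSAD/Emph Total"].iloc[0] == pytest.approx(1.5)


def test_summary_unknown_variable_rejected(smokers, fitted):
    with pytest.raises(KeyError):
        summarize_clusters(smokers.data, fitted.labels_, variables=["nope"])
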