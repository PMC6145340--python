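"""Post-clustering characterization: Wilks-lambda stepwise discriminant
variable selection, a compact decision tree distilling cluster membership,
and cluster-vs-clinical association tables.

Wilks' lambda for a variable subset is det(W)/det(T), the ratio of the
pooled within-group to the total cross-product determinant on those
columns: 1 means no group separation, values near 0 strong separation.
The stepwise selector greedily adds the variable that minimises lambda,
stopping when the partial F-to-enter falls below a threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .voxel_metrics import MIDDLE_LOWER_LOBES, UPPER_LOBES


def _columns(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _scatter_matrices(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for g in np.unique(labels):
        Xg = X[labels == g]
        W += (Xg - Xg.mean(axis=0)).T @ (Xg - Xg.mean(axis=0))
    return W, T


def wilks_lambda(X, labels, variable_subset=None) -> float:
    """Wilks' lambda det(W)/det(T) on the chosen columns.

    ``variable_subset`` may hold column names (DataFrame input) or indices.
    """
    arr, names = _columns(X)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    if variable_subset is not None:
        if len(variable_subset) == 0:
            raise ValueError("variable subset is empty")
        idx = [names.index(v) if isinstance(v, str) else int(v) for v in variable_subset]
        arr = arr[:, idx]
    W, T = _scatter_matrices(arr, labels)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise ValueError(
            f"singular total scatter matrix (cond={np.linalg.cond(T):.3g}); "
            "remove collinear variables"
        )
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0:
        return 0.0  # zero within-group variance: perfect separation
    return float(np.exp(logdet_w - logdet_t))


@dataclass
class SelectionStep:
    variable: str
    wilks_lambda: float      # lambda of the selected set after entry
    f_to_enter: float
    single_lambda: float     # one-variable lambda of this variable alone


@dataclass
class SelectionPath:
    steps: list[SelectionStep]
    stopping_reason: str

    @property
    def variables(self) -> list[str]:
        return [s.variable for s in self.steps]

    @property
    def lambdas(self) -> list[float]:
        return [s.wilks_lambda for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"variable": s.variable, "wilks_lambda": s.wilks_lambda,
              "F_to_enter": s.f_to_enter, "single_variable_lambda": s.single_lambda}
             for s in self.steps]
        )


class WilksForwardSelector(BaseEstimator):
    """Greedy forward discriminant variable selection by Wilks' lambda.

    At each step the variable giving the smallest lambda jointly with the
    current set enters, provided its partial F-to-enter

        F = (1 - r) / r * (n - g - p) / (g - 1),  r = lambda_new / lambda_old

    (n subjects, g groups, p variables already entered) reaches
    ``f_to_enter``.  Both the set lambda after entry and each variable's
    single-variable lambda are recorded, since published rankings may quote
    either.
    """

    def __init__(self, max_vars: int = 10, f_to_enter: float = 3.84):
        self.max_vars = max_vars
        self.f_to_enter = f_to_enter

    def fit(self, X, y):
        arr, names = _columns(X)
        labels = np.asarray(y)
        n = len(labels)
        g = np.unique(labels).size
        selected: list[int] = []
        remaining = list(range(arr.shape[1]))
        steps: list[SelectionStep] = []
        lam_prev = 1.0
        reason = "max_vars reached"
        while len(selected) < self.max_vars and remaining:
            best_j, best_lam = None, np.inf
            for j in remaining:
                try:
                    lam = wilks_lambda(arr, labels, selected + [j])
                except ValueError:
                    continue
                if lam < best_lam:
                    best_j, best_lam = j, lam
            if best_j is None:
                if not steps:
                    raise ValueError("no admissible variable at step 1")
                reason = "no admissible variable"
                break
            r = best_lam / lam_prev if lam_prev > 0 else 0.0
            p = len(selected)
            f_stat = np.inf if r == 0 else (1 - r) / r * (n - g - p) / (g - 1)
            if f_stat < self.f_to_enter:
                reason = f"F-to-enter {f_stat:.3g} below threshold"
                break
            if best_lam >= lam_prev:
                reason = "lambda no longer decreasing"
                break
            steps.append(SelectionStep(
                variable=names[best_j],
                wilks_lambda=best_lam,
                f_to_enter=float(f_stat),
                single_lambda=wilks_lambda(arr, labels, [best_j]),
            ))
            selected.append(best_j)
            remaining.remove(best_j)
            lam_prev = best_lam
        self.path_ = SelectionPath(steps, reason)
        self.selected_variables_ = self.path_.variables
        return self


def stepwise_forward_wilks(X, labels, max_vars: int = 10, f_to_enter: float = 3.84) -> SelectionPath:
    """Functional wrapper over :class:`WilksForwardSelector`."""
    return WilksForwardSelector(max_vars=max_vars, f_to_enter=f_to_enter).fit(X, labels).path_


# --------------------------------------------------------------------------
# Decision-tree distillation
# --------------------------------------------------------------------------


class ClusterTree(BaseEstimator, ClassifierMixin):
    """Compact Gini decision tree predicting cluster membership.

    Grows a binary CART on the candidate variables (leaf size floor 5) and,
    if needed, prunes by cost complexity until at most
    ``max_distinct_vars`` distinct variables are split on.  ``prune='1se'``
    additionally prunes to the smallest tree within one cross-validated
    standard error of the best accuracy — a more parsimonious operating
    point than the published resubstitution-accuracy regime this class
    targets by default.

    Attributes: ``tree_`` (the fitted sklearn tree), ``variables_used_``,
    ``accuracy_`` (resubstitution accuracy against the fitted labels).
    """

    def __init__(
        self,
        candidate_variables: list[str] | None = None,
        max_distinct_vars: int = 7,
        prune: str | None = None,
        cv: int = 5,
        min_samples_leaf: int = 5,
        random_state: int | None = None,
    ):
        self.candidate_variables = candidate_variables
        self.max_distinct_vars = max_distinct_vars
        self.prune = prune
        self.cv = cv
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def _distinct_vars(self, tree: DecisionTreeClassifier) -> list[int]:
        feats = tree.tree_.feature
        return sorted(set(int(f) for f in feats if f >= 0))

    def fit(self, X, y):
        arr, names = _columns(X)
        labels = np.asarray(y)
        if np.unique(labels).size < 2:
            raise ValueError("labels are single-class; nothing to distil")
        if self.candidate_variables is not None:
            idx = [names.index(v) for v in self.candidate_variables]
            arr = arr[:, idx]
            names = [names[i] for i in idx]
        self.feature_names_ = names

        def grow(alpha: float) -> DecisionTreeClassifier:
            return DecisionTreeClassifier(
                criterion="gini",
                min_samples_leaf=self.min_samples_leaf,
                ccp_alpha=alpha,
                random_state=self.random_state,
            ).fit(arr, labels)

        full = grow(0.0)
        path = full.cost_complexity_pruning_path(arr, labels)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        if self.prune == "1se" and len(alphas) > 1:
            cv = StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state)
            mean_acc = np.zeros(len(alphas))
            se_acc = np.zeros(len(alphas))
            for i, a in enumerate(alphas):
                accs = []
                for tr, te in cv.split(arr, labels):
                    t = DecisionTreeClassifier(
                        criterion="gini",
                        min_samples_leaf=self.min_samples_leaf,
                        ccp_alpha=a,
                        random_state=self.random_state,
                    ).fit(arr[tr], labels[tr])
                    accs.append(t.score(arr[te], labels[te]))
                mean_acc[i] = np.mean(accs)
                se_acc[i] = np.std(accs, ddof=1) / np.sqrt(len(accs))
            best = int(np.argmax(mean_acc))
            cutoff = mean_acc[best] - se_acc[best]
            # largest alpha (smallest tree) whose CV accuracy stays above cutoff
            ok = np.nonzero(mean_acc >= cutoff)[0]
            alpha = float(alphas[ok.max()])
        else:
            alpha = 0.0
        tree = grow(alpha)
        # enforce the distinct-variable budget by pruning harder
        ai = int(np.searchsorted(alphas, alpha))
        while len(self._distinct_vars(tree)) > self.max_distinct_vars and ai < len(alphas) - 1:
            ai += 1
            tree = grow(float(alphas[ai]))
        self.tree_ = tree
        self.classes_ = tree.classes_
        self.variables_used_ = [names[i] for i in self._distinct_vars(tree)]
        self.accuracy_ = float(tree.score(arr, labels))
        return self

    def predict(self, X):
        arr, names = _columns(X)
        if self.candidate_variables is not None and names != self.feature_names_:
            idx = [names.index(v) for v in self.feature_names_]
            arr = arr[:, idx]
        return self.tree_.predict(arr)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        t = self.tree_.tree_

        def node(i: int) -> dict:
            if t.children_left[i] == -1:
                counts = t.value[i][0]
                return {"leaf": True,
                        "cluster": int(self.classes_[int(np.argmax(counts))]),
                        "n": int(t.n_node_samples[i])}
            return {
                "leaf": False,
                "variable": self.feature_names_[int(t.feature[i])],
                "threshold": float(t.threshold[i]),
                "left": node(int(t.children_left[i])),
                "right": node(int(t.children_right[i])),
            }

        return {"variables": self.variables_used_,
                "resubstitution_accuracy": self.accuracy_,
                "root": node(0)}

    def to_rules(self) -> str:
        """Human-readable nested split rules."""
        lines: list[str] = []

        def walk(d: dict, depth: int) -> None:
            pad = "  " * depth
            if d["leaf"]:
                lines.append(f"{pad}-> cluster {d['cluster']} (n={d['n']})")
                return
            lines.append(f"{pad}if {d['variable']} <= {d['threshold']:.4g}:")
            walk(d["left"], depth + 1)
            lines.append(f"{pad}else:")
            walk(d["right"], depth + 1)

        walk(self.to_dict()["root"], 0)
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_tree(
    X,
    labels,
    candidate_variables: list[str] | None = None,
    max_distinct_vars: int = 7,
    prune: str | None = None,
    random_state: int | None = None,
) -> ClusterTree:
    """Functional wrapper over :class:`ClusterTree`."""
    return ClusterTree(
        candidate_variables=candidate_variables,
        max_distinct_vars=max_distinct_vars,
        prune=prune,
        random_state=random_state,
    ).fit(X, labels)


# --------------------------------------------------------------------------
# Association tables and cluster summaries
# --------------------------------------------------------------------------


def associate(
    labels,
    clinical: pd.DataFrame,
    continuous_test: str = "kruskal",
    alpha: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-variable cluster association tests with formatted summaries.

    Numeric columns get the Kruskal-Wallis test (or one-way ANOVA when
    ``continuous_test='anova'``); non-numeric columns a chi-square test on
    the clusters x levels contingency table without continuity correction.
    Raw p-values are reported at the ``alpha`` significance level;
    Benjamini-Hochberg adjustment is off by default and available behind
    ``bh_adjust``.
    """
    labels = np.asarray(labels)
    if len(labels) != len(clinical):
        raise ValueError("clinical rows are not aligned to cluster labels")
    clusters = np.unique(labels)
    rows = []
    for col in clinical.columns:
        series = clinical[col]
        if pd.api.types.is_numeric_dtype(series):
            groups = [series.to_numpy()[labels == c] for c in clusters]
            groups = [g[~np.isnan(g)] for g in groups]
            if continuous_test == "anova":
                stat, p = stats.f_oneway(*groups)
                test = "anova"
            else:
                stat, p = stats.kruskal(*groups)
                test = "kruskal-wallis"
            summaries = {
                f"cluster_{c}": f"{g.mean():.2f} ({g.std(ddof=1):.2f})"
                for c, g in zip(clusters, groups)
            }
        else:
            table = pd.crosstab(labels, series)
            res = stats.chi2_contingency(table.to_numpy(), correction=False)
            stat, p, expected = res.statistic, res.pvalue, res.expected_freq
            test = "chi-square"
            if (expected < 1).any():
                warnings.warn(
                    f"{col!r}: expected cell counts < 1; consider an exact test"
                )
                test = "chi-square (low expected counts)"
            pct = table.div(table.sum(axis=1), axis=0) * 100
            summaries = {
                f"cluster_{c}": "/".join(f"{v:.0f}" for v in pct.loc[c])
                for c in clusters
            }
        rows.append({"variable": col, "test": test, "statistic": float(stat),
                     "p_value": float(p), **summaries})
    out = pd.DataFrame(rows).set_index("variable")
    if bh_adjust:
        m = len(out)
        order = np.argsort(out["p_value"].to_numpy())
        adj = np.empty(m)
        prev = 1.0
        for rank, i in list(enumerate(order, start=1))[::-1]:
            prev = min(prev, out["p_value"].iloc[i] * m / rank)
            adj[i] = prev
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out


def upper_lower_ratios(data: pd.DataFrame, eps: float = 1e-9) -> pd.DataFrame:
    """Per-subject upper/(middle+lower)-zone burden ratios of fSAD% and
    Emph% from the lobar columns, plus the fSAD/Emph total ratio.  Subjects
    with zero lower-zone burden (or zero Emph% Total) yield NaN."""
    out = pd.DataFrame(index=data.index)
    for metric in ("fSAD%", "Emph%"):
        upper = sum(data[f"{metric} {lb}"] for lb in UPPER_LOBES)
        lower = sum(data[f"{metric} {lb}"] for lb in MIDDLE_LOWER_LOBES)
        out[f"{metric} U/L"] = np.where(lower > eps, upper / lower, np.nan)
    tot_emph = data["Emph% Total"]
    out["fSAD/Emph Total"] = np.where(tot_emph > eps, data["fSAD% Total"] / tot_emph, np.nan)
    return out


def summarize_clusters(
    data: pd.DataFrame,
    labels,
    variables: list[str] | None = None,
    include_ratios: bool = True,
) -> pd.DataFrame:
    """Per-cluster mean (SD) table, optionally with upper/lower-zone ratios."""
    labels = np.asarray(labels)
    variables = variables or list(data.columns)
    unknown = [v for v in variables if v not in data.columns]
    if unknown:
        raise KeyError(f"unknown variables: {unknown[:5]}")
    table = data[variables].copy()
    if include_ratios:
        needed = [f"{m} {lb}" for m in ("fSAD%", "Emph%")
                  for lb in UPPER_LOBES + MIDDLE_LOWER_LOBES]
        if all(c in data.columns for c in needed) and "Emph% Total" in data.columns:
            table = pd.concat([table, upper_lower_ratios(data)], axis=1)
    rows = {}
    for c in np.unique(labels):
        sub = table.loc[labels == c]
        rows[f"cluster_{c}"] = {
            v: f"{sub[v].mean():.3g} ({sub[v].std(ddof=1):.3g})" for v in table.columns
        }
    return pd.DataFrame(rows)
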