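"""Shadow-feature random-forest relevance scoring for binary group labels.

The method asks, for every OTU, whether a random forest finds it more useful
for telling treatment from control samples than an explicitly
uninformative copy of itself.  Each original feature is paired with a
*shadow feature* — the same values randomly permuted across samples, which
destroys any association with the label while preserving the marginal
distribution.  A forest is fitted to the augmented matrix and each column is
scored by its out-of-bag (OOB) permutation variable-importance metric (VIM):
the mean drop in a tree's OOB accuracy when the column is shuffled among the
tree's OOB samples.

This fit is repeated many times with fresh shadow permutations.  A feature's
*relevance likelihood* is ``100 × (1 − p)`` where ``p`` comes from a
one-sided Welch t-test of the feature's per-repetition VIMs against those of
the strongest shadow (the shadow with the highest mean VIM).  Comparing
against the best of all shadows makes the gate family-wise: a feature must
beat the maximum a null feature achieved, not merely an average one.  An OTU
is selected when its likelihood clears the threshold *and* its mean VIM
clears a minimum-importance floor.

:class:`ShadowRelevanceSelector` packages the procedure as a scikit-learn
feature selector (``fit`` / ``transform`` / ``get_support``); the module
functions expose the individual steps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .tables import relative_abundance, validate_metadata

DIRECTION_INCREASED = "increased"
DIRECTION_DECREASED = "decreased"
DIRECTION_UNCHANGED = "unchanged"


def make_shadow_features(X: np.ndarray, seed=None) -> np.ndarray:
    """Append one permuted copy of every column of ``X``.

    Column ``p + j`` of the result is an independent random permutation of
    column ``j``; values per column are preserved as a multiset.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError(f"X must be 2-D with >= 2 samples, got shape {X.shape}")
    rng = np.random.default_rng(seed)
    shadows = np.empty_like(X)
    for j in range(X.shape[1]):
        shadows[:, j] = rng.permutation(X[:, j])
    return np.hstack([X, shadows])


def fit_forest_vim(
    X_aug: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    vim_metric: str = "oob_permutation_accuracy",
    seed=None,
) -> np.ndarray:
    """Fit one forest on the shadow-augmented matrix and score every column.

    With the default metric the score of column ``j`` is the mean over trees
    of (OOB accuracy − OOB accuracy with column ``j`` permuted among that
    tree's OOB samples); columns a tree never splits on contribute exactly 0
    for that tree.  ``vim_metric="impurity"`` returns the forest's
    mean-decrease-impurity importances instead.
    """
    X_aug = np.asarray(X_aug, dtype=np.float64)
    y = np.asarray(y)
    if X_aug.shape[1] % 2 != 0:
        raise ValueError("augmented matrix must have an even number of columns")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"y must be binary, found classes {classes.tolist()}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    forest_seed, perm_ss = ss.spawn(2)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        bootstrap=True,
        n_jobs=1,
        random_state=int(forest_seed.generate_state(1)[0] % (2**31)),
    )
    forest.fit(X_aug, y)
    if vim_metric == "impurity":
        return forest.feature_importances_
    if vim_metric != "oob_permutation_accuracy":
        raise ValueError(f"unknown vim_metric {vim_metric!r}")
    return _oob_permutation_vim(forest, X_aug, y, np.random.default_rng(perm_ss))


def _oob_permutation_vim(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray, rng
) -> np.ndarray:
    """Breiman OOB permutation importance, averaged over trees.

    For speed, only the features a tree actually splits on are permuted —
    any other permutation cannot change that tree's predictions, so its
    accuracy drop is identically zero.
    """
    n_samples, n_features = X.shape
    y_enc = np.searchsorted(forest.classes_, y)
    n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples, None)
    vim = np.zeros(n_features)
    n_used = 0
    for tree in forest.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n_samples, n_boot, None)
        if len(oob) == 0:
            continue
        n_used += 1
        X_oob = X[oob]
        y_oob = y_enc[oob]
        acc0 = float(np.mean(tree.predict(X_oob) == y_oob))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if len(used) == 0:
            continue
        m = len(oob)
        block = np.repeat(X_oob[None, :, :], len(used), axis=0)
        for k, j in enumerate(used):
            block[k, :, j] = rng.permutation(X_oob[:, j])
        preds = tree.predict(block.reshape(len(used) * m, n_features))
        accs = (preds.reshape(len(used), m) == y_oob).mean(axis=1)
        vim[used] += acc0 - accs
    if n_used == 0:
        raise RuntimeError("no tree had out-of-bag samples; cannot compute OOB VIM")
    return vim / n_used


def stability_vims(
    X: np.ndarray,
    y: np.ndarray,
    n_repetitions: int = 50,
    n_trees: int = 500,
    vim_metric: str = "oob_permutation_accuracy",
    seed=None,
) -> np.ndarray:
    """VIMs across repeated forest fits, fresh shadow permutations each time.

    Returns a ``2p × n_repetitions`` matrix: real features first, their
    shadows second, one column per repetition.  Regenerating the shadows
    every repetition is what makes the strongest shadow's VIMs a proper null
    sample rather than one frozen permutation's quirk.
    """
    if n_repetitions < 2:
        raise ValueError(f"n_repetitions must be >= 2, got {n_repetitions}")
    X = np.asarray(X, dtype=np.float64)
    reps = []
    for rep_ss in np.random.SeedSequence(seed).spawn(n_repetitions):
        shadow_ss, forest_ss = rep_ss.spawn(2)
        X_aug = make_shadow_features(X, shadow_ss)
        reps.append(fit_forest_vim(X_aug, y, n_trees, vim_metric, forest_ss))
    return np.column_stack(reps)


def _welch_one_sided_greater(a: np.ndarray, b: np.ndarray) -> float:
    """p-value of Welch's t-test for H1: mean(a) > mean(b).

    Degenerate zero-variance-in-both case: 0 / 1 / 0.5 by comparison of the
    means (a deterministic difference is certain, a tie is a coin flip).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        ma, mb = a.mean(), b.mean()
        return 0.0 if ma > mb else (1.0 if ma < mb else 0.5)
    return float(stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue)


def relevance_likelihood(vims: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-real-feature (p_value, likelihood_pct) against the strongest shadow.

    ``vims`` is the ``2p × n_repetitions`` matrix from :func:`stability_vims`.
    The reference is the shadow row with the highest mean VIM; each real
    feature's per-repetition VIMs are tested one-sided (greater) against it
    with Welch's unequal-variance t-test, repetitions treated as independent
    draws.  ``likelihood_pct = 100 * (1 − p)``.
    """
    vims = np.asarray(vims, dtype=float)
    if vims.ndim != 2 or vims.shape[0] % 2 != 0 or vims.shape[0] == 0:
        raise ValueError("vims must be a non-empty 2p x n_repetitions matrix")
    if vims.shape[1] < 2:
        raise ValueError("need >= 2 repetitions for the t-test")
    p = vims.shape[0] // 2
    shadow_block = vims[p:]
    top_shadow = shadow_block[np.argmax(shadow_block.mean(axis=1))]
    pvals = np.array([_welch_one_sided_greater(vims[j], top_shadow) for j in range(p)])
    return pvals, 100.0 * (1.0 - pvals)


def direction_of_change(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    otu_ids=None,
) -> pd.DataFrame:
    """Direction and fold change of each OTU between treatment and control.

    Fold change is the ratio of group-mean relative abundances
    (treatment / control).  When either group mean is zero, a
    pseudo-fraction — half the smallest nonzero relative abundance in the
    table — is added to both means so OTUs absent from one arm still get a
    finite ratio; OTUs observed in both arms keep the exact ratio.
    ``fold_change > 1`` is ``increased``, ``< 1`` ``decreased``, exact ties
    ``unchanged``.
    """
    validate_metadata(meta, table)
    if otu_ids is None:
        otu_ids = list(table.columns)
    else:
        missing = [o for o in otu_ids if o not in table.columns]
        if missing:
            raise ValueError(f"OTUs absent from table: {missing}")
    groups = meta.loc[table.index, "group"]
    if set(groups.unique()) != {"control", "treatment"}:
        raise ValueError("both control and treatment samples are required")
    rel = relative_abundance(table)
    control_mean = rel.loc[(groups == "control").to_numpy()].mean(axis=0)
    treat_mean = rel.loc[(groups == "treatment").to_numpy()].mean(axis=0)
    nonzero = rel.to_numpy()[rel.to_numpy() > 0]
    eps = 0.5 * nonzero.min() if nonzero.size else 1e-12
    needs_eps = (control_mean == 0) | (treat_mean == 0)
    fold = (treat_mean + needs_eps * eps) / (control_mean + needs_eps * eps)
    out = pd.DataFrame(
        {
            "control_mean": control_mean,
            "treatment_mean": treat_mean,
            "fold_change": fold,
        }
    ).loc[list(otu_ids)]
    out["direction"] = np.select(
        [out["fold_change"] > 1, out["fold_change"] < 1],
        [DIRECTION_INCREASED, DIRECTION_DECREASED],
        DIRECTION_UNCHANGED,
    )
    return out


class ShadowRelevanceSelector(SelectorMixin, BaseEstimator):
    """Select features whose forest importance beats the strongest shadow.

    Parameters
    ----------
    n_repetitions : int, default=50
        Forest refits, each with freshly permuted shadow features.
    n_trees : int, default=500
        Trees per forest.
    vim_metric : {"oob_permutation_accuracy", "impurity"}
        Per-feature importance score; the default is the mean per-tree drop
        in out-of-bag accuracy when the feature is permuted.
    likelihood_threshold : float, default=99.5
        Minimum relevance likelihood (percent) for selection.  The default
        is "100% at integer reporting precision", i.e. ``p <= 0.005``
        against the strongest shadow.
    importance_threshold : float, default=0.001
        Minimum mean VIM (an absolute accuracy fraction under the default
        metric) for selection.
    random_state : int or None
        Master seed; split internally into per-repetition shadow, bootstrap
        and OOB-permutation streams.

    Attributes
    ----------
    vim_matrix_ : ndarray of shape (2 * n_features, n_repetitions)
        Per-repetition VIMs, real features then shadows.
    mean_vim_ : ndarray of shape (n_features,)
    p_values_, likelihood_pct_ : ndarray of shape (n_features,)
    top_shadow_mean_vim_ : float
    support_ : boolean ndarray of shape (n_features,)

    Examples
    --------
    >>> sel = ShadowRelevanceSelector(n_repetitions=10, n_trees=100,
    ...                               random_state=0).fit(X, y)
    >>> X_relevant = sel.transform(X)
    """

    def __init__(
        self,
        n_repetitions: int = 50,
        n_trees: int = 500,
        vim_metric: str = "oob_permutation_accuracy",
        likelihood_threshold: float = 99.5,
        importance_threshold: float = 0.001,
        random_state=None,
    ):
        self.n_repetitions = n_repetitions
        self.n_trees = n_trees
        self.vim_metric = vim_metric
        self.likelihood_threshold = likelihood_threshold
        self.importance_threshold = importance_threshold
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        if self.n_repetitions < 2:
            raise ValueError("n_repetitions must be >= 2")
        if self.likelihood_threshold < 0 or self.importance_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        self.n_features_in_ = X.shape[1]
        self.vim_matrix_ = stability_vims(
            X,
            y,
            n_repetitions=self.n_repetitions,
            n_trees=self.n_trees,
            vim_metric=self.vim_metric,
            seed=self.random_state,
        )
        p = self.n_features_in_
        self.mean_vim_ = self.vim_matrix_[:p].mean(axis=1)
        shadow_means = self.vim_matrix_[p:].mean(axis=1)
        self.top_shadow_mean_vim_ = float(shadow_means.max())
        self.p_values_, self.likelihood_pct_ = relevance_likelihood(self.vim_matrix_)
        self.support_ = (self.likelihood_pct_ >= self.likelihood_threshold) & (
            self.mean_vim_ >= self.importance_threshold
        )
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def results_frame(self, feature_names=None) -> pd.DataFrame:
        """Per-feature scores sorted by mean VIM (descending, ties by name)."""
        check_is_fitted(self)
        if feature_names is None:
            feature_names = [f"feature_{j}" for j in range(self.n_features_in_)]
        out = pd.DataFrame(
            {
                "mean_vim": self.mean_vim_,
                "likelihood_pct": self.likelihood_pct_,
                "p_value": self.p_values_,
                "selected": self.support_,
            },
            index=pd.Index(feature_names, name="otu_id"),
        )
        return out.sort_values(
            ["mean_vim", "otu_id"], ascending=[False, True], kind="mergesort"
        )


def select_relevant(
    results: pd.DataFrame,
    likelihood_threshold: float = 99.5,
    importance_threshold: float = 0.001,
) -> pd.DataFrame:
    """Threshold a results frame on likelihood and mean VIM.

    Returns the selected rows sorted by mean VIM descending, ties broken by
    OTU id; an empty selection is a valid outcome.
    """
    mask = (results["likelihood_pct"] >= likelihood_threshold) & (
        results["mean_vim"] >= importance_threshold
    )
    out = results.loc[mask].copy()
    return out.sort_values(
        ["mean_vim", "otu_id"], ascending=[False, True], kind="mergesort"
    )


def run_relevance_analysis(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    n_repetitions: int = 50,
    n_trees: int = 500,
    vim_metric: str = "oob_permutation_accuracy",
    likelihood_threshold: float = 99.5,
    importance_threshold: float = 0.001,
    use_relative_abundance: bool = True,
    seed=None,
) -> pd.DataFrame:
    """Full relevance analysis of an OTU table against its group labels.

    Features are per-sample relative abundances by default (library size is
    a nuisance variable); set ``use_relative_abundance=False`` to feed raw
    counts.  Returns one row per OTU: ``mean_vim``, ``likelihood_pct``,
    ``p_value``, ``selected``, ``direction`` and ``fold_change``, sorted by
    mean VIM descending.
    """
    validate_metadata(meta, table)
    y = (meta.loc[table.index, "group"] == "treatment").to_numpy().astype(int)
    X = relative_abundance(table) if use_relative_abundance else table
    selector = ShadowRelevanceSelector(
        n_repetitions=n_repetitions,
        n_trees=n_trees,
        vim_metric=vim_metric,
        likelihood_threshold=likelihood_threshold,
        importance_threshold=importance_threshold,
        random_state=seed,
    ).fit(X.to_numpy(dtype=np.float64), y)
    results = selector.results_frame(feature_names=list(table.columns))
    dirs = direction_of_change(table, meta)
    results["direction"] = dirs.loc[results.index, "direction"]
    results["fold_change"] = dirs.loc[results.index, "fold_change"]
    return results
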