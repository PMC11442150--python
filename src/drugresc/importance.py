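"""Drug-instance importance on the D2C matrix.

Observations are cells, features are drug instances.  The default scorer is
a bagged ensemble of classification trees with out-of-bag (OOB) permutation
importance computed on raw correct-vote counts:

    score_d = (1/ntree) * sum_t (C_td - CP_td)

where C_td is the number of correct OOB votes of tree t and CP_td the same
count after permuting feature d within the tree's OOB set (one fresh
permutation per (feature, tree)).  A rate-normalized variant — dividing each
tree's term by its OOB size, the classic mean-decrease-in-accuracy — is
available via ``normalize="rate"``.

Alternative backends score each instance marginally (Wilcoxon rank-sum,
Bartlett-gated ANOVA/Welch F) or jointly (L1 logistic regression with
5-fold cross-validated penalty).  SVM-RBF sensitivity and gradient-boosting
gain are thin adapters over external learners.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .enrichment import D2CMatrix
from .io import CellLabels

logger = logging.getLogger("drugresc")


@dataclass
class ForestModel:
    """A bagged tree ensemble with recorded bootstrap/OOB indices."""

    trees: list[DecisionTreeClassifier]
    bootstrap_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    ntree: int
    mtry: int

    def oob_error(self, X: np.ndarray, y: np.ndarray) -> float:
        """Out-of-bag error: aggregate OOB votes per cell, majority class."""
        n = X.shape[0]
        votes = np.zeros((n, 2))
        for tree, oob in zip(self.trees, self.oob_indices):
            pred = tree.predict(X[oob])
            votes[oob, pred.astype(int)] += 1
        covered = votes.sum(axis=1) > 0
        pred_class = (votes[:, 1] > votes[:, 0]).astype(int)
        # exact vote ties go to class 0; cells never OOB are excluded
        return float(np.mean(pred_class[covered] != y[covered]))


def _as_xy(d2c: D2CMatrix, labels: CellLabels) -> tuple[np.ndarray, np.ndarray]:
    """Cells-by-instances design matrix and aligned binary response."""
    y = labels.aligned_to(d2c.cells)
    if len(np.unique(y)) < 2:
        raise ValueError("both phenotype classes must be present")
    return d2c.scores.T.copy(), y


def fit_forest(
    d2c: D2CMatrix,
    labels: CellLabels,
    ntree: int = 100,
    mtry: int | None = None,
    seed: int = 0,
) -> ForestModel:
    """Fit ``ntree`` classification trees on bootstrap resamples of the cells.

    Each tree draws n cells with replacement; the out-of-bag set is the
    complement of the draw (redrawn in the vanishingly rare case it is
    empty).  Trees use Gini impurity, unlimited depth and minimum leaf size
    1; ``mtry`` features are candidate at each split (default floor(sqrt(D))).
    """
    X, y = _as_xy(d2c, labels)
    n, D = X.shape
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 cells in each class")
    if mtry is None:
        mtry = max(1, int(np.sqrt(D)))
    if not 1 <= mtry <= D:
        raise ValueError(f"mtry={mtry} outside [1, {D}]")
    rng = np.random.default_rng(seed)
    trees, boots, oobs = [], [], []
    all_idx = np.arange(n)
    for t in range(ntree):
        while True:
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(all_idx, boot)
            if oob.size > 0 and len(np.unique(y[boot])) == 2:
                break
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            min_samples_leaf=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        boots.append(boot)
        oobs.append(oob)
    return ForestModel(trees, boots, oobs, ntree, mtry)


def select_mtry(
    d2c: D2CMatrix,
    labels: CellLabels,
    grid: list[int] | None = None,
    ntree: int = 100,
    seed: int = 0,
) -> int:
    """Pick the grid value with minimum OOB error (ties: smallest mtry)."""
    X, y = _as_xy(d2c, labels)
    D = X.shape[1]
    if grid is None:
        root = np.sqrt(D)
        grid = sorted({int(v) for v in (root / 2, root, 2 * root, D / 3) if v >= 1} | {1})
    for m in grid:
        if not 1 <= m <= D:
            raise ValueError(f"mtry candidate {m} outside [1, {D}]")
    best_m, best_err = None, np.inf
    for m in sorted(grid):
        model = fit_forest(d2c, labels, ntree=ntree, mtry=m, seed=seed)
        err = model.oob_error(X, y)
        logger.debug("mtry=%d OOB error %.4f", m, err)
        if err < best_err:
            best_m, best_err = m, err
    return int(best_m)


def drug_score_from_counts(
    correct_votes: np.ndarray, permuted_votes: np.ndarray
) -> float:
    """Importance from per-tree correct-vote counts before/after permutation.

    The mean over trees of C_t - CP_t; exposed separately so the arithmetic
    can be exercised on forced counts.
    """
    c = np.asarray(correct_votes, dtype=float)
    cp = np.asarray(permuted_votes, dtype=float)
    if c.shape != cp.shape or c.ndim != 1:
        raise ValueError("vote-count vectors must be 1-D and aligned")
    return float(np.mean(c - cp))


def oob_permutation_importance(
    model: ForestModel,
    d2c: D2CMatrix,
    labels: CellLabels,
    seed: int = 0,
    normalize: str = "count",
    n_permutations: int = 1,
) -> pd.DataFrame:
    """Permutation importance per drug instance from OOB vote counts.

    ``normalize="count"`` follows the count-based definition above;
    ``"rate"`` divides each tree's contribution by its OOB size.  With
    ``n_permutations > 1`` the per-tree permuted count is averaged over
    independent permutations (variance reduction).
    """
    if normalize not in ("count", "rate"):
        raise ValueError("normalize must be 'count' or 'rate'")
    X, y = _as_xy(d2c, labels)
    D = X.shape[1]
    rng = np.random.default_rng(seed)
    raw = np.zeros(D)
    for tree, oob in zip(model.trees, model.oob_indices):
        X_oob = X[oob]
        y_oob = y[oob]
        c_t = int(np.sum(tree.predict(X_oob) == y_oob))
        scale = 1.0 if normalize == "count" else 1.0 / oob.size
        for d in range(D):
            cp_sum = 0.0
            col = X_oob[:, d]
            if np.all(col == col[0]):
                # permuting a constant changes nothing; keep RNG stream aligned
                for _ in range(n_permutations):
                    rng.permutation(oob.size)
                cp_sum = c_t * n_permutations
            else:
                X_perm = X_oob.copy()
                for _ in range(n_permutations):
                    X_perm[:, d] = col[rng.permutation(oob.size)]
                    cp_sum += int(np.sum(tree.predict(X_perm) == y_oob))
            raw[d] += (c_t - cp_sum / n_permutations) * scale
    raw /= model.ntree
    return _score_frame(d2c.instances, raw, method="random_forest")


def standardize(raw_scores: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to all 0.5."""
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 scores to standardize")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("all raw scores equal; standardized scores set to 0.5")
        return np.full(raw.shape, 0.5)
    return (raw - lo) / (hi - lo)


def _score_frame(
    instances: list[str], raw: np.ndarray, method: str, extra: dict | None = None
) -> pd.DataFrame:
    table = pd.DataFrame({"instance_id": instances, "raw_score": raw, "method": method})
    table["standardized_score"] = standardize(raw) if len(raw) >= 2 else np.nan
    order = sorted(range(len(raw)), key=lambda i: (-raw[i], instances[i]))
    ranks = np.empty(len(raw), dtype=int)
    ranks[order] = np.arange(1, len(raw) + 1)
    table["rank"] = ranks
    if extra:
        for k, v in extra.items():
            table[k] = v
    return table


def wilcoxon_importance(d2c: D2CMatrix, labels: CellLabels) -> pd.DataFrame:
    """-log10 p of the two-sided rank-sum test between phenotype groups."""
    X, y = _as_xy(d2c, labels)
    g1, g0 = X[y == 1], X[y == 0]
    raw = np.empty(X.shape[1])
    for d in range(X.shape[1]):
        a, b = g1[:, d], g0[:, d]
        if np.all(a == a[0]) and np.all(b == a[0]):
            p = 1.0  # all values tied; no evidence of a shift
        else:
            # exact null distribution for small tie-free groups, normal
            # approximation otherwise
            tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
            method = "exact" if tie_free and max(a.size, b.size) <= 25 else "asymptotic"
            p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        raw[d] = -np.log10(max(p, np.finfo(float).tiny))
    return _score_frame(d2c.instances, raw, method="wilcoxon")


def anova_importance(d2c: D2CMatrix, labels: CellLabels, bartlett_level: float = 0.05) -> pd.DataFrame:
    """F statistic per instance; Welch's F when Bartlett rejects homogeneity.

    With two groups Welch's F equals the square of Welch's t, which is how
    the heteroskedastic branch is computed.
    """
    X, y = _as_xy(d2c, labels)
    g1, g0 = X[y == 1], X[y == 0]
    raw = np.empty(X.shape[1])
    welch = np.zeros(X.shape[1], dtype=bool)
    for d in range(X.shape[1]):
        a, b = g1[:, d], g0[:, d]
        if np.var(a) == 0 and np.var(b) == 0:
            raw[d] = 0.0 if a.mean() == b.mean() else np.inf
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            bart_p = scipy.stats.bartlett(a, b).pvalue
        if np.isnan(bart_p) or bart_p >= bartlett_level:
            raw[d] = scipy.stats.f_oneway(a, b).statistic
        else:
            welch[d] = True
            t = scipy.stats.ttest_ind(a, b, equal_var=False).statistic
            raw[d] = t * t
    raw = np.where(np.isfinite(raw), raw, np.nanmax(raw[np.isfinite(raw)], initial=0.0) + 1.0)
    return _score_frame(d2c.instances, raw, method="anova", extra={"welch_branch": welch})


def logistic_l1_importance(d2c: D2CMatrix, labels: CellLabels, seed: int = 0) -> pd.DataFrame:
    """|coefficient| of an L1 logistic fit on standardized D2C columns.

    The penalty strength is chosen by stratified 5-fold cross-validation.
    """
    X, y = _as_xy(d2c, labels)
    Xs = StandardScaler().fit_transform(X)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        penalty="l1",
        solver="liblinear",
        Cs=10,
        cv=cv,
        scoring="neg_log_loss",
        max_iter=1000,
        random_state=seed,
    )
    clf.fit(Xs, y)
    raw = np.abs(clf.coef_.ravel())
    return _score_frame(d2c.instances, raw, method="logistic_l1")


def svm_sensitivity_importance(d2c: D2CMatrix, labels: CellLabels, seed: int = 0, n_grid: int = 21) -> pd.DataFrame:
    """One-dimensional sensitivity of an RBF-SVM decision function.

    Each feature is swept over its observed range with the others held at
    their medians; importance is the range of the decision function along
    the sweep.  Adapter over scikit-learn's SVC.
    """
    from sklearn.svm import SVC

    X, y = _as_xy(d2c, labels)
    Xs = StandardScaler().fit_transform(X)
    clf = SVC(kernel="rbf", random_state=seed).fit(Xs, y)
    med = np.median(Xs, axis=0)
    raw = np.empty(X.shape[1])
    for d in range(X.shape[1]):
        sweep = np.tile(med, (n_grid, 1))
        sweep[:, d] = np.linspace(Xs[:, d].min(), Xs[:, d].max(), n_grid)
        f = clf.decision_function(sweep)
        raw[d] = f.max() - f.min()
    return _score_frame(d2c.instances, raw, method="svm_sensitivity")


def gboost_gain_importance(d2c: D2CMatrix, labels: CellLabels, seed: int = 0, n_rounds: int = 500) -> pd.DataFrame:
    """Gradient-boosting split-gain importance; adapter over xgboost."""
    import xgboost as xgb

    X, y = _as_xy(d2c, labels)
    model = xgb.XGBClassifier(n_estimators=n_rounds, random_state=seed, verbosity=0)
    model.fit(X, y)
    booster = model.get_booster()
    gains = booster.get_score(importance_type="gain")
    raw = np.array([gains.get(f"f{d}", 0.0) for d in range(X.shape[1])])
    return _score_frame(d2c.instances, raw, method="gboost_gain")


def ensemble_vote(tables: list[pd.DataFrame], k: int = 3) -> pd.DataFrame:
    """Candidate instances receiving >= k votes across methods.

    A method votes for an instance when the instance falls in the top half
    of that method's ranking.  Returns one row per instance with the vote
    count as raw score; candidates are flagged in the ``candidate`` column.
    """
    if k > len(tables):
        raise ValueError(f"k={k} exceeds the number of score tables ({len(tables)})")
    instances = list(tables[0]["instance_id"])
    for t in tables[1:]:
        if set(t["instance_id"]) != set(instances):
            raise ValueError("score tables cover different instance sets")
    m = len(instances) // 2
    votes = {i: 0 for i in instances}
    for t in tables:
        top = t.nsmallest(m, "rank")["instance_id"]
        for i in top:
            votes[i] += 1
    raw = np.array([float(votes[i]) for i in instances])
    table = _score_frame(instances, raw, method="vote", extra={"votes": raw.astype(int)})
    table["candidate"] = table["votes"] >= k
    return table
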