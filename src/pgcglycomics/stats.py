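"""Group-discrimination statistics for compositional glycan profiles.

Differential abundance (rank tests + Benjamini-Hochberg), feature selection
by L1-penalized logistic regression and by an out-of-bag
permutation-importance random forest, empirical ROC with Youden operating
points, linear discriminant analysis with Wilks' lambda, and the qPCR
reference-gene normalization.  Stochastic procedures take explicit seeds
and are bit-reproducible given them.

The selectors and the LDA are scikit-learn-style estimators (``fit``,
fitted attributes with trailing underscores, ``get_params``/``set_params``)
so they compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    glycan_id: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    p: float
    p_adj: float = np.nan
    direction: str = ""
    constant: bool = False


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def differential_test(
    profile_df: pd.DataFrame,
    groups: pd.Series,
    method: str = "rank",
) -> list[DifferentialResult]:
    """Per-glycan two/three-group test with BH adjustment across glycans.

    Two groups: Wilcoxon rank-sum (exact when both n <= 25 and no ties,
    normal approximation with continuity correction otherwise); three or
    more: Kruskal-Wallis.  ``method="ttest"`` switches to Welch's t /
    one-way ANOVA.  Constant features get p = 1 and a flag.
    """
    groups = groups.loc[profile_df.index]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    sizes = groups.value_counts()
    if (sizes < 3).any():
        warnings.warn("groups with fewer than 3 samples give unstable p-values")

    results: list[DifferentialResult] = []
    for gid in profile_df.columns:
        values = [profile_df.loc[groups == lv, gid].to_numpy(dtype=float) for lv in levels]
        means = {lv: float(np.mean(v)) for lv, v in zip(levels, values)}
        sds = {lv: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for lv, v in zip(levels, values)}
        pooled = np.concatenate(values)
        if np.allclose(pooled, pooled[0]):
            results.append(
                DifferentialResult(gid, means, sds, p=1.0, constant=True)
            )
            continue
        if len(levels) == 2:
            a, b = values
            if method == "ttest":
                p = stats.ttest_ind(a, b, equal_var=False).pvalue
            else:
                exact = len(a) <= 25 and len(b) <= 25 and len(np.unique(pooled)) == len(pooled)
                p = stats.mannwhitneyu(
                    a, b, alternative="two-sided",
                    method="exact" if exact else "asymptotic",
                ).pvalue
            direction = f"up_{levels[0]}" if means[levels[0]] > means[levels[1]] else f"up_{levels[1]}"
        else:
            if method == "ttest":
                p = stats.f_oneway(*values).pvalue
            else:
                p = stats.kruskal(*values).pvalue
            direction = f"up_{max(means, key=means.get)}"
        results.append(DifferentialResult(gid, means, sds, p=float(p), direction=direction))

    adj = benjamini_hochberg([r.p for r in results])
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
    return results


def differential_table(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"glycan_id": r.glycan_id, "p": r.p, "p_adj": r.p_adj,
               "direction": r.direction, "constant": r.constant}
        for g, m in r.group_means.items():
            row[f"mean_{g}"] = m
            row[f"sd_{g}"] = r.group_sds[g]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

class GlmnetSelector(BaseEstimator, TransformerMixin):
    """L1-penalized (multinomial) logistic feature selector.

    Standardized predictors; a log-spaced penalty path evaluated by k-fold
    cross-validated deviance; features with a nonzero coefficient at the
    chosen penalty are selected.

    Parameters
    ----------
    n_penalties : size of the log-spaced penalty grid.
    cv : number of stratified folds (default 5).
    seed : controls fold shuffling; fixing it makes selection reproducible.
    """

    def __init__(self, n_penalties: int = 25, cv: int = 5, seed: int = 0,
                 max_fold_redraws: int = 10):
        self.n_penalties = n_penalties
        self.cv = cv
        self.seed = seed
        self.max_fold_redraws = max_fold_redraws

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        n_splits = min(self.cv, counts.min())
        if n_splits < 2:
            raise ValueError("smallest class too small for cross-validation")
        last_err = None
        for attempt in range(self.max_fold_redraws):
            folds = StratifiedKFold(
                n_splits=n_splits, shuffle=True, random_state=self.seed + attempt
            )
            try:
                model = LogisticRegressionCV(
                    penalty="l1",
                    solver="saga",
                    Cs=np.logspace(-2.5, 2.5, self.n_penalties),
                    cv=folds,
                    scoring="neg_log_loss",
                    max_iter=5000,
                    tol=1e-4,
                    random_state=self.seed,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(self._scale(X, fit=True), y)
            except ValueError as err:  # degenerate single-class fold
                last_err = err
                continue
            break
        else:
            raise RuntimeError(
                f"cross-validation folds degenerate after {self.max_fold_redraws} redraws"
            ) from last_err
        self.classes_ = model.classes_
        self.coef_ = model.coef_
        self.C_ = model.C_
        self.support_ = np.any(np.abs(model.coef_) > 1e-10, axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def _scale(self, X, fit=False):
        if fit:
            self.scaler_ = StandardScaler()
            return self.scaler_.fit_transform(X)
        return self.scaler_.transform(X)

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]


class OOBPermutationForestSelector(BaseEstimator, TransformerMixin):
    """Bagged-CART forest with out-of-bag permutation importance.

    Each of ``n_trees`` CART trees (Gini splits, sqrt(p) features per split)
    is grown on a bootstrap sample; importance of a feature is the mean
    drop in out-of-bag accuracy when that feature's OOB values are
    permuted.  The ``top_k`` features by importance are selected (k = 4 by
    default, the panel size reported for this assay).
    """

    def __init__(self, n_trees: int = 500, top_k: int = 4, seed: int = 0):
        self.n_trees = n_trees
        self.top_k = top_k
        self.seed = seed

    def fit(self, X, y):
        if self.n_trees < 50:
            warnings.warn("fewer than 50 trees gives unstable permutation importances")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        rng = np.random.default_rng(self.seed)
        importances = np.zeros(p)
        oob_counts = np.zeros(p)
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            if len(oob) == 0:
                continue
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            base_acc = np.mean(tree.predict(X[oob]) == y[oob])
            for j in range(p):
                Xp = X[oob].copy()
                Xp[:, j] = Xp[rng.permutation(len(oob)), j]
                perm_acc = np.mean(tree.predict(Xp) == y[oob])
                importances[j] += base_acc - perm_acc
                oob_counts[j] += 1
        with np.errstate(invalid="ignore"):
            self.importances_ = np.where(oob_counts > 0, importances / oob_counts, 0.0)
        order = np.argsort(-self.importances_)
        self.ranking_ = order
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[order[: self.top_k]] = True
        self.n_features_in_ = p
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]


@dataclass
class SelectionResult:
    glycan_id: str
    selected_glm: bool
    selected_rf: bool
    glm_coefficient: float
    rf_importance: float


def select_features(
    profile_df: pd.DataFrame,
    groups: pd.Series,
    seed: int = 0,
    n_trees: int = 500,
    top_k: int = 4,
    cv: int = 5,
) -> list[SelectionResult]:
    """Run both selectors on a profile matrix; one row per glycan."""
    X = profile_df.to_numpy(dtype=float)
    y = groups.loc[profile_df.index].to_numpy()
    glm = GlmnetSelector(cv=cv, seed=seed).fit(X, y)
    rf = OOBPermutationForestSelector(n_trees=n_trees, top_k=top_k, seed=seed).fit(X, y)
    coefs = np.max(np.abs(glm.coef_), axis=0)
    return [
        SelectionResult(
            glycan_id=gid,
            selected_glm=bool(glm.support_[j]),
            selected_rf=bool(rf.support_[j]),
            glm_coefficient=float(coefs[j]),
            rf_importance=float(rf.importances_[j]),
        )
        for j, gid in enumerate(profile_df.columns)
    ]


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    sensitivity: float  # percent, at the Youden-optimal threshold
    specificity: float  # percent
    threshold: float
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)


def roc(scores: Sequence[float], labels: Sequence, positive=None) -> RocResult:
    """Empirical ROC; trapezoidal AUC; Youden-J operating point.

    Ties in Youden's J are broken toward higher specificity.  The AUC
    equals the Mann-Whitney U statistic divided by n1*n2 on the same
    scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"ROC needs exactly two classes, got {list(classes)}")
    if positive is None:
        positive = classes[1]
    y = (labels == positive).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())
    # higher specificity = lower fpr
    pick = best[np.argmin(fpr[best])]
    return RocResult(
        auc=auc,
        sensitivity=float(100.0 * tpr[pick]),
        specificity=float(100.0 * (1.0 - fpr[pick])),
        threshold=float(thresholds[pick]),
        fpr=fpr,
        tpr=tpr,
    )


def panel_scores(
    profile_df: pd.DataFrame,
    groups: pd.Series,
    features: Sequence[str],
    positive=None,
) -> np.ndarray:
    """Combination score for a multi-glycan panel.

    Unpenalized logistic fit on the selected features; the predicted
    positive-class probability is the panel score.
    """
    X = profile_df[list(features)].to_numpy(dtype=float)
    y = groups.loc[profile_df.index].to_numpy()
    classes = np.unique(y)
    if positive is None:
        positive = classes[-1]
    Xs = StandardScaler().fit_transform(X)
    # unpenalized fit: C=inf (penalty=None is deprecated in scikit-learn 1.8)
    model = LogisticRegression(C=np.inf, max_iter=10000)
    model.fit(Xs, (y == positive).astype(int))
    return model.predict_proba(Xs)[:, 1]


# ---------------------------------------------------------------------------
# LDA / Wilks' lambda
# ---------------------------------------------------------------------------

@dataclass
class LdaResult:
    wilks_lambda: float
    p_value: float
    projections: pd.DataFrame
    ridged: bool = False


class WilksLda(BaseEstimator, TransformerMixin):
    """Linear discriminant analysis with Wilks' lambda and Rao's F test.

    Wilks' lambda = det(within-group scatter) / det(total scatter); small
    values indicate group separation.  The p-value uses Rao's F
    approximation.  ``transform`` projects onto at most two discriminant
    axes.  A singular within-group scatter is ridged by eps = 1e-8 and
    flagged.
    """

    def __init__(self, n_components: int = 2, ridge: float = 1e-8):
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        n, p = X.shape
        g = len(classes)
        if g < 2:
            raise ValueError("need at least two groups")
        if n <= p:
            raise ValueError(f"LDA needs n > p (n={n}, p={p}); select features first")
        grand = X.mean(axis=0)
        W = np.zeros((p, p))
        B = np.zeros((p, p))
        for cls in classes:
            Xc = X[y == cls]
            mu = Xc.mean(axis=0)
            dev = Xc - mu
            W += dev.T @ dev
            dm = (mu - grand)[:, None]
            B += len(Xc) * (dm @ dm.T)
        T = W + B
        self.ridged_ = False
        sign_w, logdet_w = np.linalg.slogdet(W)
        if sign_w <= 0:
            W = W + self.ridge * np.eye(p)
            T = W + B
            self.ridged_ = True
            sign_w, logdet_w = np.linalg.slogdet(W)
        sign_t, logdet_t = np.linalg.slogdet(T)
        lam = float(np.exp(logdet_w - logdet_t))
        self.wilks_lambda_ = min(lam, 1.0)
        self.p_value_ = _rao_f_pvalue(self.wilks_lambda_, n, p, g)

        evals, evecs = linalg.eigh(B, W + (self.ridge * np.eye(p) if self.ridged_ else 0))
        order = np.argsort(evals)[::-1]
        k = min(self.n_components, g - 1, p)
        self.scalings_ = evecs[:, order[:k]]
        self.classes_ = classes
        self.means_ = grand
        self.n_features_in_ = p
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.means_) @ self.scalings_


def _rao_f_pvalue(lam: float, n: int, p: int, g: int) -> float:
    """Rao's F approximation for Wilks' lambda."""
    if lam >= 1.0:
        return 1.0
    if lam <= 0.0:
        return 0.0
    q = g - 1
    df1 = p * q
    denom = p * p + q * q - 5
    s = np.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    m = n - 1 - (p + g) / 2.0
    df2 = m * s - df1 / 2.0 + 1.0
    if df2 <= 0:
        return float("nan")
    lam_s = lam ** (1.0 / s)
    f = (1.0 - lam_s) / lam_s * df2 / df1
    return float(stats.f.sf(f, df1, df2))


def lda(
    profile_df: pd.DataFrame,
    groups: pd.Series,
    features: Optional[Sequence[str]] = None,
) -> LdaResult:
    """Convenience wrapper: fit :class:`WilksLda` on a feature subset."""
    cols = list(features) if features is not None else list(profile_df.columns)
    X = profile_df[cols].to_numpy(dtype=float)
    y = groups.loc[profile_df.index].to_numpy()
    model = WilksLda().fit(X, y)
    proj = pd.DataFrame(
        model.transform(X),
        index=profile_df.index,
        columns=[f"LD{i+1}" for i in range(model.scalings_.shape[1])],
    )
    return LdaResult(
        wilks_lambda=model.wilks_lambda_,
        p_value=model.p_value_,
        projections=proj,
        ridged=model.ridged_,
    )


# ---------------------------------------------------------------------------
# qPCR reference-gene normalization
# ---------------------------------------------------------------------------

def normalize_gene_expression(
    cq: pd.DataFrame, reference_genes: Sequence[str]
) -> pd.DataFrame:
    """Relative expression from Cq values via reference-gene normalization.

    Each target's Cq is normalized against the mean Cq of the reference
    genes (Cq is a log2-scale quantity, so this is the logarithmic mean of
    their expression); expression = 2^-dCq, rescaled so the
    lowest-expressing sample of each target equals 1.

    ``cq``: targets x samples.  Reference genes must be present for every
    sample.
    """
    missing = [g for g in reference_genes if g not in cq.index]
    if missing:
        raise ValueError(f"reference genes missing from Cq table: {missing}")
    if cq.loc[list(reference_genes)].isna().any().any():
        raise ValueError("reference gene Cq values contain missing entries")
    ref_mean = cq.loc[list(reference_genes)].mean(axis=0)
    targets = [t for t in cq.index if t not in reference_genes]
    dcq = cq.loc[targets].sub(ref_mean, axis=1)
    expr = np.power(2.0, -dcq)
    rel = expr.div(expr.min(axis=1), axis=0)
    return rel
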