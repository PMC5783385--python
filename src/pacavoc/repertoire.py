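"""Repertoire validation statistics.

Tests whether putative call types are acoustically real: Z-score
standardization of the element parameters, linear discriminant analysis
(canonical axes of the between- over within-class scatter), a MANOVA with
Wilks' lambda and Rao's F approximation, leave-one-out cross-validated
nearest-centroid classification, an exact binomial test of the
cross-validation accuracy against chance, a two-way linear model of
per-individual means (call type x age class), and Kendall's coefficient of
concordance for inter-observer agreement.

Conventions (all configurable where noted): sample (n-1) standard
deviations; classification by nearest class centroid in discriminant space
with equal priors, ties broken by class label order; standardization refit
inside each leave-one-out fold; the binomial test is one-sided (upper
tail); the linear model uses partial (type-III-style) sums of squares with
effect coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

__all__ = [
    "FEATURES",
    "ConstantFeatureError",
    "zscore",
    "DiscriminantModel",
    "fit_lda",
    "classify",
    "manova_wilks",
    "ConfusionMatrix",
    "loo_crossvalidate",
    "binomial_vs_chance",
    "age_type_linear_model",
    "kendall_w",
]

#: The four element parameters used for discrimination (the harmonic count
#: is excluded: it shows no variation within call types).
FEATURES = ("duration", "dominant_freq", "min_freq", "max_freq")


class ConstantFeatureError(ValueError):
    """A feature with zero variance cannot be standardized (such features
    are excluded from the discriminant analysis)."""


def zscore(
    table: pd.DataFrame, features: Sequence[str] = FEATURES, ddof: int = 1
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-score transform: subtract each feature's mean, divide by its SD.

    Returns the standardized table plus the means and SDs used (needed to
    standardize held-out samples with training-set constants). ``ddof=1``
    gives the sample-SD convention; set 0 for population SD.
    """
    means = table[list(features)].mean()
    sds = table[list(features)].std(ddof=ddof)
    if (sds == 0).any() or sds.isna().any():
        bad = sds.index[(sds == 0) | sds.isna()].tolist()
        raise ConstantFeatureError(
            f"feature(s) {bad} show no variation and cannot be standardized"
        )
    out = table.copy()
    out[list(features)] = (table[list(features)] - means) / sds
    return out, means, sds


@dataclass
class DiscriminantModel:
    """Fitted linear discriminant functions.

    ``functions`` holds one coefficient vector per axis (rows), scaled so
    the pooled within-class variance along each axis is 1; sign fixed so
    each axis' largest-magnitude coefficient is positive. ``loadings`` are
    the correlations of each feature with each axis' scores.
    """

    features: tuple[str, ...]
    classes: tuple[str, ...]
    functions: np.ndarray
    explained_variance: np.ndarray
    centroids: pd.DataFrame
    loadings: pd.DataFrame
    means: pd.Series = field(repr=False)
    sds: pd.Series = field(repr=False)

    @property
    def n_axes(self) -> int:
        return self.functions.shape[0]

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        x = ((table[list(self.features)] - self.means) / self.sds).to_numpy()
        return x @ self.functions.T

    def to_report(self) -> dict:
        return {
            "features": list(self.features),
            "classes": list(self.classes),
            "functions": self.functions.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "centroids": self.centroids.to_dict(orient="index"),
            "loadings": self.loadings.to_dict(orient="index"),
        }


def _scatter_matrices(x: np.ndarray, labels: np.ndarray, classes):
    """Within-class and between-class scatter (sums of squares/products)."""
    p = x.shape[1]
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    grand = x.mean(axis=0)
    for c in classes:
        xc = x[labels == c]
        mc = xc.mean(axis=0)
        d = xc - mc
        sw += d.T @ d
        sb += len(xc) * np.outer(mc - grand, mc - grand)
    return sw, sb


def fit_lda(
    table: pd.DataFrame,
    features: Sequence[str] = FEATURES,
    class_column: str = "call_type",
) -> DiscriminantModel:
    """Fit canonical linear discriminant axes.

    Solves the generalized eigenproblem Sb v = lambda Sw v (between- over
    within-class scatter); the retained axes, at most min(features,
    classes-1), maximize class separation. Standardization constants are
    estimated here so the model can be applied to raw-unit held-out rows.
    """
    std, means, sds = zscore(table, features)
    labels = std[class_column].to_numpy()
    classes = tuple(sorted(pd.unique(labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = std[class_column].value_counts()
    if (counts <= len(features)).any():
        small = counts[counts <= len(features)].index.tolist()
        raise ValueError(f"classes with too few samples for a stable fit: {small}")
    x = std[list(features)].to_numpy()
    sw, sb = _scatter_matrices(x, labels, classes)
    n = len(x)
    try:
        evals, evecs = scipy.linalg.eigh(sb, sw)
    except scipy.linalg.LinAlgError as e:
        raise ValueError(f"singular pooled within-class scatter: {e}") from None
    order = np.argsort(evals)[::-1]
    k = min(len(features), len(classes) - 1)
    evals = np.clip(evals[order][:k], 0, None)
    axes = evecs[:, order][:, :k].T
    # scale: unit pooled within-class variance along each axis
    for i in range(k):
        wvar = axes[i] @ sw @ axes[i] / (n - len(classes))
        axes[i] = axes[i] / np.sqrt(wvar)
        j = np.argmax(np.abs(axes[i]))
        if axes[i][j] < 0:
            axes[i] = -axes[i]
    explained = evals / evals.sum() if evals.sum() > 0 else np.full(k, np.nan)
    scores = x @ axes.T
    centroids = pd.DataFrame(
        [scores[labels == c].mean(axis=0) for c in classes],
        index=list(classes),
        columns=[f"DF{i+1}" for i in range(k)],
    )
    loadings = pd.DataFrame(
        np.corrcoef(x.T, scores.T)[: len(features), len(features):],
        index=list(features),
        columns=[f"DF{i+1}" for i in range(k)],
    )
    return DiscriminantModel(
        features=tuple(features),
        classes=classes,
        functions=axes,
        explained_variance=explained,
        centroids=centroids,
        loadings=loadings,
        means=means,
        sds=sds,
    )


def classify(model: DiscriminantModel, table: pd.DataFrame) -> np.ndarray:
    """Nearest-centroid classification in discriminant space, equal priors.

    Distance ties are broken by class label order (the centroid index is
    sorted), making predictions deterministic.
    """
    scores = model.transform(table)
    cents = model.centroids.to_numpy()
    d2 = ((scores[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)  # argmin takes the first (label-order) minimum
    return np.asarray(model.centroids.index)[idx]


def manova_wilks(
    table: pd.DataFrame,
    features: Sequence[str] = FEATURES,
    class_column: str = "call_type",
) -> dict:
    """Wilks' lambda = det(W)/det(T) with Rao's F approximation.

    W is the within-class and T the total scatter matrix of the (standardized)
    features; small lambda means strong class separation. Returns lambda, F,
    the two degrees of freedom, and the p-value.
    """
    std, _, _ = zscore(table, features)
    labels = std[class_column].to_numpy()
    classes = tuple(sorted(pd.unique(labels)))
    x = std[list(features)].to_numpy()
    n, p = x.shape
    q = len(classes) - 1
    sw, sb = _scatter_matrices(x, labels, classes)
    st = sw + sb
    sign_t, logdet_t = np.linalg.slogdet(st)
    sign_w, logdet_w = np.linalg.slogdet(sw)
    if sign_t <= 0 or sign_w <= 0:
        raise ValueError("singular scatter matrix in Wilks' lambda")
    lam = float(np.exp(logdet_w - logdet_t))
    # Rao's approximation
    t = n - 1 - (p + q + 1) / 2
    s = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if p**2 + q**2 - 5 > 0 else 1.0
    df1 = p * q
    df2 = t * s - p * q / 2 + 1
    lam_s = lam ** (1 / s)
    f = (1 - lam_s) / lam_s * df2 / df1
    pval = float(scipy.stats.f.sf(f, df1, df2))
    return {"wilks_lambda": lam, "F": float(f), "df1": int(df1), "df2": float(df2), "p": pval}


@dataclass
class ConfusionMatrix:
    counts: pd.DataFrame  # true class (rows) x predicted class (columns)

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts.to_numpy()) / self.counts.to_numpy().sum())

    @property
    def per_class_accuracy(self) -> pd.Series:
        c = self.counts
        return pd.Series(np.diag(c.to_numpy()) / c.sum(axis=1).to_numpy(), index=c.index)

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts.to_numpy()))

    @property
    def n_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def loo_crossvalidate(
    table: pd.DataFrame,
    features: Sequence[str] = FEATURES,
    class_column: str = "call_type",
) -> ConfusionMatrix:
    """Leave-one-out cross-validation of the discriminant classifier.

    For every row, the standardization constants and discriminant functions
    are refit on all remaining rows ("all cases other than the one being
    classified") and the held-out row is assigned to the nearest class
    centroid. Returns the confusion matrix.
    """
    counts = table[class_column].value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with a single sample cannot be cross-validated: {bad}")
    classes = sorted(pd.unique(table[class_column]))
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    idx = table.index.to_numpy()
    for i in idx:
        train = table.drop(index=i)
        model = fit_lda(train, features, class_column)
        pred = classify(model, table.loc[[i]])[0]
        cm.loc[table.at[i, class_column], pred] += 1
    return ConfusionMatrix(counts=cm)


def binomial_vs_chance(n_correct: int, n_total: int, p_chance: float = 1 / 8) -> float:
    """One-sided exact binomial p-value for accuracy above chance."""
    if not 0 <= n_correct <= n_total:
        raise ValueError("need 0 <= n_correct <= n_total")
    if not 0 < p_chance < 1:
        raise ValueError("p_chance must be in (0, 1)")
    return float(
        scipy.stats.binomtest(n_correct, n_total, p_chance, alternative="greater").pvalue
    )


def age_type_linear_model(
    means: pd.DataFrame,
    response: str = "value",
    type_column: str = "call_type",
    age_column: str = "age_class",
    ss_type: int = 3,
) -> pd.DataFrame:
    """Two-way fixed-effects linear model on per-individual means.

    Fits response ~ call type * age class with effect (sum-to-zero) coding
    and partial (type-III-style by default) sums of squares, appropriate
    for the unbalanced per-individual design. Returns a table of F and p
    per term. Raises if a term is inestimable because of empty cells,
    naming the missing combinations.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    for col, levels in ((type_column, 2), (age_column, 2)):
        if means[col].nunique() < levels:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    cells = means.groupby([type_column, age_column], observed=True).size()
    full = pd.MultiIndex.from_product(
        [means[type_column].unique(), means[age_column].unique()]
    )
    missing = full.difference(cells.index)
    if len(missing):
        raise ValueError(
            f"interaction inestimable; empty cells: {sorted(missing.tolist())}"
        )
    formula = (
        f"{response} ~ C({type_column}, Sum) * C({age_column}, Sum)"
    )
    fit = smf.ols(formula, data=means).fit()
    table = anova_lm(fit, typ=ss_type)
    table = table.rename(
        index={
            f"C({type_column}, Sum)": "call_type",
            f"C({age_column}, Sum)": "age_class",
            f"C({type_column}, Sum):C({age_column}, Sum)": "interaction",
        }
    )
    return table


def kendall_w(ratings: pd.DataFrame | np.ndarray) -> float:
    """Kendall's coefficient of concordance with tie correction.

    ``ratings`` is an observers x items table of labels or scores; each
    observer's row is converted to ranks. W is 1 for identical rankings and
    near 0 for independent ones.
    """
    arr = np.asarray(ratings, dtype=float) if not isinstance(ratings, pd.DataFrame) else ratings.to_numpy(dtype=float)
    m, n = arr.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 observers and 2 items")
    ranks = np.vstack([scipy.stats.rankdata(row) for row in arr])
    r = ranks.sum(axis=0)
    s = float(((r - r.mean()) ** 2).sum())
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * ties
    if denom <= 0:
        raise ValueError("degenerate ratings (all tied)")
    return 12 * s / denom
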