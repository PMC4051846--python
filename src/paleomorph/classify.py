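"""Ordination and discriminant classification of log-shape ratios.

PCA is fitted on the comparative (extant) specimens only; the fossil is
projected onto the fitted axes afterwards, so it cannot distort the
ordination it is being judged against.  LDA likewise: canonical
discriminant functions are computed on the four extant clades, the
cross-validated confusion matrix quantifies the risk of misattribution,
and the fossil is a hold-out specimen scored by post-multiplying its
(centred) shape vector by the discriminant loadings and assigned to the
nearest clade under the same rule used in cross-validation.

Because log-shape ratios sum to zero, the p ratios have rank p - 1; the
last ratio is dropped before LDA (an invertible reparametrization, so the
discriminant scores are unaffected) and loadings are reported for the
retained variables.  Priors default to equal across clades — the clade
sample sizes are collection artifacts, not prevalences — and are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError
from sklearn.decomposition import PCA as _SKPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .logshape import ShapeMatrix, ShapeVector
from .morphodata import Clade, ValidationError

__all__ = [
    "PCAResult",
    "LDAResult",
    "ConfusionResult",
    "pca",
    "lda_fit",
    "lda_cv_confusion",
    "classify_holdout",
]


@dataclass(frozen=True)
class PCAResult:
    """PCA of the comparative shape rows with the fossil projected on."""

    scores: np.ndarray                 # comparative specimens x components
    loadings: np.ndarray               # variables x components
    variance_fraction: np.ndarray      # per component, sums to 1
    specimen_ids: tuple[str, ...]      # comparative row ids
    clades: tuple[Clade, ...]          # comparative row clades
    fossil_ids: tuple[str, ...]
    fossil_scores: np.ndarray          # fossils x components (may be empty)

    def pc_fraction(self, k: int = 2) -> float:
        """Cumulative variance fraction of the first *k* components."""
        return float(self.variance_fraction[:k].sum())


def pca(matrix: ShapeMatrix) -> PCAResult:
    """Eigen-decompose the covariance of comparative rows; project fossils."""
    comp = matrix.comparative
    if comp.shape[0] < 3 or comp.shape[1] < 2:
        raise ValidationError("PCA needs >= 3 comparative specimens and >= 2 variables")
    if np.allclose(comp, comp[0]):
        raise ValidationError("PCA undefined: comparative shape matrix has zero variance")
    model = _SKPCA(n_components=None)
    scores = model.fit_transform(comp)
    fossil = matrix.values[matrix.is_fossil]
    fossil_scores = model.transform(fossil) if len(fossil) else np.empty((0, scores.shape[1]))
    is_f = matrix.is_fossil
    return PCAResult(
        scores=scores,
        loadings=model.components_.T,
        variance_fraction=model.explained_variance_ratio_,
        specimen_ids=tuple(np.array(matrix.specimen_ids)[~is_f]),
        clades=tuple(c for c in matrix.clades if c is not Clade.FOSSIL),
        fossil_ids=tuple(np.array(matrix.specimen_ids)[is_f]),
        fossil_scores=fossil_scores,
    )


@dataclass(frozen=True)
class LDAResult:
    """Canonical discriminant functions fitted on the comparative clades.

    The axes are classical canonical variates (generalized eigenvectors of
    the between-group scatter against the pooled within-group scatter,
    scaled to unit pooled within-group variance), so Euclidean distance in
    score space is Mahalanobis distance under the pooled covariance.
    Classification is nearest group mean in that space, shifted by the log
    prior; with equal priors this is plain nearest-mean.
    """

    subset_used: tuple[str, ...]       # variables retained (last ratio dropped)
    discriminant_axes: np.ndarray      # retained variables x functions
    axis_variance_fraction: np.ndarray # per function, sums to 1
    classes: tuple[Clade, ...]
    group_means: dict[Clade, np.ndarray]  # clade -> per-function scores
    priors: str
    _log_priors: np.ndarray            # aligned with classes
    _center: np.ndarray                # training centring applied before scoring

    @property
    def n_functions(self) -> int:
        return self.discriminant_axes.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Discriminant scores of (already rank-reduced) shape rows."""
        x = np.atleast_2d(x)
        return (x - self._center) @ self.discriminant_axes

    def predict(self, x: np.ndarray) -> list[Clade]:
        """Nearest group mean in canonical space (log-prior shifted); exact
        ties break to the lowest clade in canonical order."""
        scores = self.transform(x)
        mu = np.stack([self.group_means[c] for c in self.classes])
        d2 = ((scores[:, None, :] - mu[None]) ** 2).sum(axis=2)
        crit = -0.5 * d2 + self._log_priors
        order = [Clade.comparative().index(c) for c in self.classes]
        out = []
        for row in crit:
            best = row.max()
            tied = np.flatnonzero(row == best)
            out.append(self.classes[min(tied, key=lambda j: order[j])])
        return out


def _reduce(matrix: ShapeMatrix) -> np.ndarray:
    """Drop the last (linearly dependent) ratio of each zero-sum row."""
    return matrix.values[:, :-1]


def lda_fit(matrix: ShapeMatrix, priors: str = "equal") -> LDAResult:
    """Fit canonical LDA on the comparative rows of a shape matrix.

    Requires all four extant clades with >= 2 specimens each.  Axis
    variance fractions are the discriminant eigenvalues over their sum.
    """
    labels = matrix.comparative_clades
    X = _reduce(matrix)[~matrix.is_fossil]
    counts = {c: labels.count(c) for c in set(labels)}
    if any(v < 2 for v in counts.values()):
        small = [c.value for c, v in counts.items() if v < 2]
        raise ValidationError(f"each clade needs >= 2 specimens; too few in {small}")
    # proportional class weighting makes the scikit-learn eigen solve exactly
    # the classical pooled-scatter canonical decomposition (priors enter the
    # classification rule only, below)
    model = LinearDiscriminantAnalysis(solver="eigen", priors=None)
    y = np.array([c.value for c in labels])
    try:
        model.fit(X, y)
    except (LinAlgError, np.linalg.LinAlgError) as exc:
        raise ValidationError(
            "singular within-group covariance; reduce the variable set "
            "(log-shape ratios are rank-deficient: drop one ratio)"
        ) from exc
    classes = tuple(Clade(v) for v in model.classes_)
    k = min(len(classes) - 1, model.scalings_.shape[1])
    axes = model.scalings_[:, :k]
    evr = model.explained_variance_ratio_[:k]
    evr = evr / evr.sum()
    center = np.asarray(model.priors_ @ model.means_)  # the grand mean
    group_scores = (model.means_ - center) @ axes
    if priors == "equal":
        pvec = np.full(len(classes), 1.0 / len(classes))
    elif priors == "proportional":
        pvec = np.array([labels.count(c) / len(labels) for c in classes])
    else:
        raise ValidationError(f"unknown priors {priors!r}; use 'equal' or 'proportional'")
    return LDAResult(
        subset_used=matrix.subset[:-1],
        discriminant_axes=axes,
        axis_variance_fraction=evr,
        classes=classes,
        group_means={c: group_scores[i] for i, c in enumerate(classes)},
        priors=priors,
        _log_priors=np.log(pvec),
        _center=center,
    )


@dataclass(frozen=True)
class ConfusionResult:
    """Cross-validated confusion matrix over the four extant clades."""

    clades: tuple[Clade, ...]          # row/column order
    counts: np.ndarray                 # true x predicted, integers
    row_percent: np.ndarray            # rows sum to 100 (exact)

    def rounded(self) -> np.ndarray:
        return np.round(self.row_percent).astype(int)


def lda_cv_confusion(
    matrix: ShapeMatrix,
    priors: str = "equal",
    cv: str = "loo",
    seed: int = 0,
) -> ConfusionResult:
    """Refit-and-classify confusion matrix (leave-one-out by default).

    ``cv`` is ``"loo"`` or ``"kfold:K"`` (stratified by nothing — folds are
    a seeded shuffle; any fold that empties a clade is an error).
    """
    labels = matrix.comparative_clades
    X = _reduce(matrix)[~matrix.is_fossil]
    n = len(labels)
    if cv == "loo":
        folds = [[i] for i in range(n)]
    elif cv.startswith("kfold:"):
        k = int(cv.split(":", 1)[1])
        if not 2 <= k <= n:
            raise ValidationError(f"kfold K must be in [2, {n}]")
        idx = np.random.default_rng(seed).permutation(n)
        folds = [list(idx[j::k]) for j in range(k)]
    else:
        raise ValidationError(f"unknown cv scheme {cv!r}; use 'loo' or 'kfold:K'")
    order = list(Clade.comparative())
    counts = np.zeros((4, 4), dtype=int)
    for fold in folds:
        keep = np.ones(n, dtype=bool)
        keep[fold] = False
        train_labels = [labels[i] for i in range(n) if keep[i]]
        missing = [c.value for c in order if c not in train_labels]
        if missing:
            raise ValidationError(
                f"cross-validation fold empties clade(s) {missing}; use smaller folds"
            )
        sub = ShapeMatrix(
            subset=matrix.subset,
            specimen_ids=tuple("x" for _ in train_labels),
            clades=tuple(train_labels),
            values=matrix.values[~matrix.is_fossil][keep][:, :],
        )
        fit = lda_fit(sub, priors=priors)
        pred = fit.predict(X[fold])
        for i, p in zip(fold, pred):
            counts[order.index(labels[i]), order.index(p)] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValidationError("a clade has no cross-validated predictions")
    return ConfusionResult(
        clades=tuple(order),
        counts=counts,
        row_percent=100.0 * counts / row_sums,
    )


def classify_holdout(
    fossil: ShapeVector, result: LDAResult
) -> tuple[Clade, np.ndarray]:
    """Project a hold-out shape vector and assign the nearest clade.

    The fossil vector must be on the same measurement subset the model was
    trained on (before rank reduction).
    """
    expected = result.subset_used
    if tuple(fossil.subset[:-1]) != tuple(expected):
        raise ValidationError(
            f"subset mismatch: model uses {expected}, fossil has {fossil.subset[:-1]}"
        )
    x = fossil.values[:-1]
    scores = result.transform(x)[0]
    clade = result.predict(x)[0]
    return clade, scores
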