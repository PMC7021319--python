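"""Linear discriminant sex classification with leave-one-out cross
validation, on shape PCs, form PCs, or centroid size alone.

The classifier is the classical pooled-covariance Gaussian LDA: class
means, a single within-class covariance (n-2 denominator for two classes),
and priors that are either proportional to class frequencies (the default
for cross-validated accuracy tables) or equal (the forensic convention for
single-specimen calls, where the case prior is unknown). Posterior
probabilities (P_post) come from the Gaussian class-conditional densities
under the shared covariance.

PCA is computed once on the full sample and only the LDA is refit inside
each leave-one-out fold, matching common practice in GM sex-estimation
studies; the slight selection optimism this carries is documented in the
methods note, and ``loo_cv`` accepts any feature matrix so a
PCA-inside-fold analysis can be run by the caller when wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TalogmError

__all__ = [
    "LDAModel",
    "ClassificationResult",
    "fit_lda",
    "posterior",
    "predict",
    "loo_cv",
    "select_pc_count",
    "classify_specimen",
]


@dataclass
class LDAModel:
    class_labels: tuple[str, str]
    class_means: np.ndarray          # (2, d)
    pooled_covariance: np.ndarray    # (d, d)
    priors: np.ndarray               # (2,), sums to 1
    variable_set: str = ""           # "shape_pcs" | "form_pcs" | "cs" | ...
    n_components: int = 0

    def __post_init__(self) -> None:
        self._cov_inv = np.linalg.inv(self.pooled_covariance)

    @property
    def dims(self) -> int:
        return self.class_means.shape[1]


@dataclass
class ClassificationResult:
    class_labels: tuple[str, str]
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    posteriors: np.ndarray           # (n, 2) rows sum to 1
    variable_set: str = ""
    n_components: int = 0
    per_class_correct: dict = field(default_factory=dict)
    per_class_pct: dict = field(default_factory=dict)
    overall_accuracy: float = 0.0    # percent

    @classmethod
    def from_predictions(cls, labels, true, pred, post, variable_set="", n_components=0):
        true = np.asarray(true)
        pred = np.asarray(pred)
        correct, pct = {}, {}
        for lab in labels:
            mask = true == lab
            n_ok = int((pred[mask] == lab).sum())
            correct[lab] = (n_ok, int(mask.sum()))
            pct[lab] = 100.0 * n_ok / mask.sum() if mask.sum() else float("nan")
        overall = 100.0 * float((pred == true).mean())
        return cls(
            class_labels=tuple(labels),
            true_labels=true,
            predicted_labels=pred,
            posteriors=np.asarray(post, dtype=float),
            variable_set=variable_set,
            n_components=n_components,
            per_class_correct=correct,
            per_class_pct=pct,
            overall_accuracy=overall,
        )


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def fit_lda(X, y, priors: str = "proportional", variable_set: str = "") -> LDAModel:
    """Fit two-class pooled-covariance LDA.

    ``priors`` is ``"proportional"`` (class frequencies), ``"equal"``, or an
    explicit pair. Raises on singular pooled covariance (too many PCs for
    the sample size).
    """
    X = _as_2d(X)
    y = np.asarray(y)
    labels = sorted(set(y.tolist()))
    if len(labels) != 2:
        raise TalogmError(f"LDA here is two-class; got labels {labels}")
    n, d = X.shape
    if n < d + 2:
        raise TalogmError(
            f"{n} specimens cannot support {d} variables; use fewer PCs"
        )
    means = np.zeros((2, d))
    pooled = np.zeros((d, d))
    counts = np.zeros(2)
    for i, lab in enumerate(labels):
        xi = X[y == lab]
        if len(xi) < 2:
            raise TalogmError(f"class {lab!r} has < 2 specimens")
        counts[i] = len(xi)
        means[i] = xi.mean(axis=0)
        pooled += (xi - means[i]).T @ (xi - means[i])
    pooled /= n - 2
    sign, logdet = np.linalg.slogdet(pooled)
    if sign <= 0 or np.linalg.cond(pooled) > 1e12:
        raise TalogmError(
            "singular pooled covariance; reduce the number of PCs"
        )
    if priors == "proportional":
        pri = counts / counts.sum()
    elif priors == "equal":
        pri = np.array([0.5, 0.5])
    else:
        pri = np.asarray(priors, dtype=float)
        if pri.shape != (2,) or not np.isclose(pri.sum(), 1.0):
            raise TalogmError("explicit priors must be two values summing to 1")
    return LDAModel(
        class_labels=tuple(labels),
        class_means=means,
        pooled_covariance=pooled,
        priors=pri,
        variable_set=variable_set,
        n_components=d,
    )


def posterior(model: LDAModel, x) -> np.ndarray:
    """Posterior class probabilities for one specimen (P_post)."""
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.shape[0] != model.dims:
        raise TalogmError(f"expected {model.dims} variables, got {x.shape[0]}")
    # log N(x; mu_c, Sigma) + log prior, shared terms dropped
    diff = x[None, :] - model.class_means
    mahal = np.einsum("ci,ij,cj->c", diff, model._cov_inv, diff)
    logp = -0.5 * mahal + np.log(model.priors)
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def predict(model: LDAModel, X) -> tuple[np.ndarray, np.ndarray]:
    X = _as_2d(X)
    post = np.stack([posterior(model, row) for row in X])
    pred = np.array([model.class_labels[i] for i in post.argmax(axis=1)])
    return pred, post


def loo_cv(X, y, priors: str = "proportional", variable_set: str = "") -> ClassificationResult:
    """Leave-one-out cross-validated LDA: each specimen is classified by a
    model refit without it."""
    X = _as_2d(X)
    y = np.asarray(y)
    n = len(X)
    labels = sorted(set(y.tolist()))
    preds = np.empty(n, dtype=object)
    posts = np.zeros((n, 2))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit_lda(X[mask], y[mask], priors=priors, variable_set=variable_set)
        p = posterior(model, X[i])
        posts[i] = p
        preds[i] = model.class_labels[int(p.argmax())]
        mask[i] = True
    return ClassificationResult.from_predictions(
        labels, y, preds.astype(str), posts,
        variable_set=variable_set, n_components=X.shape[1],
    )


def select_pc_count(
    scores, y, max_pcs: int = 10, priors: str = "proportional",
    variable_set: str = "",
) -> tuple[int, ClassificationResult]:
    """Search m = 1..min(max_pcs, available) leading PCs for the smallest m
    maximizing LOO accuracy (ties go to fewer PCs)."""
    scores = _as_2d(scores)
    upper = min(max_pcs, scores.shape[1])
    best: tuple[int, ClassificationResult] | None = None
    for m in range(1, upper + 1):
        try:
            res = loo_cv(scores[:, :m], y, priors=priors, variable_set=variable_set)
        except TalogmError:
            break  # pooled covariance ran out of degrees of freedom
        if best is None or res.overall_accuracy > best[1].overall_accuracy:
            best = (m, res)
    if best is None:
        raise TalogmError("no PC count could be evaluated")
    return best


def classify_specimen(
    morpho_model,
    lda_model: LDAModel,
    coordinates: np.ndarray,
    lncs: float | None = None,
) -> tuple[str, np.ndarray, np.ndarray]:
    """Project a (complete) specimen into the stored morphospace, take the
    LDA model's leading components, and return (label, posterior pair,
    full score vector)."""
    from .morphospace import project  # local import avoids a cycle

    scores = project(morpho_model, coordinates, lncs=lncs)
    x = scores[: lda_model.dims]
    p = posterior(lda_model, x)
    label = lda_model.class_labels[int(p.argmax())]
    return label, p, scores
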