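"""Species assignment of ungenotyped specimens by linear discriminant.

A two-class LDA is trained on genotype-labelled specimens (morphological
traits as predictors) and applied to the remaining contact-zone
individuals.  Low-confidence assignments are then removed with a
per-class multivariate confidence region: a specimen is kept only if its
squared Mahalanobis distance to its assigned class centroid falls within
the chi-square quantile at the chosen level (0.97 by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger("contactzone")


@dataclass
class DiscriminantModel:
    """Fisher two-class linear discriminant with Gaussian posteriors."""

    weights: np.ndarray          # pooled_cov^-1 (mean_A - mean_B)
    threshold: float             # decision point on the discriminant score
    class_means: tuple[np.ndarray, np.ndarray]
    pooled_cov: np.ndarray
    priors: tuple[float, float]  # (pi_A, pi_B), sum to 1
    classes: tuple[str, str] = ("A", "B")
    training_confusion: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        obj = {
            "weights": self.weights.tolist(),
            "threshold": self.threshold,
            "class_means": [m.tolist() for m in self.class_means],
            "pooled_cov": self.pooled_cov.tolist(),
            "priors": list(self.priors),
            "classes": list(self.classes),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscriminantModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(obj["weights"]),
            threshold=float(obj["threshold"]),
            class_means=tuple(np.asarray(m) for m in obj["class_means"]),
            pooled_cov=np.asarray(obj["pooled_cov"]),
            priors=tuple(obj["priors"]),
            classes=tuple(obj["classes"]),
        )


def _ridge_if_needed(S: np.ndarray, force: bool = False) -> np.ndarray:
    """Ridge lambda = 1e-8 trace/dim when the pooled covariance is
    near-singular (Procrustes coordinate blocks are rank-deficient)."""
    d = S.shape[0]
    lam = 1e-8 * np.trace(S) / d
    w = np.linalg.eigvalsh(S)
    if force or w[0] <= lam:
        return S + (lam + max(-w[0], 0.0) + lam) * np.eye(d)
    return S


def fit_lda(X: np.ndarray, labels: np.ndarray,
            equal_priors: bool = False, ridge: bool = True) -> DiscriminantModel:
    """Fit a two-class linear discriminant on labelled training data.

    The direction is ``pooled_cov^-1 (mean_A - mean_B)`` and the
    threshold the prior-adjusted midpoint; class priors default to
    training frequencies.  Training confusion counts are recorded on the
    model for a quick reliability read-out.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(sorted(pd.unique(labels)))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    A, B = classes
    XA, XB = X[labels == A], X[labels == B]
    d = X.shape[1]
    if len(XA) + len(XB) < d + 1:
        raise ValueError("too few training specimens for the trait count")
    muA, muB = XA.mean(axis=0), XB.mean(axis=0)
    nA, nB = len(XA), len(XB)
    S = ((nA - 1) * np.cov(XA, rowvar=False, ddof=1)
         + (nB - 1) * np.cov(XB, rowvar=False, ddof=1)) / (nA + nB - 2)
    S = np.atleast_2d(S)
    if ridge:
        S = _ridge_if_needed(S)
    elif np.linalg.eigvalsh(S)[0] <= 0:
        raise np.linalg.LinAlgError("singular pooled covariance (no ridge)")
    w = np.linalg.solve(S, muA - muB)
    if equal_priors:
        piA = piB = 0.5
    else:
        piA, piB = nA / (nA + nB), nB / (nA + nB)
    # assign A when w.x - w.(muA+muB)/2 + ln(piA/piB) > 0
    threshold = float(w @ (muA + muB) / 2.0 - np.log(piA / piB))
    model = DiscriminantModel(
        weights=w, threshold=threshold, class_means=(muA, muB),
        pooled_cov=S, priors=(piA, piB), classes=(str(A), str(B)),
    )
    pred = assign_species(model, X)["label"].to_numpy()
    conf = np.array([[np.sum((labels == c) & (pred == p)) for p in classes]
                     for c in classes])
    model.training_confusion = conf
    logger.info("fit_lda: classes=%s n=(%d,%d) training errors=%d",
                classes, nA, nB, int(conf.sum() - np.trace(conf)))
    return model


def assign_species(model: DiscriminantModel, X: np.ndarray) -> pd.DataFrame:
    """Assign specimens to the model's two classes.

    Returns a frame with the discriminant score, the posterior
    probability of class A under equal-covariance Gaussian
    class-conditionals with the training priors, and the argmax label.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"query has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"model expects {model.weights.shape[0]}"
        )
    score = X @ model.weights
    logit = score - model.threshold
    post_A = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
    labels = np.where(post_A >= 0.5, model.classes[0], model.classes[1])
    return pd.DataFrame({"label": labels, "score": score,
                         "posterior_A": post_A})


def confidence_filter(X: np.ndarray, labels: np.ndarray, level: float = 0.97,
                      joint: bool = False) -> np.ndarray:
    """Boolean retention mask for the per-class confidence region.

    A specimen is retained when its squared Mahalanobis distance to its
    assigned class centroid (class covariance, ridge-stabilized) is at
    most the chi-square quantile at ``level`` with df = trait count.
    With ``joint=True`` a single pooled centroid and covariance over all
    specimens is used instead.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    d = X.shape[1]
    cut = chi2.ppf(level, df=d)
    keep = np.zeros(len(X), dtype=bool)
    groups = [None] if joint else list(pd.unique(labels))
    for g in groups:
        mask = np.ones(len(X), dtype=bool) if g is None else labels == g
        Xg = X[mask]
        mu = Xg.mean(axis=0)
        S = _ridge_if_needed(np.atleast_2d(np.cov(Xg, rowvar=False, ddof=1)),
                             force=False)
        diff = Xg - mu
        d2 = np.einsum("ij,ij->i", diff, np.linalg.solve(S, diff.T).T)
        keep[mask] = d2 <= cut
    logger.info("confidence_filter: retained %d/%d at level %.2f",
                int(keep.sum()), len(keep), level)
    return keep
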