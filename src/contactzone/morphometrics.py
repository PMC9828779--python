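"""Landmark preprocessing: reflection, generalized Procrustes alignment,
wing-length measurement, size correction, and principal components.

The alignment follows standard geometric-morphometric practice: each
configuration is centred, scaled to unit centroid size, and rotated to an
iteratively updated consensus.  Reflections are never introduced during
alignment; mirrored configurations (left wings) are flipped explicitly
beforehand with :func:`reflect_config`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import LandmarkSet

logger = logging.getLogger("contactzone")


@dataclass
class ProcrustesResult:
    aligned: np.ndarray        # (n_specimens, 2 * n_landmarks)
    consensus: np.ndarray      # (n_landmarks, 2)
    centroid_sizes: np.ndarray  # (n_specimens,)
    n_iter: int
    converged: bool
    specimen_ids: list[str]


@dataclass
class ShapeScores:
    scores: np.ndarray        # (n_specimens, n_components)
    loadings: np.ndarray      # (n_components, n_variables), rows unit-length
    var_fraction: np.ndarray  # (n_components,)
    mean: np.ndarray          # (n_variables,) centering vector


def reflect_config(cfg: LandmarkSet) -> LandmarkSet:
    """Mirror a configuration about the y axis (negate x), toggling ``flipped``."""
    coords = cfg.coords.copy()
    coords[:, 0] = -coords[:, 0]
    return LandmarkSet(cfg.specimen_id, coords, flipped=not cfg.flipped,
                       scale=cfg.scale)


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances of landmarks to their centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def _optimal_rotation(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (det = +1, no reflection) minimizing ||X R - target||_F."""
    U, _, Vt = np.linalg.svd(X.T @ target)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def generalized_procrustes(configs: list[LandmarkSet], tol: float = 1e-8,
                           max_iter: int = 100) -> ProcrustesResult:
    """Generalized Procrustes alignment of landmark configurations.

    Removes translation (centroid at origin), scales each configuration
    to unit centroid size, and iterates rotation-to-consensus until the
    consensus moves less than ``tol`` (root-mean-square displacement).

    Raises
    ------
    ValueError
        If fewer than two configurations, unequal landmark counts, or a
        degenerate (zero-size) configuration is supplied.
    """
    if len(configs) < 2:
        raise ValueError("generalized_procrustes needs at least 2 configurations")
    k = configs[0].n_landmarks
    for c in configs:
        if c.n_landmarks != k:
            raise ValueError(
                f"{c.specimen_id}: {c.n_landmarks} landmarks, expected {k}"
            )
    n = len(configs)
    X = np.empty((n, k, 2))
    sizes = np.empty(n)
    for i, c in enumerate(configs):
        coords = c.coords - c.coords.mean(axis=0)
        s = np.sqrt((coords ** 2).sum())
        if s < 1e-12:
            raise ValueError(f"{c.specimen_id}: degenerate configuration "
                             "(all landmarks coincident)")
        sizes[i] = s
        X[i] = coords / s

    consensus = X[0].copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(n):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new_consensus = X.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        ns = np.sqrt((new_consensus ** 2).sum())
        new_consensus /= ns
        shift = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if shift < tol:
            converged = True
            break

    logger.info("GPA: %d specimens, %d landmarks, %d iterations, converged=%s",
                n, k, n_iter, converged)
    return ProcrustesResult(
        aligned=X.reshape(n, 2 * k),
        consensus=consensus,
        centroid_sizes=sizes,
        n_iter=n_iter,
        converged=converged,
        specimen_ids=[c.specimen_id for c in configs],
    )


def wing_length(cfg: LandmarkSet, i: int = 1, j: int = 4) -> float:
    """Euclidean distance between two landmarks (1-based indices) in
    original, pre-Procrustes units."""
    k = cfg.n_landmarks
    if not (1 <= i <= k and 1 <= j <= k):
        raise IndexError(f"landmark indices ({i}, {j}) out of range 1..{k}")
    return float(np.linalg.norm(cfg.coords[i - 1] - cfg.coords[j - 1]))


def size_correct(traits: np.ndarray, size: np.ndarray) -> np.ndarray:
    """Residuals of each trait column regressed (OLS) on a size measure.

    Removes allometric variation before shape comparison: the returned
    residual matrix has zero column means and zero sample covariance with
    ``size``.
    """
    traits = np.asarray(traits, dtype=float)
    size = np.asarray(size, dtype=float)
    if traits.shape[0] != size.shape[0]:
        raise ValueError("traits and size must have matching specimen counts")
    if traits.shape[0] < 3:
        raise ValueError("size correction needs at least 3 specimens")
    if np.ptp(size) < 1e-12:
        raise ValueError("size vector is constant; regression undefined")
    design = np.column_stack([np.ones_like(size), size])
    beta, *_ = np.linalg.lstsq(design, traits, rcond=None)
    return traits - design @ beta


def pca(X: np.ndarray, center: bool = True) -> ShapeScores:
    """Principal components of a specimens x variables matrix.

    Components are eigenvectors of the sample covariance (n-1
    denominator), ordered by decreasing eigenvalue; no variable scaling
    is applied, since Procrustes coordinates share units.  Each loading
    vector is oriented so its largest-magnitude entry is positive,
    giving reproducible score signs.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("pca needs at least 2 specimens and 1 variable")
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    # SVD route: eigenvalues of cov are s^2 / (n - 1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (X.shape[0] - 1)
    total = eigvals.sum()
    if total < 1e-300:
        raise ValueError("pca: zero-variance (rank-0) matrix")
    # sign convention: largest-|loading| entry positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]),
                      np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = Xc @ Vt.T
    return ShapeScores(scores=scores, loadings=Vt,
                       var_fraction=eigvals / total, mean=mean)
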