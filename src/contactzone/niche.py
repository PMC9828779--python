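"""Environmental-niche overlap on occurrence-density grids.

Occurrences of each group are turned into a kernel-density surface over
a shared grid in a 2-D environmental ordination, corrected by the
density of the available background and normalized to sum one.  Overlap
between two such surfaces is summarized by Schoener's D (absolute
differences) and Warren's I (Hellinger-based), and a randomization
similarity test asks whether the observed overlap is more or less
extreme than overlap with randomly relocated niches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("contactzone")


@dataclass
class NicheGrid:
    z: np.ndarray              # (R, R) nonnegative, sums to 1
    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy_mask: np.ndarray  # (R, R) bool, cells with available background

    def __post_init__(self) -> None:
        if abs(self.z.sum() - 1.0) > 1e-9:
            raise ValueError("density grid must sum to 1")
        if np.any(self.z[~self.occupancy_mask] != 0):
            raise ValueError("density outside the occupancy mask")


@dataclass
class OverlapResult:
    D: float
    I: float
    p_similarity: float        # based on D, in the requested direction
    p_similarity_I: float
    n_rep: int
    seed: int
    alternative: str


# ---------------------------------------------------------------------------
# variable selection
# ---------------------------------------------------------------------------

def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors from R^2 of each column on the others."""
    n, d = X.shape
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    out = np.empty(d)
    for j in range(d):
        others = np.delete(Xs, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(A, Xs[:, j], rcond=None)
        resid = Xs[:, j] - A @ beta
        r2 = 1.0 - resid @ resid / max((Xs[:, j] ** 2).sum(), 1e-300)
        out[j] = 1.0 / max(1.0 - r2, 1e-12)
    return out


def select_variables(E: pd.DataFrame, r_max: float = 0.8,
                     vif_max: float = 10.0) -> list[str]:
    """Prune collinear environmental variables.

    Iteratively drops the variable with the highest variance inflation
    factor until all VIF <= ``vif_max``; then, for any remaining pair
    with |Pearson r| > ``r_max``, drops the member with the higher mean
    absolute correlation to the rest.  Ties break deterministically by
    column order (the earlier column is kept).
    """
    cols = [c for c in E.columns if c != "specimen_id"]
    if len(cols) < 2:
        raise ValueError("need at least 2 variables")
    if len(E) < 10:
        raise ValueError("need at least 10 samples")
    active = list(cols)
    while len(active) > 1:
        v = _vif(E[active].to_numpy(dtype=float))
        if np.nanmax(v) <= vif_max:
            break
        active.pop(int(np.nanargmax(v)))
    while len(active) > 1:
        R = E[active].corr().to_numpy()
        np.fill_diagonal(R, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(R)), R.shape)
        if abs(R[i, j]) <= r_max:
            break
        mean_abs = np.abs(R).sum(axis=0) / (len(active) - 1)
        # drop the pair member more correlated with everything else;
        # on a tie, keep the earlier column
        drop = max((i, j), key=lambda k: (mean_abs[k], -k))
        if mean_abs[i] == mean_abs[j]:
            drop = max(i, j)
        active.pop(int(drop))
    if not active:
        raise ValueError("all variables dropped")
    return active


# ---------------------------------------------------------------------------
# density grids and overlap
# ---------------------------------------------------------------------------

class _GridContext:
    """Precomputed background grid shared by repeated density evaluations.

    Densities are grid KDEs: a 2-D histogram smoothed with a Gaussian
    kernel whose ABSOLUTE bandwidth comes from Silverman's rule on the
    background, so sharply concentrated occurrence clouds are smoothed
    with the same kernel as the background rather than their own.
    """

    def __init__(self, background: np.ndarray, R: int,
                 bandwidth: str | float = "silverman") -> None:
        background = np.asarray(background, dtype=float)
        if background.size == 0:
            raise ValueError("empty background")
        lo = background.min(axis=0)
        hi = background.max(axis=0)
        pad = 0.05 * (hi - lo + 1e-12)
        self.R = R
        self.x_edges = np.linspace(lo[0] - pad[0], hi[0] + pad[0], R + 1)
        self.y_edges = np.linspace(lo[1] - pad[1], hi[1] + pad[1], R + 1)
        dx = self.x_edges[1] - self.x_edges[0]
        dy = self.y_edges[1] - self.y_edges[0]
        n = background.shape[0]
        if isinstance(bandwidth, str):
            factor = (n * (2 + 2) / 4.0) ** (-1.0 / 6.0)  # Silverman, d=2
        else:
            factor = float(bandwidth)
        bw = factor * background.std(axis=0, ddof=1)
        bw = np.maximum(bw, [dx, dy])  # never narrower than one cell
        self.sigma_cells = (bw[0] / dx, bw[1] / dy)
        self.dens_bg = self._smooth_hist(background)
        self.mask = self.dens_bg > 1e-4 * self.dens_bg.max()

    def _smooth_hist(self, pts: np.ndarray) -> np.ndarray:
        from scipy.ndimage import gaussian_filter

        h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1],
                                 bins=[self.x_edges, self.y_edges])
        return gaussian_filter(h, sigma=self.sigma_cells, mode="constant")

    def occurrence_grid(self, scores: np.ndarray) -> NicheGrid:
        scores = np.asarray(scores, dtype=float)
        if scores.shape[0] < 5:
            raise ValueError("need at least 5 occurrences")
        dens_occ = self._smooth_hist(scores)
        z = np.zeros((self.R, self.R))
        safe = self.mask & (self.dens_bg > 1e-12)
        z[safe] = dens_occ[safe] / self.dens_bg[safe]
        cap = np.quantile(z[safe], 0.999) if safe.any() else 0.0
        z = np.minimum(z, max(cap, 1e-300))
        total = z.sum()
        if total <= 0:
            raise ValueError("degenerate occurrence density")
        z /= total
        return NicheGrid(z=z, x_edges=self.x_edges, y_edges=self.y_edges,
                         occupancy_mask=self.mask)


def density_grid(scores: np.ndarray, background: np.ndarray, R: int = 100,
                 bandwidth: str | float = "silverman") -> NicheGrid:
    """Background-corrected occurrence density on a shared R x R grid.

    Gaussian kernel densities of the occurrences and of the background
    are evaluated on a grid spanning the background extent; the
    occurrence density is divided by the background density on occupied
    cells (the ratio is clamped where the background density vanishes)
    and renormalized to sum one.  The kernel bandwidth follows
    Silverman's rule on the background by default.
    """
    return _GridContext(background, R, bandwidth).occurrence_grid(scores)


def overlap_indices(z1: NicheGrid, z2: NicheGrid) -> tuple[float, float]:
    """Schoener's D and Warren's I between two normalized density grids.

    D = 1 - 0.5 sum|z1 - z2|;  I = 1 - 0.5 sum(sqrt(z1) - sqrt(z2))^2.
    """
    if z1.z.shape != z2.z.shape or not np.array_equal(z1.x_edges, z2.x_edges) \
            or not np.array_equal(z1.y_edges, z2.y_edges):
        raise ValueError("grids do not match")
    D = 1.0 - 0.5 * np.abs(z1.z - z2.z).sum()
    I = 1.0 - 0.5 * ((np.sqrt(z1.z) - np.sqrt(z2.z)) ** 2).sum()
    return float(np.clip(D, 0, 1)), float(np.clip(I, 0, 1))


def similarity_test(occ1: np.ndarray, occ2: np.ndarray,
                    background1: np.ndarray, background2: np.ndarray,
                    n_rep: int = 1000, seed: int = 0,
                    alternative: str = "lower", R: int = 100) -> OverlapResult:
    """Niche similarity randomization test.

    The observed overlap (D, I) between the two groups' density grids is
    compared to a null built by relocating group 2's occurrence cloud:
    each replicate translates the occurrences so their centroid lands at
    a random point of group 2's background, recomputes the truncated,
    renormalized density, and measures overlap with group 1.
    ``alternative="lower"`` asks whether the niches are LESS similar
    than random (divergence); ``"greater"`` whether they are MORE
    similar.  p-values use the add-one estimator (1 + k) / (n_rep + 1).
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100")
    if alternative not in ("greater", "lower"):
        raise ValueError("alternative must be 'greater' or 'lower'")
    occ1 = np.asarray(occ1, dtype=float)
    occ2 = np.asarray(occ2, dtype=float)
    bg = np.vstack([background1, background2])
    if np.ptp(bg, axis=0).min() <= 0:
        raise ValueError("degenerate background")
    rng = np.random.default_rng(seed)
    ctx = _GridContext(bg, R, "silverman")
    g1 = ctx.occurrence_grid(occ1)
    g2 = ctx.occurrence_grid(occ2)
    D_obs, I_obs = overlap_indices(g1, g2)
    centroid = occ2.mean(axis=0)
    bg2 = np.asarray(background2, dtype=float)
    lo, hi = bg2.min(axis=0), bg2.max(axis=0)
    null_D = np.empty(n_rep)
    null_I = np.empty(n_rep)
    for r in range(n_rep):
        target = rng.uniform(lo, hi)
        shifted = occ2 + (target - centroid)
        gz = ctx.occurrence_grid(shifted)
        null_D[r], null_I[r] = overlap_indices(g1, gz)
    if alternative == "lower":
        kD = int(np.sum(null_D <= D_obs))
        kI = int(np.sum(null_I <= I_obs))
    else:
        kD = int(np.sum(null_D >= D_obs))
        kI = int(np.sum(null_I >= I_obs))
    return OverlapResult(
        D=D_obs, I=I_obs,
        p_similarity=(1 + kD) / (n_rep + 1),
        p_similarity_I=(1 + kI) / (n_rep + 1),
        n_rep=n_rep, seed=seed, alternative=alternative,
    )
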