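"""Sliding-window scan of P-matrix change along the contact zone.

Within each species, individuals are ordered by their distance from the
point of contact.  Overlapping windows (30 individuals, step 10 by
default) march away from the contact, and each window's P matrix is
compared — theta between leading eigenvectors, and the matrix distance —
against a fixed reference set of the individuals furthest from contact
on that species' own side, with bootstrap significance.  An OLS trend
test then asks whether the window statistic changes with distance
differently in the two species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from . import pmatrix
from .morphometrics import pca

logger = logging.getLogger("contactzone")


@dataclass
class WindowResult:
    species: str
    window_index: int
    member_ids: list[str]
    mean_distance_km: float
    theta_deg: float
    matrix_distance: float
    significant_theta: bool
    significant_distance: bool
    p_theta: float
    p_distance: float


def make_windows(ids_sorted_from_contact: list, size: int = 30,
                 step: int = 10) -> list[list]:
    """Overlapping index windows over an ordering away from the contact.

    Windows are [0:size], [step:size+step], ... while a full window
    fits; a final partial window is dropped.
    """
    if not (size >= step >= 1):
        raise ValueError("require size >= step >= 1")
    n = len(ids_sorted_from_contact)
    if n < size:
        raise ValueError(f"only {n} individuals for window size {size}")
    windows = []
    start = 0
    while start + size <= n:
        windows.append(list(ids_sorted_from_contact[start:start + size]))
        start += step
    return windows


def local_outlier_filter(X: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Boolean mask retaining specimens inside the local PCA confidence
    region.

    A PCA of X is taken, the leading components explaining >= 95% of the
    variance are kept, and each specimen's squared Mahalanobis distance
    in that score space (scores standardized by their eigenvalues) is
    compared to the chi-square quantile at ``level``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("local outlier filter needs >= 3 specimens")
    scores = pca(X)
    cum = np.cumsum(scores.var_fraction)
    k = int(np.searchsorted(cum, 0.95) + 1)
    k = min(k, scores.scores.shape[1])
    S = scores.scores[:, :k]
    var = S.var(axis=0, ddof=1)
    var = np.where(var < 1e-30, 1.0, var)
    d2 = ((S ** 2) / var).sum(axis=1)
    return d2 <= chi2.ppf(level, df=k)


def window_scan(X_by_species: dict[str, np.ndarray],
                positions: dict[str, np.ndarray],
                ids: dict[str, list[str]],
                contact_km: float,
                size: int = 30, step: int = 10,
                n_boot: int = 10_000, seed: int = 0) -> list[WindowResult]:
    """Scan each species' trait sample with sliding windows against a
    fixed end-of-transect reference.

    The reference is the ``size`` individuals furthest from the contact
    on the species' own side (the utmost western or eastern part of the
    transect, depending on which side the species occupies), and windows
    are built from the remaining individuals ordered by distance from
    contact.  Each window
    is compared to the reference by :func:`pmatrix.bootstrap_compare`
    for both theta and the matrix distance; the scan is reproducible
    given ``seed``.
    """
    results: list[WindowResult] = []
    for si, (species, X) in enumerate(sorted(X_by_species.items())):
        pos = np.asarray(positions[species], dtype=float)
        sp_ids = list(ids[species])
        order = np.argsort(np.abs(pos - contact_km), kind="stable")
        n = len(order)
        if n < 2 * size:
            raise ValueError(
                f"{species}: {n} individuals; need >= {2 * size} for "
                "disjoint windows and reference"
            )
        ref_idx = order[n - size:]          # furthest from contact
        scan_idx = order[:n - size]         # disjoint from the reference
        X_ref = X[ref_idx]
        windows = make_windows(list(scan_idx), size=size, step=step)
        for wi, widx in enumerate(windows):
            widx = np.asarray(widx)
            sub_seed = (seed + 7919 * si + 104729 * wi) % (2 ** 31)
            cmp_t = pmatrix.bootstrap_compare(X[widx], X_ref, "theta",
                                              n_boot=n_boot, seed=sub_seed)
            cmp_d = pmatrix.bootstrap_compare(X[widx], X_ref, "distance",
                                              n_boot=n_boot,
                                              seed=sub_seed + 1)
            results.append(WindowResult(
                species=species, window_index=wi,
                member_ids=[sp_ids[j] for j in widx],
                mean_distance_km=float(pos[widx].mean()),
                theta_deg=cmp_t.observed, matrix_distance=cmp_d.observed,
                significant_theta=cmp_t.significant,
                significant_distance=cmp_d.significant,
                p_theta=cmp_t.p_value, p_distance=cmp_d.p_value,
            ))
    logger.info("window_scan: %d windows across %d species", len(results),
                len(X_by_species))
    return results


def results_frame(results: list[WindowResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = dict(r.__dict__)
        d.pop("member_ids")
        rows.append(d)
    return pd.DataFrame(rows)


def trend_test(results: list[WindowResult] | pd.DataFrame,
               statistic: str = "theta") -> pd.DataFrame:
    """OLS trend of the window statistic on distance, species, and their
    interaction.

    The bootstrap significance state enters as an additive covariate (a
    fixed-effect stand-in for a grouping term).  Returns coefficients
    with Wald p-values; the ``distance:species`` row is the test of
    species-specific change along the transect.
    """
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    if df.groupby("species").size().min() < 3:
        raise ValueError("trend test needs >= 3 windows per species")
    yname = {"theta": "theta_deg", "distance": "matrix_distance"}[statistic]
    sig = {"theta": "significant_theta",
           "distance": "significant_distance"}[statistic]
    species_codes = pd.Categorical(df["species"]).codes.astype(float)
    Xd = pd.DataFrame({
        "const": 1.0,
        "distance": df["mean_distance_km"].to_numpy(),
        "species": species_codes,
        "distance:species": df["mean_distance_km"].to_numpy() * species_codes,
        "significant": df[sig].astype(float).to_numpy(),
    })
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if Xd["significant"].nunique() == 1:
        Xd = Xd.drop(columns="significant")
        rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        raise ValueError("collinear design in trend test")
    fit = sm.OLS(df[yname].to_numpy(), Xd).fit()
    return pd.DataFrame({"coef": fit.params, "se": fit.bse,
                         "p_value": fit.pvalues})
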