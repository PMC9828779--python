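"""Variant filtering, genotype PCA, and F1-hybrid detection.

The variant filter applies, in order: removal of non-biallelic sites;
entry-level masking by genotype quality and depth; removal of sites
exceeding the missingness ceiling; and a minor-allele-frequency floor.
Genotype PCA (missing entries mean-imputed per site) provides the
genomic axis used for cline fitting, and the hybrid index classifies
individuals against two parental reference panels at diagnostic sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix
from .morphometrics import ShapeScores, pca

logger = logging.getLogger("contactzone")

F1_INDEX_WINDOW = (0.4, 0.6)
F1_MIN_HET = 0.85


@dataclass
class HybridReport:
    sample_id: str
    hybrid_index: float        # proportion of B-type alleles, in [0, 1]
    interspecific_het: float   # fraction heterozygous at diagnostic sites
    call: str                  # pure_A / pure_B / F1_candidate / other


def filter_variants(G: GenotypeMatrix, maf_min: float = 0.04,
                    max_missing: float = 0.60, gq_min: int = 20,
                    dp_min: int = 5, dp_max: int = 30,
                    biallelic_only: bool = True,
                    ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Filter sites by the standard quality rules, reporting per-rule losses.

    Rules, in application order:

    1. ``non_biallelic`` — drop sites with more than one ALT allele.
    2. entry masking — genotypes with GQ <= ``gq_min`` or depth outside
       [``dp_min``, ``dp_max``] are set missing (per-entry when depth is
       available; sites are dropped by mean depth otherwise).
    3. ``missing`` — drop sites with more than ``max_missing`` missing
       entries (after masking).
    4. ``maf`` — drop sites with minor allele frequency below ``maf_min``.

    Returns the filtered matrix and a loss report including the number
    of entries masked by each masking rule.
    """
    dos = G.dosages.copy()
    n, m = dos.shape
    keep = np.ones(m, dtype=bool)
    losses = {"non_biallelic": 0, "depth_site": 0, "missing": 0, "maf": 0,
              "masked_gq_entries": 0, "masked_dp_entries": 0}

    if biallelic_only:
        bad = ~G.is_biallelic
        losses["non_biallelic"] = int(bad.sum())
        keep &= ~bad

    if G.gq is not None:
        mask = (G.gq <= gq_min) & ~np.isnan(G.gq)
        losses["masked_gq_entries"] = int(mask[:, keep].sum())
        dos[mask] = np.nan
    if G.depth is not None:
        mask = ((G.depth < dp_min) | (G.depth > dp_max)) & ~np.isnan(G.depth)
        losses["masked_dp_entries"] = int(mask[:, keep].sum())
        dos[mask] = np.nan

    miss_frac = np.isnan(dos).mean(axis=0)
    bad = keep & (miss_frac > max_missing)
    losses["missing"] = int(bad.sum())
    keep &= ~bad

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dos, axis=0) / 2.0  # ALT frequency per site
    maf = np.minimum(p, 1.0 - p)
    all_missing = np.isnan(p)
    bad = keep & (all_missing | (maf < maf_min))
    losses["maf"] = int(bad.sum())
    keep &= ~bad

    out = GenotypeMatrix(
        dosages=dos[:, keep],
        sample_ids=list(G.sample_ids),
        site_ids=[s for s, k in zip(G.site_ids, keep) if k],
        depth=G.depth[:, keep] if G.depth is not None else None,
        gq=G.gq[:, keep] if G.gq is not None else None,
        is_biallelic=G.is_biallelic[keep],
    )
    if out.n_sites == 0:
        logger.warning("filter_variants: all %d sites removed", m)
    logger.info("filter_variants: %d -> %d sites; losses=%s", m, out.n_sites,
                losses)
    return out, losses


def genotype_pca(G: GenotypeMatrix,
                 orient_negative_ids: list[str] | None = None) -> ShapeScores:
    """PCA of the dosage matrix with per-site mean imputation of missing
    genotypes.

    Sites that are entirely missing are dropped with a warning.  When
    ``orient_negative_ids`` is given, PC1 is sign-flipped if needed so
    the mean score of those samples (species A, by convention) is
    negative; otherwise the largest-loading-positive convention applies.
    """
    if G.n_samples < 2 or G.n_sites < 2:
        raise ValueError("genotype PCA needs >= 2 samples and >= 2 sites")
    dos = G.dosages.copy()
    all_missing = np.isnan(dos).all(axis=0)
    if all_missing.any():
        logger.warning("genotype_pca: dropping %d all-missing sites",
                       int(all_missing.sum()))
        dos = dos[:, ~all_missing]
    site_means = np.nanmean(dos, axis=0)
    idx = np.where(np.isnan(dos))
    dos[idx] = site_means[idx[1]]
    scores = pca(dos, center=True)
    if orient_negative_ids:
        rows = [G.sample_ids.index(s) for s in orient_negative_ids]
        if scores.scores[rows, 0].mean() > 0:
            scores.scores[:, 0] *= -1
            scores.loadings[0] *= -1
    return scores


def diagnostic_sites(G: GenotypeMatrix, groupA_ids: list[str],
                     groupB_ids: list[str],
                     diagnostic_delta: float = 0.9) -> np.ndarray:
    """Indices of sites whose allele-frequency difference between the two
    parental panels is at least ``diagnostic_delta``."""
    ia = [G.sample_ids.index(s) for s in groupA_ids]
    ib = [G.sample_ids.index(s) for s in groupB_ids]
    with np.errstate(invalid="ignore"):
        pA = np.nanmean(G.dosages[ia], axis=0) / 2.0
        pB = np.nanmean(G.dosages[ib], axis=0) / 2.0
    diff = np.abs(pA - pB)
    diff[np.isnan(diff)] = 0.0
    return np.where(diff >= diagnostic_delta)[0]


def hybrid_index(G: GenotypeMatrix, groupA_ids: list[str],
                 groupB_ids: list[str], diagnostic_delta: float = 0.9,
                 ) -> list[HybridReport]:
    """Hybrid index and interspecific heterozygosity at diagnostic sites.

    For every sample not in either parental panel: the hybrid index is
    the mean proportion of B-type alleles over non-missing diagnostic
    sites, and the interspecific heterozygosity the fraction of those
    sites at which the sample is heterozygous.  An F1 candidate must be
    near-balanced (index in [0.4, 0.6]) AND heterozygous at nearly all
    diagnostic sites (>= 0.85); backcrosses fail the het criterion and
    fall into ``other``.
    """
    if set(groupA_ids) & set(groupB_ids):
        raise ValueError("parental panels overlap")
    if len(groupA_ids) < 5 or len(groupB_ids) < 5:
        raise ValueError("each parental panel needs >= 5 individuals")
    sites = diagnostic_sites(G, groupA_ids, groupB_ids, diagnostic_delta)
    if sites.size == 0:
        raise ValueError(
            "no diagnostic sites at delta >= "
            f"{diagnostic_delta}; lower diagnostic_delta"
        )
    ia = [G.sample_ids.index(s) for s in groupA_ids]
    with np.errstate(invalid="ignore"):
        pA = np.nanmean(G.dosages[ia][:, sites], axis=0) / 2.0
    # orient dosages so 2 = homozygous B-type at every diagnostic site
    flip = pA > 0.5
    ingroup = set(groupA_ids) | set(groupB_ids)
    reports = []
    for i, sid in enumerate(G.sample_ids):
        if sid in ingroup:
            continue
        d = G.dosages[i, sites].copy()
        d[flip] = 2.0 - d[flip]
        ok = ~np.isnan(d)
        if not ok.any():
            reports.append(HybridReport(sid, np.nan, np.nan, "other"))
            continue
        h_index = float(d[ok].mean() / 2.0)
        het = float(np.mean(d[ok] == 1.0))
        if h_index <= 0.05 and het <= 0.05:
            call = "pure_A"
        elif h_index >= 0.95 and het <= 0.05:
            call = "pure_B"
        elif (F1_INDEX_WINDOW[0] <= h_index <= F1_INDEX_WINDOW[1]
              and het >= F1_MIN_HET):
            call = "F1_candidate"
        else:
            call = "other"
        reports.append(HybridReport(sid, h_index, het, call))
    return reports


def hybrid_report_frame(reports: list[HybridReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
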