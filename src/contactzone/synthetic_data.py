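"""Synthetic contact-zone datasets with known ground truth.

Emulates a two-species parapatric transect: a sharp species transition
on a ~14.58 km transect at ~9 km, species-specific landmark mean shapes
and covariance structures with a controllable angle between leading
eigenvectors, rare F1 hybrids with no backcrosses, diagnostic and
background SNPs, and smooth environmental gradients whose cline centers
sit west of the species transition.  Every output is a deterministic
function of the seed, and the ground-truth record is sufficient to
score every recovery test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, LandmarkSet, write_tps, write_vcf

logger = logging.getLogger("contactzone")


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated contact zone.

    Distances are km, shape quantities are in template units (the wing
    template has centroid size ~2.4 and span ~1).  ``eigen_spectrum``
    gives the leading trait variances in relative units; for landmark
    noise they are scaled by ``landmark_var_unit`` and padded with a
    small floor for the remaining coordinate dimensions.
    ``shape_divergence`` is the full between-species mean-shape offset
    along a fixed direction; with the defaults it corresponds to about
    six within-species standard deviations, matching a contact zone
    whose species a discriminant separates with ~97%+ accuracy.
    ``f1_rate`` is small: the study system yields only a handful of F1
    hybrids among hundreds of specimens, and no backcrosses.
    """

    n_individuals: int = 400
    transect_length_km: float = 14.58
    contact_km: float = 9.0
    cline_width_km: float = 0.2
    n_wing_landmarks: int = 23
    n_genital_landmarks: int = 11
    pmax_angle_deg: float = 60.0
    eigen_spectrum: tuple[float, ...] = (10.0, 2.0, 1.0)
    landmark_var_unit: float = 1e-5
    shape_divergence: float = 0.06
    f1_rate: float = 0.0065
    n_diagnostic_snps: int = 60
    n_background_snps: int = 240
    env_cline_center_km: float = 3.0
    env_cline_width_km: float = 4.0
    env_noise_sd: float = 0.15
    genotyped_fraction: float = 0.4
    genotype_missing_rate: float = 0.02
    hard_split: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.contact_km < self.transect_length_km:
            raise ValueError("contact_km must lie inside the transect")
        spec = np.asarray(self.eigen_spectrum, dtype=float)
        if np.any(spec <= 0) or np.any(np.diff(spec) > 0):
            raise ValueError("eigen_spectrum must be positive and non-increasing")
        if not 0 <= self.f1_rate < 1:
            raise ValueError("f1_rate must be in [0, 1)")
        if not 0 <= self.pmax_angle_deg <= 90:
            raise ValueError("pmax_angle_deg must be in [0, 90]")


@dataclass
class SimulatedTransect:
    specimens: pd.DataFrame
    wings: list[LandmarkSet]
    genitalia: list[LandmarkSet]
    genotypes: GenotypeMatrix
    env: pd.DataFrame
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# landmark templates (stylized outlines so TPS output is visually sane)
# ---------------------------------------------------------------------------

def wing_template() -> np.ndarray:
    """23-landmark stylized forewing: base, leading edge, apex, trailing
    edge, and a 12-point ring outlining the orange spot region
    (landmarks 12-23, 1-based)."""
    outline = [
        (0.00, 0.00),   # 1 wing base
        (0.30, 0.45),   # 2 leading edge
        (0.65, 0.42),   # 3
        (1.00, 0.25),   # 4 apex (wing length = |lm1 - lm4|)
        (0.95, 0.05),   # 5 trailing edge
        (0.85, -0.10),  # 6
        (0.70, -0.20),  # 7
        (0.50, -0.25),  # 8
        (0.30, -0.22),  # 9
        (0.15, -0.15),  # 10
        (0.05, -0.05),  # 11
    ]
    ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    spot = np.column_stack([0.72 + 0.13 * np.cos(ang),
                            0.05 + 0.08 * np.sin(ang)])
    return np.vstack([np.asarray(outline), spot])


SPOT_LANDMARKS_1BASED = list(range(12, 24))  # the 12-point spot ring


def genital_template() -> np.ndarray:
    """11-landmark stylized genital valve: length axis plus three teeth."""
    return np.asarray([
        (0.00, 0.00), (0.20, 0.08), (0.40, 0.12),
        (0.55, 0.18), (0.60, 0.10),           # tooth 1
        (0.70, 0.16), (0.75, 0.09),           # tooth 2
        (0.85, 0.14), (0.90, 0.06),           # tooth 3
        (1.00, 0.10), (0.50, -0.05),
    ])


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def _species_covs(dim: int, spectrum: np.ndarray, angle_deg: float,
                  rng: np.random.Generator,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                             np.ndarray]:
    """Two covariance matrices sharing a spectrum whose leading
    eigenvectors are separated by exactly ``angle_deg``.

    The eigenbasis is a seeded random orthonormal frame; each species'
    leading pair is the frame's first 2-plane rotated by +-angle/2, so
    the angle between the two leading eigenvectors is exact.  Returns
    (cov_A, cov_B, pmax_A, pmax_B, offset_direction).
    """
    Q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    lam = np.empty(dim)
    k = len(spectrum)
    lam[:k] = spectrum
    lam[k:] = spectrum[-1] / 4.0
    half = np.radians(angle_deg) / 2.0

    def rotated(sign: float) -> np.ndarray:
        V = Q.copy()
        c, s = np.cos(sign * half), np.sin(sign * half)
        V[:, 0] = c * Q[:, 0] + s * Q[:, 1]
        V[:, 1] = -s * Q[:, 0] + c * Q[:, 1]
        return V

    VA, VB = rotated(-1.0), rotated(+1.0)
    covA = (VA * lam) @ VA.T
    covB = (VB * lam) @ VB.T
    return covA, covB, VA[:, 0], VB[:, 0], Q[:, 0]


def simulate_two_populations(cfg: SimulationConfig, n_per_pop: int,
                             ) -> tuple[np.ndarray, np.ndarray,
                                        np.ndarray, np.ndarray]:
    """Two multivariate-normal trait samples with a known angle between
    the populations' leading eigenvectors.

    The trait dimension equals ``len(cfg.eigen_spectrum)``; the true
    p_max vectors are returned alongside the samples.
    """
    spectrum = np.asarray(cfg.eigen_spectrum, dtype=float)
    dim = len(spectrum)
    rng = np.random.default_rng(cfg.seed)
    covA, covB, pA, pB, _ = _species_covs(dim, spectrum, cfg.pmax_angle_deg,
                                          rng)
    XA = rng.multivariate_normal(np.zeros(dim), covA, size=n_per_pop,
                                 method="cholesky")
    XB = rng.multivariate_normal(np.zeros(dim), covB, size=n_per_pop,
                                 method="cholesky")
    return XA, XB, pA, pB


# ---------------------------------------------------------------------------
# full transect
# ---------------------------------------------------------------------------

_ENV_VARS = ("EvapoJul", "Isothermal", "PrecSeason", "PrecSept",
             "TMeanWetQ", "TMinAug", "TSeason")


def _sigmoid(x: np.ndarray, c: float, w: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip(-4.0 * (x - c) / w, -700, 700)))


def _make_landmarks(rng: np.random.Generator, template: np.ndarray,
                    species_num: np.ndarray, divergence: float,
                    spectrum_abs: np.ndarray, angle_deg: float,
                    prefix: str, ids: list[str],
                    ) -> tuple[list[LandmarkSet], dict]:
    """Landmark configurations around a template with species-specific
    mean shift and covariance; species_num is 0 (A), 1 (B) or 0.5 (F1)."""
    k = template.shape[0]
    dim = 2 * k
    covA, covB, pA, pB, u = _species_covs(dim, spectrum_abs, angle_deg, rng)
    base = template.reshape(-1)
    LA = np.linalg.cholesky(covA + 1e-12 * np.eye(dim))
    LB = np.linalg.cholesky(covB + 1e-12 * np.eye(dim))
    LH = np.linalg.cholesky(0.5 * (covA + covB) + 1e-12 * np.eye(dim))
    out = []
    for i, s in enumerate(species_num):
        mean = base + (s - 0.5) * divergence * u
        L = LA if s == 0 else (LB if s == 1 else LH)
        flat = mean + L @ rng.standard_normal(dim)
        coords = flat.reshape(k, 2)
        # digitization nuisance: random scale, rotation, translation
        scale = rng.normal(300.0, 12.0)
        ang = rng.normal(0.0, np.radians(5.0))
        R = np.array([[np.cos(ang), -np.sin(ang)],
                      [np.sin(ang), np.cos(ang)]])
        coords = coords @ R.T * scale + rng.uniform(0, 50, size=2)
        out.append(LandmarkSet(ids[i], coords))
    truth = {"pmax_A": pA.tolist(), "pmax_B": pB.tolist(),
             "offset_direction": u.tolist(),
             "pmax_angle_deg": angle_deg}
    return out, truth


def simulate_transect(cfg: SimulationConfig) -> SimulatedTransect:
    """Generate a complete synthetic contact-zone dataset.

    Positions are uniform on the transect; species identity is a
    Bernoulli draw from the true sigmoid at each position (or a hard
    split at the contact when ``cfg.hard_split``).  F1 hybrids occur at
    rate ``f1_rate``, are placed within 0.25 km of the contact, are
    heterozygous at every diagnostic SNP, and have landmark means at the
    parental midpoint.  Environmental variables follow logistic spatial
    gradients centered near ``env_cline_center_km`` plus Gaussian noise;
    two deliberately collinear extras are appended to exercise variable
    selection.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    L = cfg.transect_length_km
    x = np.sort(rng.uniform(0, L, size=n))
    p_B = _sigmoid(x, cfg.contact_km, cfg.cline_width_km)
    if cfg.hard_split:
        species = np.where(x > cfg.contact_km, "B", "A")
    else:
        species = np.where(rng.uniform(size=n) < p_B, "B", "A")
    species = species.astype(object)

    n_f1 = rng.binomial(n, cfg.f1_rate)
    f1_idx = rng.choice(n, size=n_f1, replace=False) if n_f1 else np.array([], int)
    x[f1_idx] = np.clip(
        rng.uniform(cfg.contact_km - 0.25, cfg.contact_km + 0.25, size=n_f1),
        0, L)
    species[f1_idx] = "hybrid"
    order = np.argsort(x, kind="stable")
    x, species = x[order], species[order]
    f1_mask = species == "hybrid"

    ids = [f"s{i:04d}" for i in range(n)]
    s_num = np.where(f1_mask, 0.5, (species == "B").astype(float))

    spectrum_abs = np.asarray(cfg.eigen_spectrum) * cfg.landmark_var_unit
    wings, wing_truth = _make_landmarks(
        rng, wing_template()[:cfg.n_wing_landmarks], s_num,
        cfg.shape_divergence, spectrum_abs, cfg.pmax_angle_deg, "wing", ids)
    genitalia, genital_truth = _make_landmarks(
        rng, genital_template()[:cfg.n_genital_landmarks], s_num,
        cfg.shape_divergence, spectrum_abs, cfg.pmax_angle_deg, "genital", ids)

    # --- genotypes -------------------------------------------------------
    m_diag, m_bg = cfg.n_diagnostic_snps, cfg.n_background_snps
    dos = np.empty((n, m_diag + m_bg))
    dos[:, :m_diag] = np.where(f1_mask, 1.0, 2.0 * (species == "B"))[:, None]
    p_bg = rng.beta(2.0, 2.0, size=m_bg)
    dos[:, m_diag:] = rng.binomial(2, p_bg, size=(n, m_bg)).astype(float)
    if n_f1:
        # F1: one gamete from each parental pool at background sites
        draws = (rng.binomial(1, p_bg, size=(n_f1, m_bg))
                 + rng.binomial(1, p_bg, size=(n_f1, m_bg)))
        dos[np.where(f1_mask)[0][:, None], np.arange(m_diag, m_diag + m_bg)] \
            = draws.astype(float)
    miss = rng.uniform(size=dos.shape) < cfg.genotype_missing_rate
    dos[miss] = np.nan
    depth = rng.poisson(15.0, size=dos.shape).astype(float) + 1.0
    gq = rng.integers(15, 99, size=dos.shape).astype(float)
    site_ids = ([f"diag_{j:04d}" for j in range(m_diag)]
                + [f"bg_{j:04d}" for j in range(m_bg)])
    genotypes = GenotypeMatrix(dos, list(ids), site_ids, depth=depth, gq=gq)

    # --- specimens table -------------------------------------------------
    genotyped = rng.uniform(size=n) < cfg.genotyped_fraction
    genotyped[f1_mask] = True  # hybrids are known from genotype data
    wl = np.array([np.linalg.norm(w.coords[0] - w.coords[3]) for w in wings])
    reported_species = np.where(genotyped, species, "unknown")
    specimens = pd.DataFrame({
        "specimen_id": ids,
        "site": "contact",
        "population_type": "contact",
        "species": reported_species,
        "genotyped": genotyped,
        "distance_km": x,
        "wing_length": wl,
    })

    # --- environment -----------------------------------------------------
    env_centers, env = {}, {"specimen_id": ids}
    amps = {"EvapoJul": 1.2, "Isothermal": 0.8, "PrecSeason": -1.0,
            "PrecSept": -25.0, "TMeanWetQ": 2.5, "TMinAug": 1.8,
            "TSeason": -0.9}
    for name in _ENV_VARS:
        c = cfg.env_cline_center_km + rng.uniform(-0.5, 0.5)
        amp = amps[name]
        env_centers[name] = c
        env[name] = (amp * _sigmoid(x, c, cfg.env_cline_width_km)
                     + rng.normal(0, cfg.env_noise_sd * abs(amp), size=n))
    env = pd.DataFrame(env)
    # collinear extras for the variable selector to prune
    env["TMeanJul"] = env["TMinAug"] * 1.1 + rng.normal(0, 0.01, size=n)
    env["GDD"] = env["TMeanWetQ"] + env["TMinAug"] + rng.normal(0, 0.01, size=n)

    truth = {
        "config": asdict(cfg),
        "contact_km": cfg.contact_km,
        "cline_width_km": cfg.cline_width_km,
        "species": list(map(str, species)),
        "hybrid_ids": [ids[i] for i in np.where(f1_mask)[0]],
        "env_cline_centers_km": env_centers,
        "env_cline_width_km": cfg.env_cline_width_km,
        "wings": wing_truth,
        "genitalia": genital_truth,
        "background_snp_freqs": p_bg.tolist(),
    }
    logger.info("simulate_transect: n=%d (%d hybrids), %d SNPs, seed=%d",
                n, int(f1_mask.sum()), genotypes.n_sites, cfg.seed)
    return SimulatedTransect(specimens, wings, genitalia, genotypes, env,
                             truth)


def paper_scale_preset(seed: int = 0) -> SimulationConfig:
    """Configuration at the scale of the field study: 464 contact-zone
    individuals, 23 wing / 11 genital landmarks, 300 SNPs (a reduced SNP
    panel), a 14.58 km transect with contact at 9.0 km, and an F1 rate
    yielding ~3 expected hybrids."""
    return SimulationConfig(
        n_individuals=464,
        n_diagnostic_snps=60,
        n_background_snps=240,
        f1_rate=3.0 / 464.0,
        seed=seed,
    )


def write_dataset(sim: SimulatedTransect, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated dataset as wings.tps, genitalia.tps,
    specimens.csv, genotypes.vcf, env.csv, truth.json."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "wings": write_tps(sim.wings, out / "wings.tps"),
        "genitalia": write_tps(sim.genitalia, out / "genitalia.tps"),
        "genotypes": write_vcf(sim.genotypes, out / "genotypes.vcf"),
    }
    sim.specimens.to_csv(out / "specimens.csv", index=False)
    sim.env.to_csv(out / "env.csv", index=False)
    (out / "truth.json").write_text(json.dumps(sim.truth, indent=1))
    paths["specimens"] = out / "specimens.csv"
    paths["env"] = out / "env.csv"
    paths["truth"] = out / "truth.json"
    return paths
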