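"""Readers and writers for the formats the pipeline touches.

Landmark configurations travel as TPS files (the plain-text interchange
format written by common digitizing tools), specimen and environment
tables as delimited text with a header row, and genotypes as VCF or a
dosage matrix.  All downstream modules operate on the in-memory types
defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("contactzone")


class TPSParseError(ValueError):
    """Raised when a TPS file violates the LM=/coordinate-line contract."""


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype input (header/row mismatch, non-diploid GT)."""


@dataclass
class LandmarkSet:
    """A single specimen's 2-D landmark configuration.

    Coordinates are Cartesian with y increasing upward.  ``flipped``
    records whether the configuration has been mirrored (e.g. a left
    wing reflected to match right wings).  ``scale`` is the optional
    units-per-pixel factor from the digitizer; it is carried along but
    only applied on request.
    """

    specimen_id: str
    coords: np.ndarray  # (n_landmarks, 2)
    flipped: bool = False
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"{self.specimen_id}: coords must be (n_landmarks, 2), "
                f"got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinate")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-sites dosage matrix.

    ``dosages`` holds 0/1/2 counts of the alternate allele as floats with
    ``nan`` marking missing genotypes.  Per-entry depth and genotype
    quality are retained when the source provides them; ``is_biallelic``
    flags sites that had exactly one ALT allele so the variant filter can
    drop the rest.
    """

    dosages: np.ndarray  # (n_samples, n_sites), float with nan = missing
    sample_ids: list[str]
    site_ids: list[str]
    depth: np.ndarray | None = None  # (n_samples, n_sites)
    gq: np.ndarray | None = None  # (n_samples, n_sites)
    is_biallelic: np.ndarray = field(default=None)  # (n_sites,) bool

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.site_ids) != m:
            raise GenotypeFormatError("id lists inconsistent with dosage shape")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise GenotypeFormatError("dosages must be 0, 1, 2 or missing")
        if self.is_biallelic is None:
            self.is_biallelic = np.ones(m, dtype=bool)
        else:
            self.is_biallelic = np.asarray(self.is_biallelic, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

_TPS_KEYS = ("LM", "ID", "IMAGE", "SCALE")


def read_tps(path: str | Path, apply_scale: bool = False,
             flip_y: bool = False) -> list[LandmarkSet]:
    """Parse a TPS landmark file into a list of :class:`LandmarkSet`.

    Accepts ``LM=``, ``ID=``, ``IMAGE=`` and ``SCALE=`` keys
    (case-insensitive); unknown keys are ignored, since digitizer output
    varies.  Each record must supply exactly ``LM=`` coordinate lines.

    Parameters
    ----------
    apply_scale
        Multiply coordinates by the record's SCALE factor when present.
    flip_y
        Negate y for files written in image convention (y increases
        downward).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[LandmarkSet] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        key, _, value = line.partition("=")
        if key.strip().upper() != "LM":
            raise TPSParseError(
                f"record {len(records)}: expected LM= line, got {line!r}"
            )
        try:
            n_lm = int(value.strip())
        except ValueError as exc:
            raise TPSParseError(f"record {len(records)}: bad LM count {value!r}") from exc
        coords = np.empty((n_lm, 2))
        for j in range(n_lm):
            if i >= n_lines:
                raise TPSParseError(
                    f"record {len(records)}: LM={n_lm} but file ends after "
                    f"{j} coordinate lines"
                )
            parts = lines[i].split()
            i += 1
            if len(parts) != 2:
                raise TPSParseError(
                    f"record {len(records)}: coordinate line {j} is not an "
                    f"x y pair: {lines[i - 1]!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TPSParseError(
                    f"record {len(records)}: non-numeric coordinate on line "
                    f"{j}: {lines[i - 1]!r}"
                ) from exc
        spec_id = f"record_{len(records)}"
        scale = None
        # trailing key=value lines up to the next LM=
        while i < n_lines:
            nxt = lines[i].strip()
            if not nxt:
                i += 1
                continue
            k, _, v = nxt.partition("=")
            k = k.strip().upper()
            if k == "LM":
                break
            i += 1
            if k == "ID":
                spec_id = v.strip()
            elif k == "SCALE":
                try:
                    scale = float(v.strip())
                except ValueError as exc:
                    raise TPSParseError(
                        f"record {len(records)}: bad SCALE {v!r}"
                    ) from exc
            # IMAGE= and unknown keys ignored
        if flip_y:
            coords[:, 1] = -coords[:, 1]
        if apply_scale and scale is not None:
            coords = coords * scale
        records.append(LandmarkSet(spec_id, coords, scale=scale))
    ids = [r.specimen_id for r in records]
    if len(set(ids)) != len(ids):
        raise TPSParseError("duplicate specimen ids in TPS file")
    logger.info("read_tps: %d records from %s", len(records), path)
    return records


def write_tps(sets: Sequence[LandmarkSet], path: str | Path,
              precision: int = 6) -> Path:
    """Write landmark sets to a TPS file parseable by :func:`read_tps`."""
    path = Path(path)
    out = []
    for s in sets:
        out.append(f"LM={s.n_landmarks}")
        for x, y in s.coords:
            out.append(f"{x:.{precision}f} {y:.{precision}f}")
        out.append(f"ID={s.specimen_id}")
        if s.scale is not None:
            out.append(f"SCALE={s.scale:.{precision}f}")
    path.write_text("\n".join(out) + ("\n" if out else ""))
    return path


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype table from VCF or a dosage-matrix CSV.

    VCF input uses the GT field for dosages (count of ALT alleles) and
    retains per-entry DP and GQ when the FORMAT declares them.  Sites
    with more than one ALT allele are kept but flagged non-biallelic so
    the variant filter can count them; their dosages are set missing.
    The matrix format is a delimited table with sites as rows, samples
    as columns, values 0/1/2 or empty/NA for missing.
    """
    if format == "vcf":
        return _read_vcf(Path(path))
    if format == "matrix":
        df = pd.read_csv(path, index_col=0)
        dos = df.to_numpy(dtype=float).T  # samples x sites
        return GenotypeMatrix(dos, list(df.columns.astype(str)),
                              list(df.index.astype(str)))
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    n = len(samples)
    dosage_rows, depth_rows, gq_rows = [], [], []
    site_ids, biallelic = [], []
    any_dp = any_gq = False
    for v in vcf:
        for g in v.genotypes:
            if len(g) != 3:  # [allele, allele, phased] for diploids
                raise GenotypeFormatError(
                    f"non-diploid genotype at {v.CHROM}:{v.POS}"
                )
        gt = np.asarray(v.gt_types, dtype=float)  # 0,1,2, 3=missing
        if gt.shape[0] != n:
            raise GenotypeFormatError(
                f"{v.CHROM}:{v.POS}: {gt.shape[0]} genotypes for {n} samples"
            )
        gt[gt == 3] = np.nan
        is_bi = len(v.ALT) == 1
        if not is_bi:
            gt[:] = np.nan
        dosage_rows.append(gt)
        biallelic.append(is_bi)
        site_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        try:
            gq = v.format("GQ")
        except KeyError:
            gq = None
        if dp is not None:
            any_dp = True
            depth_rows.append(np.asarray(dp, dtype=float).reshape(n))
        else:
            depth_rows.append(np.full(n, np.nan))
        if gq is not None:
            any_gq = True
            gq_rows.append(np.asarray(gq, dtype=float).reshape(n))
        else:
            gq_rows.append(np.full(n, np.nan))
    dosages = (np.vstack(dosage_rows).T if dosage_rows
               else np.empty((n, 0)))
    depth = np.vstack(depth_rows).T if (depth_rows and any_dp) else None
    gq_arr = np.vstack(gq_rows).T if (gq_rows and any_gq) else None
    gm = GenotypeMatrix(dosages, samples, site_ids, depth=depth, gq=gq_arr,
                        is_biallelic=np.asarray(biallelic, dtype=bool))
    logger.info("read_genotypes: %d samples x %d sites from %s",
                gm.n_samples, gm.n_sites, path)
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal diploid VCF (GT, and DP/GQ when present)."""
    path = Path(path)
    fmt_keys = ["GT"]
    if gm.depth is not None:
        fmt_keys.append("DP")
    if gm.gq is not None:
        fmt_keys.append("GQ")
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if gm.depth is not None:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    if gm.gq is not None:
        lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids))
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, site in enumerate(gm.site_ids):
        alt = "T" if gm.is_biallelic[j] else "T,G"
        cells = []
        for i in range(gm.n_samples):
            d = gm.dosages[i, j]
            parts = [gt_of.get(d, "./.")]
            if gm.depth is not None:
                dp = gm.depth[i, j]
                parts.append("." if np.isnan(dp) else str(int(dp)))
            if gm.gq is not None:
                q = gm.gq[i, j]
                parts.append("." if np.isnan(q) else str(int(q)))
            cells.append(":".join(parts))
        lines.append(f"1\t{j + 1}\t{site}\tA\t{alt}\t.\tPASS\t.\t"
                     + ":".join(fmt_keys) + "\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

SPECIMEN_COLUMNS = ["specimen_id", "site", "population_type", "species",
                    "genotyped", "distance_km", "wing_length"]


def read_specimens(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read specimens.csv, validating the column contract."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"specimens table missing columns: {missing}")
    return df


def read_env(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read env.csv: specimen_id plus one column per environmental variable."""
    df = pd.read_csv(path, sep=delimiter)
    if "specimen_id" not in df.columns:
        raise ValueError("env table must have a specimen_id column")
    return df
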