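"""Readers, writers and sample alignment for genotype, phenotype and kinship data.

Genotypes are held as minor-allele dosage matrices (values 0/1/2, one row per
sample, one column per SNP) with chromosome/position metadata.  Two on-disk
dialects are supported: PLINK ``.bed/.bim/.fam`` triplets (variant-major) and
a plain CSV pair (dosage CSV whose first column is the sample id and whose
header row holds SNP ids, plus a map CSV with columns snp_id, chromosome,
position).  Missing genotypes are tolerated at read time only and must be
mean-imputed before analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DimensionError,
    EmptyGenotypeError,
    ParseError,
)
from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)

GENOTYPE_FORMATS = ("plink_bed", "csv")

#: column order of the association-results TSV
RESULT_COLUMNS = ["snp_id", "chromosome", "position", "maf", "beta", "se", "F", "p_value"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """n x m minor-allele dosage matrix with per-SNP metadata.

    ``dosage`` holds values in {0, 1, 2}; NaN marks a missing call and is
    only legal straight after reading, before :func:`mean_impute`.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    chromosome: np.ndarray  # per-SNP, dtype str
    position: np.ndarray  # per-SNP, 1-based bp
    dosage: np.ndarray  # n x m float array

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise DimensionError(
                f"dosage has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if m != len(self.snp_ids) or m != self.chromosome.size or m != self.position.size:
            raise DimensionError("SNP metadata length does not match dosage columns")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def maf(self) -> np.ndarray:
        """Folded minor-allele frequency per SNP (missing calls ignored)."""
        freq = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in np.atleast_1d(index)],
            chromosome=self.chromosome[index],
            position=self.position[index],
            dosage=self.dosage[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(index)],
            snp_ids=list(self.snp_ids),
            chromosome=self.chromosome,
            position=self.position,
            dosage=self.dosage[index, :],
        )


@dataclass
class PhenotypeVector:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != len(self.sample_ids):
            raise DimensionError("phenotype length does not match sample ids")


@dataclass
class CovariateMatrix:
    """Covariate block of the fixed effects; intercept and SNP are added later."""

    sample_ids: list[str]
    values: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.sample_ids):
            raise DimensionError("covariate rows do not match sample ids")
        if self.names is None:
            self.names = [f"cov{i}" for i in range(self.values.shape[1])]


# ---------------------------------------------------------------------------
# genotype reading
# ---------------------------------------------------------------------------

def read_genotype(path: str | Path, format_name: str, map_path: str | Path | None = None) -> GenotypeMatrix:
    """Read a genotype matrix.

    Parameters
    ----------
    path
        For ``plink_bed``: the ``.bed`` file (``.bim``/``.fam`` found beside it).
        For ``csv``: the dosage CSV; the map CSV defaults to ``<stem>.map.csv``.
    format_name
        One of ``plink_bed`` or ``csv``.
    """
    if format_name not in GENOTYPE_FORMATS:
        raise ValueError(f"unknown genotype format {format_name!r}; expected one of {GENOTYPE_FORMATS}")
    path = Path(path)
    if format_name == "csv":
        return _read_genotype_csv(path, map_path)
    return _read_plink_bed(path)


def _read_genotype_csv(path: Path, map_path: str | Path | None) -> GenotypeMatrix:
    if map_path is None:
        map_path = path.parent / (path.stem + ".map.csv")
    map_path = Path(map_path)
    if not path.exists():
        raise FileNotFoundError(f"genotype CSV not found: {path}")
    if not map_path.exists():
        raise FileNotFoundError(f"genotype map CSV not found: {map_path}")
    try:
        table = pd.read_csv(path, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"could not parse genotype CSV {path}: {exc}") from exc
    raw = table.to_numpy(dtype=object)
    blank = np.vectorize(
        lambda c: c is None
        or (isinstance(c, float) and np.isnan(c))
        or str(c).strip() in ("", "NA", "nan", "NaN"),
        otypes=[bool],
    )(raw)
    numeric = table.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~blank & (~np.isfinite(numeric) | ~np.isin(numeric, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ParseError(
            f"{path}: row {i + 2} (sample {table.index[i]!r}), column "
            f"{table.columns[j]!r}: dosage {raw[i, j]!r} is not 0/1/2/missing"
        )
    dosage = np.where(blank, np.nan, numeric)
    snp_map = pd.read_csv(map_path, dtype={"snp_id": str, "chromosome": str})
    required = {"snp_id", "chromosome", "position"}
    if not required.issubset(snp_map.columns):
        raise ParseError(f"{map_path}: expected columns {sorted(required)}")
    snp_map = snp_map.set_index("snp_id")
    missing = [s for s in table.columns if s not in snp_map.index]
    if missing:
        raise ParseError(f"{map_path}: no map entry for SNP(s) {missing[:5]}")
    snp_map = snp_map.loc[list(table.columns)]
    return GenotypeMatrix(
        sample_ids=[str(s) for s in table.index],
        snp_ids=[str(s) for s in table.columns],
        chromosome=snp_map["chromosome"].to_numpy(dtype=object),
        position=snp_map["position"].to_numpy(dtype=np.int64),
        dosage=dosage,
    )


_PLINK_MAGIC = bytes([0x6C, 0x1B])
# 2-bit PLINK codes -> dosage of the A1 allele; 1 flags a missing call
_PLINK_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _read_plink_bed(bed_path: Path) -> GenotypeMatrix:
    bim_path = bed_path.with_suffix(".bim")
    fam_path = bed_path.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(f"PLINK file not found: {p}")
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise ParseError(f"{fam_path}: expected at least 2 whitespace-separated columns")
    sample_ids = fam.iloc[:, 1].tolist()
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] < 4:
        raise ParseError(f"{bim_path}: expected at least 4 columns (chrom, id, cm, pos)")
    snp_ids = bim.iloc[:, 1].tolist()
    chromosome = bim.iloc[:, 0].to_numpy(dtype=object)
    try:
        position = bim.iloc[:, 3].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{bim_path}: non-integer base-pair position") from exc

    n, m = len(sample_ids), len(snp_ids)
    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _PLINK_MAGIC:
        raise ParseError(f"{bed_path}: missing PLINK magic bytes")
    if raw[2] != 0x01:
        raise ParseError(f"{bed_path}: only variant-major (SNP-major) .bed files are supported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise ParseError(
            f"{bed_path}: expected {bytes_per_snp * m} data bytes for {n} samples x {m} SNPs, got {body.size}"
        )
    blocks = body.reshape(m, bytes_per_snp)
    # unpack the four 2-bit genotype codes per byte, sample-index ascending
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosage = _PLINK_CODE_TO_DOSAGE[codes[:, :n]].T  # n x m, A1 dosage
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chromosome=chromosome,
        position=position,
        dosage=dosage,
    )


def write_genotype_csv(geno: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None) -> None:
    """Write the CSV dialect (dosage CSV + ``<stem>.map.csv``)."""
    path = Path(path)
    if map_path is None:
        map_path = path.parent / (path.stem + ".map.csv")
    frame = pd.DataFrame(geno.dosage, index=geno.sample_ids, columns=geno.snp_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path, float_format="%g")
    pd.DataFrame(
        {"snp_id": geno.snp_ids, "chromosome": geno.chromosome, "position": geno.position}
    ).to_csv(map_path, index=False)


# ---------------------------------------------------------------------------
# phenotype / covariates
# ---------------------------------------------------------------------------

def read_phenotype(path: str | Path) -> PhenotypeVector:
    """Read a phenotype CSV with a header row: sample id column, value column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"phenotype file not found: {path}")
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: expected at least (sample_id, value) columns")
    return PhenotypeVector(
        sample_ids=[str(s) for s in table.iloc[:, 0]],
        values=pd.to_numeric(table.iloc[:, 1], errors="coerce").to_numpy(),
    )


def write_phenotype(pheno: PhenotypeVector, path: str | Path) -> None:
    pd.DataFrame({"sample_id": pheno.sample_ids, "value": pheno.values}).to_csv(path, index=False)


def read_covariates(path: str | Path) -> CovariateMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"covariate file not found: {path}")
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: expected a sample id column plus covariate columns")
    return CovariateMatrix(
        sample_ids=[str(s) for s in table.iloc[:, 0]],
        values=table.iloc[:, 1:].to_numpy(dtype=float),
        names=[str(c) for c in table.columns[1:]],
    )


# ---------------------------------------------------------------------------
# alignment / cleaning
# ---------------------------------------------------------------------------

def align_samples(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    covariates: CovariateMatrix | None = None,
) -> tuple[GenotypeMatrix, PhenotypeVector, CovariateMatrix | None]:
    """Restrict all inputs to shared samples, in genotype file order.

    Samples whose phenotype is missing (NaN) are dropped.  Raises
    :class:`AlignmentError` when fewer than two samples survive.
    """
    pheno_by_id = {s: v for s, v in zip(pheno.sample_ids, pheno.values)}
    cov_by_id = (
        {s: row for s, row in zip(covariates.sample_ids, covariates.values)}
        if covariates is not None
        else None
    )
    keep: list[int] = []
    for i, sid in enumerate(geno.sample_ids):
        if sid not in pheno_by_id or not np.isfinite(pheno_by_id[sid]):
            continue
        if cov_by_id is not None and sid not in cov_by_id:
            continue
        keep.append(i)
    if len(keep) < 2:
        raise AlignmentError(
            f"only {len(keep)} samples shared between genotype and phenotype"
            + ("" if covariates is None else "/covariates")
        )
    keep_arr = np.asarray(keep)
    geno_out = geno.take_samples(keep_arr)
    ids = geno_out.sample_ids
    pheno_out = PhenotypeVector(sample_ids=list(ids), values=np.array([pheno_by_id[s] for s in ids]))
    cov_out = None
    if covariates is not None:
        cov_out = CovariateMatrix(
            sample_ids=list(ids),
            values=np.vstack([cov_by_id[s] for s in ids]),
            names=list(covariates.names or []) or None,
        )
    if len(ids) < len(geno.sample_ids):
        logger.info("align_samples: kept %d of %d genotype samples", len(ids), len(geno.sample_ids))
    return geno_out, pheno_out, cov_out


def mean_impute(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the per-SNP mean dosage."""
    dosage = geno.dosage.copy()
    missing = ~np.isfinite(dosage)
    if missing.any():
        col_mean = np.nanmean(np.where(missing, np.nan, dosage), axis=0)
        if not np.all(np.isfinite(col_mean)):
            bad = np.flatnonzero(~np.isfinite(col_mean))
            raise ParseError(f"SNP(s) with all calls missing: {[geno.snp_ids[i] for i in bad[:5]]}")
        idx = np.where(missing)
        dosage[idx] = col_mean[idx[1]]
        logger.info("mean_impute: imputed %d missing calls", int(missing.sum()))
    return replace(geno, dosage=dosage)


def flip_to_minor(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Flip columns whose allele frequency exceeds 0.5 (dosage -> 2 - dosage)."""
    freq = np.nanmean(geno.dosage, axis=0) / 2.0
    flip = freq > 0.5
    if not flip.any():
        return geno
    dosage = geno.dosage.copy()
    dosage[:, flip] = 2.0 - dosage[:, flip]
    logger.info("flip_to_minor: flipped %d of %d SNPs to minor-allele orientation", int(flip.sum()), geno.n_snps)
    return replace(geno, dosage=dosage)


def filter_maf(geno: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep SNPs with folded minor-allele frequency strictly above ``min_maf``.

    With ``min_maf = 0`` this removes exactly the monomorphic columns.
    """
    if not 0.0 <= min_maf < 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5), got {min_maf}")
    keep = np.flatnonzero(geno.maf() > min_maf)
    if keep.size == 0:
        raise EmptyGenotypeError(f"no SNP has MAF > {min_maf}")
    if keep.size < geno.n_snps:
        logger.info("filter_maf: kept %d of %d SNPs at MAF > %g", keep.size, geno.n_snps, min_maf)
    return geno.take_snps(keep)


# ---------------------------------------------------------------------------
# results / kinship round-trips
# ---------------------------------------------------------------------------

def write_results(results: Sequence, path: str | Path) -> None:
    """Write association results as a TSV (snp_id .. p_value, fixed column order)."""
    if len(results) == 0:
        raise ValueError("refusing to write an empty result set")
    rows = [
        {
            "snp_id": r.snp_id,
            "chromosome": r.chromosome,
            "position": r.position,
            "maf": r.maf,
            "beta": r.beta,
            "se": r.se,
            "F": r.f_stat,
            "p_value": r.p_value,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"results file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chromosome": str})
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing result columns {missing}")
    return table


def write_kinship(K: KinshipMatrix, path: str | Path) -> None:
    """Write a kinship CSV (square, header = sample ids, 12 significant digits)."""
    frame = pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path, float_format="%.12g")


def read_kinship(path: str | Path) -> KinshipMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"kinship file not found: {path}")
    frame = pd.read_csv(path, index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise ParseError(f"{path}: kinship matrix is not square ({frame.shape})")
    values = frame.to_numpy(dtype=float)
    return KinshipMatrix(sample_ids=[str(s) for s in frame.index], values=values)
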