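"""Standard-format I/O: VCF genotypes, CSV tables, and SNP hard filtering.

Conventions
-----------
* VCF positions are 1-based inclusive; dosage coding is the ALT-allele count
  (0/0 -> 0, 0/1 -> 1, 1/1 -> 2, missing -> -1).
* Exported genomic intervals (LD blocks, QTL regions) are BED-style
  0-based half-open; the conversion happens only at export time.
* CSV dialect: UTF-8, comma separator, single header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import (AlignmentError, DataError, FormatError,
                         ParameterError)

logger = logging.getLogger(__name__)

MISSING = -1

#: the seven grain-quality traits handled by the pipeline
TRAITS = ("AC", "ASV", "GC", "CD", "PGWC", "TP", "MRR")
#: traits recorded as percentages and therefore bounded to [0, 100]
PERCENT_TRAITS = frozenset({"AC", "PGWC", "MRR"})

PHENO_COLUMNS = ["hybrid_id", "location_id", "sowing_index", "trait_name", "value"]
DESIGN_COLUMNS = ["hybrid_id", "female_parent", "male_parent"]
MET_COLUMNS = ["location_id", "date", "tmin", "tmax", "tavg",
               "diurnal_range", "solar", "rainfall"]


# ---------------------------------------------------------------------------
# genotype container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs as ALT-dosages with genomic coordinates.

    ``dosage`` is an ``(n_samples, n_snps)`` int8/int16 array taking values
    in {0, 1, 2} with :data:`MISSING` (-1) for no-calls.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise AlignmentError("dosage rows != number of sample ids")
        if m != len(self.snp_ids):
            raise AlignmentError("dosage columns != number of SNP ids")
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != m:
                raise AlignmentError(f"{name} length != number of SNPs")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError("dosage entries must be 0/1/2 or missing (-1)")
        for ch in pd.unique(self.chrom):
            p = self.pos[self.chrom == ch]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise DataError(f"positions not strictly increasing on {ch}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    # -- views -------------------------------------------------------------
    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in index],
            chrom=self.chrom[index], pos=self.pos[index],
            ref=self.ref[index], alt=self.alt[index],
            dosage=self.dosage[:, index])

    def take_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise AlignmentError(f"unknown samples: {missing[:5]}")
        rows = [lookup[s] for s in sample_ids]
        return replace(self, sample_ids=list(sample_ids),
                       dosage=self.dosage[rows, :])

    def allele_freq(self) -> np.ndarray:
        """Per-SNP ALT allele frequency among called genotypes."""
        d = np.where(self.dosage == MISSING, np.nan, self.dosage).astype(float)
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        af = self.allele_freq()
        return np.minimum(af, 1.0 - af)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT per sample) into a :class:`GenotypeMatrix`.

    With ``biallelic_only`` every multi-allelic or non-SNP record is dropped;
    the number of dropped records is logged.
    """
    from cyvcf2 import VCF

    if not str(path).endswith((".gz", ".bgz")):
        _reject_truncated(path, "VCF")
    try:
        vcf = VCF(str(path))
    except Exception as exc:            # cyvcf2 raises bare OSError/Exception
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")
    chrom, pos, ref, alt, ids, cols = [], [], [], [], [], []
    n_dropped = 0
    try:
        for var in vcf:
            if biallelic_only and (len(var.ALT) != 1 or not var.is_snp):
                n_dropped += 1
                continue
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = np.asarray(var.gt_types)
            dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2],
                             default=MISSING).astype(np.int8)
            chrom.append(var.CHROM)
            pos.append(var.POS)
            ref.append(var.REF)
            alt.append(var.ALT[0] if var.ALT else ".")
            ids.append(var.ID or f"{var.CHROM}_{var.POS}")
            cols.append(dose)
    except Exception as exc:
        raise FormatError(f"malformed VCF record in {path} "
                          f"(after {len(pos)} parsed records): {exc}") from exc
    finally:
        vcf.close()
    if n_dropped:
        logger.info("read_vcf(%s): dropped %d non-biallelic/non-SNP records",
                    path, n_dropped)
    if not pos:
        raise DataError(f"{path}: no usable SNP records")
    dosage = np.stack(cols, axis=1)
    return GenotypeMatrix(sample_ids=samples, snp_ids=ids,
                          chrom=np.array(chrom, dtype=object),
                          pos=np.array(pos, dtype=np.int64),
                          ref=np.array(ref, dtype=object),
                          alt=np.array(alt, dtype=object),
                          dosage=dosage)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal VCF v4.2 with GT fields."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for ch in dict.fromkeys(G.chrom):   # order-preserving unique
            length = int(G.pos[G.chrom == ch].max())
            fh.write(f"##contig=<ID={ch},length={length + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        for j in range(G.n_snps):
            gts = "\t".join(_GT_CODE[int(d)] for d in G.dosage[:, j])
            fh.write(f"{G.chrom[j]}\t{G.pos[j]}\t{G.snp_ids[j]}\t{G.ref[j]}\t"
                     f"{G.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# SNP hard filtering
# ---------------------------------------------------------------------------

#: (annotation, comparison, threshold) removal clauses, as printed by the
#: upstream variant-calling protocol.  A record is removed iff it satisfies at
#: least one clause.  Note the two rank-sum clauses remove *low* values with
#: positive thresholds; every threshold and its direction is configurable so
#: users can restore the conventional negative-threshold signs.
DEFAULT_SNP_FILTERS = (
    ("QUAL", "<", 30.0),
    ("QD", "<", 2.0),
    ("SOR", ">", 3.0),
    ("FS", ">", 60.0),
    ("MQ", "<", 40.0),
    ("MQRankSum", "<", 12.5),
    ("ReadPosRankSum", "<", 8.0),
)

_OPS = {"<": np.less, ">": np.greater, "<=": np.less_equal, ">=": np.greater_equal}


def hard_filter_snps(records: pd.DataFrame,
                     criteria=DEFAULT_SNP_FILTERS) -> tuple[pd.DataFrame, dict]:
    """Apply removal clauses to a table of per-SNP annotations.

    Missing annotations (NaN or absent column) never trigger removal.
    Returns the surviving records and a per-clause report.
    """
    remove = np.zeros(len(records), dtype=bool)
    report: dict = {"n_input": int(len(records)), "clauses": {}}
    for field, op, thr in criteria:
        if op not in _OPS:
            raise ParameterError(f"unknown comparison {op!r} in filter clause")
        if field not in records.columns:
            report["clauses"][f"{field}{op}{thr}"] = 0
            continue
        vals = pd.to_numeric(records[field], errors="coerce").to_numpy(float)
        with np.errstate(invalid="ignore"):
            hit = _OPS[op](vals, thr)
        hit = np.where(np.isnan(vals), False, hit)
        report["clauses"][f"{field}{op}{thr}"] = int(hit.sum())
        remove |= hit
    kept = records.loc[~remove].copy()
    report["n_removed"] = int(remove.sum())
    report["n_survivors"] = int(len(kept))
    logger.info("hard_filter_snps: %d/%d records survive",
                report["n_survivors"], report["n_input"])
    return kept, report


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _reject_truncated(path: str, name: str) -> None:
    """A text table whose last line lacks a newline is treated as truncated
    rather than silently parsed into partial data."""
    with open(path, "rb") as fh:
        fh.seek(0, 2)
        size = fh.tell()
        if size == 0:
            raise FormatError(f"{name} file {path} is empty")
        fh.seek(-1, 2)
        if fh.read(1) != b"\n":
            raise FormatError(f"{name} file {path} appears truncated "
                              "(no trailing newline)")


def _read_csv(path: str, required: list[str], name: str) -> pd.DataFrame:
    _reject_truncated(path, name)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse {name} CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{name} CSV {path} lacks columns {missing}")
    return df


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format phenotype invariants; returns the frame."""
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table lacks columns {missing}")
    key = ["hybrid_id", "location_id", "sowing_index", "trait_name"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise DataError(f"{int(dup.sum())} duplicate phenotype records "
                        f"(first: {df.loc[dup, key].iloc[0].tolist()})")
    pct = df["trait_name"].isin(PERCENT_TRAITS) & df["value"].notna()
    vals = df.loc[pct, "value"]
    if ((vals < 0) | (vals > 100)).any():
        raise DataError("percentage trait values outside [0, 100]")
    return df


def read_phenotypes(path: str) -> pd.DataFrame:
    return validate_phenotypes(_read_csv(path, PHENO_COLUMNS, "phenotype"))


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    validate_phenotypes(df)[PHENO_COLUMNS].to_csv(path, index=False)


def validate_design(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cross-design table lacks columns {missing}")
    if df["hybrid_id"].duplicated().any():
        raise DataError("duplicate hybrid ids in cross design")
    if (df["female_parent"] == df["male_parent"]).any():
        raise DataError("cross design contains a selfing row")
    return df


def read_design(path: str) -> pd.DataFrame:
    return validate_design(_read_csv(path, DESIGN_COLUMNS, "cross-design"))


def write_design(df: pd.DataFrame, path: str) -> None:
    validate_design(df)[DESIGN_COLUMNS].to_csv(path, index=False)


def read_meteorology(path: str) -> pd.DataFrame:
    df = _read_csv(path, MET_COLUMNS, "meteorology")
    df["date"] = pd.to_datetime(df["date"])
    if df.duplicated(subset=["location_id", "date"]).any():
        raise DataError("duplicate (location, date) rows in meteorology table")
    bad = (df["tmin"] > df["tavg"]) | (df["tavg"] > df["tmax"])
    if bad.any():
        raise DataError("meteorology rows violate tmin <= tavg <= tmax")
    if (df["rainfall"] < 0).any():
        raise DataError("negative rainfall")
    return df


def write_meteorology(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[MET_COLUMNS].to_csv(path, index=False)
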