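"""Readers and writers for GWAS summary statistics and genotype panels.

Summary statistics arrive as consortium-style delimited text with
heterogeneous column headers; a dialect mapping translates them onto the
canonical schema (``snp_id``, ``chromosome``, ``position``, ``effect_allele``,
``other_allele``, ``beta``, and optionally ``eaf``, ``n``). Genotypes are read
from PLINK BED/BIM/FAM triplets or VCF. Dosages count copies of the panel's
coded allele (``allele1``); missing genotypes are NaN, never 0.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta")
OPTIONAL_COLUMNS = ("chromosome", "position", "eaf", "n")

#: Case-insensitive header aliases for common consortium file dialects.
DEFAULT_ALIASES = {
    "snp_id": ["snp_id", "markername", "snp", "rsid", "rs_id", "id", "marker"],
    "chromosome": ["chromosome", "chr", "chrom"],
    "position": ["position", "pos", "bp", "base_pair_location"],
    "effect_allele": ["effect_allele", "allele1", "a1", "ea", "alt"],
    "other_allele": ["other_allele", "allele2", "a2", "oa", "nea", "ref"],
    "beta": ["beta", "b", "effect", "beta_ext", "effect_size"],
    "eaf": ["eaf", "freq.allele1.hapmapceu", "freq1", "af", "effect_allele_frequency"],
    "n": ["n", "n_ext", "samplesize", "sample_size"],
}

_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26})


def chromosome_sort_key(label) -> tuple:
    """Natural ordering for chromosome labels (1..22, X, Y, MT, then lexical)."""
    s = re.sub("^chr", "", str(label), flags=re.IGNORECASE).upper()
    if s in _CHROM_ORDER:
        return (0, _CHROM_ORDER[s], "")
    return (1, 0, s)


def read_summary_stats(path, dialect: dict | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a summary-statistic table onto the canonical schema.

    Parameters
    ----------
    path : str or Path
        Delimited text file with one row per SNP.
    dialect : dict, optional
        Mapping from canonical column names to the file's column names.
        Columns not covered are auto-detected from :data:`DEFAULT_ALIASES`.
    sep : str, optional
        Field separator; sniffed when omitted.

    Returns
    -------
    pandas.DataFrame with at least the mandatory canonical columns. Rows with
    missing or non-finite effect sizes are dropped (count logged). Alleles are
    upper-cased.
    """
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    lower = {c.lower(): c for c in raw.columns}
    colmap = {}
    dialect = dialect or {}
    for canon in MANDATORY_COLUMNS + OPTIONAL_COLUMNS:
        if canon in dialect:
            if dialect[canon] not in raw.columns:
                raise ConfigurationError(
                    f"dialect maps {canon!r} to {dialect[canon]!r}, not a column of {path}"
                )
            colmap[canon] = dialect[canon]
            continue
        for alias in DEFAULT_ALIASES[canon]:
            if alias in lower:
                colmap[canon] = lower[alias]
                break
    missing = [c for c in MANDATORY_COLUMNS if c not in colmap]
    if missing:
        raise ConfigurationError(
            f"could not map mandatory column(s) {missing} in {path}; "
            f"available columns: {list(raw.columns)}"
        )
    table = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})
    table["snp_id"] = table["snp_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        table[col] = table[col].astype(str).str.upper()
    table["beta"] = pd.to_numeric(table["beta"], errors="coerce")
    bad = ~np.isfinite(table["beta"].to_numpy(dtype=float))
    if bad.any():
        logger.info("read_summary_stats: dropped %d rows with missing/non-finite beta", bad.sum())
        table = table.loc[~bad].reset_index(drop=True)
    dup = table["snp_id"].duplicated(keep=False)
    if dup.any():
        ids = table.loc[dup, "snp_id"].unique().tolist()
        raise ValidationError(f"duplicated snp_id in summary statistics: {ids[:20]}")
    same = table["effect_allele"] == table["other_allele"]
    if same.any():
        raise ValidationError(
            f"effect_allele equals other_allele for {same.sum()} SNP(s), e.g. "
            f"{table.loc[same, 'snp_id'].iloc[0]}"
        )
    table.attrs["n_dropped_beta"] = int(bad.sum())
    return table


@dataclass
class GenotypePanel:
    """Dosage matrix plus variant and sample metadata, in genome order.

    ``dosage`` is n_samples x n_variants, entries in [0, 2] counting copies of
    ``variants.allele1`` (the coded allele); missing entries are NaN.
    """

    sample_ids: list[str]
    variants: pd.DataFrame  # snp_id, chromosome, position, allele1, allele2
    dosage: np.ndarray

    def __post_init__(self):
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        order = sorted(
            range(m),
            key=lambda j: (
                chromosome_sort_key(self.variants["chromosome"].iat[j]),
                self.variants["position"].iat[j],
            ),
        )
        if order != list(range(m)):
            self.variants = self.variants.iloc[order].reset_index(drop=True)
            self.dosage = self.dosage[:, order]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]


# PLINK .bed 2-bit code -> dosage of allele1 (A1). 0b01 is missing.
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])
_BED_ENCODE = {2: 0b00, 1: 0b10, 0: 0b11}


def read_plink(prefix) -> GenotypePanel:
    """Read a PLINK BED/BIM/FAM triplet (SNP-major .bed)."""
    prefix = str(prefix)
    if prefix.endswith(".bed"):
        prefix = prefix[:-4]
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position", "allele1", "allele2"],
        dtype={"chromosome": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, usecols=[0, 1], names=["fid", "iid"])
    sample_ids = fam["iid"].astype(str).tolist()
    n, m = len(sample_ids), len(bim)
    data = Path(prefix + ".bed").read_bytes()
    if len(data) < 3 or data[0] != 0x6C or data[1] != 0x1B:
        raise FormatError(f"{prefix}.bed: missing PLINK magic bytes 0x6c 0x1b")
    if data[2] != 0x01:
        raise FormatError(f"{prefix}.bed: not in SNP-major mode (third byte {data[2]:#x})")
    bytes_per_snp = math.ceil(n / 4)
    expected = 3 + m * bytes_per_snp
    if len(data) != expected:
        raise FormatError(
            f"{prefix}.bed: truncated or oversized binary block at byte offset "
            f"{min(len(data), expected)} (expected {expected} bytes for {m} variants "
            f"x {n} samples, found {len(data)})"
        )
    arr = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    codes = (arr[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 3
    codes = codes.reshape(m, -1)[:, :n]
    dosage = _BED_DECODE[codes].T.astype(np.float32)  # n x m
    variants = bim[["snp_id", "chromosome", "position", "allele1", "allele2"]].copy()
    return GenotypePanel(sample_ids, variants, dosage)


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a panel as PLINK BED/BIM/FAM (inverse of :func:`read_plink`)."""
    prefix = str(prefix)
    n, m = panel.dosage.shape
    bim = panel.variants.assign(cm=0)[
        ["chromosome", "snp_id", "cm", "position", "allele1", "allele2"]
    ]
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    with open(prefix + ".fam", "w") as fh:
        for sid in panel.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    bytes_per_snp = math.ceil(n / 4)
    out = bytearray([0x6C, 0x1B, 0x01])
    for j in range(m):
        col = panel.dosage[:, j]
        codes = np.empty(bytes_per_snp * 4, dtype=np.uint8)
        codes[:] = 0b01  # pad/missing
        for i in range(n):
            v = col[i]
            codes[i] = 0b01 if np.isnan(v) else _BED_ENCODE[int(round(v))]
        packed = codes.reshape(-1, 4)
        out.extend((packed[:, 0] | packed[:, 1] << 2 | packed[:, 2] << 4 | packed[:, 3] << 6).tobytes())
    Path(prefix + ".bed").write_bytes(bytes(out))


def read_vcf(path) -> GenotypePanel:
    """Read genotypes from VCF; dosage counts the ALT allele (DS preferred, else GT).

    Multi-allelic records are dropped with a log message. Missing genotypes
    (``./.``) become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    rows, meta = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = np.asarray(v.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(v.gt_types, dtype=float)  # 0,1,2; 3 = unknown
            ds = np.where(gt == 3, np.nan, gt)
        rows.append(ds)
        meta.append((v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS, v.ALT[0], v.REF))
    if n_multi:
        logger.info("read_vcf: dropped %d multi-allelic record(s)", n_multi)
    if not rows:
        raise FormatError(f"{path}: no usable biallelic records")
    variants = pd.DataFrame(meta, columns=["snp_id", "chromosome", "position", "allele1", "allele2"])
    dosage = np.vstack(rows).T.astype(np.float32)
    return GenotypePanel(sample_ids, variants, dosage)


def read_genotypes(path, format: str | None = None) -> GenotypePanel:
    """Dispatch to :func:`read_plink` or :func:`read_vcf` by format/extension."""
    p = str(path)
    if format is None:
        if p.endswith((".bed", ".bim", ".fam")) or Path(p + ".bed").exists():
            format = "plink-bed"
        elif p.endswith((".vcf", ".vcf.gz")):
            format = "vcf"
        else:
            raise ConfigurationError(f"cannot infer genotype format of {path}")
    if format == "plink-bed":
        return read_plink(p)
    if format == "vcf":
        return read_vcf(p)
    raise ConfigurationError(f"unknown genotype format {format!r}")


def read_phenotype_table(path, trait: str, covariates: list[str] | None = None) -> pd.DataFrame:
    """Read a phenotype/covariate TSV keyed by sample id."""
    df = pd.read_csv(path, sep="\t")
    idcol = next((c for c in df.columns if c.lower() in ("sample_id", "iid", "id")), df.columns[0])
    cols = [trait] + list(covariates or [])
    for c in cols:
        if c not in df.columns:
            raise ConfigurationError(f"column {c!r} not in {path}")
    out = df[[idcol] + cols].rename(columns={idcol: "sample_id"})
    out["sample_id"] = out["sample_id"].astype(str)
    return out
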