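"""Allele harmonization and standardization of genotypes, betas and traits.

The external summary coefficients and the target panel must share allele
coding before any weight tuning: the coded (counted) allele of each panel
variant is matched against the summary effect allele, flipping the beta sign
when the coding is reversed, resolving strand flips through allele
complements, and dropping (or frequency-resolving) palindromic A/T and C/G
variants whose strand is ambiguous.

Genotype columns are standardized to mean 0 and variance 1 using the
population (divide-by-n) variance convention, so that the univariate
coefficient of a standardized trait on column j is exactly x_j'y/n. Missing
dosages are mean-imputed before centering, keeping the sample size constant
across SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyIntersectionError, ValidationError
from .io import GenotypePanel, chromosome_sort_key

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, which are invariant under strand flip."""
    return COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizePolicy:
    """Options controlling SNP matching and allele resolution."""

    match_on: str = "snp_id"  # or "position" (chromosome:position)
    palindromic: str = "drop"  # or "frequency"
    freq_margin: float = 0.08  # both |eaf-0.5| must exceed this to resolve
    trim_percentiles: bool = False  # drop trait values outside 1st-99th pct
    residualize_covariates: bool = False

    def __post_init__(self):
        if self.match_on not in ("snp_id", "position"):
            raise ConfigurationError(f"match_on must be snp_id or position, got {self.match_on!r}")
        if self.palindromic not in ("drop", "frequency"):
            raise ConfigurationError(f"palindromic must be drop or frequency, got {self.palindromic!r}")


@dataclass
class HarmonizedStudy:
    """SNP-aligned bundle of standardized genotypes, betas and phenotype.

    Columns of ``genotypes_std`` have mean 0 and variance 1 (population
    convention); ``beta_ext`` is aligned to the genotype coded-allele
    orientation; SNPs are in genome order.
    """

    genotypes_std: np.ndarray  # n x m
    beta_ext: np.ndarray  # m
    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    phenotype: np.ndarray | None = None
    covariates: np.ndarray | None = None
    is_binary: bool = False

    def __post_init__(self):
        n, m = self.genotypes_std.shape
        if len(self.beta_ext) != m or len(self.snp_ids) != m:
            raise ValidationError("beta_ext/snp_ids length does not match genotype columns")
        if self.phenotype is not None and len(self.phenotype) != n:
            raise ValidationError("phenotype length does not match samples")

    @property
    def n_samples(self) -> int:
        return self.genotypes_std.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes_std.shape[1]


def standardize_betas(table: pd.DataFrame, mode: str = "already-standardized") -> pd.DataFrame:
    """Place summary betas on the per-genotype-SD scale.

    ``per-allele`` rescales each beta by the genotype SD implied by its
    effect-allele frequency under Hardy-Weinberg, sqrt(2*eaf*(1-eaf));
    ``already-standardized`` is the identity. SNPs with eaf in {0, 1} (or
    missing) under per-allele mode are dropped with a logged count.
    """
    if mode == "already-standardized":
        return table
    if mode != "per-allele":
        raise ConfigurationError(f"unknown beta standardization mode {mode!r}")
    if "eaf" not in table.columns:
        raise ConfigurationError("per-allele standardization requires an eaf column")
    eaf = pd.to_numeric(table["eaf"], errors="coerce").to_numpy(dtype=float)
    ok = np.isfinite(eaf) & (eaf > 0) & (eaf < 1)
    if (~ok).any():
        logger.info("standardize_betas: dropped %d SNPs with eaf outside (0,1)", (~ok).sum())
    out = table.loc[ok].reset_index(drop=True).copy()
    p = eaf[ok]
    out["beta"] = out["beta"].to_numpy(dtype=float) * np.sqrt(2.0 * p * (1.0 - p))
    return out


def _resolve_alleles(panel_a1, panel_a2, eff, oth):
    """Orientation of the panel coded allele vs the summary effect allele.

    Returns +1 (aligned), -1 (beta must flip), ``"palindromic"``, or ``None``
    (irresolvable). Complements handle strand flips.
    """
    alleles = {panel_a1, panel_a2, eff, oth}
    if not alleles <= set("ACGT"):
        return None
    if is_palindromic(panel_a1, panel_a2):
        return "palindromic" if {panel_a1, panel_a2} == {eff, oth} else None
    if (panel_a1, panel_a2) == (eff, oth):
        return 1
    if (panel_a1, panel_a2) == (oth, eff):
        return -1
    ca1, ca2 = COMPLEMENT[panel_a1], COMPLEMENT[panel_a2]
    if (ca1, ca2) == (eff, oth):
        return 1
    if (ca1, ca2) == (oth, eff):
        return -1
    return None


def standardize_genotypes(dosage: np.ndarray):
    """Mean-impute, center and scale dosage columns to mean 0, variance 1.

    Returns ``(X_std, kept, n_removed)`` where ``kept`` indexes the retained
    (non-monomorphic) columns of the input. Population (divide-by-n) variance.
    """
    X = np.array(dosage, dtype=np.float64, copy=True)
    if X.ndim != 2:
        raise ValidationError("dosage must be a 2-D matrix")
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    kept = np.nonzero(sd > 0)[0]
    n_removed = X.shape[1] - len(kept)
    if len(kept) == 0:
        raise ValidationError("all genotype columns are monomorphic")
    if n_removed:
        logger.info("standardize_genotypes: removed %d monomorphic column(s)", n_removed)
    X = (X[:, kept] - mu[kept]) / sd[kept]
    return X, kept, n_removed


def standardize_phenotype(
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    binary: bool = False,
    policy: HarmonizePolicy | None = None,
):
    """Standardize a quantitative trait (optionally residualized/trimmed).

    Binary traits are returned as 0/1 labels unchanged. Returns
    ``(y_out, covariates_out, keep_mask)``.
    """
    policy = policy or HarmonizePolicy()
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    if binary:
        if not set(np.unique(y[keep])) <= {0.0, 1.0}:
            raise ValidationError("binary trait must be coded 0/1")
        return y, covariates, keep
    if policy.trim_percentiles:
        lo, hi = np.nanpercentile(y[keep], [1, 99])
        keep &= (y >= lo) & (y <= hi)
    yk = y[keep]
    cov = covariates[keep] if covariates is not None else None
    if policy.residualize_covariates and cov is not None:
        design = np.column_stack([np.ones(len(yk)), cov])
        coef, *_ = np.linalg.lstsq(design, yk, rcond=None)
        yk = yk - design @ coef
    yk = (yk - yk.mean()) / yk.std()
    return yk, cov, keep


def harmonize(
    panel: GenotypePanel,
    stats: pd.DataFrame,
    policy: HarmonizePolicy | None = None,
    phenotype: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    binary: bool = False,
) -> HarmonizedStudy:
    """Intersect, allele-align and standardize a panel against summary stats.

    The output contains only SNPs present in both sources with a resolvable
    allele pairing, in genome order, with betas aligned to the panel's coded
    allele and genotype columns standardized. Palindromic SNPs are dropped or
    frequency-resolved per ``policy``.
    """
    policy = policy or HarmonizePolicy()
    stats = stats.reset_index(drop=True)
    if policy.match_on == "snp_id":
        panel_keys = panel.variants["snp_id"].astype(str)
        stat_keys = stats["snp_id"].astype(str)
    else:
        if "chromosome" not in stats.columns or "position" not in stats.columns:
            raise ConfigurationError("match_on='position' requires chromosome and position columns")
        panel_keys = panel.variants["chromosome"].astype(str) + ":" + panel.variants["position"].astype(str)
        stat_keys = stats["chromosome"].astype(str) + ":" + stats["position"].astype(str)
    stat_index = pd.Series(stats.index.values, index=stat_keys)
    shared = panel_keys.isin(stat_index.index)
    if not shared.any():
        raise EmptyIntersectionError("no SNPs shared between panel and summary statistics")

    keep_cols, signs, betas = [], [], []
    n_dropped_pal, n_dropped_irres = 0, 0
    has_eaf = "eaf" in stats.columns
    for j in np.nonzero(shared.to_numpy())[0]:
        srow = stats.iloc[int(stat_index[panel_keys.iloc[j]])]
        a1 = str(panel.variants["allele1"].iat[j]).upper()
        a2 = str(panel.variants["allele2"].iat[j]).upper()
        res = _resolve_alleles(a1, a2, srow["effect_allele"], srow["other_allele"])
        if res == "palindromic":
            res = None
            if policy.palindromic == "frequency" and has_eaf and np.isfinite(srow["eaf"]):
                col = panel.dosage[:, j]
                pa1 = np.nanmean(col) / 2.0
                eaf = float(srow["eaf"])
                if abs(pa1 - 0.5) > policy.freq_margin and abs(eaf - 0.5) > policy.freq_margin:
                    res = 1 if (pa1 > 0.5) == (eaf > 0.5) else -1
            if res is None:
                n_dropped_pal += 1
                continue
        elif res is None:
            n_dropped_irres += 1
            continue
        keep_cols.append(j)
        signs.append(res)
        betas.append(float(srow["beta"]))
    if n_dropped_pal or n_dropped_irres:
        logger.info(
            "harmonize: dropped %d palindromic and %d irresolvable SNP(s)",
            n_dropped_pal, n_dropped_irres,
        )
    if not keep_cols:
        raise EmptyIntersectionError("no SNPs with resolvable alleles after harmonization")

    keep_cols = np.asarray(keep_cols)
    beta_aligned = np.asarray(betas) * np.asarray(signs, dtype=float)
    dosage = panel.dosage[:, keep_cols]
    variants = panel.variants.iloc[keep_cols].reset_index(drop=True)

    y, cov, sample_keep = None, covariates, np.ones(panel.n_samples, bool)
    if phenotype is not None:
        y, cov, sample_keep = standardize_phenotype(phenotype, covariates, binary, policy)
        dosage = dosage[sample_keep]
    X, kept, _ = standardize_genotypes(dosage)
    variants = variants.iloc[kept].reset_index(drop=True)
    beta_aligned = beta_aligned[kept]

    order = sorted(
        range(len(variants)),
        key=lambda i: (chromosome_sort_key(variants["chromosome"].iat[i]), variants["position"].iat[i]),
    )
    variants = variants.iloc[order].reset_index(drop=True)
    sample_ids = [s for s, k in zip(panel.sample_ids, sample_keep) if k]
    return HarmonizedStudy(
        genotypes_std=X[:, order],
        beta_ext=beta_aligned[order],
        snp_ids=variants["snp_id"].to_numpy(),
        chromosomes=variants["chromosome"].to_numpy(),
        positions=variants["position"].to_numpy(),
        sample_ids=sample_ids,
        phenotype=y,
        covariates=cov,
        is_binary=binary,
    )
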