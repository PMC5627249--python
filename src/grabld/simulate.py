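"""Synthetic haplotype pools, additive traits and theory experiments.

The generator emulates the minimal ingredients a summary-statistic
polygenic-score pipeline needs, without any genotype download: a pool of
binary haplotypes over one contiguous region with controllable block LD; a
target cohort drawn from the pool; an additive standardized trait
y = X beta + e with per-SNP effects beta_j ~ N(0, h2/m), so the regional
genetic variance (the trait variance explained by the region) is h2 in
expectation; and an "external study" — an independent sample from the same
pool whose univariate coefficients b*_j = x_j'y*/N play the role of
consortium summary statistics.

Block LD is produced by thresholding equicorrelated latent Gaussians, with
the latent correlation calibrated (via the bivariate-normal orthant
probability) so the realized binary correlation hits the requested
within-block r². Each block shares one allele frequency: heterogeneous
frequencies cap the attainable correlation between binary variants below 1,
so a common frequency is what makes the full r² range reachable.

``run_theory_experiment`` reproduces the information-loss experiment for the
LD-corrected score built directly from external coefficients (weights
b*/eta, no boosting), measuring per replicate the realized genetic variance
R²_true = sum beta_j², the sample Cov(g, y), Var(g) and the prediction R².
``run_end_to_end_recovery`` exercises the full boosted pipeline against
deliberately miscalibrated external magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import multivariate_normal, norm

from .boost import BoostConfig, assign_folds, compute_beta_obs, compute_deviation, compute_weights, fit_boosted_deviation
from .exceptions import ConfigurationError, ValidationError
from .ld import apply_ld_correction, compute_eta
from .score import evaluate_r2

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LD models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoLD:
    """Mutually independent SNPs (linkage equilibrium)."""


@dataclass(frozen=True)
class BlockLD:
    """Repeating pattern of equicorrelated blocks.

    ``block_sizes`` and ``within_r2`` are cycled in parallel along the
    region. The default unit — blocks of 3, 3, 2 and 1 SNPs at within-block
    r² of 0.8, 0.5, 0.2 and 0 — mixes strong, moderate and weak LD with
    isolated sites, a stand-in for the partial LD of a real genotyped region.
    A block size of 1 (or r² = 0) yields an independent SNP; r² = 1 yields
    exact duplicates.
    """

    block_sizes: tuple = (3, 3, 2, 1)
    within_r2: tuple = (0.8, 0.5, 0.2, 0.0)

    def __post_init__(self):
        if len(self.block_sizes) != len(self.within_r2):
            raise ConfigurationError("block_sizes and within_r2 must have equal length")
        if any(s < 1 for s in self.block_sizes):
            raise ConfigurationError("block sizes must be >= 1")
        if any(not (0 <= q <= 1) for q in self.within_r2):
            raise ConfigurationError("within_r2 values must lie in [0, 1]")


@dataclass(frozen=True)
class MosaicLD:
    """Haplotypes as segmental copies of a small founder pool.

    Each haplotype copies one of ``pool_size`` founders, switching to a
    random founder after geometric((switch_rate)) distances, giving LD that
    decays with SNP distance.
    """

    pool_size: int = 20
    switch_rate: float = 0.1

    def __post_init__(self):
        if self.pool_size < 2:
            raise ConfigurationError("mosaic pool_size must be >= 2")
        if not (0 < self.switch_rate <= 1):
            raise ConfigurationError("switch_rate must be in (0, 1]")


@dataclass
class SimConfig:
    """Study conditions for the simulation experiments.

    Defaults are the reference region: 5,000 target individuals at 450
    contiguous SNPs, an external study of 50,000, a 30,000-haplotype pool,
    regional genetic variance set-points from 0.05 to 0.5 with 1,000
    replicates each, and the default :class:`BlockLD` mixture.
    """

    n_target: int = 5000
    n_external: int = 50000
    m_snps: int = 450
    h2_grid: tuple = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    n_reps: int = 1000
    ld_model: object = field(default_factory=BlockLD)
    pool_haplotypes: int = 30000
    window: int = 100
    eta_source: str = "pool"  # population LD; "target" re-estimates per replicate
    seed: int = 0

    def __post_init__(self):
        if self.m_snps < 2:
            raise ConfigurationError("m_snps must be >= 2")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if any(not (0 <= h <= 1) for h in self.h2_grid):
            raise ConfigurationError("h2 set-points must lie in [0, 1]")
        if self.eta_source not in ("pool", "target"):
            raise ConfigurationError("eta_source must be 'pool' or 'target'")

    def fast(self) -> "SimConfig":
        """Reduced-replicate copy (200 per set-point) for CI-scale runs."""
        return replace(self, n_reps=200)


# ---------------------------------------------------------------------------
# Haplotype pool
# ---------------------------------------------------------------------------

def max_binary_corr(p1: float, p2: float) -> float:
    """Upper bound on the correlation of Bernoulli(p1), Bernoulli(p2)."""
    q1, q2 = 1 - p1, 1 - p2
    return min(np.sqrt(p1 * q2 / (p2 * q1)), np.sqrt(p2 * q1 / (p1 * q2)))


def _latent_rho(p: float, r_target: float) -> float:
    """Latent Gaussian correlation giving binary correlation ``r_target``
    after thresholding two standard normals at the p-quantile."""
    if r_target >= 0.999999:
        return 1.0
    if r_target <= 0:
        return 0.0
    t = norm.ppf(p)
    q = 1 - p

    def gap(rho):
        p11 = multivariate_normal.cdf([t, t], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        return (p11 - p * p) / (p * q) - r_target

    return float(optimize.brentq(gap, 0.0, 0.999999, xtol=1e-10))


@dataclass
class HaplotypePool:
    """H x m binary haplotype matrix with per-SNP allele frequencies."""

    haplotypes: np.ndarray  # int8, H x m
    freqs: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def m_snps(self) -> int:
        return self.haplotypes.shape[1]

    def draw_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n x m dosage matrix: each individual is two pool haplotypes."""
        i1 = rng.integers(0, self.n_haplotypes, n)
        i2 = rng.integers(0, self.n_haplotypes, n)
        g = self.haplotypes[i1].astype(np.int8, copy=True)
        g += self.haplotypes[i2]
        return g

    def standardized_alleles(self) -> np.ndarray:
        """Pool alleles as standardized float32 columns (population LD)."""
        P = self.haplotypes.astype(np.float32)
        mu = P.mean(axis=0)
        sd = P.std(axis=0)
        if np.any(sd == 0):
            raise ValidationError("pool contains monomorphic SNPs")
        P -= mu
        P /= sd
        return P


def _blocks_layout(model: BlockLD, m: int):
    """Cycle the (size, r2) pattern to cover m SNPs; last block truncated."""
    layout = []
    i, total = 0, 0
    while total < m:
        s = min(model.block_sizes[i % len(model.block_sizes)], m - total)
        layout.append((s, model.within_r2[i % len(model.within_r2)]))
        total += s
        i += 1
    return layout


def generate_haplotype_pool(config: SimConfig, rng: np.random.Generator | None = None) -> HaplotypePool:
    """Build the haplotype pool for the configured LD model.

    Allele frequencies are uniform on [0.05, 0.95]: per SNP under ``NoLD``
    and ``MosaicLD``, per block under ``BlockLD`` (shared within a block —
    see the module docstring; an explicit check covers infeasible targets).
    """
    rng = rng or np.random.default_rng(config.seed)
    H, m, model = config.pool_haplotypes, config.m_snps, config.ld_model
    if isinstance(model, NoLD):
        freqs = rng.uniform(0.05, 0.95, m)
        hap = (rng.random((H, m)) < freqs).astype(np.int8)
        return HaplotypePool(hap, freqs)
    if isinstance(model, MosaicLD):
        freqs = rng.uniform(0.05, 0.95, m)
        founders = (rng.random((model.pool_size, m)) < freqs).astype(np.int8)
        # a monomorphic founder column would make the whole SNP monomorphic
        for j in np.nonzero(founders.min(0) == founders.max(0))[0]:
            founders[rng.integers(0, model.pool_size), j] ^= 1
        choice = np.empty((H, m), dtype=np.int64)
        choice[:, 0] = rng.integers(0, model.pool_size, H)
        switch = rng.random((H, m - 1)) < model.switch_rate
        fresh = rng.integers(0, model.pool_size, (H, m - 1))
        for j in range(1, m):
            choice[:, j] = np.where(switch[:, j - 1], fresh[:, j - 1], choice[:, j - 1])
        hap = founders[choice, np.arange(m)]
        return HaplotypePool(hap, hap.mean(axis=0))
    if isinstance(model, BlockLD):
        cols, freqs = [], []
        rho_cache: dict = {}
        for s, q in _blocks_layout(model, m):
            p = float(rng.uniform(0.05, 0.95))
            r = float(np.sqrt(q))
            if r > max_binary_corr(p, p) + 1e-12:  # equal freqs: never triggers
                raise ConfigurationError(f"within_r2={q} infeasible at frequency {p}")
            freqs.extend([p] * s)
            if s == 1 or q == 0.0:
                cols.append((rng.random((H, s)) < p).astype(np.int8))
                continue
            if q >= 1.0:
                col = (rng.random(H) < p).astype(np.int8)
                cols.append(np.repeat(col[:, None], s, axis=1))
                continue
            key = (round(p, 6), round(r, 6))
            if key not in rho_cache:
                rho_cache[key] = _latent_rho(p, r)
            rho = rho_cache[key]
            t = norm.ppf(p)
            shared = rng.standard_normal(H)
            latent = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * rng.standard_normal((H, s))
            cols.append((latent < t).astype(np.int8))
        return HaplotypePool(np.concatenate(cols, axis=1), np.asarray(freqs))
    raise ConfigurationError(f"unknown ld_model {model!r}")


# ---------------------------------------------------------------------------
# Effects, traits, external study
# ---------------------------------------------------------------------------

def simulate_effects(m: int, h2: float, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP effects beta_j ~ N(0, h2/m), independent across SNPs.

    The realized regional genetic variance sum beta_j² has expectation h2
    (the per-SNP effect variance sigma² = h2/m times m).
    """
    if not (0 <= h2 <= 1):
        raise ConfigurationError(f"h2 must lie in [0, 1], got {h2}")
    if h2 == 0:
        return np.zeros(m)
    return rng.normal(0.0, np.sqrt(h2 / m), m)


def simulate_trait(genotypes_std: np.ndarray, beta: np.ndarray, h2: float, rng: np.random.Generator) -> np.ndarray:
    """y = X beta + e with e ~ N(0, 1 - h2) i.i.d.; Var(y) is 1 in expectation."""
    if h2 > 1:
        raise ConfigurationError("total genetic variance m*sigma² exceeds 1")
    X = np.asarray(genotypes_std)
    return X @ beta + rng.normal(0.0, np.sqrt(1.0 - h2), X.shape[0])


def _standardize_cols(G: np.ndarray):
    """Float32 in-place column standardization of an integer dosage draw."""
    X = G.astype(np.float32)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError("monomorphic column in sampled genotypes; increase n or adjust frequencies")
    X -= mu
    X /= sd
    return X, mu, sd


@dataclass
class ExternalStudy:
    """Univariate summary coefficients from a disjoint external sample."""

    b_star: np.ndarray
    n_external: int


def simulate_external_study(
    pool: HaplotypePool,
    n_external: int,
    beta: np.ndarray,
    h2: float,
    rng: np.random.Generator,
    noise_sd: float | None = None,
) -> ExternalStudy:
    """b*_j = x*_j'y*/N on standardized columns of a fresh pool sample.

    ``noise_sd`` overrides the residual SD (default sqrt(1 - h2)), used by
    the miscalibration experiments where the external generative model is
    deliberately inconsistent with a unit trait variance.
    """
    G = pool.draw_genotypes(n_external, rng)
    Gf = G.astype(np.float32)
    mu = Gf.mean(axis=0)
    sd = Gf.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError("monomorphic column in external sample")
    sd_e = np.sqrt(1.0 - h2) if noise_sd is None else noise_sd
    # y* on the standardized scale without materializing the centered matrix
    y = Gf @ (beta / sd) - float((mu / sd) @ beta) + rng.normal(0.0, sd_e, n_external)
    b = (Gf.T @ y) / n_external
    b = (b - mu * y.mean()) / sd
    return ExternalStudy(b_star=b.astype(np.float64), n_external=n_external)


# ---------------------------------------------------------------------------
# Theory experiment: LD-corrected score from raw external coefficients
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Replicate-level outcomes of the LD-correction theory experiment."""

    replicates: pd.DataFrame  # h2, rep, r2_true, cov_gy, var_g, pred_r2
    config: SimConfig

    def summary(self) -> pd.DataFrame:
        """Per-set-point means/SDs plus the recovery ratio
        mean(pred R²) / mean(R²_true)."""
        rows = []
        for h2, grp in self.replicates.groupby("h2"):
            rows.append(
                {
                    "h2": h2,
                    "n_reps": len(grp),
                    "mean_r2_true": grp["r2_true"].mean(),
                    "mean_cov_gy": grp["cov_gy"].mean(),
                    "se_cov_gy": (grp["cov_gy"] - grp["r2_true"]).std() / np.sqrt(len(grp)),
                    "mean_var_g": grp["var_g"].mean(),
                    "mean_pred_r2": grp["pred_r2"].mean(),
                    "sd_pred_r2": grp["pred_r2"].std(),
                    "recovery_ratio": (
                        grp["pred_r2"].mean() / grp["r2_true"].mean()
                        if grp["r2_true"].mean() > 0
                        else np.nan  # h2 = 0 set-point: ratio undefined
                    ),
                }
            )
        return pd.DataFrame(rows)

    @property
    def recovery_ratio(self) -> float:
        """Overall mean of the per-set-point recovery ratios (h2 > 0 only)."""
        return float(np.nanmean(self.summary()["recovery_ratio"]))


def run_theory_experiment(config: SimConfig) -> SimResult:
    """LD-corrected score g = X (b*/eta) built from raw external
    coefficients (no boosting), replicated over the h2 grid.

    Verifies the three theoretical properties of the windowed LD correction:
    E[Cov(g, y)] equals the true regional genetic variance (unbiasedness),
    E[Var(g)] is at least that variance, and the prediction R² therefore
    under-recovers it — the information lost to partial LD.
    """
    rng = np.random.default_rng(config.seed)
    pool = generate_haplotype_pool(config, rng)
    if config.eta_source == "pool":
        eta_pool = compute_eta(pool.standardized_alleles(), window=config.window).eta
    rows = []
    for h2 in config.h2_grid:
        for rep in range(config.n_reps):
            beta = simulate_effects(config.m_snps, h2, rng)
            r2_true = float(beta @ beta)
            X, _, _ = _standardize_cols(pool.draw_genotypes(config.n_target, rng))
            y = simulate_trait(X, beta, h2, rng)
            ext = simulate_external_study(pool, config.n_external, beta, h2, rng)
            if config.eta_source == "pool":
                eta = eta_pool
            else:
                eta = compute_eta(X, window=config.window).eta
            g = X @ apply_ld_correction(ext.b_star, eta)
            cov = float(np.cov(g, y, ddof=0)[0, 1])
            var_g = float(g.var())
            pred_r2 = 0.0 if var_g == 0 else cov**2 / (var_g * y.var())
            rows.append((h2, rep, r2_true, cov, var_g, pred_r2))
    reps = pd.DataFrame(rows, columns=["h2", "rep", "r2_true", "cov_gy", "var_g", "pred_r2"])
    return SimResult(replicates=reps, config=config)


# ---------------------------------------------------------------------------
# End-to-end recovery: boosted pipeline vs unadjusted and oracle scores
# ---------------------------------------------------------------------------

def run_end_to_end_recovery(
    config: SimConfig,
    boost: BoostConfig | None = None,
    miscalibration: float = 1.0 / 3.0,
    strong_fraction: float = 0.5,
    strong_ratio: float = 5.0,
    n_validation: int | None = None,
) -> pd.DataFrame:
    """Full pipeline under deliberately miscalibrated external magnitudes.

    Target effects follow a two-level architecture: a ``strong_fraction`` of
    SNPs carry per-SNP magnitude ``strong_ratio`` times that of the rest
    (random signs, total variance h2). The external study's generative
    effects equal the target effects except that the strong stratum is
    multiplied by ``miscalibration`` (default 1/3: the external consortium
    under-reports the strong effects three-fold). The two strata then occupy
    separated |beta_ext| ranges, so the deviation is a learnable function of
    the boosting input, and repairing it restores the strong stratum's
    weight share. Per replicate the target validation split is scored three
    ways — GraBLD weights, raw external weights, and the oracle weights
    beta/eta — and their prediction R² recorded.

    A Gaussian effect model with the inflation applied to the top-|beta|
    half (``strong_ratio=1`` recovers plain Gaussian effects with a
    magnitude cut) makes the repair unprofitable: amplifying the
    information-rich stratum suppresses its relative estimation noise, and
    undoing the amplification re-weights the score toward the noisy weak
    stratum. The two-level default keeps the experiment about what the trees
    can and should fix.
    """
    boost = boost or BoostConfig()
    rng = np.random.default_rng(config.seed)
    pool = generate_haplotype_pool(config, rng)
    eta_pool = compute_eta(pool.standardized_alleles(), window=config.window).eta
    n_val = n_validation or config.n_target
    h2 = config.h2_grid[0] if len(config.h2_grid) == 1 else 0.3
    m = config.m_snps
    n_strong = max(int(round(strong_fraction * m)), 1)
    rows = []
    for rep in range(config.n_reps):
        # two-level magnitudes scaled so that sum beta_j^2 = h2 exactly
        mag = np.ones(m)
        strong = rng.permutation(m)[:n_strong]
        mag[strong] = strong_ratio
        mag *= np.sqrt(h2 / np.sum(mag**2))
        beta = mag * rng.choice([-1.0, 1.0], m)
        beta_ext_true = beta.copy()
        beta_ext_true[strong] *= miscalibration
        ext = simulate_external_study(
            pool, config.n_external, beta_ext_true, h2, rng, noise_sd=np.sqrt(1.0 - h2)
        )
        # calibration cohort: tune the weights
        Xc, _, _ = _standardize_cols(pool.draw_genotypes(config.n_target, rng))
        yc = simulate_trait(Xc, beta, h2, rng)
        beta_ext = ext.b_star
        beta_obs = compute_beta_obs(Xc, yc)
        active = beta_ext != 0
        d = compute_deviation(beta_obs[active], beta_ext[active])
        folds = assign_folds(config.m_snps, boost.n_folds)
        d_hat = fit_boosted_deviation(np.abs(beta_ext[active]), d, folds[active], boost)
        w_hat = np.zeros(m)
        w_hat[active] = compute_weights(beta_ext[active], d_hat)
        # validation cohort: compare scores
        Xv, _, _ = _standardize_cols(pool.draw_genotypes(n_val, rng))
        yv = simulate_trait(Xv, beta, h2, rng)
        r2_grabld = evaluate_r2(Xv @ apply_ld_correction(w_hat, eta_pool), yv)
        r2_unadjusted = evaluate_r2(Xv @ beta_ext, yv)
        r2_oracle = evaluate_r2(Xv @ apply_ld_correction(beta, eta_pool), yv)
        rows.append((rep, r2_grabld, r2_unadjusted, r2_oracle))
    return pd.DataFrame(rows, columns=["rep", "r2_grabld", "r2_unadjusted", "r2_oracle"])


# ---------------------------------------------------------------------------
# Offline cohort fixtures
# ---------------------------------------------------------------------------

def write_cohort_fixture(outdir, config: SimConfig, h2: float = 0.3):
    """Emit a simulated cohort as PLINK BED/BIM/FAM + phenotype and summary
    TSVs, so the file-based pipeline is testable offline.

    Returns the paths dict and the generating arrays for round-trip checks.
    """
    from pathlib import Path

    from .io import GenotypePanel, write_plink

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    pool = generate_haplotype_pool(config, rng)
    m = config.m_snps
    G = pool.draw_genotypes(config.n_target, rng)
    beta = simulate_effects(m, h2, rng)
    X, _, _ = _standardize_cols(G)
    y = simulate_trait(X, beta, h2, rng)
    ext = simulate_external_study(pool, config.n_external, beta, h2, rng)

    pairs = np.array([("A", "G"), ("T", "C"), ("A", "C"), ("T", "G")])  # non-palindromic
    alleles = pairs[rng.integers(0, len(pairs), m)].T
    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1}" for j in range(m)],
            "chromosome": "1",
            "position": np.arange(1, m + 1) * 1000,
            "allele1": alleles[0],
            "allele2": alleles[1],
        }
    )
    sample_ids = [f"S{i + 1}" for i in range(config.n_target)]
    panel = GenotypePanel(sample_ids, variants, G.astype(np.float32))
    write_plink(panel, outdir / "cohort")
    pd.DataFrame({"sample_id": sample_ids, "trait": y}).to_csv(
        outdir / "phenotype.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "snp_id": variants["snp_id"],
            "chromosome": variants["chromosome"],
            "position": variants["position"],
            "effect_allele": variants["allele1"],
            "other_allele": variants["allele2"],
            "beta": ext.b_star,
            "eaf": pool.freqs,
            "n": config.n_external,
        }
    ).to_csv(outdir / "summary_stats.tsv", sep="\t", index=False)
    paths = {
        "plink": outdir / "cohort",
        "phenotype": outdir / "phenotype.tsv",
        "summary": outdir / "summary_stats.tsv",
    }
    return paths, {"dosage": G, "beta": beta, "b_star": ext.b_star, "trait": y}
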