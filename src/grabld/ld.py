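"""Windowed sum-of-r² LD adjustment of polygenic-score weights.

Each SNP's weight is divided by eta_j, the sum of squared Pearson
correlations between SNP j and every scored SNP within a window of
``window`` SNPs on either side (default 100), on the same chromosome. The
self term r²_jj = 1 is part of the sum, so eta >= 1 and an isolated SNP is
unchanged, while c mutually duplicate SNPs each get eta = c: their corrected
contributions add back up to a single uncorrected SNP.

r² is computed from the calibration-set genotypes supplied as standardized
columns; only SNPs included in the score may be present in the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, ValidationError

#: Column count below which a full Gram matrix beats the per-offset loop.
_FULL_GRAM_MAX = 1500


@dataclass
class EtaVector:
    """Per-SNP windowed r² sums, aligned to score SNP order."""

    eta: np.ndarray
    window: int

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=float)
        if not np.all(np.isfinite(self.eta)):
            raise ValidationError("eta contains non-finite values")

    def __len__(self):
        return len(self.eta)


def _eta_single_chrom(X: np.ndarray, window: int, r2_floor: float) -> np.ndarray:
    n, m = X.shape
    if m <= _FULL_GRAM_MAX:
        G = (X.T @ X) / n
        r2 = G * G
        if window < m:
            idx = np.arange(m)
            r2 = np.where(np.abs(idx[:, None] - idx[None, :]) <= window, r2, 0.0)
        if r2_floor > 0:
            np.fill_diagonal(r2, 1.0)  # self term is never floored
            r2 = np.where(r2 >= r2_floor, r2, 0.0)
        return r2.sum(axis=1)
    eta = np.ones(m)
    for off in range(1, min(window, m - 1) + 1):
        r = np.einsum("ij,ij->j", X[:, :-off], X[:, off:]) / n
        r2 = r * r
        if r2_floor > 0:
            r2 = np.where(r2 >= r2_floor, r2, 0.0)
        eta[: m - off] += r2
        eta[off:] += r2
    return eta


def compute_eta(
    genotypes_std: np.ndarray,
    window: int = 100,
    chromosome_labels: np.ndarray | None = None,
    r2_floor: float = 0.0,
) -> EtaVector:
    """Sum r² between each SNP and its neighbours within ``window`` SNPs.

    Parameters
    ----------
    genotypes_std : ndarray, n x m
        Standardized genotype columns (mean 0, variance 1, population
        convention) for the scored SNPs, in genome order.
    window : int
        SNP-count radius; truncated at chromosome ends. Windows never cross
        chromosome boundaries.
    chromosome_labels : array, optional
        Per-SNP chromosome labels; omitted means a single chromosome.
    r2_floor : float
        Small-sample noise floor: r² values below this threshold are zeroed
        (the self term is exempt). Default 0 — the literal formula.
    """
    if window < 1:
        raise ConfigurationError(f"window must be >= 1, got {window}")
    X = np.asarray(genotypes_std)
    n, m = X.shape
    eta = np.empty(m)
    if chromosome_labels is None:
        eta[:] = _eta_single_chrom(X, window, r2_floor)
    else:
        labels = np.asarray(chromosome_labels)
        if len(labels) != m:
            raise ValidationError("chromosome_labels length does not match columns")
        # contiguous runs of equal labels (input is in genome order)
        boundaries = np.nonzero(labels[1:] != labels[:-1])[0] + 1
        for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, m]):
            eta[lo:hi] = _eta_single_chrom(X[:, lo:hi], window, r2_floor)
    return EtaVector(eta=eta, window=window)


def apply_ld_correction(weights: np.ndarray, eta) -> np.ndarray:
    """Divide weights elementwise by eta: w_tilde_j = w_j / eta_j."""
    w = np.asarray(weights, dtype=float)
    e = eta.eta if isinstance(eta, EtaVector) else np.asarray(eta, dtype=float)
    if w.shape != e.shape:
        raise ValidationError(f"weights shape {w.shape} does not match eta shape {e.shape}")
    return w / e
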