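"""Deviation targets, leakage-free contiguous folds and boosted weight tuning.

External per-SD coefficients beta_ext are adapted to a target cohort by
regressing the signed deviation

    d_j = (beta_obs_j - beta_ext_j) * sign(beta_ext_j)

on SNP annotations (by default the single column |beta_ext|) with gradient
boosted regression trees under squared-error loss. SNPs are split into K
contiguous genome-order blocks; the deviation of every SNP in block f is
predicted by a model trained on the other K-1 blocks, so a SNP's own observed
coefficient never touches its own weight, and LD spillover between train and
test SNPs is confined to the two block edges.

Tuned weights follow w_hat_j = sign(beta_ext_j) * (|beta_ext_j| + d_hat_j):
when the deviation is predicted exactly and directions agree this recovers
the external direction with the target-population magnitude |beta_obs_j|.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor

from .exceptions import ConfigurationError, ValidationError


@dataclass
class BoostConfig:
    """Hyperparameters of the boosted deviation fit.

    Defaults are the reference settings: 2,000 trees of interaction depth 5,
    shrinkage 0.001, bag fraction 0.5, five contiguous folds. ``interaction
    depth`` counts splits per tree (depth d = d+1 leaves, grown best-first).
    ``tree_selection`` picks the effective tree count: ``oob`` takes the
    maximum of the cumulative out-of-bag improvement curve (requires
    bag_fraction < 1), ``inner-cv`` cross-validates the stagewise loss inside
    the training folds, ``fixed`` uses all trees.
    """

    n_trees: int = 2000
    interaction_depth: int = 5
    shrinkage: float = 0.001
    bag_fraction: float = 0.5
    n_folds: int = 5
    tree_selection: str = "oob"
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if not (0 < self.bag_fraction <= 1):
            raise ConfigurationError("bag_fraction must be in (0, 1]")
        if self.shrinkage <= 0:
            raise ConfigurationError("shrinkage must be positive")
        if self.tree_selection not in ("oob", "inner-cv", "fixed"):
            raise ConfigurationError(f"unknown tree_selection {self.tree_selection!r}")
        if self.tree_selection == "oob" and self.bag_fraction >= 1:
            raise ConfigurationError("oob tree selection requires bag_fraction < 1")


def compute_beta_obs(genotypes_std: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Univariate per-SNP coefficients x_j'y/n on standardized data.

    With columns standardized to mean 0 / variance 1 (population convention)
    and a standardized phenotype, this equals the one-predictor least-squares
    slope for each SNP.
    """
    X = np.asarray(genotypes_std)
    y = np.asarray(phenotype, dtype=float)
    if X.shape[0] != len(y):
        raise ValidationError(f"genotypes have {X.shape[0]} rows but phenotype has {len(y)}")
    return (X.T @ y) / len(y)


def compute_deviation(beta_obs: np.ndarray, beta_ext: np.ndarray) -> np.ndarray:
    """Signed deviation of observed from external coefficients.

    d_j = (beta_obs_j - beta_ext_j) * sign(beta_ext_j); equals
    |beta_obs_j| - |beta_ext_j| whenever the two directions agree.
    """
    bo = np.asarray(beta_obs, dtype=float)
    be = np.asarray(beta_ext, dtype=float)
    if bo.shape != be.shape:
        raise ValidationError("beta_obs and beta_ext must have equal length")
    return (bo - be) * np.sign(be)


def assign_folds(m: int, k: int) -> np.ndarray:
    """K contiguous genome-order blocks with sizes differing by at most 1.

    Returns integer labels in 1..k; concatenating the blocks in label order
    recovers the SNPs exactly once. Block boundaries ignore chromosome
    boundaries on purpose: contiguity, not chromosome identity, is what
    prevents LD leakage between train and held-out SNPs.
    """
    if k > m:
        raise ConfigurationError(f"cannot split {m} SNPs into {k} folds")
    labels = np.empty(m, dtype=int)
    for f, idx in enumerate(np.array_split(np.arange(m), k), start=1):
        labels[idx] = f
    return labels


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31 - 1))


def _pick_n_trees(model: GradientBoostingRegressor, Ztr, dtr, config: BoostConfig) -> int:
    if config.tree_selection == "fixed":
        return config.n_trees
    if config.tree_selection == "oob":
        curve = np.cumsum(model.oob_improvement_)
        return int(np.argmax(curve)) + 1
    # inner-cv: 5-fold CV over the stagewise squared-error curve
    rng = np.random.default_rng(_fold_seed(config.seed, 1_000_001))
    perm = rng.permutation(len(dtr))
    losses = np.zeros(config.n_trees)
    for part in np.array_split(perm, 5):
        mask = np.ones(len(dtr), dtype=bool)
        mask[part] = False
        inner = GradientBoostingRegressor(
            loss="squared_error",
            n_estimators=config.n_trees,
            learning_rate=config.shrinkage,
            subsample=config.bag_fraction,
            max_leaf_nodes=config.interaction_depth + 1,
            max_depth=None,
            random_state=_fold_seed(config.seed, 1_000_002),
        ).fit(Ztr[mask], dtr[mask])
        for s, pred in enumerate(inner.staged_predict(Ztr[~mask])):
            losses[s] += np.sum((dtr[~mask] - pred) ** 2)
    return int(np.argmin(losses)) + 1


def fit_boosted_deviation(
    z: np.ndarray,
    d: np.ndarray,
    folds: np.ndarray,
    config: BoostConfig | None = None,
) -> np.ndarray:
    """Out-of-fold boosted predictions d_hat of the deviation target.

    For each fold f a gradient boosted regression-tree model is trained on
    all SNPs outside f (inputs ``z``, target ``d``) and evaluated on the SNPs
    of f, so d_hat_j never depends on d_j. Deterministic given
    ``config.seed``.

    Parameters
    ----------
    z : ndarray, (m,) or (m, p)
        Annotation columns; the default pipeline passes |beta_ext| only.
    d : ndarray, (m,)
        Deviation targets.
    folds : ndarray of int
        Contiguous fold labels from :func:`assign_folds`.
    """
    config = config or BoostConfig()
    Z = np.asarray(z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    d = np.asarray(d, dtype=float)
    folds = np.asarray(folds)
    if not (len(Z) == len(d) == len(folds)):
        raise ValidationError("z, d and folds must have equal length")
    if not np.all(np.isfinite(Z)) or not np.all(np.isfinite(d)):
        raise ValidationError("z and d must be finite")
    d_hat = np.empty_like(d)
    for f in np.unique(folds):
        train = folds != f
        if train.sum() < config.interaction_depth + 1:
            raise ValidationError(
                f"degenerate fit: {train.sum()} training SNPs for interaction depth "
                f"{config.interaction_depth}"
            )
        model = GradientBoostingRegressor(
            loss="squared_error",
            n_estimators=config.n_trees,
            learning_rate=config.shrinkage,
            subsample=config.bag_fraction,
            max_leaf_nodes=config.interaction_depth + 1,
            max_depth=None,
            random_state=_fold_seed(config.seed, int(f)),
        ).fit(Z[train], d[train])
        n_use = _pick_n_trees(model, Z[train], d[train], config)
        if n_use >= config.n_trees:
            d_hat[~train] = model.predict(Z[~train])
        else:
            d_hat[~train] = next(islice(model.staged_predict(Z[~train]), n_use - 1, None))
    return d_hat


def compute_weights(
    beta_ext: np.ndarray,
    d_hat: np.ndarray,
    convention: str = "adapted",
) -> np.ndarray:
    """Tuned signed weights from external betas and predicted deviations.

    ``adapted`` (default): w_hat_j = sign(beta_ext_j) * (|beta_ext_j| +
    d_hat_j) — perfect deviation prediction with agreeing directions yields
    sign(beta_ext_j) * |beta_obs_j|. ``literal`` computes
    (beta_ext_j - d_hat_j) * sign(beta_ext_j) verbatim. SNPs with
    beta_ext = 0 get weight 0 under either convention.
    """
    be = np.asarray(beta_ext, dtype=float)
    dh = np.asarray(d_hat, dtype=float)
    if be.shape != dh.shape:
        raise ValidationError("beta_ext and d_hat must have equal length")
    s = np.sign(be)
    if convention == "adapted":
        return s * (np.abs(be) + dh)
    if convention == "literal":
        return (be - dh) * s
    raise ConfigurationError(f"unknown weight convention {convention!r}")
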