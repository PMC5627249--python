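"""The GraBLD model: boosted weight tuning with windowed LD correction.

Usage follows the fit/results pattern::

    model = GraBLD(study, boost=BoostConfig(seed=7), ld_window=100)
    res = model.fit()
    print(res.summary())
    scores = res.predict(validation_genotypes_std)

``GraBLD.fit`` runs the full weight pipeline on the calibration study:
per-SNP observed coefficients beta_obs = X'y/n, signed deviations d,
contiguous leakage-free folds, out-of-fold boosted deviation predictions
d_hat, tuned weights w_hat, windowed sum-of-r² eta from the calibration
genotypes, and LD-corrected weights w_tilde = w_hat / eta. The results
object carries the full per-SNP audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boost import (
    BoostConfig,
    assign_folds,
    compute_beta_obs,
    compute_deviation,
    compute_weights,
    fit_boosted_deviation,
)
from .exceptions import ValidationError
from .harmonize import HarmonizedStudy
from .ld import EtaVector, apply_ld_correction, compute_eta
from .score import (
    ScoreSet,
    EvalReport,
    calibrate_linear,
    compute_score,
    evaluate,
)

WEIGHT_COLUMNS = ["snp_id", "beta_ext", "beta_obs", "d", "d_hat", "w_hat", "eta", "w_tilde", "fold"]


class GraBLD:
    """Tunes external GWAS summary weights on a harmonized calibration study.

    Parameters
    ----------
    study : HarmonizedStudy
        Calibration cohort with standardized genotypes, aligned external
        betas and a standardized (or 0/1) phenotype.
    boost : BoostConfig, optional
        Boosting hyperparameters (reference defaults when omitted).
    ld_window : int
        SNP-count radius of the eta window.
    annotations : ndarray (m, p), optional
        Extra SNP annotation columns appended to |beta_ext| as boosting
        inputs.
    weight_convention : {"adapted", "literal"}
        Weight composition rule; see :func:`grabld.boost.compute_weights`.
    """

    def __init__(
        self,
        study: HarmonizedStudy,
        boost: BoostConfig | None = None,
        ld_window: int = 100,
        annotations: np.ndarray | None = None,
        weight_convention: str = "adapted",
    ):
        if study.phenotype is None:
            raise ValidationError("calibration study must carry a phenotype")
        self.study = study
        self.boost = boost or BoostConfig()
        self.ld_window = ld_window
        self.annotations = annotations
        self.weight_convention = weight_convention

    def fit(self) -> "GraBLDResults":
        study = self.study
        X, y = study.genotypes_std, study.phenotype
        m = study.n_snps
        beta_ext = np.asarray(study.beta_ext, dtype=float)
        beta_obs = compute_beta_obs(X, y)
        folds = assign_folds(m, self.boost.n_folds)

        # SNPs with beta_ext == 0 carry no external direction: weight 0,
        # excluded from the boosted fit.
        active = beta_ext != 0
        d = np.zeros(m)
        d[active] = compute_deviation(beta_obs[active], beta_ext[active])
        z = np.abs(beta_ext)[:, None]
        if self.annotations is not None:
            z = np.column_stack([z, self.annotations])
        d_hat = np.zeros(m)
        d_hat[active] = fit_boosted_deviation(z[active], d[active], folds[active], self.boost)
        w_hat = np.zeros(m)
        w_hat[active] = compute_weights(beta_ext[active], d_hat[active], self.weight_convention)

        eta = compute_eta(X, window=self.ld_window, chromosome_labels=study.chromosomes)
        w_tilde = apply_ld_correction(w_hat, eta)
        weights = pd.DataFrame(
            {
                "snp_id": study.snp_ids,
                "beta_ext": beta_ext,
                "beta_obs": beta_obs,
                "d": d,
                "d_hat": d_hat,
                "w_hat": w_hat,
                "eta": eta.eta,
                "w_tilde": w_tilde,
                "fold": folds,
            }
        )
        return GraBLDResults(model=self, weights=weights, eta=eta)


@dataclass
class GraBLDResults:
    """Fitted GraBLD weights plus prediction and evaluation helpers."""

    model: GraBLD
    weights: pd.DataFrame  # the WeightTable audit trail
    eta: EtaVector
    calibration: object = field(default=None)  # LinearCalibration after calibrate()

    @property
    def params(self) -> pd.Series:
        """Final LD-corrected weights, indexed by SNP id."""
        return self.weights.set_index("snp_id")["w_tilde"]

    def predict(self, genotypes_std: np.ndarray, sample_ids=None) -> ScoreSet:
        """Polygenic scores for a standardized genotype matrix (SNP-aligned)."""
        return compute_score(genotypes_std, self.weights["w_tilde"].to_numpy(), sample_ids)

    def calibrate(self, genotypes_std, trait, covariates=None) -> "GraBLDResults":
        """Fit the linear recalibration on a training set; returns self."""
        scores = self.predict(genotypes_std)
        self.calibration = calibrate_linear(scores.score, trait, covariates)
        return self

    def evaluate(self, genotypes_std, trait, covariates=None, binary: bool = False) -> EvalReport:
        """Score and evaluate a validation cohort (disjoint from calibration)."""
        scores = self.predict(genotypes_std)
        scores.trait = np.asarray(trait, dtype=float)
        scores.covariates = covariates
        calibrated = None
        if self.calibration is not None:
            calibrated = self.calibration.apply(scores.score, covariates)
        return evaluate(scores, binary=binary, calibrated=calibrated)

    def save_weights(self, path) -> None:
        self.weights[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        """Plain-text fit summary in the statsmodels style."""
        from statsmodels.iolib.table import SimpleTable

        w = self.weights
        b = self.model.boost
        active = w["beta_ext"] != 0
        corr = np.corrcoef(w.loc[active, "beta_ext"], w.loc[active, "w_hat"])[0, 1]
        info = [
            ("No. SNPs", f"{len(w)}"),
            ("No. samples (calibration)", f"{self.model.study.n_samples}"),
            ("Folds (contiguous)", f"{b.n_folds}"),
            ("Trees / depth / shrinkage", f"{b.n_trees} / {b.interaction_depth} / {b.shrinkage}"),
            ("Bag fraction / selection", f"{b.bag_fraction} / {b.tree_selection}"),
            ("LD window (SNPs)", f"{self.eta.window}"),
            ("Weight convention", self.model.weight_convention),
            ("corr(beta_ext, w_hat)", f"{corr:.4f}"),
            ("mean eta", f"{w['eta'].mean():.4f}"),
            ("mean |d_hat|", f"{w['d_hat'].abs().mean():.6f}"),
        ]
        table = SimpleTable(
            [[k, v] for k, v in info],
            headers=["", ""],
            title="GraBLD polygenic score fit",
        )
        return table.as_text()
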