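"""Polygenic score computation, discrimination and calibration metrics.

The score of individual i is g(x_i) = sum_j x_ij * w_tilde_j over the
standardized genotype columns and LD-corrected weights. Discrimination is
measured by the prediction R² — the squared Pearson correlation between
score and trait — for quantitative traits and by the area under the ROC
curve for binary ones. Calibration is assessed by a linear recalibration fit
in a training set, per-decile predicted/observed differences, and, for
binary traits, the Hosmer-Lemeshow chi-squared test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .exceptions import UndefinedMetricError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ScoreSet:
    """Per-sample polygenic scores paired with the observed trait."""

    sample_ids: list
    score: np.ndarray
    trait: np.ndarray | None = None
    covariates: np.ndarray | None = None

    def __post_init__(self):
        self.score = np.asarray(self.score, dtype=float)
        if not np.all(np.isfinite(self.score)):
            raise ValidationError("scores contain non-finite values")
        if self.trait is not None and len(self.trait) != len(self.score):
            raise ValidationError("trait length does not match scores")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "score": self.score})


@dataclass
class EvalReport:
    """Discrimination and calibration summary of a score set."""

    r2: float | None = None
    r2_with_covariates: float | None = None
    auc: float | None = None
    mean_abs_diff: float | None = None
    decile_table: pd.DataFrame | None = None
    hl_statistic: float | None = None
    hl_pvalue: float | None = None
    hl_df: int | None = None
    n: int = 0

    def to_json(self, path=None) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "decile_table"}
        if self.decile_table is not None:
            payload["decile_table"] = self.decile_table.to_dict(orient="records")
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def compute_score(genotypes_std: np.ndarray, w_tilde: np.ndarray, sample_ids=None) -> ScoreSet:
    """g(x_i) = sum_j x_ij * w_tilde_j; linear in the weights."""
    X = np.asarray(genotypes_std)
    w = np.asarray(w_tilde, dtype=float)
    if X.shape[1] != len(w):
        raise ValidationError(f"{X.shape[1]} genotype columns vs {len(w)} weights")
    if sample_ids is None:
        sample_ids = list(range(X.shape[0]))
    return ScoreSet(sample_ids=sample_ids, score=X @ w)


def evaluate_r2(score: np.ndarray, trait: np.ndarray) -> float:
    """Squared Pearson correlation Cov(g,y)² / (Var(g) Var(y))."""
    g = np.asarray(score, dtype=float)
    y = np.asarray(trait, dtype=float)
    if g.shape != y.shape:
        raise ValidationError("score and trait must have equal length")
    if g.var() == 0:
        warnings.warn("score has zero variance; prediction R2 defined as 0")
        return 0.0
    c = np.cov(g, y, ddof=0)
    return float(c[0, 1] ** 2 / (c[0, 0] * c[1, 1]))


def evaluate_r2_with_covariates(score, trait, covariates) -> float:
    """R² of the joint linear model trait ~ score + covariates."""
    design = sm.add_constant(np.column_stack([np.asarray(score, float), np.asarray(covariates, float)]))
    return float(sm.OLS(np.asarray(trait, float), design).fit().rsquared)


def evaluate_auc(score: np.ndarray, labels: np.ndarray) -> float:
    """P(random case outscores random control), ties counted half."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise UndefinedMetricError("AUC undefined: only one class present")
    if not set(classes.astype(float)) <= {0.0, 1.0}:
        raise ValidationError("labels must be 0/1")
    return float(roc_auc_score(y, np.asarray(score, float)))


@dataclass
class LinearCalibration:
    """Least-squares recalibration trait ~ score (+ covariates)."""

    intercept: float
    slope: float
    covariate_coefs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def apply(self, score, covariates=None) -> np.ndarray:
        out = self.intercept + self.slope * np.asarray(score, float)
        if len(self.covariate_coefs):
            if covariates is None:
                raise ValidationError("calibration was fitted with covariates; none supplied")
            C = np.asarray(covariates, float)
            if C.ndim == 1:
                C = C[:, None]
            out = out + C @ self.covariate_coefs
        return out


def calibrate_linear(score, trait, covariates=None) -> LinearCalibration:
    """Fit the recalibration model in a training set (disjoint from evaluation).

    Collinear covariate columns are dropped with a warning before fitting.
    """
    g = np.asarray(score, dtype=float)
    y = np.asarray(trait, dtype=float)
    cols = [np.ones_like(g), g]
    kept_cov = []
    n_cov = 0
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        n_cov = C.shape[1]
        for k in range(n_cov):
            trial = np.column_stack(cols + [C[:, k]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(C[:, k])
                kept_cov.append(k)
            else:
                warnings.warn(f"dropping collinear covariate column {k}")
    design = np.column_stack(cols)
    params = sm.OLS(y, design).fit().params
    coefs = np.zeros(n_cov)
    for i, k in enumerate(kept_cov):
        coefs[k] = params[2 + i]
    return LinearCalibration(intercept=float(params[0]), slope=float(params[1]), covariate_coefs=coefs)


def mean_abs_difference(predicted, observed) -> float:
    """Mean |predicted_i - observed_i| (trait SD units for standardized traits)."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValidationError("predicted and observed must have equal length")
    return float(np.mean(np.abs(p - o)))


def hosmer_lemeshow(observed_events, expected_events, bin_sizes, n_params_df: int = 2):
    """Hosmer-Lemeshow chi-squared statistic over pre-binned counts.

    HL = sum_g (O_g - E_g)² / (E_g (1 - E_g/n_g)), chi² with G - n_params_df
    degrees of freedom (the standard G-2 for 10 bins).
    """
    O = np.asarray(observed_events, dtype=float)
    E = np.asarray(expected_events, dtype=float)
    n = np.asarray(bin_sizes, dtype=float)
    stat = float(np.sum((O - E) ** 2 / (E * (1.0 - E / n))))
    df = max(len(O) - n_params_df, 1)
    return stat, float(sps.chi2.sf(stat, df)), df


def calibration_by_decile(predicted, observed, binary: bool = False, n_bins: int = 10):
    """Per-decile calibration table (plus HL test for binary traits).

    Samples are ranked by predicted value (stable sort, so ties keep input
    order) into ``n_bins`` equal-count bins. Each row reports the bin's mean
    predicted and observed values, their difference, and a normal-
    approximation 95% CI on the difference. In binary mode, bins whose
    expected events are 0 or n_g are merged with a neighbour (logged) before
    the HL statistic is computed on G-2 degrees of freedom.

    Returns ``(table,)`` or ``(table, hl_statistic, hl_pvalue, hl_df)``.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValidationError("predicted and observed must have equal length")
    if len(p) < n_bins:
        raise ValidationError(f"need at least {n_bins} samples for {n_bins} bins")
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    for b, idx in enumerate(bins, start=1):
        diff = o[idx] - p[idx]
        if binary:
            obar = o[idx].mean()
            se = np.sqrt(max(obar * (1 - obar), 0.0) / len(idx))
        else:
            se = diff.std(ddof=1) / np.sqrt(len(idx)) if len(idx) > 1 else 0.0
        rows.append(
            {
                "decile": b,
                "n": len(idx),
                "mean_predicted": p[idx].mean(),
                "mean_observed": o[idx].mean(),
                "difference": diff.mean(),
                "ci_low": diff.mean() - 1.96 * se,
                "ci_high": diff.mean() + 1.96 * se,
            }
        )
    table = pd.DataFrame(rows)
    if not binary:
        return (table,)
    # merge degenerate bins for the HL statistic
    groups = [[idx] for idx in bins]
    merged = True
    while merged and len(groups) > 1:
        merged = False
        for i, grp in enumerate(groups):
            idx = np.concatenate(grp)
            E = p[idx].sum()
            if E <= 0 or E >= len(idx):
                j = i - 1 if i > 0 else i + 1
                logger.info("calibration_by_decile: merging degenerate bin %d into neighbour", i + 1)
                groups[j] = groups[j] + grp
                del groups[i]
                merged = True
                break
    O = [o[np.concatenate(g)].sum() for g in groups]
    E = [p[np.concatenate(g)].sum() for g in groups]
    ng = [len(np.concatenate(g)) for g in groups]
    stat, pval, df = hosmer_lemeshow(O, E, ng)
    return table, stat, pval, df


def evaluate(scores: ScoreSet, binary: bool = False, calibrated: np.ndarray | None = None) -> EvalReport:
    """Bundle discrimination and calibration metrics into an :class:`EvalReport`.

    ``calibrated`` supplies recalibrated predictions (from a training-set
    :func:`calibrate_linear` fit) for the calibration metrics; the raw score
    is used when omitted.
    """
    if scores.trait is None:
        raise ValidationError("score set has no observed trait")
    y = np.asarray(scores.trait, dtype=float)
    pred = scores.score if calibrated is None else np.asarray(calibrated, dtype=float)
    report = EvalReport(n=len(y))
    if binary:
        report.auc = evaluate_auc(scores.score, y)
        table, stat, pval, df = calibration_by_decile(pred, y, binary=True)
        report.decile_table, report.hl_statistic, report.hl_pvalue, report.hl_df = table, stat, pval, df
    else:
        report.r2 = evaluate_r2(scores.score, y)
        if scores.covariates is not None:
            report.r2_with_covariates = evaluate_r2_with_covariates(scores.score, y, scores.covariates)
        report.mean_abs_diff = mean_abs_difference(pred, y)
        (report.decile_table,) = calibration_by_decile(pred, y, binary=False)
    return report


def r2_by_snp_fraction(
    genotypes_std,
    weights,
    trait,
    order_by,
    fractions=(0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0),
    binary: bool = False,
):
    """Discrimination as a function of the top SNP fraction.

    SNPs are ranked by ``order_by`` (descending, e.g. |beta_ext| so the
    strongest external associations enter first); for each fraction the
    score is rebuilt from the top subset only and its prediction R² (or AUC
    in binary mode) recorded.
    """
    X = np.asarray(genotypes_std)
    w = np.asarray(weights, dtype=float)
    rank = np.argsort(-np.asarray(order_by, dtype=float), kind="stable")
    rows = []
    for frac in fractions:
        k = max(int(round(frac * len(w))), 1)
        top = rank[:k]
        g = X[:, top] @ w[top]
        value = evaluate_auc(g, trait) if binary else evaluate_r2(g, trait)
        rows.append({"fraction": frac, "n_snps": k, ("auc" if binary else "r2"): value})
    return pd.DataFrame(rows)


def plot_r2_by_snp_fraction(table: pd.DataFrame, path=None):
    """Line plot of the discrimination-vs-SNP-fraction curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metric = "auc" if "auc" in table.columns else "r2"
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(table["fraction"], table[metric], marker="o")
    ax.set_xlabel("fraction of top SNPs in score")
    ax.set_ylabel("AUC" if metric == "auc" else "prediction $R^2$")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_calibration(table: pd.DataFrame, path=None):
    """Decile calibration plot (difference vs mean predicted, with CIs)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        table["mean_predicted"],
        table["difference"],
        yerr=[table["difference"] - table["ci_low"], table["ci_high"] - table["difference"]],
        fmt="o", capsize=3,
    )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("mean predicted trait (decile)")
    ax.set_ylabel("observed - predicted")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
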