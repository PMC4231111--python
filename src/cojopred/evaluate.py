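"""Prediction performance and variance explained for case-control GRS models.

Covers the validation arm of a conditional/joint GWAS analysis: logistic
models of disease on age, sex and a genetic risk score; AUC with the DeLong
paired test for correlated ROC curves; Nagelkerke's pseudo-R²; AIC; and
per-SNP variance explained on the liability scale from odds ratios, allele
frequencies and disease prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


class SeparationError(RuntimeError):
    """Perfect separation: a coefficient diverges; penalization advised."""


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    params: np.ndarray  # intercept first
    llf: float
    fitted: np.ndarray
    se: np.ndarray
    converged: bool
    nobs: int

    @property
    def k_params(self) -> int:
        return len(self.params)

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def aic(self) -> float:
        return aic(self.llf, self.k_params)


def fit_logistic(y, X=None, max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    ``X`` is the covariate matrix WITHOUT intercept (one is prepended);
    ``X=None`` fits intercept-only. Converges when the max coefficient
    change is below ``tol``. A coefficient exceeding 15 on the standardized
    scale triggers :class:`SeparationError`.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise EvaluationError("status must be 0/1")
    if y.min() == y.max():
        raise EvaluationError("both outcome classes must be present")
    n = len(y)
    if X is None:
        Xd = np.ones((n, 1))
        sds = np.array([1.0])
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        sds = X.std(axis=0)
        if (sds == 0).any():
            raise EvaluationError("constant covariate (other than intercept)")
        Xd = np.column_stack([np.ones(n), X])
        sds = np.concatenate([[1.0], sds])

    beta = np.zeros(Xd.shape[1])
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    converged = False
    for _ in range(max_iter):
        eta = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-12, None)
        grad = Xd.T @ (y - p)
        hess = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix; consider penalized regression"
            ) from None
        beta = beta + step
        if len(beta) > 1 and np.max(np.abs(beta[1:] * sds[1:])) > 15:
            raise SeparationError(
                "diverging coefficient (>15 SD-scaled): data may be perfectly "
                "separated; consider penalized regression"
            )
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = Xd @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    w = np.clip(p * (1 - p), 1e-12, None)
    cov = np.linalg.inv((Xd * w[:, None]).T @ Xd)
    return LogisticFit(beta, llf, p, np.sqrt(np.diag(cov)), converged, n)


# ---------------------------------------------------------------------------
# AUC and DeLong
# ---------------------------------------------------------------------------

def auc(scores, status) -> float:
    """Mann–Whitney AUC: fraction of (case, control) pairs where the case
    scores higher, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status)
    n1 = int((status == 1).sum())
    n0 = int((status == 0).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both classes required for AUC")
    ranks = sps.rankdata(scores)
    return float((ranks[status == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placements(scores, status):
    """DeLong structural components (midrank formulation).

    Returns (auc, V10 per case, V01 per control).
    """
    scores = np.asarray(scores, dtype=float)
    cases = scores[status == 1]
    controls = scores[status == 0]
    m, n = len(cases), len(controls)
    all_r = sps.rankdata(np.concatenate([cases, controls]))
    r_cases = sps.rankdata(cases)
    r_controls = sps.rankdata(controls)
    a = float((all_r[:m].sum() - m * (m + 1) / 2) / (m * n))
    v10 = (all_r[:m] - r_cases) / n  # per-case placement
    v01 = 1.0 - (all_r[m:] - r_controls) / m  # per-control placement
    return a, v10, v01


def delong_compare(scores_a, scores_b, status) -> tuple[float, float, float]:
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns (delta_auc = AUC_A − AUC_B, z, two-sided p). Identical score
    rankings give zero difference variance and p = 1 (flagged via log).
    """
    status = np.asarray(status)
    if len(np.unique(status)) < 2:
        raise EvaluationError("both classes required")
    a_a, v10_a, v01_a = _placements(scores_a, status)
    a_b, v10_b, v01_b = _placements(scores_b, status)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))  # 2x2, ddof=1
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = a_a - a_b
    if var <= 0:
        logger.warning("zero variance of AUC difference (identical rankings)")
        return delta, 0.0, 1.0
    z = delta / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(delta), float(z), float(p)


# ---------------------------------------------------------------------------
# pseudo-R2 and AIC
# ---------------------------------------------------------------------------

def nagelkerke(model_ll: float, null_ll: float, n: int) -> float:
    """Nagelkerke's R² = (1 − exp(2(L0 − L1)/n)) / (1 − exp(2 L0 / n))."""
    if model_ll < null_ll - 1e-9:
        raise EvaluationError("model log-likelihood below null: models not nested?")
    cox_snell = 1.0 - np.exp(2.0 * (null_ll - model_ll) / n)
    max_cs = 1.0 - np.exp(2.0 * null_ll / n)
    return float(cox_snell / max_cs)


def aic(model_ll: float, k_params: int) -> float:
    """Akaike information criterion, 2k − 2·logL (k includes the intercept)."""
    return 2.0 * k_params - 2.0 * model_ll


# ---------------------------------------------------------------------------
# liability-scale variance explained
# ---------------------------------------------------------------------------

def liability_variance_snp(odds_ratio: float, freq: float, prevalence: float = 0.10) -> float:
    """Liability-scale variance explained by one biallelic SNP.

    Under HWE genotype frequencies (q², 2pq, p²) for risk-allele frequency p
    and multiplicative per-allele odds (1, OR, OR²), solve for the baseline
    odds o₀ giving population prevalence K, map the genotype penetrances to
    liability means μ_g = T − Φ⁻¹(1 − π_g) with threshold T = Φ⁻¹(1 − K),
    and return Var(μ) / (1 + Var(μ)).
    """
    K = prevalence
    if not 0 < K < 1:
        raise EvaluationError("prevalence must be in (0,1)")
    if odds_ratio <= 0:
        raise EvaluationError("odds ratio must be positive")
    p = float(freq)
    if not 0 < p < 1:
        raise EvaluationError("frequency must be in (0,1)")
    if odds_ratio == 1.0:
        return 0.0
    fg = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    org = odds_ratio ** np.arange(3)

    def prev_minus_k(log_o0):
        o = np.exp(log_o0) * org
        return float(fg @ (o / (1 + o))) - K

    lo, hi = np.log(1e-12), np.log(1e12)
    assert prev_minus_k(lo) < 0 < prev_minus_k(hi), "no root for baseline odds"
    log_o0 = optimize.brentq(prev_minus_k, lo, hi, xtol=1e-14)
    pen = np.exp(log_o0) * org / (1 + np.exp(log_o0) * org)
    T = sps.norm.ppf(1 - K)
    mu = T - sps.norm.ppf(1 - pen)
    mu_bar = float(fg @ mu)
    vg = float(fg @ (mu - mu_bar) ** 2)
    return vg / (1.0 + vg)


def liability_variance_set(entries, prevalence: float = 0.10) -> float:
    """Total liability variance of a SNP collection: sum of per-SNP values
    (independence assumption), capped at 1 with a warning."""
    total = 0.0
    for odds_ratio, freq in entries:
        total += liability_variance_snp(odds_ratio, freq, prevalence)
    if total > 1.0:
        logger.warning("summed liability variance %.3f exceeds 1; capped", total)
        total = 1.0
    return total


# ---------------------------------------------------------------------------
# model-comparison report
# ---------------------------------------------------------------------------

def prediction_report(
    pheno: pd.DataFrame,
    grs_columns: dict[str, np.ndarray],
    liability: dict[str, list[tuple[float, float]]] | None = None,
    prevalence: float = 0.10,
) -> dict:
    """Fit baseline (age+sex) and baseline+GRS logistic models and compare.

    ``pheno`` needs columns status, age, sex. ``grs_columns`` maps a model
    label to a per-sample score vector; ``liability`` optionally maps the
    same labels to [(odds_ratio, freq), ...] for liability-scale variance.

    Returns a dict with ``models`` (DataFrame: label, auc, nagelkerke_r2,
    aic, liability_variance) and ``pairs`` (DataFrame: label_a, label_b,
    delta_auc, delong_z, delong_p), the PredictionReport structure.
    """
    y = pheno["status"].to_numpy(float)
    base_X = pheno[["age", "sex"]].to_numpy(float)
    null_fit = fit_logistic(y)
    base_fit = fit_logistic(y, base_X)
    rows = [
        {
            "label": "baseline",
            "auc": auc(base_fit.fitted, y),
            "nagelkerke_r2": nagelkerke(base_fit.llf, null_fit.llf, base_fit.nobs),
            "aic": base_fit.aic,
            "liability_variance": np.nan,
        }
    ]
    fitted = {"baseline": base_fit.fitted}
    for label, g in grs_columns.items():
        fit = fit_logistic(y, np.column_stack([base_X, np.asarray(g, float)]))
        fitted[label] = fit.fitted
        lv = np.nan
        if liability and label in liability:
            lv = liability_variance_set(liability[label], prevalence)
        rows.append(
            {
                "label": label,
                "auc": auc(fit.fitted, y),
                "nagelkerke_r2": nagelkerke(fit.llf, null_fit.llf, fit.nobs),
                "aic": fit.aic,
                "liability_variance": lv,
            }
        )
    labels = list(fitted)
    pair_rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            delta, z, p = delong_compare(fitted[labels[j]], fitted[labels[i]], y)
            pair_rows.append(
                {
                    "label_a": labels[j],
                    "label_b": labels[i],
                    "delta_auc": delta,
                    "delong_z": z,
                    "delong_p": p,
                }
            )
    return {
        "models": pd.DataFrame(rows),
        "pairs": pd.DataFrame(
            pair_rows, columns=["label_a", "label_b", "delta_auc", "delong_z", "delong_p"]
        ),
    }
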