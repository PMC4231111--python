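"""Approximate conditional/joint (C/J) estimation from GWAS summary statistics.

Individual-level multiple regression of a phenotype on a set of SNPs needs
the cross-product matrix X'X and X'y. Neither is available from a
meta-analysis, but both can be reconstructed from per-SNP marginal effects
(b_j), standard errors (s_j), effect-allele frequencies (p_j), sample sizes
(n_j) and an LD correlation matrix r estimated in a reference panel of the
same ancestry:

    v_j       = 2 p_j (1 - p_j)                (HWE dosage variance)
    D_jj      = n_j v_j                        (diagonal of X'X)
    (X'X)_jk  = r_jk sqrt(v_j v_k) min(n_j, n_k)
    (X'y)_j   = D_jj b_j
    y'y_j     = D_jj b_j^2 + D_jj s_j^2 (n_j - 1)

Joint coefficients solve X'X β = X'y; their standard errors use the residual
variance σ² = (y'y − β'X'y) / (df − |S|), with y'y taken as the median of the
per-SNP reconstructions (robust to mis-specified n) and df the median n over
the selected SNPs. Conditional statistics for a candidate SNP are its
coefficient in the joint fit over {model ∪ candidate}. Stepwise selection
alternates adding the best conditional SNP with joint refits and backward
elimination, mirroring the summary-based model-selection scheme used to
dissect allelic heterogeneity at GWAS loci.

The model/results API follows the statsmodels convention:

>>> model = JointGwas(stats, ld)                       # doctest: +SKIP
>>> res = model.fit(["rs1", "rs2"])                    # joint fit of a set
>>> res, trace = model.select(p_threshold=5e-8)        # stepwise selection
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ldpanel import LDView

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (5e-8, 5e-7, 5e-6, 5e-5, 5e-4)


class CojoError(RuntimeError):
    pass


class CollinearityError(CojoError):
    def __init__(self, snp_pair):
        self.snp_pair = snp_pair
        super().__init__(
            f"X'X not positive definite; most collinear pair: {snp_pair[0]}, {snp_pair[1]}"
        )


def estimate_ypy(stats: pd.DataFrame, var: np.ndarray | None = None):
    """Reconstruct the phenotype sum of squares y'y from marginal statistics.

    Per SNP j: ypy_j = D_jj b_j² + D_jj s_j² (n_j − 1) with D_jj = n_j v_j.
    Returns (median over SNPs, per-SNP array). ``var`` overrides the HWE
    variance 2p(1−p) when the actual dosage variance is known.
    """
    if len(stats) == 0:
        raise CojoError("no SNPs for y'y estimation")
    b = stats["b"].to_numpy(float)
    s = stats["se"].to_numpy(float)
    n = stats["n"].to_numpy(float)
    p = stats["freq"].to_numpy(float)
    v = 2 * p * (1 - p) if var is None else np.asarray(var, dtype=float)
    d = n * v
    per_snp = d * b**2 + d * s**2 * (n - 1)
    return float(np.median(per_snp)), per_snp


@dataclass
class JointGwasResults:
    """Joint-fit results for a selected SNP set.

    Attributes mirror a fitted regression: ``beta_joint`` (bJ), ``se_joint``
    (bJ_se), ``p_joint`` (pJ, two-sided normal Wald), the residual-variance
    estimate ``sigma2``, the working ``ypy``, the degrees-of-freedom sample
    size ``n_model`` and the reconstructed ``xtx`` kept for diagnostics.
    """

    snp_ids: list[str]
    beta_joint: np.ndarray
    se_joint: np.ndarray
    p_joint: np.ndarray
    sigma2: float
    ypy: float
    n_model: float
    xtx: np.ndarray
    sigma2_floored: bool = False
    converged: bool = True

    def __len__(self):
        return len(self.snp_ids)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "bJ": self.beta_joint,
                "bJ_se": self.se_joint,
                "pJ": self.p_joint,
            }
        )

    def __repr__(self):
        k = len(self.snp_ids)
        return f"<JointGwasResults: {k} SNP{'s' if k != 1 else ''}, sigma2={self.sigma2:.4g}>"


@dataclass
class TraceEvent:
    iteration: int
    action: str  # add | drop | skip-collinear | stop
    snp: str | None
    p: float | None


@dataclass
class StepwiseTrace:
    events: list[TraceEvent] = field(default_factory=list)

    def record(self, iteration, action, snp=None, p=None):
        self.events.append(TraceEvent(iteration, action, snp, p))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.iteration, e.action, e.snp, e.p) for e in self.events],
            columns=["iteration", "action", "snp", "p"],
        )

    def final_model(self) -> list[str]:
        model: list[str] = []
        for e in self.events:
            if e.action == "add":
                model.append(e.snp)
            elif e.action == "drop":
                model.remove(e.snp)
        return model


class JointGwas:
    """Summary-statistic joint association model for one genomic region.

    Parameters
    ----------
    stats : DataFrame
        Marginal summary statistics (see :mod:`cojopred.sumstats`), one row
        per SNP, already harmonized so that ``b`` refers to the same allele
        the LD matrix is oriented to.
    ld : LDView
        Effect-allele-oriented correlation matrix covering the SNPs.
    freq : array, optional
        Effect-allele frequencies used for the dosage variance; defaults to
        the ``freq`` column of ``stats`` (normally the reference-panel
        frequency after harmonization).
    var : array, optional
        Per-SNP dosage variance. Overrides 2p(1−p); supplying the variance
        measured on the same sample as the marginal statistics makes the
        reconstruction exact for a quantitative trait.
    ypy : float, optional
        Phenotype sum of squares; estimated via :func:`estimate_ypy` when
        omitted.
    """

    def __init__(self, stats: pd.DataFrame, ld: LDView, freq=None, var=None, ypy=None):
        stats = stats.reset_index(drop=True)
        self.stats = stats
        self.snp_ids = stats["snp"].astype(str).tolist()
        if set(self.snp_ids) - set(map(str, ld.snp_ids)):
            raise CojoError("LD matrix does not cover all SNPs in stats")
        self.ld = ld.subset(self.snp_ids)
        p = stats["freq"].to_numpy(float) if freq is None else np.asarray(freq, float)
        self.var = 2 * p * (1 - p) if var is None else np.asarray(var, float)
        self.n = stats["n"].to_numpy(float)
        self.b = stats["b"].to_numpy(float)
        self.se = stats["se"].to_numpy(float)
        self.pmarg = stats["p"].to_numpy(float)
        self.diag = self.n * self.var
        self.ypy = estimate_ypy(stats, var=self.var)[0] if ypy is None else float(ypy)
        self._pos = {s: i for i, s in enumerate(self.snp_ids)}

    # -- linear algebra ----------------------------------------------------

    def _xtx(self, idx: np.ndarray) -> np.ndarray:
        v = self.var[idx]
        n = self.n[idx]
        r = self.ld.r[np.ix_(idx, idx)]
        nmin = np.minimum.outer(n, n)
        xtx = r * np.sqrt(np.outer(v, v)) * nmin
        np.fill_diagonal(xtx, self.diag[idx])
        return xtx

    def fit(self, snp_ids=None) -> JointGwasResults:
        """Joint fit of a SNP set: solve X'X β = X'y and derive Wald stats.

        Raises :class:`CollinearityError` when X'X is not positive definite,
        naming the most collinear SNP pair.
        """
        ids = self.snp_ids if snp_ids is None else [str(s) for s in snp_ids]
        if len(ids) == 0:
            raise CojoError("cannot fit an empty SNP set")
        idx = np.array([self._pos[s] for s in ids])
        xtx = self._xtx(idx)
        xty = self.diag[idx] * self.b[idx]
        try:
            chol = np.linalg.cholesky(xtx)
        except np.linalg.LinAlgError:
            raise CollinearityError(self._most_collinear(idx)) from None
        # Cholesky can numerically succeed on a singular matrix; guard on the
        # smallest pivot relative to the scale of X'X
        if np.min(np.diag(chol)) ** 2 <= 1e-8 * np.max(np.diag(xtx)):
            raise CollinearityError(self._most_collinear(idx))
        beta = _chol_solve(chol, xty)
        xtx_inv = _chol_inv(chol)
        k = len(ids)
        n_dof = float(np.median(self.n[idx]))
        sigma2 = (self.ypy - float(beta @ xty)) / (n_dof - k)
        floored = False
        if sigma2 <= 0:
            logger.warning("non-positive sigma2 (%.3g); falling back to ypy/n", sigma2)
            sigma2 = self.ypy / n_dof
            floored = True
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        z = beta / se
        pj = 2 * sps.norm.sf(np.abs(z))
        pj = np.clip(pj, np.nextafter(0, 1), 1.0)
        return JointGwasResults(ids, beta, se, pj, sigma2, self.ypy, n_dof, xtx, floored)

    def _most_collinear(self, idx) -> tuple[str, str]:
        r = self.ld.r[np.ix_(idx, idx)].copy()
        np.fill_diagonal(r, 0.0)
        j, k = np.unravel_index(np.argmax(np.abs(r)), r.shape)
        return (self.snp_ids[idx[j]], self.snp_ids[idx[k]])

    def conditional(self, model_snps, candidate) -> tuple[float, float, float]:
        """Candidate's effect adjusted for the current model.

        The candidate's coefficient, SE and Wald p in a joint fit over
        ``model_snps ∪ {candidate}`` (model coefficients are re-estimated).
        With no model SNPs this degenerates to the joint (≈ marginal) fit of
        the candidate alone.
        """
        candidate = str(candidate)
        model_snps = [str(s) for s in model_snps]
        if candidate in model_snps:
            raise CojoError("candidate already in model")
        res = self.fit(model_snps + [candidate])
        return float(res.beta_joint[-1]), float(res.se_joint[-1]), float(res.p_joint[-1])

    # -- stepwise selection -------------------------------------------------

    def _order_key(self, snp: str):
        i = self._pos[snp]
        bp = self.stats["bp"].iloc[i] if "bp" in self.stats.columns else 0
        return (bp, snp)

    def select(
        self,
        p_threshold: float,
        r2_collinear: float = 0.9,
        max_iter: int = 100,
    ) -> tuple[JointGwasResults | None, StepwiseTrace]:
        """Stepwise C/J model selection.

        Seeds with the minimum-marginal-p SNP (if below threshold), then
        alternates: add the candidate with the best conditional p (among
        candidates whose max r² with the model is ≤ ``r2_collinear``), refit
        jointly, and backward-eliminate model SNPs whose joint p exceeds the
        threshold (worst first, one per refit). Deterministic: ties are
        broken by (p, bp, snp id).

        Returns (results or None for an empty model, trace). A model hitting
        ``max_iter`` is returned with ``converged=False``.
        """
        trace = StepwiseTrace()
        order = sorted(
            range(len(self.snp_ids)),
            key=lambda i: (self.pmarg[i], *self._order_key(self.snp_ids[i])),
        )
        seed = order[0]
        if self.pmarg[seed] >= p_threshold:
            trace.record(0, "stop", None, None)
            return None, trace
        model = [self.snp_ids[seed]]
        trace.record(0, "add", self.snp_ids[seed], float(self.pmarg[seed]))

        skipped_logged: set[str] = set()
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            changed = False
            # --- forward step
            midx = np.array([self._pos[s] for s in model])
            best = None
            for s in self.snp_ids:
                if s in model:
                    continue
                i = self._pos[s]
                r2 = float(np.max(self.ld.r[i, midx] ** 2)) if len(midx) else 0.0
                if r2 > r2_collinear:
                    if s not in skipped_logged:
                        trace.record(it, "skip-collinear", s, None)
                        skipped_logged.add(s)
                    continue
                try:
                    _, _, p_c = self.conditional(model, s)
                except CollinearityError:
                    if s not in skipped_logged:
                        trace.record(it, "skip-collinear", s, None)
                        skipped_logged.add(s)
                    continue
                key = (p_c, *self._order_key(s))
                if best is None or key < best[0]:
                    best = (key, s, p_c)
            if best is not None and best[2] < p_threshold:
                model.append(best[1])
                trace.record(it, "add", best[1], best[2])
                changed = True
            # --- backward elimination, worst first, one per refit
            while len(model) > 0:
                res = self.fit(model)
                worst = int(np.argmax(res.p_joint))
                if res.p_joint[worst] <= p_threshold:
                    break
                snp = model[worst]
                trace.record(it, "drop", snp, float(res.p_joint[worst]))
                model.remove(snp)
                changed = True
            if not model:
                trace.record(it, "stop", None, None)
                return None, trace
            if not changed:
                converged = True
                break
        trace.record(it, "stop", None, None)
        res = self.fit(model)
        res.converged = converged
        if not converged:
            logger.warning("stepwise selection hit max_iter=%d", max_iter)
        return res, trace


def thresholds_sweep(
    model: JointGwas,
    thresholds=DEFAULT_THRESHOLDS,
    r2_collinear: float = 0.9,
    max_iter: int = 100,
) -> dict[float, tuple[JointGwasResults | None, StepwiseTrace]]:
    """Run stepwise selection once per p-value threshold.

    Models at stricter thresholds need not nest within looser ones.
    """
    return {
        float(t): model.select(float(t), r2_collinear=r2_collinear, max_iter=max_iter)
        for t in thresholds
    }


def _chol_solve(chol: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    y = solve_triangular(chol, rhs, lower=True)
    return solve_triangular(chol.T, y, lower=False)


def _chol_inv(chol: np.ndarray) -> np.ndarray:
    inv_l = np.linalg.inv(chol)
    return inv_l.T @ inv_l
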