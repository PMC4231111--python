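"""Synthetic cohorts with known truth for summary-based C/J analysis.

Genotypes are simulated with a Gaussian copula: each haplotype is a latent
multivariate normal draw thresholded at Φ⁻¹(1 − p_j), so the allele-indicator
(and genotype) frequencies hit their targets and the LD structure is
controlled directly on the latent scale. Since correlation is attenuated by
dichotomization, target correlations for specific pairs should be set on the
GENOTYPE scale via :func:`latent_from_genotype_corr` and verified with
:func:`genotype_corr_from_latent`.

Disease status follows a liability-threshold model: standardized genotypes,
age and sex contribute to a unit-variance liability; individuals above
Φ⁻¹(1 − K) are cases (prevalence K, default 10%).

Marginal summary statistics come from per-SNP logistic regressions on the
GWAS cohort, yielding exactly the fields a ``.ma`` file carries. Reference,
GWAS and validation cohorts are always drawn independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .ldpanel import GenotypePanel


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# copula calibration
# ---------------------------------------------------------------------------

def _bvn_upper(t1: float, t2: float, rho: float) -> float:
    """P(Z1 > t1, Z2 > t2) for standard bivariate normal with correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(sps.multivariate_normal(mean=[0, 0], cov=cov).cdf([-t1, -t2]))


def genotype_corr_from_latent(rho: float, p1: float, p2: float) -> float:
    """Genotype-scale Pearson correlation induced by latent correlation rho.

    Haplotype indicators x_j = 1{Z_j > Φ⁻¹(1−p_j)}; genotypes sum two
    independent haplotypes, so the genotype correlation equals the indicator
    correlation.
    """
    t1, t2 = sps.norm.ppf(1 - p1), sps.norm.ppf(1 - p2)
    p11 = _bvn_upper(t1, t2, rho)
    cov = p11 - p1 * p2
    return cov / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def latent_from_genotype_corr(target_r: float, p1: float, p2: float) -> float:
    """Latent correlation achieving a target genotype correlation.

    Raises :class:`SimulationError` when the target exceeds the Fréchet
    bound for the given allele frequencies.
    """
    lo = genotype_corr_from_latent(-0.9999, p1, p2)
    hi = genotype_corr_from_latent(0.9999, p1, p2)
    if not lo <= target_r <= hi:
        raise SimulationError(
            f"genotype correlation {target_r} unattainable at freqs "
            f"({p1}, {p2}); feasible range [{lo:.3f}, {hi:.3f}]"
        )
    return float(
        optimize.brentq(
            lambda rho: genotype_corr_from_latent(rho, p1, p2) - target_r,
            -0.9999,
            0.9999,
            xtol=1e-10,
        )
    )


# ---------------------------------------------------------------------------
# scenario
# ---------------------------------------------------------------------------

@dataclass
class SimScenario:
    """Generative truth for one locus region.

    ``causal`` lists (snp index, standardized liability effect); ``freqs``
    are risk/effect (counted) allele frequencies; ``ld_latent`` is the
    latent-scale correlation matrix (must be positive definite).
    """

    freqs: np.ndarray
    ld_latent: np.ndarray
    causal: list[tuple[int, float]]
    seed: int
    n_ref: int = 6_000
    n_gwas: int = 50_000
    n_val: int = 2_000
    prevalence: float = 0.10
    gamma_age: float = 0.15
    gamma_sex: float = 0.10
    age_range: tuple[float, float] = (45.0, 84.0)
    chrom: str = "1"
    bp_start: int = 10_000_000
    bp_step: int = 20_000
    label: str = "scenario"
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.ld_latent = np.asarray(self.ld_latent, dtype=float)
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if not (0 < self.prevalence < 1):
            raise SimulationError("prevalence must be in (0,1)")
        if self.ld_latent.shape != (self.m_snps, self.m_snps):
            raise SimulationError("ld_latent shape mismatch")
        try:
            np.linalg.cholesky(self.ld_latent)
        except np.linalg.LinAlgError:
            raise SimulationError("latent correlation matrix not positive definite") from None
        for idx, _ in self.causal:
            if not 0 <= idx < self.m_snps:
                raise SimulationError(f"causal index {idx} out of range")

    @property
    def m_snps(self) -> int:
        return len(self.freqs)

    def variants(self) -> pd.DataFrame:
        m = self.m_snps
        return pd.DataFrame(
            {
                "snp": [f"snp{j:04d}" for j in range(m)],
                "chrom": self.chrom,
                "bp": self.bp_start + self.bp_step * np.arange(m),
                "a1": "A",
                "a2": "G",  # counted (risk/effect) allele
            }
        )

    def genotype_corr(self, j: int, k: int) -> float:
        """Analytic genotype-scale correlation between SNPs j and k."""
        if j == k:
            return 1.0
        return genotype_corr_from_latent(self.ld_latent[j, k], self.freqs[j], self.freqs[k])


@dataclass
class SimOutput:
    scenario: SimScenario
    ref_panel: GenotypePanel
    gwas_panel: GenotypePanel
    gwas_pheno: pd.DataFrame
    val_panel: GenotypePanel
    val_pheno: pd.DataFrame
    sumstats: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_panel(scenario: SimScenario, n: int, rng: np.random.Generator) -> GenotypePanel:
    """Draw n diploid individuals: two independent copula haplotypes each."""
    m = scenario.m_snps
    chol = np.linalg.cholesky(scenario.ld_latent)
    thresh = sps.norm.ppf(1 - scenario.freqs)
    geno = np.zeros((n, m))
    for _ in range(2):
        z = rng.standard_normal((n, m)) @ chol.T
        geno += (z > thresh[None, :]).astype(float)
    return GenotypePanel(
        [f"id{i:06d}" for i in range(n)], scenario.variants(), geno, hard_called=True
    )


def _liability_components(scenario: SimScenario, panel: GenotypePanel, rng):
    n = panel.n_samples
    lo, hi = scenario.age_range
    age = rng.uniform(lo, hi, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    age_sd = (hi - lo) / np.sqrt(12.0)
    age_std = (age - (lo + hi) / 2) / age_sd

    g_term = np.zeros(n)
    var_g = 0.0
    for (j, bj) in scenario.causal:
        p = scenario.freqs[j]
        sd = np.sqrt(2 * p * (1 - p))
        g_term += bj * (panel.dosage[:, j] - 2 * p) / sd
    for (j, bj) in scenario.causal:
        for (k, bk) in scenario.causal:
            var_g += bj * bk * scenario.genotype_corr(j, k)

    var_fixed = var_g + scenario.gamma_age**2 + scenario.gamma_sex**2 * 0.25
    if var_fixed >= 1.0:
        raise SimulationError(f"explained liability variance {var_fixed:.3f} >= 1")
    eps = rng.standard_normal(n) * np.sqrt(1.0 - var_fixed)
    liability = g_term + scenario.gamma_age * age_std + scenario.gamma_sex * sex + eps
    # center the sex contribution so the threshold sits at the right quantile
    liability -= scenario.gamma_sex * 0.5
    return age, sex, liability


def simulate_phenotype(
    scenario: SimScenario, panel: GenotypePanel, rng: np.random.Generator
) -> pd.DataFrame:
    """Liability-threshold case/control status with age and sex covariates."""
    age, sex, liability = _liability_components(scenario, panel, rng)
    status = (liability > sps.norm.ppf(1 - scenario.prevalence)).astype(int)
    return pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "status": status,
            "age": age,
            "sex": sex,
            "liability": liability,
        }
    )


def simulate_quantitative(
    scenario: SimScenario, panel: GenotypePanel, rng: np.random.Generator
) -> np.ndarray:
    """The continuous liability itself, as a quantitative trait."""
    return _liability_components(scenario, panel, rng)[2]


def marginal_gwas(panel: GenotypePanel, pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP logistic regression of status on dosage (no covariates).

    Returns a summary-statistics table (one row per polymorphic SNP) with
    beta = log OR, its SE, Wald p, counted-allele frequency and n.
    Monomorphic SNPs are excluded.
    """
    y = pheno["status"].to_numpy(float)
    if y.min() == y.max():
        raise SimulationError("both classes required for a GWAS")
    g = panel.dosage
    freq = panel.allele_freq()
    poly = (freq > 0) & (freq < 1)
    b, se = _batched_logistic(g[:, poly], y)
    z = b / se
    p = np.clip(2 * sps.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    var = panel.variants.loc[poly].reset_index(drop=True)
    return pd.DataFrame(
        {
            "snp": var["snp"],
            "chrom": var["chrom"].astype(str),
            "bp": var["bp"],
            "a1": var["a2"],  # effect allele = counted allele
            "a2": var["a1"],
            "freq": freq[poly],
            "b": b,
            "se": se,
            "p": p,
            "n": float(len(y)),
        }
    )


def marginal_linear(panel: GenotypePanel, y: np.ndarray) -> pd.DataFrame:
    """Per-SNP simple linear regression of a quantitative trait on dosage."""
    y = np.asarray(y, dtype=float)
    g = panel.dosage
    n = len(y)
    freq = panel.allele_freq()
    poly = (freq > 0) & (freq < 1)
    gc = g[:, poly] - g[:, poly].mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    b = (gc * yc[:, None]).sum(axis=0) / sxx
    resid_ss = (yc**2).sum() - b**2 * sxx
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    t = b / se
    p = np.clip(2 * sps.t.sf(np.abs(t), df=n - 2), np.nextafter(0, 1), 1.0)
    var = panel.variants.loc[poly].reset_index(drop=True)
    return pd.DataFrame(
        {
            "snp": var["snp"],
            "chrom": var["chrom"].astype(str),
            "bp": var["bp"],
            "a1": var["a2"],
            "a2": var["a1"],
            "freq": freq[poly],
            "b": b,
            "se": se,
            "p": p,
            "n": float(n),
        }
    )


def _batched_logistic(g: np.ndarray, y: np.ndarray, max_iter=30, tol=1e-10):
    """Vectorized per-SNP 2-parameter logistic Newton fits.

    Each column of ``g`` gets its own (intercept, slope); returns (slope,
    slope SE) arrays.
    """
    n, m = g.shape
    ybar = y.mean()
    a = np.full(m, np.log(ybar / (1 - ybar)))
    b = np.zeros(m)
    yc = y[:, None]
    for _ in range(max_iter):
        eta = a[None, :] + g * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        r = yc - p
        u0 = r.sum(axis=0)
        u1 = (g * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * g).sum(axis=0)
        h11 = (w * g * g).sum(axis=0)
        det = h00 * h11 - h01**2
        da = (h11 * u0 - h01 * u1) / det
        db = (-h01 * u0 + h00 * u1) / det
        a += da
        b += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
            break
    eta = a[None, :] + g * b[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    h00 = w.sum(axis=0)
    h01 = (w * g).sum(axis=0)
    h11 = (w * g * g).sum(axis=0)
    det = h00 * h11 - h01**2
    se_b = np.sqrt(h00 / det)
    return b, se_b


def simulate(scenario: SimScenario) -> SimOutput:
    """Draw all three cohorts and the GWAS summary statistics.

    All randomness flows from ``scenario.seed``; equal seeds give
    byte-identical outputs. The reference, GWAS and validation cohorts are
    independent draws from the same generative law.
    """
    ss = np.random.SeedSequence(scenario.seed)
    rng_ref, rng_gwas, rng_gpheno, rng_val, rng_vpheno = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    ref_panel = simulate_panel(scenario, scenario.n_ref, rng_ref)
    gwas_panel = simulate_panel(scenario, scenario.n_gwas, rng_gwas)
    gwas_pheno = simulate_phenotype(scenario, gwas_panel, rng_gpheno)
    val_panel = simulate_panel(scenario, scenario.n_val, rng_val)
    val_pheno = simulate_phenotype(scenario, val_panel, rng_vpheno)
    sumstats = marginal_gwas(gwas_panel, gwas_pheno)
    causal_idx = [c[0] for c in scenario.causal]
    truth = {
        "causal_snps": [scenario.variants()["snp"][j] for j in causal_idx],
        "causal_betas": [c[1] for c in scenario.causal],
        "expected_marginal_std": _expected_marginal(scenario),
        "realized_ld_ref": None,  # filled lazily by callers that need it
    }
    return SimOutput(
        scenario, ref_panel, gwas_panel, gwas_pheno, val_panel, val_pheno, sumstats, truth
    )


def _expected_marginal(scenario: SimScenario) -> dict[str, float]:
    """Expected standardized marginal liability effect per causal SNP:
    β_j + Σ_{k≠j} r_jk β_k (joint normality of standardized genotypes)."""
    out = {}
    names = scenario.variants()["snp"]
    for j, bj in scenario.causal:
        e = bj
        for k, bk in scenario.causal:
            if k != j:
                e += scenario.genotype_corr(j, k) * bk
        out[names[j]] = float(e)
    return out


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _null_block_latent(m: int, block: int = 5, rho: float = 0.3) -> np.ndarray:
    """Block-diagonal latent LD: blocks of ``block`` SNPs at correlation rho."""
    r = np.eye(m)
    for start in range(0, m, block):
        stop = min(start + block, m)
        r[start:stop, start:stop] = rho
    np.fill_diagonal(r, 1.0)
    return r


def preset_masked_pair(
    seed: int,
    beta: float = 0.15,
    target_r: float = -0.54,
    freqs_pair: tuple[float, float] = (0.43, 0.75),
    m_null: int = 50,
) -> SimScenario:
    """Two risk alleles in negative LD whose marginal effects are attenuated.

    Both causal SNPs carry standardized liability effect ``beta``; their
    risk-allele genotype correlation is ``target_r`` (default −0.54), so each
    expected standardized marginal effect shrinks to β(1 + r) ≈ 0.069 — the
    masking phenomenon that motivates conditional/joint analysis. The pair
    sits mid-region among ``m_null`` null SNPs in mild block LD.

    Note on frequencies: with risk-allele frequencies 0.43 and ~0.8 a
    correlation of −0.54 is infeasible for ANY bivariate allele distribution
    (Fréchet bound ≈ −0.53), so the second frequency defaults to 0.75, which
    admits the target correlation under the copula.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11E1E)))
    m = m_null + 2
    c1, c2 = m // 2 - 1, m // 2
    freqs = rng.uniform(0.10, 0.90, size=m)
    freqs[c1], freqs[c2] = freqs_pair
    latent = _null_block_latent(m)
    # carve the causal pair out of the null block structure
    latent[c1, :] = latent[:, c1] = 0.0
    latent[c2, :] = latent[:, c2] = 0.0
    rho = latent_from_genotype_corr(target_r, *freqs_pair)
    latent[c1, c2] = latent[c2, c1] = rho
    latent[c1, c1] = latent[c2, c2] = 1.0
    return SimScenario(
        freqs=freqs,
        ld_latent=latent,
        causal=[(c1, beta), (c2, beta)],
        seed=seed,
        label="masked-pair",
        notes={"target_genotype_r": target_r, "latent_r": rho},
    )


def preset_chain(
    seed: int,
    betas: tuple[float, float, float] = (0.06, 0.20, 0.10),
    consecutive_r: tuple[float, float] = (0.344, -0.126),
    freqs_triplet: tuple[float, float, float] = (0.479, 0.237, 0.180),
    m_null: int = 50,
) -> SimScenario:
    """Three causal SNPs with consecutive LD (r = 0.344, then −0.126) and one
    dominant effect, exercising 3-SNP stepwise behavior."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC4A11)))
    m = m_null + 3
    c = [m // 2 - 1, m // 2, m // 2 + 1]
    freqs = rng.uniform(0.10, 0.90, size=m)
    for j, f in zip(c, freqs_triplet):
        freqs[j] = f
    latent = _null_block_latent(m)
    for j in c:
        latent[j, :] = latent[:, j] = 0.0
        latent[j, j] = 1.0
    r12 = latent_from_genotype_corr(consecutive_r[0], freqs_triplet[0], freqs_triplet[1])
    r23 = latent_from_genotype_corr(consecutive_r[1], freqs_triplet[1], freqs_triplet[2])
    latent[c[0], c[1]] = latent[c[1], c[0]] = r12
    latent[c[1], c[2]] = latent[c[2], c[1]] = r23
    latent[c[0], c[2]] = latent[c[2], c[0]] = r12 * r23  # Markov chain closure: PD
    return SimScenario(
        freqs=freqs,
        ld_latent=latent,
        causal=list(zip(c, betas)),
        seed=seed,
        label="chain",
        notes={"consecutive_genotype_r": consecutive_r},
    )


def preset_null(seed: int, m_snps: int = 50, n_gwas: int = 20_000) -> SimScenario:
    """A region with no causal SNPs (stepwise should select nothing)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x0)))
    freqs = rng.uniform(0.10, 0.90, size=m_snps)
    return SimScenario(
        freqs=freqs,
        ld_latent=_null_block_latent(m_snps),
        causal=[],
        seed=seed,
        n_gwas=n_gwas,
        label="null",
    )


def with_seed(scenario: SimScenario, seed: int) -> SimScenario:
    """Same scenario, different random seed (replicate draws)."""
    return replace(scenario, seed=seed)
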