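"""Reference genotype panels: QC, allele frequencies and LD correlations.

A :class:`GenotypePanel` holds a samples × variants dosage matrix counting
copies of the B allele (``a2``), with ``NaN`` marking missing genotypes.
Imputed dosages are real-valued in [0, 2]; :func:`hard_call` converts them to
{0, 1, 2} the way summary-based conditional analysis expects, masking
genotypes whose dosage falls in the uncertain bands (0.33, 0.66) or
(1.33, 1.66).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["snp", "chrom", "bp", "a1", "a2"]


class PanelError(ValueError):
    pass


@dataclass
class GenotypePanel:
    """Diploid dosage panel. ``dosage[i, j]`` counts sample i's copies of
    variant j's ``a2`` allele; missing entries are NaN."""

    sample_ids: list[str]
    variants: pd.DataFrame  # columns: snp, chrom, bp, a1, a2
    dosage: np.ndarray  # (n_samples, n_variants) float
    hard_called: bool = False

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise PanelError("dosage shape does not match sample/variant lists")
        d = self.dosage[np.isfinite(self.dosage)]
        if d.size and (d.min() < 0 or d.max() > 2):
            raise PanelError("dosages must lie in [0, 2]")
        if self.hard_called and d.size and not np.allclose(d, np.round(d)):
            raise PanelError("hard_called panel contains non-integer dosages")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> list[str]:
        return self.variants["snp"].astype(str).tolist()

    def index_of(self, snp_ids) -> np.ndarray:
        pos = pd.Index(self.variants["snp"].astype(str))
        idx = pos.get_indexer([str(s) for s in snp_ids])
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise PanelError(f"variants absent from panel: {missing}")
        return idx

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (a2) allele: mean non-missing dosage / 2.

        All-missing variants get NaN (undefined-frequency flag).
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def dosage_variance(self) -> np.ndarray:
        """Per-variant sample variance (ddof=0) of non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanvar(self.dosage, axis=0)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def subset_variants(self, mask_or_ids) -> "GenotypePanel":
        if isinstance(mask_or_ids, (list, tuple, pd.Index)) or (
            isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype.kind in "UOS"
        ):
            idx = self.index_of(mask_or_ids)
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        return GenotypePanel(
            self.sample_ids,
            self.variants.iloc[idx],
            self.dosage[:, idx],
            self.hard_called,
        )

    def subset_samples(self, keep) -> "GenotypePanel":
        keep = list(keep)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in keep])
        return GenotypePanel(keep, self.variants, self.dosage[idx], self.hard_called)


@dataclass
class LDView:
    """Effect-allele-oriented LD: ``r[j, k]`` is the Pearson correlation of
    the effect-allele dosages of SNPs j and k."""

    snp_ids: list[str]
    r: np.ndarray
    n_pairs: np.ndarray = None
    monomorphic: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if self.n_pairs is None:
            self.n_pairs = np.full_like(self.r, np.nan)

    def subset(self, snp_ids) -> "LDView":
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        idx = np.array([pos[str(s)] for s in snp_ids])
        return LDView(
            [str(s) for s in snp_ids],
            self.r[np.ix_(idx, idx)],
            self.n_pairs[np.ix_(idx, idx)],
            [m for m in self.monomorphic if m in set(map(str, snp_ids))],
        )


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def hard_call(
    panel: GenotypePanel,
    low_band: tuple[float, float] = (0.33, 0.66),
    high_band: tuple[float, float] = (1.33, 1.66),
    snp_level: bool = False,
) -> GenotypePanel:
    """Round dosages to {0, 1, 2}, masking those strictly inside either band.

    Band endpoints are kept (open intervals), then rounded to the nearest
    integer. Idempotent on integer dosages. With ``snp_level=True`` the
    stricter reading is applied instead: any variant with at least one
    genotype inside a band is dropped entirely.
    """
    if panel.hard_called:
        raise PanelError("panel is already hard-called")
    d = panel.dosage.copy()
    in_band = ((d > low_band[0]) & (d < low_band[1])) | (
        (d > high_band[0]) & (d < high_band[1])
    )
    if snp_level:
        keep = ~in_band.any(axis=0)
        if not keep.any():
            raise PanelError("SNP-level dosage-band exclusion removed every variant")
        out = GenotypePanel(
            panel.sample_ids,
            panel.variants.iloc[np.flatnonzero(keep)],
            np.round(panel.dosage[:, keep]),
            hard_called=True,
        )
        return out
    d[in_band] = np.nan
    d = np.round(d)
    return GenotypePanel(panel.sample_ids, panel.variants, d, hard_called=True)


def hwe_chi2(counts) -> float:
    """Hardy–Weinberg 1-df chi-square p-value from (n_AA, n_Aa, n_aa).

    Uses the sample allele frequency for expected counts. Monomorphic
    variants return p = 1 by convention.
    """
    n_aa, n_ab, n_bb = (float(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise PanelError("empty genotype counts")
    p = (2 * n_bb + n_ab) / (2 * n)
    if p <= 0 or p >= 1:
        return 1.0
    exp = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
    obs = np.array([n_aa, n_ab, n_bb])
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(sps.chi2.sf(stat, df=1))


def hwe_pvalues(panel: GenotypePanel) -> np.ndarray:
    """Per-variant HWE chi-square p on hard-called genotype counts."""
    if not panel.hard_called:
        raise PanelError("HWE test requires a hard-called panel")
    d = panel.dosage
    out = np.empty(panel.n_variants)
    for j in range(panel.n_variants):
        col = d[:, j]
        col = col[np.isfinite(col)]
        counts = ((col == 0).sum(), (col == 1).sum(), (col == 2).sum())
        out[j] = hwe_chi2(counts) if sum(counts) else 1.0
    return out


def qc_variants(
    panel: GenotypePanel,
    maf_min: float | None = 0.005,
    miss_max: float | None = 0.10,
    hwe_p_min: float | None = 0.005,
    info_min: float | None = 0.6,
    info: np.ndarray | None = None,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Apply the standard variant QC, in order: info → missingness → MAF → HWE.

    A variant is excluded at the first rule it fails; the report counts
    exclusions per rule. Any threshold set to None disables that rule.
    """
    m = panel.n_variants
    status = np.array(["pass"] * m, dtype=object)
    active = np.ones(m, dtype=bool)

    if info_min is not None and info is not None:
        fail = active & (np.asarray(info, dtype=float) < info_min)
        status[fail] = "info"
        active &= ~fail
    if miss_max is not None:
        fail = active & (panel.missing_rate() > miss_max)
        status[fail] = "missingness"
        active &= ~fail
    if maf_min is not None:
        freq = panel.allele_freq()
        maf = np.minimum(freq, 1 - freq)
        fail = active & ((maf < maf_min) | ~np.isfinite(maf))
        status[fail] = "maf"
        active &= ~fail
    if hwe_p_min is not None:
        hwe = hwe_pvalues(panel) if panel.hard_called else hwe_pvalues(hard_call(panel))
        fail = active & (hwe < hwe_p_min)
        status[fail] = "hwe"
        active &= ~fail

    report = pd.DataFrame({"snp": panel.snp_ids, "status": status})
    if not active.any():
        raise PanelError("variant QC removed every variant")
    n_removed = int((~active).sum())
    if n_removed:
        logger.info("variant QC removed %d of %d variants", n_removed, m)
    return panel.subset_variants(active), report


def ld_corr(
    panel: GenotypePanel,
    snp_ids=None,
    orientation: np.ndarray | None = None,
) -> LDView:
    """Pairwise-complete Pearson correlation of (oriented) dosages.

    ``orientation`` holds ±1 per SNP; −1 means the effect allele is the
    panel's A allele, so the dosage is reflected (2 − d) before correlating.
    Variants monomorphic in the non-missing subsample get zero correlation
    with everything (flagged in ``monomorphic``).
    """
    if snp_ids is None:
        snp_ids = panel.snp_ids
        sub = panel
    else:
        sub = panel.subset_variants(list(snp_ids))
    d = sub.dosage.copy()
    m = d.shape[1]
    if orientation is not None:
        orientation = np.asarray(orientation, dtype=float)
        d = np.where(orientation[None, :] < 0, 2.0 - d, d)

    finite = np.isfinite(d)
    n_pairs = finite.astype(float).T @ finite.astype(float)
    if (n_pairs < 2).any():
        logger.warning("some SNP pairs have <2 complete observations")

    # pairwise-complete correlation; loop only when missingness is present
    mono: list[str] = []
    if finite.all():
        sd = d.std(axis=0)
        mono_mask = sd == 0
        dc = d - d.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = (dc.T @ dc) / d.shape[0]
            r = cov / np.outer(np.where(mono_mask, np.nan, sd), np.where(mono_mask, np.nan, sd))
        r[np.isnan(r)] = 0.0
        mono = [s for s, f in zip(sub.snp_ids, mono_mask) if f]
    else:
        r = np.eye(m)
        for j in range(m):
            for k in range(j + 1, m):
                ok = finite[:, j] & finite[:, k]
                if ok.sum() < 2:
                    r[j, k] = r[k, j] = 0.0
                    continue
                xj, xk = d[ok, j], d[ok, k]
                if xj.std() == 0 or xk.std() == 0:
                    r[j, k] = r[k, j] = 0.0
                else:
                    r[j, k] = r[k, j] = float(np.corrcoef(xj, xk)[0, 1])
        for j in range(m):
            col = d[finite[:, j], j]
            if col.size and col.std() == 0:
                mono.append(sub.snp_ids[j])
    np.fill_diagonal(r, 1.0)
    if mono:
        logger.warning("monomorphic-in-subsample SNPs: %s", mono)
    return LDView(sub.snp_ids, r, n_pairs, mono)


def genomic_relationship(panel: GenotypePanel) -> np.ndarray:
    """VanRaden-style genomic relationship matrix.

    A_ij = (1/m) Σ_k (x_ik − 2p_k)(x_jk − 2p_k) / (2 p_k (1 − p_k)),
    with missing genotypes mean-imputed (contributing zero).
    """
    freq = panel.allele_freq()
    var = 2 * freq * (1 - freq)
    use = np.isfinite(var) & (var > 0)
    if use.sum() < 2:
        raise PanelError("need >=2 polymorphic variants for relatedness")
    x = panel.dosage[:, use]
    p = freq[use]
    z = (x - 2 * p[None, :]) / np.sqrt(2 * p * (1 - p))[None, :]
    z = np.nan_to_num(z, nan=0.0)
    return (z @ z.T) / use.sum()


def relatedness_prune(panel: GenotypePanel, threshold: float = 0.025) -> list[str]:
    """Greedily prune samples so no pair has relationship ≥ threshold.

    From each over-threshold pair the member with more over-threshold
    partners is removed (ties: the later sample id), iterating until no
    pair remains. Returns the retained sample ids.
    """
    A = genomic_relationship(panel)
    n = A.shape[0]
    over = (A >= threshold) & ~np.eye(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    ids = list(panel.sample_ids)
    while True:
        counts = (over & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = 0
        if counts.max() == 0:
            break
        worst = counts.max()
        cand = [i for i in np.flatnonzero(counts == worst)]
        # ties -> remove the later sample id
        drop = max(cand, key=lambda i: ids[i])
        alive[drop] = False
    return [s for s, a in zip(ids, alive) if a]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_vcf(path, field: str = "auto") -> GenotypePanel:
    """Read a VCF into a panel, counting the ALT allele.

    ``field`` selects the dosage source: ``"DS"`` (imputed dosages), ``"GT"``
    (hard genotypes) or ``"auto"`` (DS when present, else GT).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        rows.append(
            {
                "snp": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "bp": int(var.POS),
                "a1": str(var.REF),
                "a2": str(alt),
            }
        )
        ds = None
        if field in ("auto", "DS"):
            try:
                ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
            except Exception:
                ds = None
        if ds is None:
            if field == "DS":
                raise PanelError("VCF record lacks DS field")
            # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
            g = np.asarray(var.gt_types, dtype=float)
            ds = np.select([g == 0, g == 1, g == 3], [0.0, 1.0, 2.0], default=np.nan)
        cols.append(ds)
    if not cols:
        raise PanelError(f"no variants in {path}")
    dosage = np.column_stack(cols)
    hard = bool(np.all(np.isnan(dosage) | (dosage == np.round(dosage))))
    return GenotypePanel(samples, pd.DataFrame(rows), dosage, hard_called=hard)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as an uncompressed VCF with GT (hard calls) and DS."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        chroms = panel.variants["chrom"].astype(str).unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in enumerate(panel.variants.itertuples(index=False)):
            cells = []
            for d in panel.dosage[:, j]:
                if not np.isfinite(d):
                    cells.append("./.:.")
                else:
                    gt = gt_map.get(int(round(d)), "./.")
                    cells.append(f"{gt}:{d:.3f}")
            fh.write(
                f"{v.chrom}\t{v.bp}\t{v.snp}\t{v.a1}\t{v.a2}\t.\tPASS\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def read_plink(prefix) -> GenotypePanel:
    """Read PLINK1 bed/bim/fam hard calls (SNP-major variant order).

    The returned panel counts the bim's second allele (A2), matching the
    panel convention that ``a2`` is the counted allele.
    """
    prefix = str(prefix)
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp", "allele1", "allele2"],
        dtype={"chrom": str, "snp": str},
    )
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, usecols=[1], names=["iid"])
    samples = fam["iid"].astype(str).tolist()
    n, m = len(samples), len(bim)
    data = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if data[0] != 0x6C or data[1] != 0x1B or data[2] != 0x01:
        raise PanelError("not a SNP-major PLINK .bed file")
    data = data[3:]
    bytes_per_snp = (n + 3) // 4
    # 2-bit codes: 00=hom A1 (0 copies of A2), 01=missing, 10=het, 11=hom A2
    code_to_a2 = np.array([0.0, np.nan, 1.0, 2.0])
    dosage = np.empty((n, m))
    for j in range(m):
        chunk = data[j * bytes_per_snp : (j + 1) * bytes_per_snp]
        bits = np.unpackbits(chunk[:, None], axis=1, bitorder="little")
        codes = (bits[:, 0::2] + 2 * bits[:, 1::2]).reshape(-1)[:n]
        dosage[:, j] = code_to_a2[codes]
    variants = bim.rename(columns={"allele1": "a1", "allele2": "a2"})[VARIANT_COLUMNS]
    return GenotypePanel(samples, variants, dosage, hard_called=True)


def write_ld_tsv(ld: LDView, path) -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")
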