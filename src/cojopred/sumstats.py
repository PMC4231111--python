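"""GWAS summary-statistics I/O, harmonization and regional subsetting.

Summary statistics are carried as a pandas DataFrame with the canonical
columns below (the GCTA ``.ma`` exchange format plus optional positions):

==========  =====================================================
column      meaning
==========  =====================================================
snp         variant identifier (unique)
chrom       chromosome label (string; optional in minimal files)
bp          1-based physical position (optional in minimal files)
a1          effect allele
a2          other allele (may be absent in minimal dialects)
freq        effect-allele frequency, in (0, 1)
b           marginal log odds ratio (or linear beta)
se          standard error of ``b``, > 0
p           marginal p-value, in (0, 1]
n           per-SNP sample size (meta-analyses report non-integers)
==========  =====================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for a full table
COLUMNS = ["snp", "chrom", "bp", "a1", "a2", "freq", "b", "se", "p", "n"]

#: columns that must be present after dialect mapping
REQUIRED = ["snp", "a1", "freq", "b", "se", "p", "n"]

#: default header mapping for the minimal ``.ma`` dialect
#: ``SNP A1 A2 freq b se p N`` (whitespace delimited, with header)
MA_DIALECT = {
    "SNP": "snp",
    "Chr": "chrom",
    "bp": "bp",
    "A1": "a1",
    "A2": "a2",
    "freq": "freq",
    "b": "b",
    "se": "se",
    "p": "p",
    "N": "n",
}

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class RegionSpec:
    """A locus region: ``center_bp`` ± ``half_width_bp`` (closed) on ``chrom``."""

    lead_snp_id: str
    chrom: str
    center_bp: int
    half_width_bp: int = 1_000_000

    def __post_init__(self):
        if self.half_width_bp < 0:
            raise ValueError("half_width_bp must be >= 0")


class SumStatsError(ValueError):
    pass


def validate_sumstats(df: pd.DataFrame, drop_invalid: bool = True) -> pd.DataFrame:
    """Enforce the table invariants, dropping (and logging) offending rows.

    Invariants: unique snp ids, se > 0, 0 < freq < 1, 0 < p <= 1, n > 1,
    finite b.
    """
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise SumStatsError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df.copy()
    for c in ["freq", "b", "se", "p", "n"]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ok = (
        df["se"].gt(0)
        & df["freq"].gt(0)
        & df["freq"].lt(1)
        & df["p"].gt(0)
        & df["p"].le(1)
        & df["n"].gt(1)
        & np.isfinite(df["b"])
    )
    ok &= ~df["snp"].duplicated(keep="first")
    n_bad = int((~ok).sum())
    if n_bad:
        if not drop_invalid:
            raise SumStatsError(f"{n_bad} rows violate summary-statistic invariants")
        logger.warning("dropped %d invalid summary-statistic rows", n_bad)
        df = df[ok]
    if len(df) == 0:
        raise SumStatsError("no valid summary-statistic rows")
    return df.reset_index(drop=True)


def read_ma(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a whitespace-delimited ``.ma``-style summary-statistics file.

    Parameters
    ----------
    path : str or Path
    dialect : dict, optional
        Mapping from file header names to canonical column names; defaults
        to :data:`MA_DIALECT`. Unmapped file columns are ignored.
    """
    dialect = dict(MA_DIALECT if dialect is None else dialect)
    raw = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str})
    raw = raw.rename(columns=dialect)
    df = validate_sumstats(raw[[c for c in COLUMNS if c in raw.columns]])
    df["snp"] = df["snp"].astype(str)
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    return df


def write_ma(df: pd.DataFrame, path) -> None:
    """Write summary statistics in the whitespace-delimited ``.ma`` dialect."""
    inv = {v: k for k, v in MA_DIALECT.items()}
    out = df[[c for c in COLUMNS if c in df.columns]].rename(columns=inv)
    out.to_csv(path, sep="\t", index=False)


def extract_region(df: pd.DataFrame, region: RegionSpec) -> pd.DataFrame:
    """Subset to SNPs on ``region.chrom`` with |bp − center| ≤ half-width."""
    if "chrom" not in df.columns or "bp" not in df.columns:
        raise SumStatsError("table lacks chrom/bp columns needed for regions")
    if not (df["chrom"].astype(str) == region.chrom).any():
        raise SumStatsError(f"chromosome {region.chrom!r} not present in table")
    keep = (df["chrom"].astype(str) == region.chrom) & (
        (df["bp"] - region.center_bp).abs() <= region.half_width_bp
    )
    out = df[keep].reset_index(drop=True)
    if len(out) == 0:
        logger.warning("region %s yielded no SNPs", region)
    return out


def define_lead_snp(df: pd.DataFrame, region: RegionSpec | None = None) -> str:
    """Return the snp id with the smallest p in the region.

    Ties are broken by smallest bp, then lexicographically by snp id, so the
    result is invariant to input row order.
    """
    sub = extract_region(df, region) if region is not None else df
    if len(sub) == 0:
        raise SumStatsError("empty region: no lead SNP")
    cols = ["p", "bp", "snp"] if "bp" in sub.columns else ["p", "snp"]
    idx = sub.sort_values(cols, kind="mergesort").index[0]
    return str(sub.loc[idx, "snp"])


def harmonize_to_reference(
    df: pd.DataFrame,
    panel_variants: pd.DataFrame,
    ambiguous_policy: str = "exclude_midrange",
    ambiguous_freq_band: tuple[float, float] = (0.35, 0.65),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Orient summary statistics against a genotype panel's counted allele.

    The panel counts ``a2`` (the dosage allele). Each summary SNP receives an
    ``orientation`` of +1 when its effect allele is the panel's counted
    allele, −1 when it is the other allele; strand flips are resolved by
    complementing. ``b, se, p, n`` are never altered.

    Strand-ambiguous SNPs (A/T, C/G) cannot be strand-resolved from alleles.
    Policy ``"exclude_midrange"`` (default) drops them when the effect-allele
    frequency lies inside ``ambiguous_freq_band`` and otherwise resolves them
    by matching frequency to the panel; ``"exclude"`` drops all of them;
    ``"keep"`` assumes same strand.

    Returns
    -------
    (harmonized, report)
        ``harmonized`` gains ``orientation`` and ``panel_freq`` columns;
        ``report`` has one row per input SNP with its disposition
        (kept / flipped / ambiguous / dropped) and a reason.
    """
    pv = panel_variants.set_index(panel_variants["snp"].astype(str))
    rows, report = [], []

    def _dispose(snp, status, reason=""):
        report.append({"snp": snp, "status": status, "reason": reason})

    for rec in df.itertuples(index=False):
        snp = str(rec.snp)
        if snp not in pv.index:
            _dispose(snp, "dropped", "absent_from_panel")
            continue
        pa, pb = str(pv.at[snp, "a1"]), str(pv.at[snp, "a2"])
        pfreq = float(pv.at[snp, "freq"]) if "freq" in pv.columns else np.nan
        e = str(rec.a1)
        o = str(getattr(rec, "a2", "")) or None
        pair = (e.upper(), (o or "").upper())
        ambiguous = pair in AMBIGUOUS_PAIRS
        orient = _orientation(e, o, pa, pb)
        if ambiguous:
            lo, hi = ambiguous_freq_band
            if ambiguous_policy == "exclude" or (
                ambiguous_policy == "exclude_midrange" and lo <= rec.freq <= hi
            ):
                _dispose(snp, "ambiguous", "strand_ambiguous_excluded")
                continue
            if ambiguous_policy != "keep" and np.isfinite(pfreq):
                # resolve strand by frequency: counted-allele freq should
                # match freq (orientation +1) or 1-freq (orientation -1)
                orient = 1 if abs(pfreq - rec.freq) <= abs(pfreq - (1 - rec.freq)) else -1
        if orient == 0:
            _dispose(snp, "dropped", "allele_mismatch")
            continue
        _dispose(snp, "kept" if orient == 1 else "flipped", "")
        row = rec._asdict()
        row["orientation"] = orient
        row["panel_freq"] = pfreq
        rows.append(row)

    report = pd.DataFrame(report, columns=["snp", "status", "reason"])
    n_drop = int((report["status"].isin(["dropped", "ambiguous"])).sum())
    if n_drop:
        logger.info("harmonization excluded %d SNPs", n_drop)
    harmonized = pd.DataFrame(rows) if rows else df.iloc[:0].assign(orientation=[], panel_freq=[])
    return harmonized.reset_index(drop=True), report


def _orientation(e: str, o: str | None, pa: str, pb: str) -> int:
    """+1 effect allele is the counted (B) allele, −1 the A allele, 0 no match."""
    e, pa, pb = e.upper(), pa.upper(), pb.upper()
    o = o.upper() if o else None
    if o is not None:
        if (e, o) == (pb, pa):
            return 1
        if (e, o) == (pa, pb):
            return -1
        ec, oc = COMPLEMENT.get(e), COMPLEMENT.get(o)
        if (ec, oc) == (pb, pa):
            return 1
        if (ec, oc) == (pa, pb):
            return -1
        return 0
    if e == pb or COMPLEMENT.get(e) == pb:
        return 1
    if e == pa or COMPLEMENT.get(e) == pa:
        return -1
    return 0


def read_regions(path) -> list[RegionSpec]:
    """Read a 4-column TSV (lead_snp_id, chrom, center_bp, half_width_bp)."""
    df = pd.read_csv(path, sep="\t", dtype={"lead_snp_id": str, "chrom": str})
    return [
        RegionSpec(str(r.lead_snp_id), str(r.chrom), int(r.center_bp), int(r.half_width_bp))
        for r in df.itertuples(index=False)
    ]
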