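"""Weighted genetic risk scores (GRS).

A GRS is a per-individual weighted sum of effect-allele dosages,
score_i = Σ_j w_j d_ij, with weights on the log-odds-ratio scale — either
marginal meta-analysis effects of lead SNPs or joint effects from the
conditional/joint analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cojo import JointGwasResults
from .ldpanel import GenotypePanel

logger = logging.getLogger(__name__)


class GrsError(ValueError):
    pass


@dataclass
class WeightSet:
    """SNP weights defining a risk score.

    ``entries`` columns: snp, effect_allele, weight, source
    (source ∈ {"marginal", "joint"}).
    """

    entries: pd.DataFrame
    label: str = ""

    def __post_init__(self):
        need = {"snp", "effect_allele", "weight", "source"}
        if not need.issubset(self.entries.columns):
            raise GrsError(f"weight set needs columns {sorted(need)}")
        if self.entries["snp"].duplicated().any():
            dup = self.entries.loc[self.entries["snp"].duplicated(), "snp"].tolist()
            raise GrsError(f"duplicate SNPs in weight set: {dup}")
        if not np.isfinite(self.entries["weight"].to_numpy(float)).all():
            raise GrsError("non-finite weights")
        self.entries = self.entries.reset_index(drop=True)

    def __len__(self):
        return len(self.entries)

    def to_tsv(self, path):
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label=""):
        return cls(pd.read_csv(path, sep="\t", dtype={"snp": str}), label)


def build_lead_weightset(stats: pd.DataFrame, lead_ids, label="lead") -> WeightSet:
    """Marginal-weight GRS over the lead SNPs (weight = meta-analysis b)."""
    lead_ids = [str(s) for s in lead_ids]
    idx = stats.set_index(stats["snp"].astype(str))
    missing = [s for s in lead_ids if s not in idx.index]
    if missing:
        raise GrsError(f"lead SNPs absent from summary statistics: {missing}")
    sub = idx.loc[lead_ids]
    entries = pd.DataFrame(
        {
            "snp": lead_ids,
            "effect_allele": sub["a1"].tolist(),
            "weight": sub["b"].to_numpy(float),
            "source": "marginal",
        }
    )
    return WeightSet(entries, label)


def build_cj_weightset(
    models: dict, stats: pd.DataFrame | None = None, label="cj"
) -> WeightSet:
    """Joint-weight GRS: union over regions of (snp, bJ) from C/J results.

    ``models`` maps region label → :class:`JointGwasResults` (or None for an
    empty region, which contributes nothing). ``stats`` supplies effect
    alleles when given; otherwise effect_allele is left empty and must be
    resolved at scoring time.
    """
    rows = []
    allele = {}
    if stats is not None:
        allele = dict(zip(stats["snp"].astype(str), stats["a1"]))
    for region, res in models.items():
        if res is None or (isinstance(res, JointGwasResults) and len(res) == 0):
            continue
        for snp, bj in zip(res.snp_ids, res.beta_joint):
            rows.append(
                {
                    "snp": str(snp),
                    "effect_allele": allele.get(str(snp), ""),
                    "weight": float(bj),
                    "source": "joint",
                }
            )
    entries = pd.DataFrame(rows, columns=["snp", "effect_allele", "weight", "source"])
    return WeightSet(entries, label)


def combine_weightsets(lead: WeightSet, cj: WeightSet, label="lead+cj") -> WeightSet:
    """Union of lead and C/J weights; a SNP in both keeps its joint weight."""
    cj_snps = set(cj.entries["snp"])
    keep = lead.entries[~lead.entries["snp"].isin(cj_snps)]
    return WeightSet(pd.concat([keep, cj.entries], ignore_index=True), label)


def score(
    panel: GenotypePanel,
    weights: WeightSet,
    missing_policy: str = "mean",
) -> pd.DataFrame:
    """Score individuals: score_i = Σ_j w_j d_ij on effect-allele dosages.

    Scoring uses the panel's raw (possibly fractional) dosages. Weight SNPs
    absent from the panel are dropped with a logged count; a missing dosage
    is mean-imputed as 2 × panel effect-allele frequency (policy ``"mean"``)
    or treated as zero contribution (``"zero"``).

    Returns a DataFrame (sample_id, score, n_snps_used).
    """
    snp_in_panel = set(panel.variants["snp"].astype(str))
    present = weights.entries[weights.entries["snp"].astype(str).isin(snp_in_panel)]
    n_dropped = len(weights) - len(present)
    if len(present) == 0:
        raise GrsError("no weight SNPs overlap the genotype panel")
    if n_dropped:
        logger.warning("%d weight SNPs absent from panel, dropped", n_dropped)

    idx = panel.index_of(present["snp"].tolist())
    d = panel.dosage[:, idx].copy()
    var = panel.variants.iloc[idx]
    # orient dosages to each weight's effect allele
    orient = np.ones(len(present))
    for k, (ea, pa, pb) in enumerate(
        zip(present["effect_allele"], var["a1"].astype(str), var["a2"].astype(str))
    ):
        ea = str(ea)
        if ea == "" or ea == pb:
            continue
        if ea == pa:
            orient[k] = -1.0
        else:
            raise GrsError(f"effect allele {ea} not among panel alleles for {var.iloc[k]['snp']}")
    d = np.where(orient[None, :] < 0, 2.0 - d, d)

    if missing_policy == "mean":
        ea_freq = np.nanmean(d, axis=0) / 2.0
        fill = 2.0 * ea_freq
        d = np.where(np.isnan(d), fill[None, :], d)
    elif missing_policy == "zero":
        d = np.nan_to_num(d, nan=0.0)
    else:
        raise GrsError(f"unknown missing policy {missing_policy!r}")

    w = present["weight"].to_numpy(float)
    scores = d @ w
    return pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "score": scores,
            "n_snps_used": len(present),
        }
    )
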