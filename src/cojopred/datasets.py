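"""Worked-example association statistics at two-SNP type-2 diabetes loci.

Published marginal meta-analysis statistics (log odds ratio ``b``, its SE,
p-value, effect-allele frequency, per-SNP sample size), the LD correlation
``r`` between the pair's risk alleles in a European reference sample, and
the published conditional/joint re-estimates (``bj``, ``bj_se``, ``pj``).
Loci where exactly two SNPs were jointly selected are self-contained: the
printed pairwise r is the full LD matrix, so the joint fit can be reproduced
from this table alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ldpanel import LDView

# locus, snp, chrom, bp, a1, freq, b, se, p, n, bj, bj_se, pj, r_pair
_ROWS = [
    ("BCL11A", "rs2192512", "2", 59854224, "C", 0.475, 0.058, 0.014, 6.5e-4, 110517, 0.060, 0.014, 2.75e-5, -0.017),
    ("BCL11A", "rs243019", "2", 60439310, "C", 0.451, 0.086, 0.014, 2.7e-6, 117602, 0.087, 0.014, 3.24e-10, -0.017),
    ("IGF2BP2", "rs12233623", "3", 186712890, "C", 0.548, 0.058, 0.014, 1.0e-3, 111251, 0.065, 0.014, 5.49e-6, -0.074),
    ("IGF2BP2", "rs6767484", "3", 187003272, "G", 0.305, 0.122, 0.018, 3.9e-10, 83684.8, 0.127, 0.018, 7.89e-13, -0.074),
    ("ANKRD55", "rs9686661", "5", 55897543, "T", 0.189, 0.095, 0.023, 9.2e-5, 70923.6, 0.100, 0.023, 1.05e-5, -0.063),
    ("ANKRD55", "rs1895452", "5", 56096152, "T", 0.635, 0.058, 0.014, 3.1e-3, 118858, 0.061, 0.014, 1.69e-5, -0.063),
    ("ZBED3", "rs12522618", "5", 75491695, "G", 0.425, 0.058, 0.014, 3.7e-3, 112754, 0.058, 0.014, 4.99e-5, 0.009),
    ("ZBED3", "rs7708285", "5", 76461623, "G", 0.300, 0.122, 0.022, 1.1e-6, 54523.4, 0.122, 0.022, 3.70e-8, 0.009),
    ("TP53INP1", "rs4735337", "8", 96042641, "T", 0.490, 0.077, 0.014, 6.9e-5, 114412, 0.078, 0.014, 2.01e-8, -0.022),
    ("TP53INP1", "rs6991742", "8", 96533562, "T", 0.596, 0.068, 0.014, 1.8e-4, 116576, 0.069, 0.014, 8.77e-7, -0.022),
    ("ZMIZ1", "rs3915932", "10", 80611942, "G", 0.592, 0.095, 0.018, 4.7e-8, 69629.2, 0.098, 0.018, 7.10e-8, -0.040),
    ("ZMIZ1", "rs6480947", "10", 80906216, "G", 0.156, 0.113, 0.027, 2.2e-4, 59743.8, 0.119, 0.027, 8.58e-6, -0.040),
    ("KCNJ11", "rs7928810", "11", 17329019, "C", 0.396, 0.068, 0.014, 1.3e-4, 117423, 0.068, 0.014, 1.50e-6, -0.004),
    ("KCNJ11", "rs757984", "11", 17576484, "T", 0.803, 0.077, 0.019, 4.9e-4, 102511, 0.077, 0.019, 3.09e-5, -0.004),
    ("MTNR1B", "rs10830962", "11", 92338075, "G", 0.408, 0.104, 0.014, 1.5e-8, 124966, 0.101, 0.014, 1.61e-13, 0.069),
    ("MTNR1B", "rs531573", "11", 92444531, "C", 0.182, 0.086, 0.018, 1.7e-4, 111150, 0.077, 0.018, 2.75e-5, 0.069),
    ("TSPAN8", "rs11178531", "12", 69694957, "A", 0.449, 0.077, 0.014, 9.2e-6, 115565, 0.059, 0.014, 4.73e-5, 0.271),
    ("TSPAN8", "rs1533104", "12", 69942814, "T", 0.338, 0.086, 0.014, 2.8e-6, 130115, 0.072, 0.014, 4.26e-7, 0.271),
    ("SPRY2", "rs1616547", "13", 78884037, "C", 0.512, 0.058, 0.014, 3.0e-3, 110308, 0.058, 0.014, 4.84e-5, 0.006),
    ("SPRY2", "rs1327316", "13", 79607064, "G", 0.717, 0.095, 0.018, 9.4e-7, 82902.8, 0.095, 0.018, 1.92e-7, 0.006),
    ("C2CD4A", "rs6494307", "15", 60181982, "C", 0.572, 0.077, 0.014, 1.8e-5, 116797, 0.077, 0.014, 3.65e-8, -0.001),
    ("C2CD4A", "rs2456936", "15", 60502334, "C", 0.785, 0.077, 0.019, 1.1e-3, 96195.2, 0.077, 0.019, 3.32e-5, -0.001),
    ("HNF4A", "rs387769", "20", 41745269, "C", 0.881, 0.113, 0.027, 1.4e-5, 75082.1, 0.113, 0.027, 2.34e-5, 0.008),
    ("HNF4A", "rs6073708", "20", 43386291, "A", 0.562, 0.058, 0.014, 2.4e-3, 111949, 0.058, 0.014, 4.81e-5, 0.008),
]

_COLUMNS = [
    "locus", "snp", "chrom", "bp", "a1", "freq", "b", "se", "p", "n",
    "bj", "bj_se", "pj", "r_pair",
]


def two_snp_loci() -> pd.DataFrame:
    """The full worked-example table, one row per SNP (two per locus)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def locus_inputs(locus: str) -> tuple[pd.DataFrame, LDView]:
    """Marginal statistics and the 2×2 LD matrix for one locus.

    Returns the inputs a joint fit needs; the published joint estimates
    remain available in the ``bj``/``bj_se``/``pj`` columns for comparison.
    """
    df = two_snp_loci()
    sub = df[df["locus"] == locus].reset_index(drop=True)
    if len(sub) != 2:
        raise KeyError(f"unknown two-SNP locus {locus!r}")
    r = float(sub["r_pair"].iloc[0])
    ld = LDView(sub["snp"].tolist(), np.array([[1.0, r], [r, 1.0]]))
    return sub, ld


def locus_names() -> list[str]:
    return list(dict.fromkeys(r[0] for r in _ROWS))
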