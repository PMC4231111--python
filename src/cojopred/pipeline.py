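"""End-to-end orchestration: discovery (per-region C/J sweeps) and
validation (GRS model comparison on an independent case-control cohort).

Discovery, per region and p-value threshold: harmonize the summary
statistics to the reference panel, compute effect-allele-oriented LD, run
stepwise conditional/joint selection, and emit one association table per
threshold. Validation: build lead-SNP, C/J and combined weight sets, score
the validation cohort on raw dosages, and compare logistic models
(baseline age+sex vs baseline+GRS) by AUC/DeLong, Nagelkerke R², AIC and
liability-scale variance explained.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import sumstats as ss
from .cojo import DEFAULT_THRESHOLDS, JointGwas, thresholds_sweep
from .evaluate import prediction_report
from .grs import WeightSet, build_cj_weightset, build_lead_weightset, combine_weightsets, score
from .ldpanel import GenotypePanel, hard_call, ld_corr, qc_variants, read_vcf

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and knobs for a full run; all paths must resolve at run start."""

    sumstats: str
    ref_panel: str
    regions: str
    val_panel: str | None = None
    phenotype: str | None = None
    out_dir: str = "cojopred_out"
    thresholds: tuple = DEFAULT_THRESHOLDS
    r2_collinear: float = 0.9
    max_iter: int = 100
    maf_min: float = 0.005
    miss_max: float = 0.10
    hwe_p_min: float = 0.005
    prevalence: float = 0.10
    seed: int = 0
    extra: dict = dc_field(default_factory=dict)

    def validate_paths(self, need_validation=False):
        paths = [self.sumstats, self.ref_panel, self.regions]
        if need_validation:
            paths += [self.val_panel, self.phenotype]
        for p in paths:
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"input path missing: {p}")
        if not all(0 < t < 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0,1)")


def _threshold_tag(t: float) -> str:
    return f"{t:.0e}".replace("e-0", "e-")


def _panel_variant_table(panel: GenotypePanel) -> pd.DataFrame:
    v = panel.variants.copy()
    v["freq"] = panel.allele_freq()
    return v


def discover_region(
    stats_region: pd.DataFrame,
    panel: GenotypePanel,
    thresholds=DEFAULT_THRESHOLDS,
    r2_collinear: float = 0.9,
    max_iter: int = 100,
):
    """Harmonize → LD → threshold sweep for one region.

    Returns (sweep dict, harmonized stats, LDView, match report); the sweep
    maps each threshold to (JointGwasResults or None, StepwiseTrace).
    """
    harm, report = ss.harmonize_to_reference(stats_region, _panel_variant_table(panel))
    if len(harm) == 0:
        return None, harm, None, report
    ld = ld_corr(panel, harm["snp"].tolist(), orientation=harm["orientation"].to_numpy())
    eff_freq = np.where(harm["orientation"] > 0, harm["panel_freq"], 1 - harm["panel_freq"])
    model = JointGwas(harm, ld, freq=eff_freq)
    sweep = thresholds_sweep(model, thresholds, r2_collinear=r2_collinear, max_iter=max_iter)
    return sweep, harm, ld, report


def region_table(harm: pd.DataFrame, ld, results) -> pd.DataFrame:
    """Association table for the selected SNPs of one region.

    Columns mirror the conventional C/J report: marginal and joint
    statistics plus the LD r between each SNP and the following selected SNP
    (0 for the last).
    """
    if results is None or len(results) == 0:
        return pd.DataFrame(
            columns=["snp", "chr", "bp", "refA", "freq", "b", "se", "p", "n", "bJ", "bJ_se", "pJ", "ld_r"]
        )
    sub = harm.set_index(harm["snp"].astype(str)).loc[results.snp_ids]
    order = np.argsort(sub["bp"].to_numpy()) if "bp" in sub.columns else np.arange(len(sub))
    ids = [results.snp_ids[i] for i in order]
    pos = {s: i for i, s in enumerate(ld.snp_ids)}
    ld_r = [
        float(ld.r[pos[ids[i]], pos[ids[i + 1]]]) if i + 1 < len(ids) else 0.0
        for i in range(len(ids))
    ]
    res_pos = {s: i for i, s in enumerate(results.snp_ids)}
    rows = []
    for i, snp in enumerate(ids):
        r = sub.loc[snp]
        j = res_pos[snp]
        rows.append(
            {
                "snp": snp,
                "chr": r.get("chrom", ""),
                "bp": r.get("bp", np.nan),
                "refA": r["a1"],
                "freq": r["freq"],
                "b": r["b"],
                "se": r["se"],
                "p": r["p"],
                "n": r["n"],
                "bJ": results.beta_joint[j],
                "bJ_se": results.se_joint[j],
                "pJ": results.p_joint[j],
                "ld_r": ld_r[i],
            }
        )
    return pd.DataFrame(rows)


def run_discovery(config: RunConfig) -> dict:
    """Full discovery pass over all regions; writes per-threshold tables.

    Returns {"regions": {region_label: {"sweep":…, "harm":…, "ld":…}},
    "tables": {threshold: DataFrame}}. Regions that fail are logged,
    reported and skipped; if every region fails a RuntimeError is raised.
    """
    config.validate_paths()
    t0 = time.time()
    stats = ss.read_ma(config.sumstats)
    panel = read_vcf(config.ref_panel)
    if not panel.hard_called:
        panel = hard_call(panel)
    panel, qc_report = qc_variants(
        panel, maf_min=config.maf_min, miss_max=config.miss_max, hwe_p_min=config.hwe_p_min
    )
    regions = ss.read_regions(config.regions)
    out: dict = {"regions": {}, "tables": {}, "qc_report": qc_report, "failures": {}}
    for region in regions:
        try:
            sub = ss.extract_region(stats, region)
            sweep, harm, ld, report = discover_region(
                sub, panel, config.thresholds, config.r2_collinear, config.max_iter
            )
            if sweep is None:
                raise RuntimeError("no SNPs harmonized to the reference panel")
            lead = ss.define_lead_snp(sub)
            out["regions"][region.lead_snp_id] = {
                "region": region,
                "sweep": sweep,
                "harm": harm,
                "ld": ld,
                "match_report": report,
                "lead": lead,
            }
        except Exception as exc:  # noqa: BLE001 - per-region isolation
            logger.error("region %s failed: %s", region.lead_snp_id, exc)
            out["failures"][region.lead_snp_id] = str(exc)
    if not out["regions"]:
        raise RuntimeError("discovery failed for every region")
    for t in config.thresholds:
        frames = []
        for label in sorted(out["regions"]):
            info = out["regions"][label]
            res, _trace = info["sweep"][float(t)]
            tab = region_table(info["harm"], info["ld"], res)
            tab.insert(0, "region", label)
            frames.append(tab)
        out["tables"][float(t)] = pd.concat(frames, ignore_index=True)
    logger.info("discovery finished in %.1fs", time.time() - t0)
    return out


def write_discovery(out: dict, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for t, tab in out["tables"].items():
        tab.to_csv(out_dir / f"table1.{_threshold_tag(t)}.tsv", sep="\t", index=False)
    traces = []
    for label in sorted(out["regions"]):
        info = out["regions"][label]
        for t, (_res, trace) in info["sweep"].items():
            tf = trace.to_frame()
            tf.insert(0, "threshold", t)
            tf.insert(0, "region", label)
            traces.append(tf)
    pd.concat(traces, ignore_index=True).to_csv(out_dir / "trace.log", sep="\t", index=False)
    # serialized models for the validation stage
    blob = {}
    for label in sorted(out["regions"]):
        info = out["regions"][label]
        blob[label] = {
            "lead": info["lead"],
            "models": {
                _threshold_tag(t): (
                    None
                    if res is None
                    else {
                        "snps": res.snp_ids,
                        "bJ": [float(x) for x in res.beta_joint],
                        "bJ_se": [float(x) for x in res.se_joint],
                        "pJ": [float(x) for x in res.p_joint],
                    }
                )
                for t, (res, _tr) in info["sweep"].items()
            },
        }
    (out_dir / "discovery.json").write_text(json.dumps(blob, indent=1, sort_keys=True))


def read_phenotype(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    need = {"sample_id", "status", "age", "sex"}
    if not need.issubset(pheno.columns):
        raise ValueError(f"phenotype file needs columns {sorted(need)}")
    return pheno


def _weightsets_for_threshold(stats, regions_info, t) -> tuple[WeightSet, WeightSet, WeightSet] | None:
    """Lead / C/J / combined weight sets at one threshold.

    Only regions whose C/J model is non-empty at the threshold contribute;
    lead SNPs keep their marginal weights, C/J SNPs their joint weights.
    """
    models, leads = {}, []
    for label, info in regions_info.items():
        res, _ = info["sweep"][float(t)]
        if res is None or len(res) == 0:
            continue
        models[label] = res
        leads.append(info["lead"])
    if not models:
        return None
    lead_ws = build_lead_weightset(stats, leads, label=f"lead@{_threshold_tag(t)}")
    cj_ws = build_cj_weightset(models, stats, label=f"cj@{_threshold_tag(t)}")
    both = combine_weightsets(lead_ws, cj_ws, label=f"lead+cj@{_threshold_tag(t)}")
    return lead_ws, cj_ws, both


def _liability_entries(ws: WeightSet, stats: pd.DataFrame, harm_freq: dict) -> list:
    """(odds ratio, risk-allele frequency) per weight SNP.

    The risk allele is the one with positive log-OR: weights with negative
    sign are flipped to the other allele so OR > 1 and freq is complemented.
    """
    freq_map = dict(zip(stats["snp"].astype(str), stats["freq"]))
    freq_map.update(harm_freq)
    out = []
    for rec in ws.entries.itertuples(index=False):
        w = float(rec.weight)
        f = float(freq_map.get(str(rec.snp), np.nan))
        if not np.isfinite(f):
            continue
        if w < 0:
            w, f = -w, 1 - f
        out.append((float(np.exp(w)), f))
    return out


def run_validation(config: RunConfig, discovery: dict) -> dict:
    """GRS model comparison on the validation cohort, per threshold.

    Scores use raw (un-rounded) dosages. Returns {"table": DataFrame,
    "pairs": DataFrame, "report": dict} mirroring the usual
    variance-explained / AUC presentation.
    """
    config.validate_paths(need_validation=True)
    stats = ss.read_ma(config.sumstats)
    val_panel = read_vcf(config.val_panel)
    pheno = read_phenotype(config.phenotype)
    pheno = pheno.set_index("sample_id").loc[val_panel.sample_ids].reset_index()
    if pheno["status"].nunique() < 2:
        raise RuntimeError("validation phenotype must contain both classes")

    model_rows, pair_rows, report_json = [], [], {}
    for t in config.thresholds:
        built = _weightsets_for_threshold(stats, discovery["regions"], t)
        if built is None:
            continue
        lead_ws, cj_ws, both_ws = built
        grs_cols, liab = {}, {}
        for name, ws in [("lead", lead_ws), ("cj", cj_ws), ("lead+cj", both_ws)]:
            grs_cols[name] = score(val_panel, ws)["score"].to_numpy()
            liab[name] = _liability_entries(ws, stats, {})
        rep = prediction_report(pheno, grs_cols, liab, prevalence=config.prevalence)
        models = rep["models"].copy()
        models.insert(0, "threshold", float(t))
        models["n_snps"] = (
            [np.nan] + [len(lead_ws), len(cj_ws), len(both_ws)]
        )
        model_rows.append(models)
        pairs = rep["pairs"].copy()
        pairs.insert(0, "threshold", float(t))
        pair_rows.append(pairs)
        report_json[_threshold_tag(t)] = {
            "models": models.drop(columns="threshold").to_dict("records"),
            "pairs": pairs.drop(columns="threshold").to_dict("records"),
        }
    if not model_rows:
        raise RuntimeError("no threshold produced a non-empty C/J model")
    return {
        "table": pd.concat(model_rows, ignore_index=True),
        "pairs": pd.concat(pair_rows, ignore_index=True),
        "report": report_json,
    }


def write_bundle(sim, out_dir) -> None:
    """Write a simulated scenario as the file bundle the pipeline consumes:
    summary stats (.ma), reference and validation VCFs, phenotype TSV,
    a single-region regions TSV, and the generative truth as JSON."""
    from .ldpanel import write_vcf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss.write_ma(sim.sumstats, out_dir / "sumstats.ma")
    write_vcf(sim.ref_panel, out_dir / "ref.vcf")
    write_vcf(sim.val_panel, out_dir / "val.vcf")
    sim.val_pheno[["sample_id", "status", "age", "sex"]].to_csv(
        out_dir / "pheno.tsv", sep="\t", index=False
    )
    lead = ss.define_lead_snp(sim.sumstats)
    center = int(sim.sumstats.set_index("snp").loc[lead, "bp"])
    pd.DataFrame(
        [
            {
                "lead_snp_id": lead,
                "chrom": sim.scenario.chrom,
                "center_bp": center,
                "half_width_bp": 1_000_000,
            }
        ]
    ).to_csv(out_dir / "regions.tsv", sep="\t", index=False)
    truth = dict(sim.truth)
    truth["label"] = sim.scenario.label
    truth["seed"] = sim.scenario.seed
    truth.pop("realized_ld_ref", None)
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True, default=str))


def write_validation(val: dict, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    val["table"].to_csv(out_dir / "table2.tsv", sep="\t", index=False)
    val["pairs"].to_csv(out_dir / "table2_pairs.tsv", sep="\t", index=False)
    (out_dir / "report.json").write_text(json.dumps(val["report"], indent=1, sort_keys=True))
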