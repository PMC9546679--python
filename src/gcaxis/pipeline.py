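"""End-to-end orchestration: config -> staged analysis -> TSV/JSON outputs.

Stages run in method order (preprocess, consensus modules, subtyping,
survival, differential expression, enrichment, immune scores, genomic
contrasts). Each stage's parameters and seed are echoed into
``provenance.json``; stage results are cached on disk keyed by a content
hash of the stage inputs + parameters, so partial re-runs resume from the
last unchanged stage. Outputs carry no timestamps: a re-run with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import asdict
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import diffexpr as de
from . import enrichment as enr
from . import genomics as gen
from . import io as gio
from . import preprocess as prep
from . import simulate as sim
from . import subtyping as sub
from . import survival as surv

logger = logging.getLogger("gcaxis")

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "glycolysis_set": "GLYCOLYSIS_SIGNATURE",
    "cholesterol_set": "CHOLESTEROL_SIGNATURE",
    "low_expression": {"min_value": 1.0, "min_fraction": 0.5},
    "consensus": {"k_range": [2, 6], "n_reps": 100, "p_item": 0.8, "k": None},
    "subtyping": {"log_scale": True},
    "de": {"lfc_cut": 1.0, "fdr_cut": 0.05, "prior_df": None},
    "gsea": {"n_perm": 200, "weight_p": 1.0},
    "estimate": None,  # {"stromal_set": ..., "immune_set": ...}
    "cox_covariates": {
        "age_group": [">65"],
        "gender": ["Male"],
        "t_stage": ["T3+T4"],
        "stage": ["III+IV"],
        "grade": ["G3+G4"],
        "recurrence": ["YES"],
    },
    "contrast_genes": ["TP53", "CTNNB1", "MYC", "TTN", "MUC16"],
    "cnv_contrasts": [["TP53", "Loss"], ["MYC", "Gain"], ["CTNNB1", "Gain"]],
    "exclusivity_pair": ["TP53", "CTNNB1"],
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _hash(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _StageRunner:
    """Content-hash keyed stage cache under <outdir>/.cache."""

    def __init__(self, outdir: Path):
        self.cache_dir = outdir / ".cache"
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.provenance: dict[str, dict] = {}

    def run(self, name: str, params: dict, upstream_key: str, fn: Callable[[], Any]) -> tuple[Any, str]:
        key = _hash({"stage": name, "params": params, "upstream": upstream_key})
        self.provenance[name] = {"params": params, "key": key}
        cached = self.cache_dir / f"{name}-{key}.pkl"
        if cached.exists():
            logger.info("stage %s: cached (%s)", name, key)
            with open(cached, "rb") as fh:
                return pickle.load(fh), key
        logger.info("stage %s: computing", name)
        result = fn()
        with open(cached, "wb") as fh:
            pickle.dump(result, fh)
        return result, key


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full subtype analysis; returns a results bundle.

    ``config`` is a mapping (or YAML path) with either a ``simulate`` block
    (synthetic cohort) or an ``inputs`` block naming the expression,
    clinical, mutation, CNV and gene-set files. Missing inputs fail before
    any computation.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- pre-flight -------------------------------------------------------
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs either a 'simulate' or an 'inputs' block")
    if "inputs" in cfg and "simulate" not in cfg:
        required = ["expression", "clinical", "gene_sets"]
        missing = [k for k in required if k not in cfg["inputs"]]
        if missing:
            raise ValueError(f"inputs block missing {missing}")
        absent = [
            str(p)
            for k, p in cfg["inputs"].items()
            if k not in ("unit", "tumor_samples") and not Path(p).exists()
        ]
        if absent:
            raise FileNotFoundError(f"input file(s) not found: {absent}")

    runner = _StageRunner(outdir)
    seed = int(cfg["seed"])

    # ---- stage: load / simulate ------------------------------------------
    def load_stage():
        if "simulate" in cfg:
            sim_cfg = sim.SimulationConfig(**{**cfg["simulate"], "seed": seed})
            cohort = sim.simulate_cohort(sim_cfg)
            return {
                "expression": cohort.expression,
                "clinical": cohort.clinical,
                "mutations": cohort.mutations,
                "cnv": cohort.cnv,
                "gene_sets": cohort.gene_sets,
                "tumor_samples": cohort.tumor_samples,
                "normal_samples": cohort.normal_samples,
                "truth": cohort.truth,
            }
        inp = cfg["inputs"]
        unit = gio.Unit(inp.get("unit", "TPM"))
        expression = gio.read_expression(inp["expression"], unit)
        clinical = gio.read_clinical(inp["clinical"])
        mutations = gio.read_mutations(inp["mutations"]) if "mutations" in inp else None
        cnv = gio.read_cnv(inp["cnv"]) if "cnv" in inp else None
        tumor = inp.get("tumor_samples") or clinical.sample_ids
        normal = [s for s in expression.sample_ids if s not in set(tumor)]
        return {
            "expression": expression,
            "clinical": clinical,
            "mutations": mutations,
            "cnv": cnv,
            "gene_sets": gio.read_gmt(inp["gene_sets"]),
            "tumor_samples": list(tumor),
            "normal_samples": normal,
            "truth": None,
        }

    load_params = {"simulate": cfg.get("simulate"), "inputs": cfg.get("inputs"), "seed": seed}
    data, key = runner.run("load", load_params, "", load_stage)

    # ---- stage: preprocess ------------------------------------------------
    def preprocess_stage():
        m = prep.collapse_duplicate_symbols(data["expression"])
        if m.unit is gio.Unit.FPKM:
            m = gio.fpkm_to_tpm(m)
        clin, tumor_expr = prep.filter_samples_with_followup(data["clinical"], m)
        tumor = [s for s in data["tumor_samples"] if s in set(clin.sample_ids)]
        filtered, dropped = prep.filter_low_expression(m, **cfg["low_expression"])
        sig = prep.extract_signature_matrix(
            filtered, data["gene_sets"], [cfg["glycolysis_set"], cfg["cholesterol_set"]]
        )
        return {"matrix": m, "filtered": filtered, "signature": sig,
                "clinical": clin, "tumor_samples": tumor, "dropped_genes": dropped}

    pre, key = runner.run("preprocess", cfg["low_expression"], key, preprocess_stage)
    gio.write_expression(pre["signature"], outdir / "signature_matrix.tsv")

    # ---- stage: consensus modules ----------------------------------------
    ccfg = cfg["consensus"]

    def consensus_stage():
        sig_tumor = pre["signature"].subset_samples(pre["tumor_samples"])
        if ccfg.get("k"):
            ks = [int(ccfg["k"])]
        else:
            lo, hi = ccfg["k_range"]
            ks = list(range(int(lo), int(hi) + 1))
        results = cns.consensus_cluster(
            sig_tumor, ks, n_reps=int(ccfg["n_reps"]), p_item=float(ccfg["p_item"]), seed=seed
        )
        if len(results) > 1:
            sel = cns.select_k(results)
            chosen = next(r for r in results if r.k == sel.k)
            k_report = {"k": sel.k, "areas": sel.areas,
                        "relative_increase": sel.relative_increase, "threshold": sel.threshold}
        else:
            chosen = results[0]
            k_report = {"k": chosen.k, "areas": {chosen.k: chosen.cdf_area}}
        modules = cns.label_modules(
            chosen.assignments, data["gene_sets"], cfg["glycolysis_set"], cfg["cholesterol_set"]
        )
        return {"chosen": chosen, "k_report": k_report, "modules": modules}

    cons, key = runner.run("consensus", ccfg, key, consensus_stage)
    _write_tsv(cons["chosen"].consensus, outdir / "consensus_matrix.tsv")
    with open(outdir / "k_selection.json", "w") as fh:
        json.dump(cons["k_report"], fh, indent=1, sort_keys=True)
    pd.DataFrame(
        sorted(cons["chosen"].assignments.items()), columns=["gene", "cluster"]
    ).to_csv(outdir / "gene_clusters.tsv", sep="\t", index=False)

    # ---- stage: subtyping --------------------------------------------------
    def subtype_stage():
        scores = sub.compute_axis_scores(
            pre["matrix"], cons["modules"], pre["tumor_samples"],
            log_scale=bool(cfg["subtyping"]["log_scale"]),
        )
        return sub.assign_subtype(scores)

    calls, key = runner.run("subtype", cfg["subtyping"], key, subtype_stage)
    calls_out = calls.copy()
    calls_out.index.name = "sample_id"
    _write_tsv(calls_out, outdir / "subtype_calls.tsv")

    recovery = None
    if data["truth"] is not None:
        truth = pd.Series(data["truth"]["subtype"]).loc[calls.index]
        acc, ari, confusion = sim.evaluate_recovery(calls, truth)
        recovery = {"accuracy": acc, "ari": ari}
        _write_tsv(confusion, outdir / "recovery_confusion.tsv")

    # ---- stage: survival ----------------------------------------------------
    def survival_stage():
        clin = pre["clinical"].data.loc[calls.index]
        t = clin["os_time_days"].to_numpy()
        e = clin["os_event"].to_numpy()
        labels = calls["subtype"].astype(str).to_numpy()
        overall = surv.logrank_test(t, e, labels)
        pairwise = surv.pairwise_logrank(t, e, labels)
        km = {}
        for s in np.unique(labels):
            mask = labels == s
            km[s] = surv.km_estimate(t[mask], e[mask])
        # Cox: binary-coded clinical contrasts + one-vs-rest subtype indicators
        coded = pd.DataFrame(index=clin.index)
        for var, positive in cfg["cox_covariates"].items():
            if var in clin.columns:
                coded[var] = surv.code_binary(clin[var], positive)
        onehot = surv.subtype_onehot(calls)
        cox_input = gio.ClinicalTable(
            pd.concat([clin[["os_time_days", "os_event"]], coded, onehot], axis=1)
        )
        uni = surv.cox_fit(
            cox_input, list(coded.columns) + list(onehot.columns), model="univariate"
        )
        multi_parts = []
        for s in onehot.columns:
            part = surv.cox_fit(
                cox_input, list(coded.columns) + [s], model="multivariate"
            )
            part["contrast"] = s
            multi_parts.append(part)
        multi = pd.concat(multi_parts, ignore_index=True)
        return {"overall": overall, "pairwise": pairwise, "km": km, "uni": uni, "multi": multi}

    sv, key = runner.run("survival", {"covariates": cfg["cox_covariates"]}, key, survival_stage)
    _write_tsv(sv["pairwise"], outdir / "logrank_pairwise.tsv", index=False)
    _write_tsv(sv["uni"], outdir / "cox_univariate.tsv", index=False)
    _write_tsv(sv["multi"], outdir / "cox_multivariate.tsv", index=False)
    km_rows = []
    for s, curve in sv["km"].items():
        for t_, p_, r_ in zip(curve.times, curve.survival, curve.at_risk):
            km_rows.append({"subtype": s, "time": t_, "survival": p_, "at_risk": r_})
    _write_tsv(pd.DataFrame(km_rows), outdir / "km_curves.tsv", index=False)

    # ---- stage: differential expression ------------------------------------
    def de_stage():
        mixed = calls.index[calls["subtype"] == "Mixed"].tolist()
        quiescent = calls.index[calls["subtype"] == "Quiescent"].tolist()
        if len(mixed) < 2 or len(quiescent) < 2:
            raise RuntimeError("Mixed/Quiescent groups too small for DE")
        log_m = gio.log2_tpm1(pre["filtered"])
        table = de.de_analysis(
            log_m, mixed, quiescent,
            prior_df=cfg["de"]["prior_df"],
            lfc_cut=cfg["de"]["lfc_cut"], fdr_cut=cfg["de"]["fdr_cut"],
        )
        up, down = de.select_degs(table, cfg["de"]["lfc_cut"], cfg["de"]["fdr_cut"])
        return {"table": table, "up": up, "down": down,
                "groups": {"Mixed": mixed, "Quiescent": quiescent}}

    dres, key = runner.run("de", cfg["de"], key, de_stage)
    det = dres["table"].copy()
    det.index.name = "gene"
    _write_tsv(det[["log2fc", "t", "p", "fdr", "direction"]], outdir / "de_mixed_vs_quiescent.tsv")

    # ---- stage: enrichment ---------------------------------------------------
    def enrich_stage():
        background = dres["table"].index.tolist()
        out: dict[str, Any] = {}
        for direction in ("up", "down"):
            degs = dres[direction]
            out[f"ora_{direction}"] = (
                enr.ora_test(degs, background, data["gene_sets"]) if degs else None
            )
        log_m = gio.log2_tpm1(pre["filtered"])
        out["gsea"] = enr.gsea_test(
            log_m,
            dres["groups"]["Mixed"],
            dres["groups"]["Quiescent"],
            data["gene_sets"],
            n_perm=int(cfg["gsea"]["n_perm"]),
            seed=seed,
            weight_p=float(cfg["gsea"]["weight_p"]),
        )
        return out

    enres, key = runner.run("enrich", cfg["gsea"], key, enrich_stage)
    for direction in ("up", "down"):
        t = enres[f"ora_{direction}"]
        if t is not None:
            _write_tsv(t, outdir / f"ora_{direction}.tsv")
    _write_tsv(enres["gsea"], outdir / "gsea_mixed_vs_quiescent.tsv")

    # ---- stage: immune scores ------------------------------------------------
    immune = None
    if cfg.get("estimate"):
        est_cfg = cfg["estimate"]

        def immune_stage():
            tumor_m = pre["filtered"].subset_samples(pre["tumor_samples"])
            scores = enr.estimate_scores(
                tumor_m, data["gene_sets"], est_cfg["stromal_set"], est_cfg["immune_set"]
            )
            tests = {}
            labels = calls["subtype"].astype(str).loc[scores.table.index]
            for col in scores.table.columns:
                h, p = gen.kruskal_wallis(scores.table[col].to_numpy(), labels.to_numpy())
                tests[col] = {"H": h, "p": p}
            return {"scores": scores.table, "tests": tests}

        immune, key = runner.run("immune", est_cfg, key, immune_stage)
        st = immune["scores"].copy()
        st.index.name = "sample_id"
        _write_tsv(st, outdir / "estimate_scores.tsv")

    # ---- stage: genomic contrasts ---------------------------------------------
    def genomics_stage():
        out: dict[str, Any] = {}
        if data["mutations"] is not None:
            out["mutation_freq"] = gen.mutation_frequency_by_subtype(
                data["mutations"], calls, cfg["contrast_genes"]
            )
            ga, gb = cfg["exclusivity_pair"]
            odds, p, counts = gen.mutual_exclusivity(
                data["mutations"], ga, gb, samples=list(calls.index)
            )
            out["exclusivity"] = {"genes": [ga, gb], "odds_ratio": odds, "p": p,
                                  "counts": counts}
        if data["cnv"] is not None:
            parts = [
                gen.cnv_proportion_test(data["cnv"], calls, g, s)
                for g, s in cfg["cnv_contrasts"]
            ]
            out["cnv"] = pd.concat(parts, ignore_index=True) if parts else None
        # tumor subtypes + normal: per-signature-gene Kruskal-Wallis
        normals = [s for s in data["normal_samples"] if s in pre["filtered"].data.columns]
        if normals:
            all_samples = list(calls.index) + normals
            labels = calls["subtype"].astype(str).tolist() + ["Normal"] * len(normals)
            log_m = gio.log2_tpm1(pre["filtered"].subset_samples(all_samples))
            sig_genes = cons["modules"].glycolysis_module + cons["modules"].cholesterol_module
            rows = []
            for g in sig_genes:
                h, p = gen.kruskal_wallis(log_m.data.loc[g].to_numpy(), labels)
                med_norm = float(np.median(log_m.data.loc[g, normals]))
                med_tum = float(np.median(log_m.data.loc[g, list(calls.index)]))
                rows.append({"gene": g, "H": h, "p": p,
                             "median_normal": med_norm, "median_tumor": med_tum})
            out["tumor_vs_normal"] = pd.DataFrame(rows)
        return out

    gn, key = runner.run(
        "genomics",
        {"genes": cfg["contrast_genes"], "cnv": cfg["cnv_contrasts"],
         "pair": cfg["exclusivity_pair"]},
        key,
        genomics_stage,
    )
    if "mutation_freq" in gn:
        _write_tsv(gn["mutation_freq"], outdir / "mutation_frequency.tsv", index=False)
    if gn.get("cnv") is not None:
        _write_tsv(gn["cnv"], outdir / "cnv_proportions.tsv", index=False)
    if "tumor_vs_normal" in gn:
        _write_tsv(gn["tumor_vs_normal"], outdir / "tumor_vs_normal.tsv", index=False)

    # ---- provenance + report ----------------------------------------------
    with open(outdir / "provenance.json", "w") as fh:
        json.dump({"seed": seed, "stages": runner.provenance}, fh, indent=1, sort_keys=True)
    counts = sub.subtype_counts(calls)
    report = [
        "# Metabolic subtyping report",
        "",
        f"- samples subtyped: {len(calls)}",
        f"- selected k: {cons['k_report']['k']}",
        f"- glycolysis module ({len(cons['modules'].glycolysis_module)} genes): "
        + ", ".join(cons["modules"].glycolysis_module),
        f"- cholesterol module ({len(cons['modules'].cholesterol_module)} genes): "
        + ", ".join(cons["modules"].cholesterol_module),
        "",
        "## Subtype counts",
        "",
        counts.to_string(),
        "",
        "## Survival",
        "",
        f"- overall log-rank: chi2={sv['overall'].statistic:.3f}, "
        f"df={sv['overall'].df}, p={sv['overall'].p:.3g}",
        "",
        "## Differential expression (Mixed vs Quiescent)",
        "",
        f"- up-regulated DEGs: {len(dres['up'])}",
        f"- down-regulated DEGs: {len(dres['down'])}",
    ]
    if recovery is not None:
        report += ["", "## Recovery vs planted truth", "",
                   f"- subtype accuracy: {recovery['accuracy']:.3f}",
                   f"- subtype ARI: {recovery['ari']:.3f}"]
    (outdir / "report.md").write_text("\n".join(report) + "\n")

    return {
        "outdir": outdir,
        "calls": calls,
        "modules": cons["modules"],
        "k_report": cons["k_report"],
        "survival": sv,
        "de": dres,
        "enrichment": enres,
        "immune": immune,
        "genomics": gn,
        "recovery": recovery,
        "provenance": runner.provenance,
        "preprocessed": pre,
        "data": data,
    }
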