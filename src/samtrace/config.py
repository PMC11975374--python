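"""Pipeline orchestration: config validation, seeded stage execution,
fixture generation and the run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, expression, fixtures, isotopologue, phenotypes
from .pathway import (
    CohortSpec,
    NoiseSpec,
    arm_label,
    build_scenario,
    emit_peak_table,
    emit_supernatant_table,
    simulate_cohort,
    simulate_tracer,
)

logger = logging.getLogger(__name__)

STAGES = ("tracer", "phenotypes", "expression")

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["tracer", "phenotypes", "expression"],
    "scenario": {
        "genotypes": ["control", "Ahcy-RNAi"],
        "infections": [False, True],
        "tracer": "Met-13C5",
        "n_replicates": 3,
    },
    "noise": {"sd": 0.15, "detection_floor": 0.0},
    "cohort": {"n_per_arm": 250},
}

_SCHEMA = {
    "seed": int,
    "stages": list,
    "scenario": dict,
    "noise": dict,
    "cohort": dict,
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config root must be a mapping")
        for key, value in user.items():
            if key not in _SCHEMA:
                raise ValueError(f"unknown config key {key!r}")
            if not isinstance(value, _SCHEMA[key]):
                raise ValueError(
                    f"config key {key!r} expects {_SCHEMA[key].__name__}, "
                    f"got {type(value).__name__}")
            if isinstance(value, dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    for stage in cfg["stages"]:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {stage: int(child.generate_state(1)[0] % (2**31))
            for stage, child in zip(STAGES, children)}


def run_tracer_stage(cfg: dict, seed: int, out: Path) -> dict:
    sc = cfg["scenario"]
    tracer = sc["tracer"]
    n_rep = int(sc["n_replicates"])
    results = {}
    for genotype in sc["genotypes"]:
        for infected in sc["infections"]:
            scen = build_scenario(genotype=genotype, infected=infected,
                                  tracer=tracer)
            res = simulate_tracer(scen)
            group = arm_label(genotype, infected)
            for rep in range(n_rep):
                results[f"{group}_r{rep + 1}"] = (group, res)

    noise = NoiseSpec(sd=cfg["noise"]["sd"],
                      detection_floor=cfg["noise"]["detection_floor"],
                      seed=seed)
    table = emit_peak_table(results, noise)
    supernatant, protein = emit_supernatant_table(results, noise)
    table.to_csv(out / "peak_table.tsv", sep="\t", index=False)
    supernatant.to_csv(out / "supernatant.tsv", sep="\t", index=False)

    reference = next(s for s, (g, _) in results.items() if "Uninf" in g)
    nf = isotopologue.normalization_factors(table, reference)
    normalized = isotopologue.normalize(table, nf)
    fractions = isotopologue.isotopologue_fractions(normalized)
    fractions.to_csv(out / "fractions.tsv", sep="\t", index=False)
    mi = isotopologue.methylation_index(normalized)

    summary: dict = {
        "tracer": tracer,
        "reference_sample": reference,
        "normalization_factors": nf.to_dict(),
        "methylation_index": mi.attrs.get("group_summary", {}),
    }
    if tracer == "Met-13C5":
        scen0 = build_scenario(genotype="control", infected=False, tracer=tracer)
        medium = {"m+4": scen0.tracer_impurity, "m+5": 1 - scen0.tracer_impurity}
        met_fr = fractions[fractions["metabolite"] == "methionine"]
        cell = (met_fr.groupby("isotopologue")["fraction"].mean()).to_dict()
        verdict = isotopologue.remethylation_test(cell, medium)
        summary["remethylation"] = {
            "r_cell": verdict.r_cell, "r_medium": verdict.r_medium,
            "detected": verdict.remethylation_detected}
        summary["labeled_met_fraction_by_group"] = (
            fractions[fractions["metabolite"] == "methionine"]
            .query("isotopologue != 'm+0'")
            .groupby("group")["fraction"].sum().to_dict())
    if tracer == "Ado-13C5":
        rec = {}
        for group in sorted({g for g, _ in results.values()}):
            sub = fractions[fractions["group"] == group]
            sam5 = sub.query(
                "metabolite == 'SAM' and isotopologue == 'm+5'")["fraction"].mean()
            atp5 = sub.query(
                "metabolite == 'ATP' and isotopologue == 'm+5'")["fraction"].mean()
            rec[group] = isotopologue.recycling_fraction(sam5, atp5)
        summary["recycling_fraction"] = rec

    purines = isotopologue.extracellular_purines(supernatant, protein)
    summary["extracellular_purines"] = purines.attrs.get("group_summary", {})
    _write_json(out / "tracer_summary.json", summary)
    return summary


def run_phenotype_stage(cfg: dict, seed: int, out: Path) -> dict:
    spec = CohortSpec(seed=seed, **cfg["cohort"])
    records = simulate_cohort(spec)
    records.to_csv(out / "cohort.tsv", sep="\t", index=False)

    summary: dict = {"delays": {}, "logrank": {}, "survival": {},
                     "lamellocytes": {}}
    genotypes = sorted(records["genotype"].unique())
    for genotype in genotypes:
        a, b = arm_label(genotype, False), arm_label(genotype, True)
        est = phenotypes.pupation_delay(records, a, b, seed=seed)
        summary["delays"][genotype] = {
            "delta_h": est.delta_h, "ci95": est.ci95,
            "t50_uninfected": est.t50_a, "t50_infected": est.t50_b}
        summary["logrank"][genotype] = phenotypes.logrank(records, a, b)
    surv = phenotypes.survival_to_adult(records)
    summary["survival"] = surv.set_index("arm")["percent_survival"].to_dict()
    infected = records[records["infected"]]
    if not infected.empty:
        lam = phenotypes.lamellocyte_summary(
            infected, control_arm=arm_label("control", True))
        summary["lamellocytes"] = lam.set_index("arm").to_dict("index")
    _write_json(out / "phenotype_summary.json", summary)
    return summary


def run_expression_stage(cfg: dict, seed: int, out: Path) -> dict:
    counts = fixtures.synth_counts(seed=seed)
    counts.to_csv(out / "counts.tsv", sep="\t")
    tpm = expression.tpm(counts)
    thr = expression.threshold_summary(tpm, 15.0)
    ct = fixtures.synth_ct_table(seed=seed)
    ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)
    folds = expression.ddct(ct, reference_gene="RpL32", calibrator="0hpi")
    de9, de18, gene_set = fixtures.synth_de_tables(seed=seed)
    de9.to_csv(out / "de_9hpi.tsv", sep="\t", index=False)
    de18.to_csv(out / "de_18hpi.tsv", sep="\t", index=False)
    both = expression.count_significant_in_both(de9, de18, gene_set)
    summary = {
        "tpm_fraction_above_15": thr["overall"],
        "ddct_mean_fold_by_condition_gene": (
            folds.groupby(["condition", "gene"])["fold_change"].mean()
            .unstack().round(4).to_dict()),
        "significant_at_both_timepoints": both["count"],
    }
    _write_json(out / "expression_summary.json", summary)
    return summary


def run_pipeline(config_path: str | Path | None, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Execute the requested stages in dependency order.

    Writes delimited tables, JSON summaries and a run manifest into
    ``out_dir``; identical config+seed give byte-identical tables and
    summaries.
    """
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])

    runners = {"tracer": run_tracer_stage,
               "phenotypes": run_phenotype_stage,
               "expression": run_expression_stage}
    for stage in STAGES:
        if stage in cfg["stages"]:
            logger.info("running stage %s", stage)
            runners[stage](cfg, seeds[stage], out)

    write_manifest(cfg, out)
    return out


def write_manifest(cfg: dict, out: Path) -> Path:
    """Run manifest: config hash, seeds, versions and output checksums."""
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    files = {}
    for path in sorted(out.glob("*")):
        if path.name == "manifest.json" or not path.is_file():
            continue
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    outputs_hash = hashlib.sha256(
        json.dumps(files, sort_keys=True).encode()).hexdigest()
    manifest = {
        "config_hash": config_hash,
        "seed": cfg["seed"],
        "stage_seeds": _stage_seeds(cfg["seed"]),
        "version": __version__,
        "outputs": files,
        "outputs_hash": outputs_hash,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out / "manifest.json"
    _write_json(path, manifest)
    return path


def make_fixtures(seed: int, out_dir: str | Path) -> list[Path]:
    """Write the small bundled datasets (peak, supernatant, Ct, counts, DE,
    cohort tables); bit-identical for equal seeds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)

    scen = build_scenario(genotype="control", infected=True, tracer="Met-13C5")
    res = simulate_tracer(scen)
    results = {f"INF_r{i + 1}": (arm_label("control", True), res)
               for i in range(3)}
    noise = NoiseSpec(sd=0.15, seed=seeds["tracer"])
    emit_peak_table(results, noise).to_csv(
        out / "peak_table.tsv", sep="\t", index=False)
    sup, _ = emit_supernatant_table(results, noise)
    sup.to_csv(out / "supernatant.tsv", sep="\t", index=False)

    spec = CohortSpec(n_per_arm=100, seed=seeds["phenotypes"])
    simulate_cohort(spec, arms=[("control", False), ("control", True)]).to_csv(
        out / "cohort.tsv", sep="\t", index=False)

    fixtures.synth_ct_table(seed=seeds["expression"]).to_csv(
        out / "ct_table.tsv", sep="\t", index=False)
    fixtures.synth_counts(seed=seeds["expression"], n_genes=500,
                          depth=200_000).to_csv(out / "counts.tsv", sep="\t")
    de9, de18, _ = fixtures.synth_de_tables(seed=seeds["expression"])
    de9.to_csv(out / "de_9hpi.tsv", sep="\t", index=False)
    de18.to_csv(out / "de_18hpi.tsv", sep="\t", index=False)
    return sorted(out.glob("*.tsv"))
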