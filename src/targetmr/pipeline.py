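"""Per-drug-class orchestration: select → harmonize → gate → MR → coloc.

For each drug class the pipeline selects cis instruments (a primary run at
the strict clumping threshold and a sensitivity run at the relaxed one),
harmonizes them against the outcome, optionally checks the positive-control
gate, runs the MR estimator battery, and — for classes whose primary
estimate survives the Bonferroni gate — colocalizes the regional exposure
and outcome signals.  Every class ends in an explicit status: ``analyzed``,
``gate-failed`` or ``no-instruments``.  The run is deterministic given the
config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import coloc as coloc_mod
from .controls import default_expectations, evaluate_gate
from .estimators import MrConfig, MrResult, run_mr
from .harmonize import align_datasets
from .selection import InstrumentSet, SelectionParams, select_instruments
from .sumstats import (
    DrugTarget,
    LdReference,
    SummaryDataset,
    load_drug_targets,
    read_ld,
    read_sumstats,
)

__all__ = ["ControlInput", "PipelineConfig", "run_pipeline", "write_report"]

logger = logging.getLogger("targetmr")

VERSION = "0.1.0"


@dataclass(frozen=True)
class ControlInput:
    """One positive-control outcome dataset."""

    name: str
    path: str
    trait_type: str = "binary"
    n_cases: int | None = None
    n_controls: int | None = None


@dataclass
class PipelineConfig:
    exposure_path: str = ""
    outcome_path: str = ""
    ld_path: str = ""
    targets_path: str | None = None
    controls: list[ControlInput] = field(default_factory=list)
    outcome_trait_type: str = "binary"
    outcome_n_cases: int | None = None
    outcome_n_controls: int | None = None
    window_bp: int = 2_500
    fdr_threshold: float = 0.05
    clump_r2: float = 0.001
    relaxed_clump_r2: float = 0.1
    proxy_r2: float = 0.8
    palindrome_maf: float = 0.3
    functional_variants: dict[str, list[str]] = field(default_factory=dict)
    alpha: float = 0.05
    n_tests: int = 6
    scale_factor: float = -0.1
    bootstrap_reps: int = 10_000
    coloc_flank_bp: int = 200_000
    seed: int = 0
    out_dir: str = "targetmr_out"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        controls = [ControlInput(**c) for c in raw.pop("controls", [])]
        return cls(controls=controls, **raw)

    def selection_params(self, clump_r2: float | None = None) -> SelectionParams:
        return SelectionParams(
            window_bp=self.window_bp,
            fdr_threshold=self.fdr_threshold,
            clump_r2=self.clump_r2 if clump_r2 is None else clump_r2,
            proxy_r2=self.proxy_r2,
            palindrome_maf=self.palindrome_maf,
        )

    def mr_config(self) -> MrConfig:
        return MrConfig(
            scale_factor=self.scale_factor,
            alpha=self.alpha,
            n_tests=self.n_tests,
            bootstrap_reps=self.bootstrap_reps,
            seed=self.seed,
        )


def _mr_for_outcome(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    target: DrugTarget,
    panel: LdReference,
    params: SelectionParams,
    mr_config: MrConfig,
    forced_rsids: list[str] | None = None,
    clump_seed_rsids: list[str] | None = None,
) -> tuple[InstrumentSet, list[MrResult]]:
    iset = select_instruments(
        exposure, outcome, target, panel, params, forced_rsids, clump_seed_rsids
    )
    hs, drops = align_datasets(iset, outcome, panel)
    iset.exclusions.extend(drops)
    results = run_mr(hs, target.drug_class, mr_config, mean_f=iset.mean_f)
    return iset, results


def _result_dict(res: MrResult) -> dict:
    d = {
        "method": res.method,
        "theta": res.theta,
        "se": res.se,
        "n_instruments": res.n_instruments,
        "mean_f": res.mean_f,
        "or_scaled": res.or_scaled,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "pval": res.pval,
        "bonferroni_significant": res.bonferroni_significant,
    }
    if res.egger_intercept is not None:
        d["egger_intercept"] = res.egger_intercept
        d["egger_intercept_se"] = res.egger_intercept_se
    return d


def _iset_dict(iset: InstrumentSet) -> dict:
    return {
        "n": len(iset),
        "rsids": [ins.rsid for ins in iset.instruments],
        "mean_f": None if not len(iset) else iset.mean_f,
        "weak": iset.is_weak,
        "proxies": {
            ins.rsid: {"proxy_of": ins.proxy_of, "r2": ins.proxy_r2}
            for ins in iset.instruments
            if ins.proxy_of is not None
        },
        "n_excluded": len(iset.exclusions),
    }


def _coloc_region(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    target: DrugTarget,
    flank_bp: int,
    cfg: coloc_mod.ColocConfig,
) -> coloc_mod.ColocResult | None:
    shared = []
    for rec in exposure:
        if rec.rsid not in outcome:
            continue
        for g in target.genes:
            if rec.chrom == g.chrom and g.start - flank_bp <= rec.pos <= g.end + flank_bp:
                shared.append(rec.rsid)
                break
    if not shared:
        return None
    ex = [exposure[r] for r in shared]
    oy = [outcome[r] for r in shared]
    abf_x = coloc_mod.trait_abf(
        np.array([r.beta for r in ex]),
        np.array([r.se for r in ex]),
        exposure.trait_type,
        cfg,
        eaf=np.array([r.eaf for r in ex]),
        n=np.array([r.n for r in ex]),
    )
    abf_y = coloc_mod.trait_abf(
        np.array([r.beta for r in oy]),
        np.array([r.se for r in oy]),
        outcome.trait_type,
        cfg,
        eaf=np.array([r.eaf for r in oy]),
        n=np.array([r.n for r in oy]),
    )
    label = "+".join(g.gene for g in target.genes)
    return coloc_mod.coloc_posteriors(abf_x, abf_y, cfg, region=label)


def run_pipeline(
    config: PipelineConfig,
    exposure: SummaryDataset | None = None,
    outcome: SummaryDataset | None = None,
    panel: LdReference | None = None,
    targets: list[DrugTarget] | None = None,
    control_datasets: dict[str, SummaryDataset] | None = None,
) -> dict:
    """Run the full analysis and return the report as a plain dict.

    Datasets may be passed in memory; otherwise they are read from the
    paths in ``config``.
    """
    if exposure is None:
        exposure = read_sumstats(config.exposure_path, "exposure", "continuous")
    if outcome is None:
        outcome = read_sumstats(
            config.outcome_path,
            "outcome",
            config.outcome_trait_type,
            n_cases=config.outcome_n_cases,
            n_controls=config.outcome_n_controls,
        )
    if panel is None:
        panel = read_ld(config.ld_path)
    if targets is None:
        targets = load_drug_targets(config.targets_path)
    if control_datasets is None:
        control_datasets = {
            c.name: read_sumstats(c.path, c.name, c.trait_type, n_cases=c.n_cases, n_controls=c.n_controls)
            for c in config.controls
        }

    mr_cfg = config.mr_config()
    primary_params = config.selection_params()
    relaxed_params = config.selection_params(config.relaxed_clump_r2)
    expectations = default_expectations()

    report: dict = {
        "provenance": {
            "version": VERSION,
            "seed": config.seed,
            "config": _config_dict(config),
        },
        "classes": {},
    }

    analyses: list[tuple[str, DrugTarget, list[str] | None]] = []
    for target in targets:
        analyses.append((target.drug_class, target, None))
        for rsid_list in ([config.functional_variants[target.drug_class]]
                          if target.drug_class in config.functional_variants else []):
            analyses.append((f"{target.drug_class} (functional variant)", target, rsid_list))

    for label, target, forced in analyses:
        logger.info("analyzing %s", label)
        entry: dict = {"status": "analyzed", "gate": None, "mr": {}, "coloc": None}

        iset, primary_results = _mr_for_outcome(
            exposure, outcome, target, panel, primary_params, mr_cfg, forced
        )
        entry["instruments"] = _iset_dict(iset)
        entry["exclusions"] = [
            {"rsid": e.rsid, "stage": e.stage, "reason": e.reason} for e in iset.exclusions
        ]

        if not len(iset):
            entry["status"] = "no-instruments"
            report["classes"][label] = entry
            continue

        # positive-control gate (only when control outcomes were supplied)
        if control_datasets and forced is None:
            control_results: dict[str, MrResult] = {}
            for name, ds in control_datasets.items():
                _, c_res = _mr_for_outcome(
                    exposure, ds, target, panel, primary_params, mr_cfg
                )
                if c_res:
                    control_results[name] = c_res[0]
            gate = evaluate_gate(target.drug_class, control_results, expectations)
            entry["gate"] = {
                "passed": gate.passed,
                "reasons": gate.reasons,
                "checks": [
                    {
                        "outcome": c.outcome,
                        "expected": c.expected,
                        "observed_sign": c.observed_sign,
                        "concordant": c.concordant,
                    }
                    for c in gate.checks
                ],
            }
            if not gate.passed:
                entry["status"] = "gate-failed"
                report["classes"][label] = entry
                continue

        entry["mr"]["primary"] = [_result_dict(r) for r in primary_results]
        # sensitivity: relaxed clumping nested on the primary instruments,
        # so the relaxed set is a superset of the primary one
        primary_seed = [ins.proxy_of or ins.rsid for ins in iset.instruments]
        _, relaxed_results = _mr_for_outcome(
            exposure, outcome, target, panel, relaxed_params, mr_cfg, forced, primary_seed
        )
        entry["mr"]["sensitivity_relaxed_clumping"] = [_result_dict(r) for r in relaxed_results]

        head = primary_results[0] if primary_results else None
        if head is not None and head.bonferroni_significant:
            cres = _coloc_region(
                exposure, outcome, target, config.coloc_flank_bp, coloc_mod.ColocConfig()
            )
            if cres is not None:
                entry["coloc"] = {
                    "region": cres.region,
                    "n_variants": cres.n_variants,
                    "posteriors": cres.posteriors,
                    "priors": {
                        "p1": cres.config.p1,
                        "p2": cres.config.p2,
                        "p12": cres.config.p12,
                    },
                }
        report["classes"][label] = entry

    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["controls"] = [dataclasses.asdict(c) for c in config.controls]
    return d


def write_report(report: dict, out_dir: str) -> None:
    """Write the JSON report, the flat results TSV and the exclusion log."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    rows = ["\t".join([
        "drug_class", "run", "method", "n_instruments", "mean_f",
        "or_scaled", "ci_low", "ci_high", "pval", "bonferroni_significant",
    ])]
    excl = ["rsid\tstage\treason\tdrug_class"]
    for label, entry in report["classes"].items():
        for run, results in (entry.get("mr") or {}).items():
            for r in results:
                rows.append("\t".join(str(x) for x in [
                    label, run, r["method"], r["n_instruments"],
                    f"{r['mean_f']:.6g}", f"{r['or_scaled']:.6g}",
                    f"{r['ci_low']:.6g}", f"{r['ci_high']:.6g}",
                    f"{r['pval']:.6g}", r["bonferroni_significant"],
                ]))
        for e in entry.get("exclusions", []):
            excl.append(f"{e['rsid']}\t{e['stage']}\t{e['reason']}\t{label}")
    with open(os.path.join(out_dir, "results.tsv"), "w") as fh:
        fh.write("\n".join(rows) + "\n")
    with open(os.path.join(out_dir, "exclusions.tsv"), "w") as fh:
        fh.write("\n".join(excl) + "\n")
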