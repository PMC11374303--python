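"""Configuration-driven orchestration of the full analysis chain.

Stages run in dependency order — differential abundance, enrichment
scoring, anchor-set classifier, enrichment calls, SEC co-elution,
substrate set logic, structural proximity — each writing its tabular
artifact under the output directory.  A single master seed fans out to
per-stage seeds through :func:`numpy.random.SeedSequence` with a fixed
per-stage index, so any stage can be rerun in isolation and identical
config + seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .classifier import (AnchorSets, call_enriched, call_enriched_by_cutoff,
                         compute_enrichment_scores, fit_enrichment_classifier)
from .coelution import (bait_correlations, compare_enriched_correlations,
                        normalize_profiles, window_signal_fraction)
from .diffabund import run_differential
from .structure import anchor_point, load_structure, site_anchor_distances
from .substrates import annotate_candidates, enriched_ids, exclusive_enriched_set

log = logging.getLogger("proxiscore")

STAGES = ("differential", "classify", "coelution", "substrates", "structure")


@dataclass
class PipelineConfig:
    """Paths, stage toggles and numeric parameters for one run."""

    quant_table: str | None = None
    design: str | None = None
    anchors_positive: str | None = None
    anchors_negative: str | None = None
    sec_run: str | None = None
    structure_file: str | None = None
    sites: str | None = None
    ups_list: str | None = None
    substrate_list: str | None = None
    ubi_responsive_list: str | None = None
    out_dir: str = "proxiscore_out"

    conditions: list[str] = field(default_factory=lambda: ["main"])
    treated_condition: str | None = None
    control_condition: str | None = None
    bait_id: str | None = None
    bait_chain: str | None = None

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    normalize: bool = True
    impute: str = "none"
    storey_lambda: float | str = 0.5
    target_fpr: float = 0.05
    call_mode: str = "classifier"  # or "cutoff"
    fc_cutoff: float = 1.0
    q_cutoff: float = 0.05
    n_folds: int = 10
    n_repeats: int = 30
    min_fractions: int = 5
    radius_A: float = 100.0
    sec_windows: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = io.load_config(path)
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0]
                   % (2**31))


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Cross-check file existence and identifier consistency; returns the
    itemized error list (empty = valid)."""
    errors: list[str] = []

    def need(path, what):
        if path is None:
            errors.append(f"{what}: no path configured")
            return None
        if not Path(path).exists():
            errors.append(f"{what}: file not found: {path}")
            return None
        return path

    table = design = None
    if "differential" in config.stages or "classify" in config.stages:
        tp = need(config.quant_table, "quant_table")
        dp = need(config.design, "design")
        if tp and dp:
            table = io.read_quant_table(tp)
            design = io.read_design(dp)
            missing = set(design.index) - set(table.columns)
            for s in sorted(missing):
                errors.append(f"design: sample {s!r} absent from quant_table")
            for cond in config.conditions:
                if cond not in set(design["condition"]):
                    errors.append(f"design: condition {cond!r} not present")

    if "classify" in config.stages:
        pp = need(config.anchors_positive, "anchors_positive")
        np_ = need(config.anchors_negative, "anchors_negative")
        if pp and np_ and table is not None:
            pos = io.read_id_list(pp) & set(table.index)
            neg = io.read_id_list(np_) & set(table.index)
            if not pos:
                errors.append("anchors_positive: zero overlap with quantified proteins")
            if not neg:
                errors.append("anchors_negative: zero overlap with quantified proteins")

    if "coelution" in config.stages:
        sp = need(config.sec_run, "sec_run")
        if sp and config.bait_id is None:
            errors.append("bait_id: required for the coelution stage")
        if sp and config.bait_id is not None:
            run = io.read_sec_run(sp)
            if config.bait_id not in run.index:
                errors.append(f"sec_run: bait {config.bait_id!r} not present")

    if "structure" in config.stages:
        need(config.structure_file, "structure_file")
        need(config.sites, "sites")
        if config.bait_chain is None:
            errors.append("bait_chain: required for the structure stage")

    if "substrates" in config.stages:
        if config.treated_condition is None or config.control_condition is None:
            errors.append("substrates: treated_condition and control_condition "
                          "are required")
    return errors


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and write every intermediate artifact.

    Returns the run report (also written as ``run_report.json``).
    """
    errors = validate_inputs(config)
    if errors:
        raise ValueError("input validation failed:\n" + "\n".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.as_dict()
    # the output location must not change output content, so it is not hashed
    hash_cfg = {k: v for k, v in cfg_dict.items() if k != "out_dir"}
    report: dict = {"version": __version__, "config": cfg_dict, "stages": {}}

    contrasts: dict = {}
    calls: dict = {}

    if "differential" in config.stages:
        table = io.read_quant_table(config.quant_table)
        design = io.read_design(config.design)
        for cond in config.conditions:
            res = run_differential(table, design, cond,
                                   normalize=config.normalize,
                                   impute=config.impute,
                                   lam=config.storey_lambda)
            contrasts[cond] = res
            io.write_contrast(res, out / f"contrast_{cond}.tsv", hash_cfg)
            report["stages"].setdefault("differential", {})[cond] = {
                "n_proteins": int(len(res.table)),
                "n_tested": int(res.table["p_value"].notna().sum()),
            }
        log.info("differential: %d condition(s)", len(contrasts))

    if "classify" in config.stages:
        anchors = AnchorSets(io.read_id_list(config.anchors_positive),
                             io.read_id_list(config.anchors_negative))
        for cond, res in contrasts.items():
            if config.call_mode == "cutoff":
                cond_calls = call_enriched_by_cutoff(
                    res, config.fc_cutoff, config.q_cutoff)
                stage_info = {"mode": "cutoff", "fc_cutoff": config.fc_cutoff,
                              "q_cutoff": config.q_cutoff}
            else:
                scores = compute_enrichment_scores(res)
                fit = fit_enrichment_classifier(
                    scores, anchors, target_fpr=config.target_fpr,
                    n_folds=config.n_folds, n_repeats=config.n_repeats,
                    seed=config.stage_seed("classify"))
                cond_calls = call_enriched(scores, fit)
                stage_info = {
                    "mode": "classifier",
                    "threshold": fit.threshold,
                    "achieved_fpr": fit.achieved_fpr,
                    "mean_cv_auc": fit.cv.mean_auc if fit.cv else None,
                    "n_dropped": scores.n_dropped,
                }
            calls[cond] = cond_calls
            cond_calls.to_csv(out / f"calls_{cond}.tsv", sep="\t",
                              index_label="protein_id")
            stage_info["n_enriched"] = int(cond_calls["enriched"].sum())
            report["stages"].setdefault("classify", {})[cond] = stage_info
        log.info("classify: %s", report["stages"].get("classify"))

    if "coelution" in config.stages:
        run = io.read_sec_run(config.sec_run)
        normalized, excluded = normalize_profiles(run)
        coel = bait_correlations(normalized, config.bait_id,
                                 min_fractions=config.min_fractions)
        coel.table.to_csv(out / "coelution.tsv", sep="\t",
                          index_label="protein_id")
        info = {"n_excluded_zero_total": len(excluded),
                "n_with_r": int(coel.table["r"].notna().sum())}
        first_cond = config.conditions[0]
        if first_cond in calls:
            enriched = enriched_ids(calls[first_cond])
            try:
                info["enriched_vs_rest"] = compare_enriched_correlations(
                    coel, enriched)
            except ValueError as exc:
                info["enriched_vs_rest_error"] = str(exc)
        if config.sec_windows:
            info["bait_window_fraction"] = window_signal_fraction(
                normalized, config.bait_id,
                [tuple(w) for w in config.sec_windows])
        report["stages"]["coelution"] = info
        log.info("coelution: %s", info)

    if "substrates" in config.stages:
        if not calls:
            raise ValueError("substrates stage needs the classify stage "
                             "(no enrichment calls available)")
        exclusive = exclusive_enriched_set(
            calls, config.treated_condition, config.control_condition)
        refs = {k: io.read_id_list(p) if p else set() for k, p in (
            ("ups", config.ups_list),
            ("substrates", config.substrate_list),
            ("ubi", config.ubi_responsive_list))}
        sub = annotate_candidates(exclusive, refs["ups"], refs["substrates"],
                                  refs["ubi"])
        sub.categories.rename("category").to_csv(
            out / "substrate_candidates.tsv", sep="\t",
            index_label="protein_id")
        report["stages"]["substrates"] = {
            "n_exclusive": len(sub.exclusive),
            "counts": sub.counts,
            "percentages": sub.percentages,
            "ubi_responsive_of_remainder": sub.ubi_responsive_of_remainder,
            "ubi_responsive_percent": sub.ubi_responsive_percent,
        }
        log.info("substrates: %s", report["stages"]["substrates"])

    if "structure" in config.stages:
        model = load_structure(config.structure_file)
        anchor, anchor_info = anchor_point(model, config.bait_chain)
        sites = io.read_sites(config.sites)
        prox = site_anchor_distances(model, anchor, sites,
                                     radius_A=config.radius_A)
        prox.sites.to_csv(out / "proximity.tsv", sep="\t", index=False)
        report["stages"]["structure"] = {
            "anchor": anchor_info,
            "n_resolved": prox.n_resolved,
            "n_within": prox.n_within,
            "n_unresolved": int(len(prox.unresolved)),
            "fraction_within": prox.fraction_within,
            "radius_A": config.radius_A,
        }
        log.info("structure: %s", report["stages"]["structure"])

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
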