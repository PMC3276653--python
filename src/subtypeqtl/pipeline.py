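"""End-to-end pipeline: simulate (optional) -> classical association -> FAMT
-> subtype clustering -> full and leave-one-subtype-out trait scans ->
haplotype calling -> interaction testing -> candidate genes.

The report is a plain dict (JSON-serializable) carrying every count,
position, interval, p-value and seed, so a run is reproducible from its
report alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import classical_gene_lists, gene_test_table
from .famt import FactorAnalysisMT
from .genmap import MarkerMap
from .haplotypes import call_haplotype, haplotype_table, subtype_haplotype_summary
from .interaction import (
    eqtl_candidate_filter,
    interaction_scan,
    two_qtl_additive_scan,
    two_way_anova_interaction,
)
from .linkage import (
    adjust_phenotype,
    adjustment_design,
    empirical_threshold,
    leave_one_subtype_out_scans,
    scan_chromosome,
    transmission_probabilities,
)
from .simulate import SimulationConfig, simulate_study
from .subtyping import cluster_animals, label_subtypes

__all__ = ["PipelineConfig", "run_pipeline", "PipelineRun"]

_STAGES = (
    "simulate", "associate", "famt", "cluster", "scan", "haplotypes",
    "interact", "candidates",
)


@dataclass
class PipelineConfig:
    """All pipeline parameters; unknown YAML keys are rejected."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple = _STAGES
    alpha: float = 0.05
    extreme_group_k: int = 10
    n_factors: int | None = 6  # None -> estimate from the data
    q_max: int = 8
    k_subtypes: int = 5
    cluster_method: str = "ward"
    grid_step_cm: float = 1.0
    n_sim_threshold: int = 2000
    h2_threshold: float = 0.5
    scan_level: float = 0.05
    fixed_pos: float | None = None  # None -> full-family max-LRT position
    proximal_region: tuple = (85.0, 20.0)  # (center, halfwidth) cM, fine-mapped center
    distal_region: tuple = (168.0, 15.0)
    haplotype_threshold: float = 0.99
    alpha_interaction: float = 0.1
    alpha_de: float = 0.1
    n_sim_candidates: int = 500

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        sim_known = set(SimulationConfig.__dataclass_fields__)
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
        if "marker_positions" in sim_raw and sim_raw["marker_positions"] is not None:
            sim_raw["marker_positions"] = tuple(sim_raw["marker_positions"])
        cfg = cls(simulation=SimulationConfig(**sim_raw), **raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        for key in ("proximal_region", "distal_region"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineRun:
    """Report plus the in-memory objects of a pipeline execution."""

    report: dict
    objects: dict

    def to_json(self, **kw) -> str:
        return json.dumps(self.report, sort_keys=True, **kw)


def _scan_report(scan) -> dict:
    out = {
        "max_pos": scan.max_pos,
        "max_lrt": scan.max_lrt,
        "ci": list(scan.ci) if scan.ci else None,
        "effect_sd": scan.effect_sd,
        "n": scan.n,
    }
    if scan.threshold is not None:
        out["threshold"] = scan.threshold.value
        out["significant"] = scan.significant
        out["chromosome_p"] = scan.threshold.pvalue(scan.max_lrt)
    return out


def run_pipeline(
    config: PipelineConfig,
    data: dict | None = None,
    out_dir=None,
) -> PipelineRun:
    """Execute the configured stages in study order.

    ``data`` supplies pre-loaded inputs (keys marker_map, inheritance,
    phenotypes, expression) when the simulate stage is toggled off.  A stage
    failure raises with the stage name; earlier results survive in the
    report.  With identical config the run is bit-identical.
    """
    report = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {s: ("run" if s in config.stages else "skipped") for s in _STAGES},
    }
    obj = {}
    rng = np.random.default_rng(config.seed)
    stage = "setup"
    try:
        # -- simulate -----------------------------------------------------
        if "simulate" in config.stages:
            stage = "simulate"
            study = simulate_study(config.simulation, seed=config.seed)
            obj["study"] = study
            marker_map = study.marker_map
            inherit = study.inheritance
            pheno = study.phenotypes
            expr = study.expression
            report["simulate"] = {
                "n_offspring": len(pheno),
                "n_genes": expr.shape[0],
                "n_markers": len(marker_map),
            }
        else:
            if not data:
                raise ValueError("simulate stage skipped but no data supplied")
            marker_map = data["marker_map"]
            inherit = data["inheritance"]
            pheno = data["phenotypes"]
            expr = data["expression"]

        trait = pheno["trait"]
        adj_trait = adjust_phenotype(pheno)
        design = adjustment_design(pheno)
        obj["adjusted_trait"] = adj_trait

        # -- classical association ---------------------------------------
        if "associate" in config.stages:
            stage = "associate"
            assoc = gene_test_table(expr, trait, k=config.extreme_group_k)
            corr_list, union_list = classical_gene_lists(assoc, alpha=config.alpha)
            obj["association"] = assoc
            report["associate"] = {
                "n_genes_tested": int(assoc["tested"].sum()),
                "n_correlation_list": len(corr_list),
                "n_union_list": len(union_list),
                "n_bh_significant": int((assoc["p_bh"] < config.alpha).sum()),
            }
            obj["corr_list"], obj["union_list"] = corr_list, union_list

        # -- FAMT ---------------------------------------------------------
        famt_list = None
        cluster_expr = expr
        if "famt" in config.stages:
            stage = "famt"
            model = FactorAnalysisMT(expr, trait)
            if config.n_factors is None:
                q_hat, crits = model.select_n_factors(q_max=config.q_max)
            else:
                q_hat, crits = config.n_factors, None
            famt_res = model.fit(q=q_hat)
            famt_list = famt_res.significant_genes(alpha=config.alpha)
            cluster_expr = famt_res.adjusted_expression
            obj["famt"] = famt_res
            obj["famt_list"] = famt_list
            report["famt"] = {
                "q": q_hat,
                "q_estimated": config.n_factors is None,
                "n_iter": famt_res.n_iter,
                "n_adjusted_list": len(famt_list),
            }

        # -- clustering ---------------------------------------------------
        subtype_names = None
        if "cluster" in config.stages:
            stage = "cluster"
            gene_list = famt_list if famt_list else obj.get("corr_list")
            if not gene_list:
                raise ValueError("no trait-associated genes available to cluster on")
            assign = cluster_animals(
                cluster_expr, gene_list, k=config.k_subtypes, method=config.cluster_method
            )
            assign = label_subtypes(assign, trait)
            subtype_names = assign.names
            obj["subtypes"] = assign
            report["cluster"] = {
                "k": config.k_subtypes,
                "n_clustering_genes": len(gene_list),
                "sizes": {str(k): len(v) for k, v in assign.groups.items()},
            }

        # -- transmission + scans ------------------------------------------
        profile = transmission_probabilities(
            inherit, marker_map,
            step_cm=config.grid_step_cm,
            chromosome_length=config.simulation.chromosome_length,
        )
        obj["profile"] = profile
        scans = None
        if "scan" in config.stages:
            stage = "scan"
            if subtype_names is not None:
                scans = leave_one_subtype_out_scans(
                    adj_trait, profile, subtype_names,
                    n_sim=config.n_sim_threshold, h2=config.h2_threshold,
                    level=config.scan_level, rng=rng, design=design,
                )
            else:
                full = scan_chromosome(adj_trait, profile)
                full.threshold = empirical_threshold(
                    profile, n_sim=config.n_sim_threshold, h2=config.h2_threshold,
                    level=config.scan_level, rng=rng, design=design,
                )
                scans = {"full": full}
            obj["scans"] = scans
            report["scan"] = {name: _scan_report(s) for name, s in scans.items()}

        # -- haplotypes -----------------------------------------------------
        table = None
        if "haplotypes" in config.stages:
            stage = "haplotypes"
            prox = call_haplotype(
                inherit, marker_map, *config.proximal_region,
                threshold=config.haplotype_threshold,
            )
            dist = call_haplotype(
                inherit, marker_map, *config.distal_region,
                threshold=config.haplotype_threshold,
            )
            table = haplotype_table(prox, dist, subtype_names)
            obj["haplotypes"] = table
            report["haplotypes"] = {
                "n_proximal_determined": table.n_proximal_determined,
                "n_distal_determined": table.n_distal_determined,
                "n_both_determined": table.n_both_determined,
            }
            if subtype_names is not None and (subtype_names == "lean2").any():
                n_in, n_det, n_Q, n_q = subtype_haplotype_summary(table, "lean2", "distal")
                report["haplotypes"]["lean2_distal"] = {
                    "n_in_group": n_in, "n_determined": n_det, "count_Q": n_Q, "count_q": n_q,
                }

        # -- interaction ----------------------------------------------------
        fixed_pos = config.fixed_pos
        if fixed_pos is None and scans is not None:
            fixed_pos = scans["full"].max_pos
        if "interact" in config.stages:
            stage = "interact"
            report["interact"] = {"fixed_pos": fixed_pos}
            if table is not None:
                try:
                    anova = two_way_anova_interaction(adj_trait, table)
                    obj["anova"] = anova
                    report["interact"]["anova"] = {
                        "n": anova.n,
                        "p_interaction": anova.p_interaction,
                        "p_proximal": anova.p_proximal,
                        "p_distal": anova.p_distal,
                        "diff_given_distal_Q": anova.diff_given_distal_Q,
                        "diff_given_distal_q": anova.diff_given_distal_q,
                    }
                except ValueError as err:
                    report["interact"]["anova"] = {"error": str(err)}
            i_scan = interaction_scan(
                adj_trait, profile, fixed_pos,
                n_sim=config.n_sim_threshold, h2=config.h2_threshold,
                level=config.scan_level, rng=rng, design=design,
            )
            a_scan = two_qtl_additive_scan(
                adj_trait, profile, fixed_pos,
                n_sim=config.n_sim_threshold, h2=config.h2_threshold,
                level=config.scan_level, rng=rng, design=design,
            )
            obj["interaction_scan"], obj["additive_scan"] = i_scan, a_scan
            report["interact"]["interaction_scan"] = _scan_report(i_scan)
            report["interact"]["additive_scan"] = _scan_report(a_scan)

        # -- candidate genes -----------------------------------------------
        if "candidates" in config.stages:
            stage = "candidates"
            if subtype_names is None or scans is None:
                raise ValueError("candidate filtering needs the cluster and scan stages")
            gene_list = famt_list if famt_list else obj.get("corr_list", [])
            distal_ci = tuple(scans["full"].ci)
            prox_ci = tuple(obj["interaction_scan"].ci) if "interaction_scan" in obj else (
                config.proximal_region[0] - config.proximal_region[1],
                config.proximal_region[0] + config.proximal_region[1],
            )
            cand = eqtl_candidate_filter(
                expr.loc[[g for g in gene_list if g in expr.index]],
                profile, distal_ci, prox_ci, subtype_names,
                fixed_pos=fixed_pos,
                alpha_interaction=config.alpha_interaction,
                alpha_de=config.alpha_de,
                n_sim=config.n_sim_candidates,
                h2=config.h2_threshold,
                rng=rng,
            )
            obj["candidates"] = cand
            report["candidates"] = {
                "n_screened": len(cand),
                "n_candidates": int(cand["candidate"].sum()),
                "candidate_genes": sorted(cand.index[cand["candidate"]]),
            }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    if out_dir is not None:
        _write_outputs(Path(out_dir), config, report, obj)
    return PipelineRun(report=report, objects=obj)


def _write_outputs(out_dir: Path, config, report, obj):
    from . import io as sio

    out_dir.mkdir(parents=True, exist_ok=True)
    if "study" in obj:
        study = obj["study"]
        sio.write_marker_map(study.marker_map, out_dir / "map.tsv")
        sio.write_inheritance(study.inheritance, out_dir / "inherit.tsv")
        sio.write_phenotypes(study.phenotypes, out_dir / "pheno.tsv")
        sio.write_expression(study.expression, out_dir / "expr.tsv")
        (out_dir / "truth.json").write_text(study.truth.to_json())
    if "famt" in obj:
        sio.write_expression(obj["famt"].adjusted_expression, out_dir / "adjusted.tsv")
    if "subtypes" in obj and obj["subtypes"].names is not None:
        obj["subtypes"].names.rename("subgroup").to_csv(out_dir / "subtypes.tsv", sep="\t")
    if "haplotypes" in obj:
        sio.write_haplotype_table(obj["haplotypes"], out_dir / "haplotypes.tsv")
    if "scans" in obj:
        for name, scan in obj["scans"].items():
            sio.write_scan(scan, out_dir / f"scan_{name}.tsv", out_dir / f"scan_{name}.json")
    if "candidates" in obj:
        obj["candidates"].to_csv(out_dir / "candidates.tsv", sep="\t")
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
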