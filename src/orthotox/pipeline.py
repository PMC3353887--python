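"""End-to-end orchestration: simulate or load inputs, then run every stage.

Stage order mirrors the analysis: ortholog merge and phenotype projection,
network connectivity and enrichment, candidate selection, clonogenic
toxicity calling with knockdown QC, optional autophagy scoring, report.
All stage outputs are plain TSV/JSON under the run directory; the report
contains only numbers recomputable from those files, and a fixed seed
makes two runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import autophagy_scoring, candidate_selection, io as oio
from . import network_analysis as na
from . import synthetic_data as sd
from . import toxicity_caller as tc
from .homology import HomologyTable, PhenotypeTable, merge_ortholog_sources, project_phenotypes

logger = logging.getLogger(__name__)

DEFAULT_AUTOPHAGY_CONDITIONS = {
    "untreated": 0.08, "MMS": 0.30, "rapamycin": 0.30, "BA1": 0.30,
}


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: bool = True
    merge_mode: str = "union"
    n_permutations: int = 1000
    null_model: str = "uniform"
    frac_lines_with_effect: float = 0.75
    n_comparison_lines: int = 5
    frac_comparison_with_effect: float = 0.25
    autophagy_conditions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AUTOPHAGY_CONDITIONS))
    autophagy_reference: str = "untreated"
    run_autophagy: bool = True
    sim: sd.SimConfig = None  # type: ignore[assignment]
    selection: candidate_selection.SelectionConfig = None  # type: ignore[assignment]
    caller: tc.CallerConfig = None  # type: ignore[assignment]
    # input paths, used when simulate is false
    inputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        errors = []
        if self.merge_mode not in ("union", "intersection"):
            errors.append(f"merge_mode must be union|intersection, got {self.merge_mode!r}")
        if self.null_model not in ("uniform", "degree_matched"):
            errors.append(f"null_model must be uniform|degree_matched, got {self.null_model!r}")
        if self.n_permutations < 1:
            errors.append("n_permutations must be >= 1")
        for name in ("frac_lines_with_effect", "frac_comparison_with_effect"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name} must lie in [0,1], got {v}")
        if self.n_comparison_lines < 0:
            errors.append("n_comparison_lines must be >= 0")
        if self.sim is None:
            self.sim = sd.SimConfig(seed=self.seed)
        elif self.sim.seed != self.seed:
            self.sim = self.sim.replace(seed=self.seed)
        if self.selection is None:
            self.selection = candidate_selection.SelectionConfig()
        if self.caller is None:
            self.caller = tc.CallerConfig()
        if not self.simulate:
            required = {"ortholog_a", "ortholog_b", "phenotypes", "network",
                        "expression", "annotations", "survival", "residuals"}
            missing = required - set(self.inputs)
            if missing:
                errors.append(f"simulate=false requires input paths {sorted(missing)}")
        if errors:
            raise ValueError("invalid pipeline config:\n  - " + "\n  - ".join(errors))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key, typ in (("sim", sd.SimConfig),
                         ("selection", candidate_selection.SelectionConfig),
                         ("caller", tc.CallerConfig)):
            if isinstance(raw.get(key), dict):
                raw[key] = typ(**raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    """Headline numbers of a completed run, all recomputable from disk."""

    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"seed": self.seed, "stages": self.stages}, fh,
                      indent=2, sort_keys=True)
        # trailing newline keeps the file diff-friendly
        with open(path, "a", encoding="utf-8") as fh:
            fh.write("\n")


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed)
    stage = "setup"
    try:
        if cfg.simulate:
            stage = "simulate"
            paths = _simulate_inputs(cfg, outdir / "inputs")
        else:
            paths = dict(cfg.inputs)

        stage = "homology"
        table_a = HomologyTable.from_tsv(paths["ortholog_a"], source="source_a")
        table_b = HomologyTable.from_tsv(paths["ortholog_b"], source="source_b")
        merged = merge_ortholog_sources(table_a, table_b, mode=cfg.merge_mode)
        phenotypes = PhenotypeTable.from_tsv(paths["phenotypes"])
        partition = project_phenotypes(merged, phenotypes)
        partition.to_tsv(outdir / "partition.tsv")
        report.stages["homology"] = {
            "n_pairs_source_a": len(table_a),
            "n_pairs_source_b": len(table_b),
            "n_pairs_merged": len(merged.pair_keys()),
            "n_modulator_homologs": len(partition.modulator_homologs),
            "n_nonmodulator_homologs": len(partition.nonmodulator_homologs),
            "n_core_all_agent": len(partition.core_all_agent_homologs),
            "n_unscreened_orfs": partition.n_unscreened_orfs,
        }

        stage = "network_analysis"
        net = na.build_network(oio.read_edge_rows(paths["network"]))
        lcc = na.induced_lcc(net, partition.modulator_homologs)
        perm = na.permutation_test_lcc(
            net, partition.modulator_homologs,
            n_permutations=cfg.n_permutations,
            null_model=cfg.null_model, seed=cfg.seed,
        )
        annotations = oio.read_annotations(paths["annotations"])
        enrichment = na.hypergeom_enrichment(lcc.lcc_members, set(net.nodes), annotations)
        oio.write_tsv(pd.DataFrame({"gene": sorted(lcc.lcc_members)}),
                      outdir / "lcc_members.tsv")
        oio.write_tsv(pd.DataFrame(
            [(r.term, r.k, r.K, r.n, r.N, float(f"{r.p_hypergeom:.6g}"),
              float(f"{r.p_bh:.6g}"), round(r.fold, 4)) for r in enrichment],
            columns=["term", "k", "K", "n", "N", "p_hypergeom", "p_bh", "fold"]),
            outdir / "enrichment.tsv")
        oio.write_graphml(net.subgraph(lcc.lcc_members), outdir / "lcc.graphml")
        report.stages["network_analysis"] = {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "query_size": lcc.query_size,
            "in_network": lcc.in_network,
            "lcc_size": lcc.lcc_size,
            "lcc_fraction": None if lcc.lcc_fraction is None else round(lcc.lcc_fraction, 4),
            "permutation_p": float(f"{perm.p_estimate:.6g}"),
            "p_is_upper_bound": perm.p_is_upper_bound,
            "null_model": perm.null_model,
            "null_lcc_mean": round(perm.null_mean, 3),
            "null_lcc_sd": round(perm.null_sd, 3),
            "null_lcc_max": perm.null_max,
            "n_enriched_terms_bh05": sum(r.p_bh < 0.05 for r in enrichment),
        }

        stage = "candidate_selection"
        expression = oio.read_gene_value_map(paths["expression"])
        degree = {n: d for n, d in net.degree()}
        records = candidate_selection.select_candidates(
            partition, lcc, merged, expression, annotations,
            cfg=cfg.selection, degree=degree,
        )
        selected = candidate_selection.selected_genes(records)
        oio.write_tsv(candidate_selection.records_to_frame(records),
                      outdir / "candidates.tsv")
        oio.write_tsv(candidate_selection.trace_to_frame(records),
                      outdir / "selection_trace.tsv")
        report.stages["candidate_selection"] = {
            "n_evaluated": len(records),
            "n_selected": len(selected),
            "n_core_selected": sum(r.is_core and r.included for r in records),
            "n_addon": sum(r.is_addon for r in records),
        }

        stage = "toxicity_caller"
        if cfg.simulate:
            survival_path, residual_path, screen_lines, comparison_lines = \
                _simulate_survival(cfg, outdir / "inputs", selected, partition)
        else:
            survival_path, residual_path = paths["survival"], paths["residuals"]
            screen_lines = comparison_lines = None
        tox = _call_screen(cfg, survival_path, residual_path,
                           screen_lines, comparison_lines, outdir)
        report.stages["toxicity_caller"] = tox

        if cfg.run_autophagy:
            stage = "autophagy_scoring"
            if cfg.simulate:
                puncta = sd.gen_puncta_counts(cfg.sim, cfg.autophagy_conditions)
                oio.write_tsv(puncta, outdir / "inputs" / "puncta.tsv")
            elif "puncta" in paths:
                puncta = oio.read_tsv(paths["puncta"])
            else:
                puncta = None
            if puncta is not None:
                scores = autophagy_scoring.score_autophagy(puncta)
                results = autophagy_scoring.autophagy_report(
                    scores, cfg.autophagy_reference)
                oio.write_tsv(autophagy_scoring.results_to_frame(results),
                              outdir / "autophagy.tsv")
                report.stages["autophagy_scoring"] = {
                    r.condition: {
                        "fraction": round(r.fraction, 4),
                        "fold_vs_reference": None if r.fold_vs_reference is None
                        else round(r.fold_vs_reference, 3),
                        "p": float(f"{r.p_vs_reference:.4g}"),
                        "stars": r.stars,
                    } for r in results
                }

        stage = "report"
        report.to_json(outdir / "report.json")
        write_report(report, outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n",
                                       encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return report


def _simulate_inputs(cfg: PipelineConfig, indir: Path) -> dict[str, str]:
    indir.mkdir(parents=True, exist_ok=True)
    table_a, table_b = sd.gen_ortholog_sources(cfg.sim)
    table_a.to_tsv(indir / "orthologs_a.tsv")
    table_b.to_tsv(indir / "orthologs_b.tsv")
    phenotypes = sd.gen_phenotype_table(cfg.sim)
    phenotypes.to_tsv(indir / "phenotypes.tsv")
    # the network's planted module needs the modulator homolog set
    merged = merge_ortholog_sources(table_a, table_b, mode=cfg.merge_mode)
    partition = project_phenotypes(merged, phenotypes)
    net = sd.gen_ppi_network(cfg.sim, sorted(partition.modulator_homologs))
    oio.write_edge_tsv(net, indir / "network.tsv")
    oio.write_sif(net, indir / "network.sif")
    expression = sd.gen_expression(cfg.sim)
    oio.write_tsv(pd.DataFrame(sorted(expression.items()),
                               columns=["gene", "intensity"]),
                  indir / "expression.tsv")
    annotations = sd.gen_annotations(
        cfg.sim, enriched_genes=net.graph.get("planted_module", ()))
    oio.write_annotations(annotations, indir / "annotations.tsv")
    return {
        "ortholog_a": str(indir / "orthologs_a.tsv"),
        "ortholog_b": str(indir / "orthologs_b.tsv"),
        "phenotypes": str(indir / "phenotypes.tsv"),
        "network": str(indir / "network.tsv"),
        "expression": str(indir / "expression.tsv"),
        "annotations": str(indir / "annotations.tsv"),
    }


def _simulate_survival(cfg: PipelineConfig, indir: Path, selected: list[str],
                       partition) -> tuple[str, str, set[str], set[str]]:
    import numpy as np
    comparison_pool = sorted(partition.nonmodulator_homologs)
    n_comp = min(cfg.n_comparison_lines, len(comparison_pool))
    # dedicated stream so comparison-line choice never perturbs effect draws
    rng = np.random.default_rng([cfg.sim.seed, 999])
    comparison = sorted(
        rng.choice(np.array(comparison_pool, dtype=object), size=n_comp,
                   replace=False).tolist()) if n_comp else []
    screen_effects = sd.gen_line_effects(
        cfg.sim, selected, cfg.frac_lines_with_effect)
    comp_effects = sd.gen_line_effects(
        cfg.sim.replace(seed=cfg.sim.seed + 1), comparison,
        cfg.frac_comparison_with_effect)
    effects = {**screen_effects, **comp_effects}
    obs, residuals = sd.gen_survival_dataset(cfg.sim, effects)
    oio.write_tsv(obs, indir / "survival.tsv")
    oio.write_tsv(residuals, indir / "residuals.tsv")
    return (str(indir / "survival.tsv"), str(indir / "residuals.tsv"),
            set(screen_effects), set(comp_effects))


def _call_screen(cfg: PipelineConfig, survival_path, residual_path,
                 screen_lines: set[str] | None,
                 comparison_lines: set[str] | None,
                 outdir: Path) -> dict:
    obs = oio.read_tsv(survival_path)
    residuals = oio.read_gene_value_map(residual_path)
    curves = tc.relative_survival(obs)

    # knockdown QC: non-silenced test lines join the control pool
    silenced_lines = {
        line for line, residual in residuals.items()
        if tc.classify_knockdown(residual, cfg.caller) == "silenced"
    }
    failed_kd_lines = set()
    for c in curves:
        if c.role == "test" and c.line.upper() not in silenced_lines:
            c.role = "nonsilenced"
            failed_kd_lines.add(c.line)
    n_failed_kd = len(failed_kd_lines)

    controls = [c for c in curves if c.role in ("nontargeting", "nonsilenced")]
    regions = tc.build_noise_region(controls, cfg.caller)
    nontargeting = {c.agent: c for c in curves if c.role == "nontargeting"}

    calls, comparison_calls = [], []
    for c in sorted((c for c in curves if c.role == "test"),
                    key=lambda c: (c.line, c.agent)):
        call = tc.call_toxicity(c, nontargeting[c.agent], regions[c.agent],
                                cfg.caller)
        if comparison_lines and c.line in comparison_lines:
            comparison_calls.append(call)
        else:
            calls.append(call)
    if not calls:
        raise ValueError("no silenced test lines to call")
    summary = tc.summarize_screen(calls, comparison_calls or None)

    oio.write_tsv(tc.calls_to_frame(calls + comparison_calls), outdir / "calls.tsv")
    heat = tc.heatmap_table(calls)
    heat.to_csv(outdir / "heatmap.tsv", sep="\t")
    noise_rows = [(agent, dose, round(r.lo[dose], 4), round(r.hi[dose], 4))
                  for agent, r in sorted(regions.items()) for dose in r.doses()]
    oio.write_tsv(pd.DataFrame(noise_rows, columns=["agent", "dose", "lo", "hi"]),
                  outdir / "noise_region.tsv")

    out = {
        "n_called_lines": summary.n_called_lines,
        "n_nonsilenced_test_lines": n_failed_kd,
        "n_modulating": summary.n_modulating,
        "pct_modulating": summary.pct_modulating,
        "pct_sensitivity": summary.pct_sensitivity,
        "pct_resistance": summary.pct_resistance,
        "pct_high": summary.pct_high,
        "category_counts": summary.category_counts,
    }
    if summary.fisher_p is not None:
        out["contingency"] = summary.contingency
        out["fisher_p"] = float(f"{summary.fisher_p:.4g}")
    return out


def write_report(report: RunReport, outdir: Path | str,
                 fmt: str = "markdown") -> Path:
    """Render the run report; numbers come verbatim from the RunReport."""
    outdir = Path(outdir)
    if fmt not in ("markdown", "tsv"):
        raise ValueError(f"unknown report format {fmt!r}")
    if fmt == "tsv":
        rows = [(stage, key, json.dumps(val, sort_keys=True))
                for stage, rec in sorted(report.stages.items())
                for key, val in sorted(rec.items())]
        path = outdir / "report.tsv"
        oio.write_tsv(pd.DataFrame(rows, columns=["stage", "key", "value"]), path)
        return path
    lines = ["# Screen run report", "", f"seed: {report.seed}", ""]
    for stage, rec in report.stages.items():
        lines.append(f"## {stage}")
        lines.append("")
        for key, val in rec.items():
            lines.append(f"- {key}: {json.dumps(val, sort_keys=True)}")
        lines.append("")
    heat_path = outdir / "heatmap.tsv"
    if heat_path.exists():
        lines.append("## call heatmap (++ high resistance, + low resistance, "
                     "· none, − low sensitivity, −− high sensitivity)")
        lines.append("")
        lines.append("```")
        lines.append(heat_path.read_text(encoding="utf-8").rstrip())
        lines.append("```")
        lines.append("")
    path = outdir / "report.md"
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def load_report(outdir: Path | str) -> RunReport:
    with open(Path(outdir) / "report.json", encoding="utf-8") as fh:
        raw = json.load(fh)
    return RunReport(seed=raw["seed"], stages=raw["stages"])
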