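"""Synthetic inputs with the statistical structure the pipeline assumes.

No public accessions exist for the original screen's raw tables, so every
input is emulated: ortholog tables from two partially overlapping sources,
a genome-wide yeast sensitivity table, a degree-heterogeneous interactome
with a planted connected module among modulator homologs, a log-normal
expression table, functional annotations, clonogenic survival counts with
multiplicative log-normal replicate noise, residual-mRNA QC values, and
per-cell autophagosome puncta counts.

Reproducibility contract: one global integer seed drives a splittable
per-generator stream (``default_rng([seed, stream_index])`` with a stable
index per generator), so identical (config, seed) gives byte-identical
outputs and adding a generator never perturbs existing ones.

Survival noise is multiplicative log-normal, so log2 ratios carry
homoscedastic additive noise — matching the caller's log2-space
thresholds. Survival is truncated at 1.0 after noise; zero survival is
never generated (colony counts of zero can still arise from rounding at
extreme kill and are handled by the caller's continuity correction).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import HomologyTable, PhenotypeTable

DEFAULT_AGENTS = ("MMS", "4NQO", "tBuOOH", "UV")

# Stable per-generator stream indices (append-only; never renumber).
_STREAMS = {
    "orthologs": 0,
    "phenotypes": 1,
    "ppi": 2,
    "survival": 3,
    "puncta": 4,
    "expression": 5,
    "annotations": 6,
    "line_effects": 7,
}


@dataclass
class SimConfig:
    """Parameters of the simulated screen.

    Defaults emulate the study conditions: ~30% of yeast genes sensitive
    per agent, ~30% ortholog coverage, a small core sensitive to all four
    agents, equitoxic abstract doses whose top dose leaves ~10% control
    survival, duplicate-to-triplicate colony assays with ~10% CV, and a
    planted connected module among modulator homologs in a
    preferential-attachment interactome.
    """

    n_yeast_genes: int = 2000
    n_human_genes: int = 2000
    ortholog_coverage: float = 0.30
    one_to_many_prob: float = 0.15
    source_retention: float = 0.80   # per-source fraction of true pairs retained
    frac_sensitive_per_agent: float = 0.30
    n_core_all_agent: int = 12       # genes forced sensitive to every agent
    agents: tuple[str, ...] = DEFAULT_AGENTS
    ppi_mean_degree: float = 6.0
    planted_module_size: int = 30
    planted_edge_prob: float = 0.25
    expr_log_mean: float = 5.0       # natural-log scale; median intensity ~148
    expr_log_sd: float = 1.5
    doses_per_agent: dict[str, tuple[float, ...]] | None = None
    survival_decay: dict[str, float] | None = None  # log2 kill per dose unit
    replicate_cv: float = 0.10
    n_replicates: int = 3
    effect_log2: float = 0.5         # magnitude of an injected survival shift
    knockdown_residual_range: tuple[float, float] = (0.10, 0.50)
    nonsilenced_residual_range: tuple[float, float] = (0.65, 1.00)
    n_nonsilenced_controls: int = 4
    plating_efficiency: float = 0.5
    cells_seeded_base: int = 200     # scaled up with expected kill, clipped to 50-5000
    puncta_lambda_basal: float = 1.5
    puncta_lambda_induced: float = 12.0
    puncta_cells_per_condition: int = 200
    seed: int = 0

    def __post_init__(self):
        for name in ("n_yeast_genes", "n_human_genes", "n_replicates",
                     "puncta_cells_per_condition", "cells_seeded_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be > 0")
        for name in ("ortholog_coverage", "one_to_many_prob", "source_retention",
                     "frac_sensitive_per_agent", "planted_edge_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"SimConfig.{name} must lie in [0,1], got {v}")
        for name in ("replicate_cv", "ppi_mean_degree", "puncta_lambda_basal",
                     "puncta_lambda_induced"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimConfig.{name} must be >= 0")
        if not (0.0 < self.plating_efficiency <= 1.0):
            raise ValueError("SimConfig.plating_efficiency must lie in (0,1]")
        if self.n_core_all_agent < 0 or self.planted_module_size < 0:
            raise ValueError("counts must be >= 0")
        if self.doses_per_agent is None:
            self.doses_per_agent = {a: (0.0, 1.0, 2.0, 3.0) for a in self.agents}
        if self.survival_decay is None:
            # top dose 3 at 1.1 log2-units/dose -> ~10% control survival
            self.survival_decay = {a: 1.1 for a in self.agents}
        for agent, doses in self.doses_per_agent.items():
            arr = np.asarray(doses, dtype=float)
            if (arr < 0).any() or not (np.diff(arr) > 0).all():
                raise ValueError(
                    f"SimConfig.doses_per_agent[{agent!r}] must be strictly "
                    f"increasing and non-negative"
                )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


def yeast_orf_names(n: int) -> list[str]:
    """Systematic-style ORF names (YAL001C pattern), unique and deterministic."""
    chroms = "ABCDEFGHIJKLMNOP"
    names = []
    for i in range(n):
        chrom = chroms[(i // 250) % len(chroms)]
        arm = "LR"[(i // 125) % 2]
        strand = "CW"[i % 2]
        names.append(f"Y{chrom}{arm}{i % 1000:03d}{strand}-{i // 4000}"
                     if i >= 4000 else f"Y{chrom}{arm}{i % 1000:03d}{strand}")
    return names


def human_gene_names(n: int) -> list[str]:
    return [f"HG{i:04d}" for i in range(n)]


def gen_ortholog_sources(config: SimConfig) -> tuple[HomologyTable, HomologyTable]:
    """Two ortholog tables drawn from one latent truth.

    A ``ortholog_coverage`` fraction of yeast genes gets >=1 human ortholog
    (two with probability ``one_to_many_prob``); each source then retains
    an independent ``source_retention`` fraction of the true pairs, so the
    sources partially overlap, as real databases do.
    """
    rng = config.rng("orthologs")
    yeast = yeast_orf_names(config.n_yeast_genes)
    human = human_gene_names(config.n_human_genes)
    true_pairs: list[tuple[str, str]] = []
    perm = rng.permutation(config.n_human_genes)
    cursor = 0
    for y in yeast:
        if rng.random() >= config.ortholog_coverage:
            continue
        k = 2 if rng.random() < config.one_to_many_prob else 1
        for _ in range(k):
            h = human[perm[cursor % config.n_human_genes]]
            cursor += 1
            true_pairs.append((y, h))
    tables = []
    for source in ("ensembl_like", "inparanoid_like"):
        keep = rng.random(len(true_pairs)) < config.source_retention
        kept = [p for p, k in zip(true_pairs, keep) if k]
        tables.append(HomologyTable.from_records(kept, source=source))
    return tables[0], tables[1]


def gen_phenotype_table(config: SimConfig) -> PhenotypeTable:
    """Per-gene x agent Bernoulli sensitivity, plus a forced all-agent core.

    The first ``n_core_all_agent`` yeast genes are sensitive to every
    agent, emulating the small core of universally sensitive deletions.
    """
    rng = config.rng("phenotypes")
    yeast = yeast_orf_names(config.n_yeast_genes)
    core = set(yeast[: config.n_core_all_agent]) if config.frac_sensitive_per_agent > 0 else set()
    records = []
    for agent in config.agents:
        draws = rng.random(config.n_yeast_genes) < config.frac_sensitive_per_agent
        for orf, hit in zip(yeast, draws):
            records.append((orf, agent, bool(hit) or orf in core))
    return PhenotypeTable.from_long(records, agents=list(config.agents))


def gen_ppi_network(config: SimConfig, modulator_genes: Sequence[str]):
    """Preferential-attachment background plus a planted module.

    The background is a Barabasi-Albert graph over all human genes (so the
    degree distribution is heavy-tailed, as in real interactomes) with
    node labels assigned in shuffled order. Extra edges are added among a
    random ``planted_module_size`` subset of ``modulator_genes``, each pair
    independently with ``planted_edge_prob``, creating the enriched-LCC
    signal the permutation test must detect. The result is simple: no
    self-loops, no multi-edges.
    """
    import networkx as nx

    modulator_genes = sorted({str(g).upper() for g in modulator_genes})
    universe = set(human_gene_names(config.n_human_genes))
    if not set(modulator_genes) <= universe:
        raise ValueError("modulator_genes must lie within the human gene universe")
    if config.planted_module_size > len(modulator_genes):
        raise ValueError(
            f"planted_module_size {config.planted_module_size} exceeds "
            f"|modulator_genes| = {len(modulator_genes)}"
        )
    rng = config.rng("ppi")
    m = max(1, int(round(config.ppi_mean_degree / 2)))
    base = nx.barabasi_albert_graph(
        config.n_human_genes, m, seed=np.random.RandomState(rng.integers(2**31))
    )
    names = human_gene_names(config.n_human_genes)
    order = rng.permutation(config.n_human_genes)
    mapping = {i: names[order[i]] for i in range(config.n_human_genes)}
    g = nx.relabel_nodes(base, mapping)
    module = list(rng.choice(np.array(modulator_genes, dtype=object),
                             size=config.planted_module_size, replace=False))
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            if rng.random() < config.planted_edge_prob:
                g.add_edge(module[i], module[j])
    g.graph["planted_module"] = sorted(module)
    return g


def gen_expression(config: SimConfig) -> dict[str, float]:
    """Log-normal microarray-style intensities for every human gene."""
    rng = config.rng("expression")
    values = rng.lognormal(config.expr_log_mean, config.expr_log_sd,
                           size=config.n_human_genes)
    return {g: float(round(v, 2))
            for g, v in zip(human_gene_names(config.n_human_genes), values)}


DEFAULT_TERM_VOCABULARY = (
    "DNA repair", "cell cycle control", "ribosomal protein",
    "transcription", "chromatin remodeling", "vesicle transport",
    "protein degradation", "mRNA degradation",
    "metabolism", "signal transduction", "unknown function",
)


def gen_annotations(
    config: SimConfig,
    enriched_genes: Sequence[str] = (),
    enriched_term: str = "vesicle transport",
    enriched_prob: float = 0.5,
) -> dict[str, set[str]]:
    """One to three functional terms per gene from a fixed vocabulary.

    ``enriched_genes`` receive ``enriched_term`` with elevated probability,
    planting a detectable enrichment signal in that subnetwork.
    """
    rng = config.rng("annotations")
    vocab = np.array(DEFAULT_TERM_VOCABULARY, dtype=object)
    enriched = {str(g).upper() for g in enriched_genes}
    out: dict[str, set[str]] = {}
    for gene in human_gene_names(config.n_human_genes):
        k = int(rng.integers(1, 4))
        terms = set(rng.choice(vocab, size=k, replace=False))
        if gene in enriched and rng.random() < enriched_prob:
            terms.add(enriched_term)
        out[gene] = terms
    return out


def _seeded_for(config: SimConfig, agent: str, dose: float) -> int:
    """Cells seeded at a dose, scaled to the expected kill, clipped to 50-5000."""
    kill = 2.0 ** (config.survival_decay[agent] * dose)
    return int(np.clip(round(config.cells_seeded_base * kill), 50, 5000))


def gen_survival_dataset(
    config: SimConfig,
    line_effects: Mapping[str, Mapping[str, float]],
    nonsilenced_test_lines: frozenset[str] | set[str] = frozenset(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Colony-count observations plus a residual-mRNA QC table.

    For each line x agent x dose x replicate the latent relative survival
    is ``exp2(-decay * dose + effect)`` (the per-line effect applies only
    at dose > 0; dose 0 is the normalization anchor) times multiplicative
    log-normal noise with CV ``replicate_cv``, truncated to (0, 1]. Colony
    counts are the rounded product with plating efficiency and seeded
    cells. Control lines (one non-targeting, ``n_nonsilenced_controls``
    non-silenced clones) carry zero effect. Residual mRNA is uniform in
    ``knockdown_residual_range`` for silenced lines and in
    ``nonsilenced_residual_range`` for non-silenced lines and clones.
    """
    rng = config.rng("survival")
    for line, effects in line_effects.items():
        unknown = set(effects) - set(config.agents)
        if unknown:
            raise ValueError(f"line {line!r} has unknown agents {sorted(unknown)}")
    sigma = (np.sqrt(np.log1p(config.replicate_cv**2))
             if config.replicate_cv > 0 else 0.0)

    lines: list[tuple[str, str, Mapping[str, float]]] = []
    lines.append(("NONTARGETING", "nontargeting", {}))
    for i in range(config.n_nonsilenced_controls):
        lines.append((f"NONSILENCED_{i + 1}", "nonsilenced", {}))
    for line in sorted(line_effects):
        lines.append((line, "test", line_effects[line]))

    rows = []
    for line, role, effects in lines:
        for agent in config.agents:
            decay = config.survival_decay[agent]
            effect = float(effects.get(agent, 0.0))
            for dose in config.doses_per_agent[agent]:
                seeded = _seeded_for(config, agent, dose)
                latent = 2.0 ** (-decay * dose + (effect if dose > 0 else 0.0))
                for rep in range(1, config.n_replicates + 1):
                    noise = float(np.exp(rng.normal(0.0, sigma))) if sigma else 1.0
                    rel = min(latent * noise, 1.0)
                    colonies = int(round(seeded * config.plating_efficiency * rel))
                    colonies = min(colonies, seeded)
                    rows.append((line, agent, dose, rep, colonies, seeded, role))
    obs = pd.DataFrame(rows, columns=["line", "agent", "dose", "replicate",
                                      "colonies", "cells_seeded", "role"])

    res_rows = [("NONTARGETING", 1.0)]
    lo_s, hi_s = config.knockdown_residual_range
    lo_n, hi_n = config.nonsilenced_residual_range
    for line, role, _ in lines:
        if role == "nontargeting":
            continue
        if role == "nonsilenced" or line in nonsilenced_test_lines:
            res_rows.append((line, float(round(rng.uniform(lo_n, hi_n), 3))))
        else:
            res_rows.append((line, float(round(rng.uniform(lo_s, hi_s), 3))))
    residuals = pd.DataFrame(res_rows, columns=["line", "residual"])
    return obs, residuals


def gen_line_effects(
    config: SimConfig,
    lines: Sequence[str],
    frac_with_effect: float,
    n_agents_hit: int = 1,
) -> dict[str, dict[str, float]]:
    """Assign injected log2 survival shifts to test lines.

    Each line is a modulator with probability ``frac_with_effect``; a
    modulator line receives a shift of magnitude ``config.effect_log2``
    with random sign on ``n_agents_hit`` randomly chosen agents (real
    modulators mostly affect specific agents, not all). Non-modulator
    lines get an empty effect map.
    """
    if not (0.0 <= frac_with_effect <= 1.0):
        raise ValueError("frac_with_effect must lie in [0,1]")
    rng = config.rng("line_effects")
    agents = np.array(config.agents, dtype=object)
    out: dict[str, dict[str, float]] = {}
    for line in sorted({str(l) for l in lines}):
        if rng.random() < frac_with_effect:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            hit = rng.choice(agents, size=min(n_agents_hit, len(agents)),
                             replace=False)
            out[line] = {str(a): sign * config.effect_log2 for a in hit}
        else:
            out[line] = {}
    return out


def gen_puncta_counts(
    config: SimConfig, conditions: Mapping[str, float]
) -> pd.DataFrame:
    """Per-cell puncta counts from a two-component Poisson mixture.

    ``conditions`` maps condition label -> induced fraction; each cell is
    induced with that probability and draws its count from
    Poisson(lambda_induced), otherwise Poisson(lambda_basal).
    """
    if not conditions:
        raise ValueError("at least one condition is required")
    rng = config.rng("puncta")
    rows = []
    for cond in sorted(conditions):
        frac = float(conditions[cond])
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"induced fraction for {cond!r} must lie in [0,1]")
        induced = rng.random(config.puncta_cells_per_condition) < frac
        lam = np.where(induced, config.puncta_lambda_induced,
                       config.puncta_lambda_basal)
        counts = rng.poisson(lam)
        for i, c in enumerate(counts, start=1):
            rows.append((cond, f"{cond}_cell{i:04d}", int(c)))
    return pd.DataFrame(rows, columns=["condition", "cell_id", "puncta"])
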