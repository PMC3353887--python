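"""Ordered selection rules that reduce modulator homologs to screen candidates.

The rules, applied in order with a per-gene audit trail:

1. core include — homologs of yeast genes sensitive to every agent are
   auto-included, bypassing all filters (the core set spans heterogeneous
   functions and is kept regardless of category or expression);
2. LCC membership — the remaining pool is restricted to the largest
   connected component of the modulator subnetwork (configurable);
3. category exclusion — genes annotated with an excluded category (known
   DNA repair, cell cycle control, ribosomal proteins) are dropped;
4. expression — genes must be expressed (microarray intensity strictly
   above the threshold, default 100); genes missing from the expression
   table count as not expressed, logged;
5. ranking — survivors are ordered by (core membership, one-to-one
   homology, preferred functional category, network degree) descending,
   gene symbol ascending as the final tiebreak;
6. truncation to max_candidates minus the telomere add-on size;
7. telomere add-on — a configured gene list (e.g. shelterin members,
   which have no yeast homolog) appended unconditionally, flagged.

"One-to-one" means the human gene is the unique human homolog of at least
one of its yeast orthologs. "Several protein-protein interactions" enters
as a rank criterion (degree), not a hard cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .homology import HomologyTable, ModulatorPartition
from .network_analysis import LCCResult

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED = frozenset({"DNA repair", "cell cycle control", "ribosomal protein"})
DEFAULT_PREFERRED = frozenset({
    "transcription", "chromatin remodeling", "vesicle transport",
    "protein degradation", "mRNA degradation",
})


@dataclass
class SelectionConfig:
    expression_threshold: float = 100.0
    excluded_categories: frozenset[str] = DEFAULT_EXCLUDED
    preferred_categories: frozenset[str] = DEFAULT_PREFERRED
    require_in_lcc: bool = True
    telomere_addon: tuple[str, ...] = ()
    max_candidates: int = 45

    def __post_init__(self):
        if self.expression_threshold < 0:
            raise ValueError("expression_threshold must be >= 0")
        if self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1")
        self.excluded_categories = frozenset(self.excluded_categories)
        self.preferred_categories = frozenset(self.preferred_categories)
        self.telomere_addon = tuple(g.upper() for g in self.telomere_addon)


@dataclass
class CandidateRecord:
    gene: str
    included: bool
    rule_trace: list[tuple[str, str, str]] = field(default_factory=list)
    rank_key: tuple[int, int, int, int] | None = None
    is_core: bool = False
    is_addon: bool = False

    def trace(self, rule: str, verdict: str, detail: str = "") -> None:
        self.rule_trace.append((rule, verdict, detail))

    @property
    def first_failing_rule(self) -> str | None:
        for rule, verdict, _ in self.rule_trace:
            if verdict == "fail":
                return rule
        return None


def select_candidates(
    partition: ModulatorPartition,
    lcc: LCCResult | None,
    homology: HomologyTable,
    expression: Mapping[str, float],
    annotations: Mapping[str, set[str]],
    cfg: SelectionConfig | None = None,
    degree: Mapping[str, int] | None = None,
) -> list[CandidateRecord]:
    """Evaluate every modulator homolog against the selection rules.

    Returns records for all evaluated genes (included first, in rank
    order, then excluded genes alphabetically); every record carries a
    non-empty rule trace and excluded records name the first failing rule.
    """
    cfg = cfg or SelectionConfig()
    degree = degree or {}
    expression = {str(g).upper(): v for g, v in expression.items()}
    if cfg.require_in_lcc and lcc is None:
        raise ValueError("require_in_lcc is set but no LCC result was given")

    known_terms = set()
    for terms in annotations.values():
        known_terms |= set(terms)
    unknown_cfg_terms = (cfg.excluded_categories | cfg.preferred_categories) - known_terms
    if unknown_cfg_terms and known_terms:
        logger.info("selection categories never seen in annotations (ignored where "
                    "absent): %s", sorted(unknown_cfg_terms))

    yeast_mult = homology.yeast_multiplicity
    human_to_yeast: dict[str, set[str]] = {}
    for y, hg in homology.pair_keys():
        human_to_yeast.setdefault(hg, set()).add(y)

    records: list[CandidateRecord] = []
    survivors: list[CandidateRecord] = []
    n_missing_expr = 0
    for gene in sorted(partition.modulator_homologs):
        rec = CandidateRecord(gene=gene, included=False)
        terms = set(annotations.get(gene, set()))
        is_core = gene in partition.core_all_agent_homologs
        rec.is_core = is_core

        if is_core:
            rec.trace("core_include", "bonus",
                      "homolog of an all-agent-sensitive yeast gene")
        else:
            rec.trace("core_include", "pass", "not in core set")
            if cfg.require_in_lcc:
                if gene in lcc.lcc_members:
                    rec.trace("lcc_membership", "pass", "in largest connected component")
                else:
                    rec.trace("lcc_membership", "fail", "outside the LCC")
                    records.append(rec)
                    continue
            hit = terms & cfg.excluded_categories
            if hit:
                rec.trace("category_exclusion", "fail", f"excluded: {sorted(hit)}")
                records.append(rec)
                continue
            rec.trace("category_exclusion", "pass", "")
            value = expression.get(gene)
            if value is None:
                n_missing_expr += 1
                rec.trace("expression", "fail", "missing from expression table")
                records.append(rec)
                continue
            if value <= cfg.expression_threshold:
                rec.trace("expression", "fail",
                          f"intensity {value:g} <= {cfg.expression_threshold:g}")
                records.append(rec)
                continue
            rec.trace("expression", "pass", f"intensity {value:g}")

        one_to_one = any(
            yeast_mult.get(y, 0) == 1 for y in human_to_yeast.get(gene, set())
        )
        preferred = bool(terms & cfg.preferred_categories)
        rec.rank_key = (
            int(is_core), int(one_to_one), int(preferred), int(degree.get(gene, 0))
        )
        rec.trace("rank", "pass",
                  f"core={int(is_core)} one_to_one={int(one_to_one)} "
                  f"preferred={int(preferred)} degree={degree.get(gene, 0)}")
        survivors.append(rec)

    if n_missing_expr:
        logger.info("%d genes missing from the expression table (treated as not "
                    "expressed)", n_missing_expr)

    survivors.sort(key=lambda r: (
        -r.rank_key[0], -r.rank_key[1], -r.rank_key[2], -r.rank_key[3], r.gene
    ))
    n_keep = max(cfg.max_candidates - len(cfg.telomere_addon), 0)
    for i, rec in enumerate(survivors):
        if i < n_keep:
            rec.included = True
            rec.trace("truncation", "pass", f"rank {i + 1} of {n_keep}")
        else:
            rec.trace("truncation", "fail", f"rank {i + 1} beyond cutoff {n_keep}")

    addons: list[CandidateRecord] = []
    for gene in cfg.telomere_addon:
        rec = CandidateRecord(gene=gene, included=True, is_addon=True)
        rec.trace("telomere_addon", "bonus", "configured add-on, included unconditionally")
        addons.append(rec)

    included = [r for r in survivors if r.included] + addons
    excluded = sorted(
        [r for r in survivors if not r.included] + records, key=lambda r: r.gene
    )
    return included + excluded


def selected_genes(records: list[CandidateRecord]) -> list[str]:
    return [r.gene for r in records if r.included]


def records_to_frame(records: list[CandidateRecord]) -> pd.DataFrame:
    rows = [
        (r.gene, int(r.included), int(r.is_core), int(r.is_addon),
         "" if r.rank_key is None else ",".join(map(str, r.rank_key)),
         r.first_failing_rule or "")
        for r in records
    ]
    return pd.DataFrame(rows, columns=["gene", "included", "core", "addon",
                                       "rank_key", "first_failing_rule"])


def trace_to_frame(records: list[CandidateRecord]) -> pd.DataFrame:
    """Long-format audit trail: one row per gene x rule."""
    rows = [
        (r.gene, rule, verdict, detail)
        for r in records
        for rule, verdict, detail in r.rule_trace
    ]
    return pd.DataFrame(rows, columns=["gene", "rule", "verdict", "detail"])
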