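"""Ortholog-table merging and yeast-phenotype projection onto human genes.

The screen design starts from genome-wide yeast deletion data: each ORF is
scored sensitive or not to each DNA damaging agent (MMS, 4NQO, tBuOOH, UV).
Ortholog tables from two sources are merged, and each human gene inherits
"toxicity-modulator homolog" status if at least one of its yeast orthologs
is sensitive to at least one agent. Genes whose screened orthologs are all
non-sensitive form the non-modulator homolog set; the two sets partition
the human genes that have at least one screened ortholog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

from .io import read_tsv, write_tsv

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["yeast_orf", "human_gene", "source", "confidence"]


@dataclass(frozen=True)
class OrthologPair:
    """One yeast-ORF / human-gene ortholog assertion from one source."""

    yeast_orf: str
    human_gene: str
    source: str
    confidence: float | None = None

    def __post_init__(self):
        if not self.yeast_orf or not self.human_gene:
            raise ValueError("OrthologPair requires non-empty yeast_orf and human_gene")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0,1], got {self.confidence}")


class HomologyTable:
    """A collection of ortholog pairs with per-gene multiplicity indices.

    Identifiers are upper-cased on ingest; no alias resolution is attempted.
    (yeast_orf, human_gene, source) must be unique within a table.
    """

    def __init__(self, pairs: Iterable[OrthologPair]):
        self.pairs: list[OrthologPair] = sorted(
            pairs, key=lambda p: (p.yeast_orf, p.human_gene, p.source)
        )
        seen: set[tuple[str, str, str]] = set()
        dupes = []
        for p in self.pairs:
            key = (p.yeast_orf, p.human_gene, p.source)
            if key in seen:
                dupes.append(key)
            seen.add(key)
        if dupes:
            raise ValueError(
                f"duplicate (yeast_orf, human_gene, source) rows: {sorted(dupes)}"
            )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], source: str | None = None
    ) -> "HomologyTable":
        """Build from (yeast, human[, source[, confidence]]) tuples."""
        pairs = []
        for rec in records:
            rec = tuple(rec)
            yeast, human = str(rec[0]).upper(), str(rec[1]).upper()
            src = str(rec[2]) if len(rec) > 2 and rec[2] is not None else source
            if src is None:
                raise ValueError("source must be given per record or as default")
            conf = None
            if len(rec) > 3 and rec[3] is not None:
                conf = float(rec[3])
                if conf != conf:  # NaN from an empty TSV cell
                    conf = None
            pairs.append(OrthologPair(yeast, human, src, conf))
        return cls(pairs)

    @classmethod
    def from_tsv(cls, path, source: str | None = None) -> "HomologyTable":
        df = read_tsv(path)
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        conf = df["confidence"] if "confidence" in cols else [None] * len(df)
        src = df["source"] if "source" in cols else [source] * len(df)
        return cls.from_records(
            zip(df["yeast_orf"], df["human_gene"], src, conf), source=source
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.yeast_orf, p.human_gene, p.source, p.confidence) for p in self.pairs],
            columns=PAIR_COLUMNS,
        )

    def to_tsv(self, path) -> None:
        write_tsv(self.to_frame(), path)

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_keys(self) -> set[tuple[str, str]]:
        """Distinct (yeast, human) pairs, ignoring source."""
        return {(p.yeast_orf, p.human_gene) for p in self.pairs}

    @property
    def yeast_multiplicity(self) -> dict[str, int]:
        """yeast ORF -> number of distinct human orthologs."""
        mult: dict[str, set[str]] = {}
        for y, h in self.pair_keys():
            mult.setdefault(y, set()).add(h)
        return {y: len(hs) for y, hs in mult.items()}

    @property
    def human_multiplicity(self) -> dict[str, int]:
        """human gene -> number of distinct yeast orthologs."""
        mult: dict[str, set[str]] = {}
        for y, h in self.pair_keys():
            mult.setdefault(h, set()).add(y)
        return {h: len(ys) for h, ys in mult.items()}

    def yeast_orthologs_of(self, human_gene: str) -> set[str]:
        return {y for y, h in self.pair_keys() if h == human_gene.upper()}


def read_inparanoid_clusters(path) -> HomologyTable:
    """Expand an Inparanoid-style cluster table into ortholog pairs.

    Expected columns: cluster_id, species (``yeast``/``human``), gene.
    Every yeast x human combination within a cluster becomes a pair
    (inparalog semantics: within-species duplicates all inherit the
    cross-species relation).
    """
    df = read_tsv(path)
    df.columns = [c.lower() for c in df.columns]
    pairs = []
    for _, grp in df.groupby("cluster_id"):
        species = grp["species"].str.lower()
        yeast = grp.loc[species == "yeast", "gene"]
        human = grp.loc[species == "human", "gene"]
        for y in yeast:
            for h in human:
                pairs.append((y, h))
    return HomologyTable.from_records(pairs, source="inparanoid")


class PhenotypeTable:
    """Yeast ORF x agent boolean sensitivity calls."""

    def __init__(self, rows: pd.DataFrame, agents: list[str]):
        rows = rows.copy()
        rows["orf"] = rows["orf"].astype(str).str.upper()
        rows["sensitive"] = rows["sensitive"].astype(bool)
        bad = set(rows["agent"]) - set(agents)
        if bad:
            raise ValueError(f"agents {sorted(bad)} not in declared agent list {agents}")
        self.rows = rows[["orf", "agent", "sensitive"]].reset_index(drop=True)
        self.agents = list(agents)

    @classmethod
    def from_long(cls, records: Iterable[tuple[str, str, bool]], agents=None):
        df = pd.DataFrame(records, columns=["orf", "agent", "sensitive"])
        if agents is None:
            agents = sorted(df["agent"].unique())
        return cls(df, agents)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        """Read long (orf, agent, sensitive) or wide (orf, one column per agent)."""
        df = read_tsv(path)
        lower = {c: c.lower() for c in df.columns}
        if {"orf", "agent", "sensitive"} <= set(lower.values()):
            df = df.rename(columns=lower)
            agents = sorted(df["agent"].unique())
            return cls(df, agents)
        # wide layout: first column is the ORF, remaining columns are agents
        # (agent labels keep their case: MMS, 4NQO, tBuOOH, UV)
        orf_col = df.columns[0]
        agents = [c for c in df.columns if c != orf_col]
        long = df.melt(id_vars=orf_col, var_name="agent", value_name="sensitive")
        long = long.rename(columns={orf_col: "orf"})
        long["sensitive"] = long["sensitive"].astype(int).astype(bool)
        return cls(long, agents)

    def to_tsv(self, path) -> None:
        out = self.rows.copy()
        out["sensitive"] = out["sensitive"].astype(int)
        write_tsv(out, path)

    def orfs(self) -> set[str]:
        return set(self.rows["orf"])

    def sensitive_agents(self, orf: str) -> set[str]:
        sel = self.rows[(self.rows["orf"] == orf.upper()) & self.rows["sensitive"]]
        return set(sel["agent"])


@dataclass
class ModulatorPartition:
    """Human genes partitioned by the phenotype of their yeast orthologs."""

    modulator_homologs: set[str]
    nonmodulator_homologs: set[str]
    core_all_agent_homologs: set[str]
    # human gene -> yeast ORF -> agents that ORF is sensitive to
    provenance: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    n_unscreened_orfs: int = 0

    def __post_init__(self):
        overlap = self.modulator_homologs & self.nonmodulator_homologs
        if overlap:
            raise ValueError(f"partition sets overlap: {sorted(overlap)[:5]}")
        if not self.core_all_agent_homologs <= self.modulator_homologs:
            raise ValueError("core_all_agent_homologs must be modulator homologs")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.modulator_homologs):
            rows.append(
                (g, "modulator", int(g in self.core_all_agent_homologs),
                 ";".join(sorted(self.provenance.get(g, {}))))
            )
        for g in sorted(self.nonmodulator_homologs):
            rows.append((g, "nonmodulator", 0, ";".join(sorted(self.provenance.get(g, {})))))
        return pd.DataFrame(rows, columns=["gene", "status", "core_all_agents", "yeast_orfs"])

    def to_tsv(self, path) -> None:
        write_tsv(self.to_frame(), path)


def merge_ortholog_sources(
    a: HomologyTable, b: HomologyTable, mode: Literal["union", "intersection"] = "union"
) -> HomologyTable:
    """Combine two ortholog tables.

    ``union`` keeps every distinct (yeast, human) pair with all contributing
    source labels attached; ``intersection`` keeps only pairs asserted by
    both sources.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    if mode == "union":
        return HomologyTable(list(a.pairs) + list(b.pairs))
    shared = a.pair_keys() & b.pair_keys()
    kept = [p for p in list(a.pairs) + list(b.pairs)
            if (p.yeast_orf, p.human_gene) in shared]
    return HomologyTable(kept)


def project_phenotypes(h: HomologyTable, p: PhenotypeTable) -> ModulatorPartition:
    """Project yeast sensitivity onto human genes via the ortholog map.

    A human gene is a modulator homolog iff at least one of its screened
    yeast orthologs is sensitive to at least one agent (any-ortholog rule);
    a non-modulator homolog iff it has at least one screened ortholog and
    none is sensitive. Orthologs absent from the phenotype table are dropped
    with a logged count, not treated as non-sensitive.
    """
    if len(h) == 0:
        raise ValueError("empty homology table")
    screened = p.orfs()
    # yeast ORF -> agents sensitive (precomputed once)
    sens = (
        p.rows[p.rows["sensitive"]]
        .groupby("orf")["agent"]
        .apply(set)
        .to_dict()
    )
    all_agents = set(p.agents)

    modulators: set[str] = set()
    nonmodulators: set[str] = set()
    core: set[str] = set()
    provenance: dict[str, dict[str, set[str]]] = {}
    unscreened: set[str] = set()

    human_to_yeast: dict[str, set[str]] = {}
    for y, hg in h.pair_keys():
        human_to_yeast.setdefault(hg, set()).add(y)

    for gene, yeasts in human_to_yeast.items():
        screened_yeasts = yeasts & screened
        unscreened |= yeasts - screened
        if not screened_yeasts:
            continue
        gene_prov: dict[str, set[str]] = {}
        is_mod = False
        is_core = False
        for y in screened_yeasts:
            agents = sens.get(y, set())
            if agents:
                is_mod = True
                gene_prov[y] = set(agents)
                if agents >= all_agents:
                    is_core = True
        if is_mod:
            modulators.add(gene)
            provenance[gene] = gene_prov
            if is_core:
                core.add(gene)
        else:
            nonmodulators.add(gene)
            provenance[gene] = {y: set() for y in sorted(screened_yeasts)}

    if unscreened:
        logger.warning(
            "%d yeast ORFs in the ortholog table were not screened; dropped",
            len(unscreened),
        )
    return ModulatorPartition(
        modulator_homologs=modulators,
        nonmodulator_homologs=nonmodulators,
        core_all_agent_homologs=core,
        provenance=provenance,
        n_unscreened_orfs=len(unscreened),
    )
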