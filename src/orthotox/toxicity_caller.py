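"""Clonogenic-survival hit calling for the RNAi toxicity screen.

Each knockdown cell line is exposed to an agent over a dose series in
replicate; survival is measured by colony formation and normalized to
the line's own untreated plating efficiency. Calls are made against the
contemporaneous non-targeting control in log2-ratio space:

* noise region — per dose, the interval of log2(line/non-targeting)
  ratios spanned by the control lines (non-targeting plus non-silenced
  shRNA clones). The non-targeting line's self-ratio is 0, so the region
  always contains 0. It represents the screen's detection limits.
* a line is called at a dose iff (a) its log2 replicate survivals differ
  from the non-targeting control's by Welch's t-test at p < alpha, and
  (b) its log2 ratio lies at least ``low_threshold_log2`` beyond the
  nearest noise-region boundary. A 20% survival change is a 1.20-fold
  ratio, log2(1.20) = 0.26; the high tier (25% change) is log2(1.25) =
  0.32 beyond the boundary.
* the reported call uses the qualifying dose with maximum excess; a line
  with no qualifying dose is "none".

Knockdown QC: a line counts as silenced iff its residual target mRNA is
strictly below 0.60 of control; non-silenced lines join the control pool.

No multiple-testing correction is applied across lines or doses: each
line x agent call is a single declared comparison at alpha, gated by the
effect-size threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORIES = ["high_resistance", "low_resistance", "none",
              "low_sensitivity", "high_sensitivity"]

#: Heatmap glyphs for screen summaries: ++ high resistance ... -- high sensitivity.
CATEGORY_SYMBOLS = {
    "high_resistance": "++",
    "low_resistance": "+",
    "none": "·",
    "low_sensitivity": "−",
    "high_sensitivity": "−−",
}

ROLES = ("test", "nontargeting", "nonsilenced")


@dataclass
class CallerConfig:
    alpha: float = 0.05
    low_threshold_log2: float = 0.26   # 20% change: log2(1.20)
    high_threshold_log2: float = 0.32  # 25% change: log2(1.25)
    knockdown_residual_max: float = 0.60

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")
        if not (0.0 < self.low_threshold_log2 < self.high_threshold_log2):
            raise ValueError("require 0 < low_threshold_log2 < high_threshold_log2")


@dataclass
class SurvivalCurve:
    """Relative survival per dose for one line x agent, with replicates."""

    line: str
    agent: str
    role: str = "test"
    # dose -> array of per-replicate relative survival, plating-normalized
    replicates: dict[float, np.ndarray] = field(default_factory=dict)
    n_zero_colony_corrected: int = 0

    def doses(self) -> list[float]:
        return sorted(self.replicates)

    def mean_survival(self, dose: float) -> float:
        return float(np.mean(self.replicates[dose]))


def relative_survival(obs: pd.DataFrame) -> list[SurvivalCurve]:
    """Convert colony counts to plating-efficiency-normalized survival curves.

    Input columns: line, agent, dose, replicate, colonies, cells_seeded and
    optionally role. Per line x agent: plating efficiency PE is the mean of
    colonies/cells_seeded at dose 0; each replicate's relative survival is
    (colonies/cells_seeded)/PE, capped at 1.0. Zero-colony replicates are
    replaced by 0.5 colonies (continuity correction, keeps log2 finite) and
    counted on the curve.
    """
    required = {"line", "agent", "dose", "replicate", "colonies", "cells_seeded"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"survival table is missing columns {sorted(missing)}")
    if (obs["colonies"] < 0).any():
        raise ValueError("colonies must be >= 0")
    if (obs["cells_seeded"] <= 0).any():
        raise ValueError("cells_seeded must be > 0")
    if (obs["colonies"] > obs["cells_seeded"]).any():
        raise ValueError("colonies cannot exceed cells_seeded")

    curves: list[SurvivalCurve] = []
    for (line, agent), grp in obs.groupby(["line", "agent"], sort=True):
        at0 = grp[grp["dose"] == 0]
        if at0.empty:
            raise ValueError(f"no dose-0 observations for line {line!r}, agent {agent!r}")
        pe = float((at0["colonies"] / at0["cells_seeded"]).mean())
        if pe <= 0:
            raise ValueError(f"plating efficiency is 0 for line {line!r}, agent {agent!r}")
        role = str(grp["role"].iloc[0]) if "role" in grp.columns else "test"
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} for line {line!r}")
        curve = SurvivalCurve(line=str(line), agent=str(agent), role=role)
        n_zero = 0
        for dose, dgrp in grp.groupby("dose", sort=True):
            colonies = dgrp["colonies"].to_numpy(dtype=float)
            n_zero += int((colonies == 0).sum())
            colonies = np.where(colonies == 0, 0.5, colonies)
            rel = (colonies / dgrp["cells_seeded"].to_numpy(dtype=float)) / pe
            curve.replicates[float(dose)] = np.minimum(rel, 1.0)
        curve.n_zero_colony_corrected = n_zero
        if n_zero:
            logger.info("line %s/%s: %d zero-colony replicates corrected to 0.5",
                        line, agent, n_zero)
        curves.append(curve)
    return curves


@dataclass
class NoiseRegion:
    """Per-dose control-spanned interval of log2 survival ratios for one agent."""

    agent: str
    lo: dict[float, float]
    hi: dict[float, float]

    def __post_init__(self):
        for d in self.lo:
            if not (self.lo[d] <= 0.0 <= self.hi[d]):
                raise ValueError(
                    f"noise region at dose {d} must contain 0 "
                    f"(non-targeting self-ratio): [{self.lo[d]}, {self.hi[d]}]"
                )

    def doses(self) -> list[float]:
        return sorted(self.lo)


def build_noise_region(
    control_curves: Sequence[SurvivalCurve], cfg: CallerConfig | None = None
) -> dict[str, NoiseRegion]:
    """Screen detection limits from the control lines, per agent.

    ``control_curves`` holds, per agent, exactly one non-targeting curve
    (role ``nontargeting``) and any number of non-silenced clones (role
    ``nonsilenced``). Per dose, each control line contributes
    log2(mean survival / mean survival of the non-targeting line); the
    region is [min, max] over control lines. The non-targeting line itself
    contributes 0, so the interval always contains 0.
    """
    by_agent: dict[str, list[SurvivalCurve]] = {}
    for c in control_curves:
        by_agent.setdefault(c.agent, []).append(c)
    regions: dict[str, NoiseRegion] = {}
    for agent, curves in sorted(by_agent.items()):
        nts = [c for c in curves if c.role == "nontargeting"]
        if len(nts) != 1:
            raise ValueError(
                f"agent {agent!r}: need exactly one non-targeting control, got {len(nts)}"
            )
        nt = nts[0]
        lo: dict[float, float] = {}
        hi: dict[float, float] = {}
        for dose in nt.doses():
            ratios = [0.0]  # the non-targeting control's self-ratio
            for c in curves:
                if c is nt:
                    continue
                if dose not in c.replicates:
                    raise ValueError(
                        f"control line {c.line!r} lacks dose {dose} for agent {agent!r}"
                    )
                ratios.append(math.log2(c.mean_survival(dose) / nt.mean_survival(dose)))
            lo[dose], hi[dose] = min(ratios), max(ratios)
        regions[agent] = NoiseRegion(agent=agent, lo=lo, hi=hi)
    return regions


@dataclass
class ToxicityCall:
    line: str
    agent: str
    category: str
    best_dose: float | None
    effect_log2_beyond_noise: float
    p_value: float | None
    ratio_log2: float | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def symbol(self) -> str:
        return CATEGORY_SYMBOLS[self.category]


def call_toxicity(
    curve: SurvivalCurve,
    nontargeting: SurvivalCurve,
    noise: NoiseRegion,
    cfg: CallerConfig | None = None,
) -> ToxicityCall:
    """Call one line x agent into one of the five toxicity categories.

    Per dose d: r(d) = log2(mean survival / mean non-targeting survival);
    excess(d) is how far r(d) lies outside [lo(d), hi(d)] (0 inside); the
    p-value is a two-sided Welch t-test on log2 replicate survivals. A dose
    qualifies at the low tier iff p < alpha and |excess| >= 0.26 and at the
    high tier iff additionally |excess| >= 0.32; the call is made at the
    qualifying dose of maximum |excess|.
    """
    cfg = cfg or CallerConfig()
    if curve.agent != nontargeting.agent:
        raise ValueError(
            f"agent mismatch: {curve.agent!r} vs control {nontargeting.agent!r}"
        )
    if curve.doses() != nontargeting.doses():
        raise ValueError(
            f"dose grids differ for line {curve.line!r} vs control: "
            f"{curve.doses()} vs {nontargeting.doses()}"
        )
    best: tuple[float, float, float, float] | None = None  # |excess|, excess, p, dose
    for dose in curve.doses():
        x = curve.replicates[dose]
        y = nontargeting.replicates[dose]
        if len(x) < 2 or len(y) < 2:
            raise ValueError(
                f"need >=2 replicates at dose {dose} for a t-test "
                f"(line {curve.line!r})"
            )
        r = math.log2(float(np.mean(x)) / float(np.mean(y)))
        lo, hi = noise.lo[dose], noise.hi[dose]
        if r > hi:
            excess = r - hi
        elif r < lo:
            excess = r - lo
        else:
            excess = 0.0
        if abs(excess) < cfg.low_threshold_log2:
            continue  # cannot qualify regardless of p; skip the t-test
        t_res = stats.ttest_ind(np.log2(x), np.log2(y), equal_var=False)
        p = float(t_res.pvalue)
        if p < cfg.alpha:
            cand = (abs(excess), excess, p, dose, r)
            if best is None or cand[0] > best[0]:
                best = cand
    if best is None:
        return ToxicityCall(curve.line, curve.agent, "none", None, 0.0, None)
    abs_exc, excess, p, dose, r = best
    tier = "high" if abs_exc >= cfg.high_threshold_log2 else "low"
    direction = "resistance" if excess > 0 else "sensitivity"
    return ToxicityCall(
        line=curve.line,
        agent=curve.agent,
        category=f"{tier}_{direction}",
        best_dose=dose,
        effect_log2_beyond_noise=excess,
        p_value=p,
        ratio_log2=r,
    )


def classify_knockdown(residual: float, cfg: CallerConfig | None = None) -> str:
    """Silenced iff residual target mRNA is strictly below 0.60 of control."""
    cfg = cfg or CallerConfig()
    if residual < 0:
        raise ValueError(f"residual mRNA fraction cannot be negative: {residual}")
    return "silenced" if residual < cfg.knockdown_residual_max else "non_silenced"


@dataclass
class FisherResult:
    p_value: float
    degenerate: bool = False  # a zero margin: p defined as 1


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher's exact test by exact integer enumeration.

    Sums the conditional hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (the standard minimum-likelihood two-sided rule). Computed on
    integer weights C(r1, a) * C(r2, c1 - a), so comparisons are exact.
    A zero margin makes the table degenerate: p is defined as 1, flagged.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"cell counts must be non-negative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return FisherResult(1.0, degenerate=True)
    amin, amax = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(amin, amax + 1)}
    w_obs = weights[a]
    numer = sum(w for w in weights.values() if w <= w_obs)
    return FisherResult(numer / comb(n, c1))


def _pct_half_away(numerator: int, denominator: int) -> int:
    """Whole-percent rounding, halves away from zero."""
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ScreenSummary:
    n_called_lines: int
    category_counts: dict[str, dict[str, int]]  # agent -> category -> count
    n_modulating: int
    n_sensitivity_modulators: int
    n_resistance_modulators: int
    n_high_modulators: int
    pct_modulating: int
    pct_sensitivity: int
    pct_resistance: int
    pct_high: int
    contingency: list[list[int]] | None = None
    fisher_p: float | None = None
    fisher_degenerate: bool = False


def summarize_screen(
    calls: Iterable[ToxicityCall],
    comparison_calls: Iterable[ToxicityCall] | None = None,
) -> ScreenSummary:
    """Screen-level summary over per-line x agent calls.

    A line is a modulator iff any agent call is not "none"; a sensitivity
    modulator iff any call is (low|high)_sensitivity; a high modulator iff
    any call is high_(sensitivity|resistance). Percentages are whole-percent,
    halves rounded away from zero. With ``comparison_calls`` (e.g. randomly
    selected genes), a 2x2 modulator-vs-not contingency table and two-sided
    Fisher p are attached.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("empty call set")
    by_line: dict[str, list[ToxicityCall]] = {}
    agents: set[str] = set()
    for c in calls:
        by_line.setdefault(c.line, []).append(c)
        agents.add(c.agent)
    n_agents_per_line = {ln: len({c.agent for c in cs}) for ln, cs in by_line.items()}
    if len(set(n_agents_per_line.values())) > 1:
        raise ValueError("every line must have calls for the same agents")

    category_counts = {
        agent: {cat: 0 for cat in CATEGORIES} for agent in sorted(agents)
    }
    for c in calls:
        category_counts[c.agent][c.category] += 1

    def line_flags(cs: list[ToxicityCall]) -> tuple[bool, bool, bool, bool]:
        cats = {c.category for c in cs}
        mod = bool(cats - {"none"})
        sens = bool(cats & {"low_sensitivity", "high_sensitivity"})
        res = bool(cats & {"low_resistance", "high_resistance"})
        high = bool(cats & {"high_sensitivity", "high_resistance"})
        return mod, sens, res, high

    flags = [line_flags(cs) for cs in by_line.values()]
    n_lines = len(by_line)
    n_mod = sum(f[0] for f in flags)
    n_sens = sum(f[1] for f in flags)
    n_res = sum(f[2] for f in flags)
    n_high = sum(f[3] for f in flags)

    summary = ScreenSummary(
        n_called_lines=n_lines,
        category_counts=category_counts,
        n_modulating=n_mod,
        n_sensitivity_modulators=n_sens,
        n_resistance_modulators=n_res,
        n_high_modulators=n_high,
        pct_modulating=_pct_half_away(n_mod, n_lines),
        pct_sensitivity=_pct_half_away(n_sens, n_lines),
        pct_resistance=_pct_half_away(n_res, n_lines),
        pct_high=_pct_half_away(n_high, n_lines),
    )
    if comparison_calls is not None:
        comp = list(comparison_calls)
        comp_by_line: dict[str, list[ToxicityCall]] = {}
        for c in comp:
            comp_by_line.setdefault(c.line, []).append(c)
        comp_mod = sum(line_flags(cs)[0] for cs in comp_by_line.values())
        comp_n = len(comp_by_line)
        table = [[n_mod, n_lines - n_mod], [comp_mod, comp_n - comp_mod]]
        res = fisher_exact_2x2(table)
        summary.contingency = table
        summary.fisher_p = res.p_value
        summary.fisher_degenerate = res.degenerate
    return summary


def calls_to_frame(calls: Iterable[ToxicityCall]) -> pd.DataFrame:
    rows = [
        (c.line, c.agent, c.category, c.symbol, c.best_dose,
         round(c.effect_log2_beyond_noise, 6),
         None if c.p_value is None else float(f"{c.p_value:.6g}"),
         None if c.ratio_log2 is None else round(c.ratio_log2, 6))
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["line", "agent", "category", "symbol", "best_dose",
                 "effect_log2_beyond_noise", "p_value", "ratio_log2"],
    )


def heatmap_table(calls: Iterable[ToxicityCall]) -> pd.DataFrame:
    """Line x agent table of call glyphs (++ / + / · / − / −−)."""
    df = calls_to_frame(calls)
    return df.pivot(index="line", columns="agent", values="symbol").fillna("·")
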