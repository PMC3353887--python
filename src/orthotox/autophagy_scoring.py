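"""Autophagy scoring from per-cell LC3 puncta counts.

A cell is scored autophagic when it shows more than ``threshold`` (default
5) visible LC3-GFP puncta, each punctum marking an autophagosome. Condition
fractions are compared to an untreated reference by two-sided Fisher's
exact test on the autophagic/non-autophagic counts, with significance
stars at p < 0.05 (*) and p < 0.01 (**). A chi-square variant is offered
for large cell counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd
from scipy import stats

from .toxicity_caller import fisher_exact_2x2

logger = logging.getLogger(__name__)

DEFAULT_PUNCTA_THRESHOLD = 5


@dataclass
class ConditionScore:
    condition: str
    n_cells: int
    n_autophagic: int

    @property
    def fraction(self) -> float:
        return self.n_autophagic / self.n_cells


@dataclass
class AutophagyResult:
    condition: str
    n_cells: int
    n_autophagic: int
    fraction: float
    fold_vs_reference: float | None  # None when the reference fraction is 0
    p_vs_reference: float
    stars: str

    def __post_init__(self):
        if self.n_autophagic > self.n_cells:
            raise ValueError("n_autophagic cannot exceed n_cells")


def stars_for_p(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def score_autophagy(
    data: pd.DataFrame, threshold: int = DEFAULT_PUNCTA_THRESHOLD
) -> dict[str, ConditionScore]:
    """Per-condition autophagic-cell counts from a puncta table.

    Input columns: condition, cell_id, puncta. Autophagic iff
    puncta > threshold (strict). Conditions with no cells are excluded
    with a warning.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    required = {"condition", "puncta"}
    if not required <= set(data.columns):
        raise ValueError(f"puncta table needs columns {sorted(required)}")
    counts = data["puncta"]
    if (counts < 0).any() or (counts != counts.astype(int)).any():
        raise ValueError("puncta counts must be non-negative integers")
    out: dict[str, ConditionScore] = {}
    for cond, grp in data.groupby("condition", sort=True):
        if grp.empty:
            logger.warning("condition %r has no cells; excluded", cond)
            continue
        n_auto = int((grp["puncta"] > threshold).sum())
        out[str(cond)] = ConditionScore(str(cond), len(grp), n_auto)
    return out


def compare_conditions(
    a: ConditionScore,
    b: ConditionScore,
    method: Literal["fisher", "chi2"] = "fisher",
) -> tuple[float, float | None, str]:
    """(p, fold a/b, stars) for condition ``a`` against reference ``b``."""
    if a.n_cells < 1 or b.n_cells < 1:
        raise ValueError("both conditions need at least one cell")
    table = [
        [a.n_autophagic, a.n_cells - a.n_autophagic],
        [b.n_autophagic, b.n_cells - b.n_autophagic],
    ]
    if method == "fisher":
        p = fisher_exact_2x2(table).p_value
    elif method == "chi2":
        p = float(stats.chi2_contingency(table, correction=True).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    fold = None if b.fraction == 0 else a.fraction / b.fraction
    return p, fold, stars_for_p(p)


def autophagy_report(
    scores: dict[str, ConditionScore],
    reference: str,
    method: Literal["fisher", "chi2"] = "fisher",
) -> list[AutophagyResult]:
    """Score every condition against the reference condition."""
    if reference not in scores:
        raise ValueError(f"reference condition {reference!r} not in data")
    ref = scores[reference]
    results = []
    for cond in sorted(scores):
        s = scores[cond]
        p, fold, star = compare_conditions(s, ref, method=method)
        results.append(AutophagyResult(
            condition=cond, n_cells=s.n_cells, n_autophagic=s.n_autophagic,
            fraction=s.fraction, fold_vs_reference=fold,
            p_vs_reference=p, stars=star,
        ))
    return results


def results_to_frame(results: Iterable[AutophagyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.condition, r.n_cells, r.n_autophagic, round(r.fraction, 6),
          None if r.fold_vs_reference is None else round(r.fold_vs_reference, 6),
          float(f"{r.p_vs_reference:.6g}"), r.stars)
         for r in results],
        columns=["condition", "n_cells", "n_autophagic", "fraction",
                 "fold_vs_reference", "p_vs_reference", "stars"],
    )
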