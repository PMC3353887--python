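"""Clonogenic survival normalization, noise region, category calling,
screen summaries, and the exact Fisher test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthotox.toxicity_caller import (
    CallerConfig,
    ToxicityCall,
    build_noise_region,
    call_toxicity,
    classify_knockdown,
    fisher_exact_2x2,
    heatmap_table,
    relative_survival,
    summarize_screen,
)

from conftest import make_survival_frame


def curves_by_line(curves):
    return {(c.line, c.agent): c for c in curves}


class TestRelativeSurvival:
    def test_arithmetic(self):
        # 100 seeded, PE = 0.5 (from dose 0: 50/100), 10 colonies -> 0.2
        obs = pd.DataFrame(
            [("L", "MMS", 0.0, 1, 50, 100, "test"),
             ("L", "MMS", 0.0, 2, 50, 100, "test"),
             ("L", "MMS", 1.0, 1, 10, 100, "test"),
             ("L", "MMS", 1.0, 2, 20, 100, "test")],
            columns=["line", "agent", "dose", "replicate", "colonies",
                     "cells_seeded", "role"])
        (curve,) = relative_survival(obs)
        assert curve.replicates[0.0] == pytest.approx([1.0, 1.0])
        assert curve.replicates[1.0] == pytest.approx([0.2, 0.4])

    def test_capped_at_one(self):
        obs = pd.DataFrame(
            [("L", "MMS", 0.0, 1, 40, 100, "test"),
             ("L", "MMS", 0.0, 2, 60, 100, "test"),
             ("L", "MMS", 1.0, 1, 70, 100, "test"),
             ("L", "MMS", 1.0, 2, 10, 100, "test")],
            columns=["line", "agent", "dose", "replicate", "colonies",
                     "cells_seeded", "role"])
        (curve,) = relative_survival(obs)
        assert curve.replicates[1.0].max() == 1.0

    def test_zero_colonies_get_continuity_correction(self):
        obs = pd.DataFrame(
            [("L", "MMS", 0.0, 1, 50, 100, "test"),
             ("L", "MMS", 2.0, 1, 0, 1000, "test")],
            columns=["line", "agent", "dose", "replicate", "colonies",
                     "cells_seeded", "role"])
        (curve,) = relative_survival(obs)
        assert curve.n_zero_colony_corrected == 1
        assert curve.replicates[2.0][0] == pytest.approx((0.5 / 1000) / 0.5)

    def test_missing_dose_zero_is_an_error(self):
        obs = pd.DataFrame(
            [("L", "MMS", 1.0, 1, 10, 100, "test")],
            columns=["line", "agent", "dose", "replicate", "colonies",
                     "cells_seeded", "role"])
        with pytest.raises(ValueError, match="dose-0"):
            relative_survival(obs)

    def test_matches_naive_per_row_recomputation(self):
        rng = np.random.default_rng(8)
        frame = make_survival_frame(
            {f"L{i}": {"role": "test", "MMS": float(rng.normal(0, 0.3))}
             for i in range(6)},
            cv=0.2, rng=rng)
        curves = curves_by_line(relative_survival(frame))
        # oracle: spreadsheet-style recomputation straight off the rows
        for (line, agent), grp in frame.groupby(["line", "agent"]):
            pe = (grp[grp["dose"] == 0]["colonies"]
                  / grp[grp["dose"] == 0]["cells_seeded"]).mean()
            for _, row in grp.iterrows():
                col = row["colonies"] if row["colonies"] > 0 else 0.5
                expected = min((col / row["cells_seeded"]) / pe, 1.0)
                got = curves[(line, agent)].replicates[row["dose"]][
                    int(row["replicate"]) - 1]
                assert got == pytest.approx(expected)


class TestNoiseRegion:
    def test_only_nontargeting_gives_zero_region(self):
        frame = make_survival_frame({"NT": {"role": "nontargeting"}})
        regions = build_noise_region(relative_survival(frame))
        r = regions["MMS"]
        assert all(r.lo[d] == 0 == r.hi[d] for d in r.doses())

    def test_min_max_of_control_ratios(self):
        frame = make_survival_frame(
            {"NT": {"role": "nontargeting"},
             "NS1": {"role": "nonsilenced", "MMS": -0.1},
             "NS2": {"role": "nonsilenced", "MMS": 0.05}},
            seeded=100_000)  # large seeding so colony rounding is negligible
        regions = build_noise_region(relative_survival(frame))
        r = regions["MMS"]
        for d in r.doses():
            if d == 0:
                continue
            # tolerance reflects integer colony counts at 1e5 seeded cells
            assert r.lo[d] == pytest.approx(-0.1, abs=1e-3)
            assert r.hi[d] == pytest.approx(0.05, abs=1e-3)

    def test_region_always_contains_zero(self):
        frame = make_survival_frame(
            {"NT": {"role": "nontargeting"},
             "NS1": {"role": "nonsilenced", "MMS": 0.2},
             "NS2": {"role": "nonsilenced", "MMS": 0.3}})
        r = build_noise_region(relative_survival(frame))["MMS"]
        assert all(r.lo[d] <= 0 <= r.hi[d] for d in r.doses())

    def test_width_grows_with_replicate_cv(self):
        widths = []
        for cv in (0.02, 0.10, 0.30):
            rng = np.random.default_rng(123)
            frame = make_survival_frame(
                {"NT": {"role": "nontargeting"},
                 **{f"NS{i}": {"role": "nonsilenced"} for i in range(4)}},
                cv=cv, rng=rng, seeded=100_000)
            r = build_noise_region(relative_survival(frame))["MMS"]
            widths.append(np.mean([r.hi[d] - r.lo[d] for d in r.doses() if d > 0]))
        assert widths[0] < widths[1] < widths[2]

    def test_no_nontargeting_control_is_an_error(self):
        frame = make_survival_frame({"NS": {"role": "nonsilenced"}})
        with pytest.raises(ValueError, match="non-targeting"):
            build_noise_region(relative_survival(frame))


def call_fixture(shift, cv=0.03, seed=0, n_replicates=3):
    rng = np.random.default_rng(seed)
    frame = make_survival_frame(
        {"NT": {"role": "nontargeting"},
         "NS1": {"role": "nonsilenced"},
         "KD": {"role": "test", "MMS": shift}},
        cv=cv, rng=rng, n_replicates=n_replicates, seeded=100_000)
    curves = curves_by_line(relative_survival(frame))
    regions = build_noise_region(
        [c for c in curves.values() if c.role != "test"])
    return curves[("KD", "MMS")], curves[("NT", "MMS")], regions["MMS"]


class TestCallToxicity:
    def test_identical_curve_called_none(self):
        curve, nt, region = call_fixture(0.0, cv=0.0)
        call = call_toxicity(curve, nt, region)
        assert call.category == "none"
        assert call.effect_log2_beyond_noise == 0.0

    def test_threshold_constants_match_fold_changes(self):
        cfg = CallerConfig()
        assert round(math.log2(1.20), 2) == cfg.low_threshold_log2 == 0.26
        assert round(math.log2(1.25), 2) == cfg.high_threshold_log2 == 0.32

    def test_direction_and_tier(self):
        curve, nt, region = call_fixture(-0.8)
        assert call_toxicity(curve, nt, region).category == "high_sensitivity"
        curve, nt, region = call_fixture(0.8)
        assert call_toxicity(curve, nt, region).category == "high_resistance"
        # between low (0.26) and high (0.32) beyond a ~zero-width region
        curve, nt, region = call_fixture(-0.29, cv=0.005)
        assert call_toxicity(curve, nt, region).category == "low_sensitivity"

    def test_call_requires_significance_and_excess_jointly(self):
        # large shift but a single pair of wildly varying replicates: the
        # t-test cannot reach alpha, so no call is made
        curve, nt, region = call_fixture(-0.8, cv=1.5, n_replicates=2, seed=4)
        call = call_toxicity(curve, nt, region)
        if call.category != "none":  # only a qualifying dose may be reported
            assert call.p_value < 0.05

    def test_never_reports_p_above_alpha(self):
        rng = np.random.default_rng(77)
        for trial in range(20):
            curve, nt, region = call_fixture(
                float(rng.normal(0, 0.5)), cv=0.2, seed=trial)
            call = call_toxicity(curve, nt, region)
            if call.category != "none":
                assert call.p_value < 0.05
                assert abs(call.effect_log2_beyond_noise) >= 0.26

    def test_mismatched_grid_and_single_replicate_errors(self):
        curve, nt, region = call_fixture(0.0)
        bad = type(curve)(line="X", agent="MMS", role="test",
                          replicates={0.0: curve.replicates[0.0]})
        with pytest.raises(ValueError, match="dose grids"):
            call_toxicity(bad, nt, region)
        single = type(curve)(
            line="X", agent="MMS", role="test",
            replicates={d: v[:1] for d, v in curve.replicates.items()})
        with pytest.raises(ValueError, match="replicates"):
            call_toxicity(single, nt, region)


class TestClassifyKnockdown:
    @pytest.mark.parametrize("residual,expected", [
        (0.59, "silenced"), (0.60, "non_silenced"), (0.0, "silenced"),
        (0.95, "non_silenced"),
    ])
    def test_strict_threshold(self, residual, expected):
        assert classify_knockdown(residual) == expected

    def test_negative_residual_rejected(self):
        with pytest.raises(ValueError):
            classify_knockdown(-0.1)


def make_calls(spec):
    """spec: list of (line, {agent: category})"""
    calls = []
    for line, cats in spec:
        for agent, cat in cats.items():
            calls.append(ToxicityCall(line, agent, cat,
                                      1.0 if cat != "none" else None,
                                      0.5 if cat != "none" else 0.0,
                                      0.01 if cat != "none" else None))
    return calls


def screen_34_lines():
    """Category table with 14 sensitivity / 11 resistance / 19 high lines."""
    spec = []
    for i in range(10):
        spec.append((f"S{i}", {"MMS": "high_sensitivity", "UV": "none"}))
    for i in range(4):
        spec.append((f"s{i}", {"MMS": "low_sensitivity", "UV": "none"}))
    for i in range(9):
        spec.append((f"R{i}", {"MMS": "high_resistance", "UV": "none"}))
    for i in range(2):
        spec.append((f"r{i}", {"MMS": "low_resistance", "UV": "none"}))
    for i in range(9):
        spec.append((f"N{i}", {"MMS": "none", "UV": "none"}))
    return make_calls(spec)


class TestSummarizeScreen:
    def test_printed_percentages_from_category_counts(self):
        summary = summarize_screen(screen_34_lines())
        assert summary.n_called_lines == 34
        assert summary.n_sensitivity_modulators == 14
        assert summary.n_resistance_modulators == 11
        assert summary.n_high_modulators == 19
        assert summary.n_modulating == 25
        assert summary.pct_sensitivity == 41
        assert summary.pct_resistance == 32
        assert summary.pct_high == 56
        assert summary.pct_modulating == 74

    def test_category_counts_sum_to_lines_per_agent(self):
        summary = summarize_screen(screen_34_lines())
        for agent, counts in summary.category_counts.items():
            assert sum(counts.values()) == 34

    def test_contingency_and_fisher_vs_comparison(self):
        comparison = make_calls(
            [("C0", {"MMS": "high_sensitivity", "UV": "none"})]
            + [(f"C{i}", {"MMS": "none", "UV": "none"}) for i in range(1, 4)])
        summary = summarize_screen(screen_34_lines(), comparison)
        assert summary.contingency == [[25, 9], [1, 3]]
        assert round(summary.fisher_p, 2) == 0.08

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            summarize_screen([])

    def test_heatmap_symbols(self):
        calls = make_calls([("L1", {"MMS": "high_resistance",
                                    "UV": "high_sensitivity"})])
        heat = heatmap_table(calls)
        assert heat.loc["L1", "MMS"] == "++"
        assert heat.loc["L1", "UV"] == "−−"


class TestFisherExact:
    def test_screen_vs_random_table(self):
        res = fisher_exact_2x2([[25, 9], [1, 3]])
        assert round(res.p_value, 2) == 0.08
        assert round(res.p_value, 4) == 0.0842
        # oracle: enumerate a in 0..4 over tables with fixed margins
        w = {a: math.comb(26, a) * math.comb(12, 4 - a) for a in range(5)}
        expected = sum(v for v in w.values() if v <= w[1]) / math.comb(38, 4)
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_symmetric_extreme_tables(self):
        for k in (2, 5, 8):
            res = fisher_exact_2x2([[k, 0], [0, k]])
            assert res.p_value == pytest.approx(2 / math.comb(2 * k, k))

    def test_zero_margin_flagged(self):
        res = fisher_exact_2x2([[0, 0], [3, 4]])
        assert res.p_value == 1.0 and res.degenerate

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(300):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            ours = fisher_exact_2x2(t.tolist()).p_value
            ref = stats.fisher_exact(t, alternative="two-sided").pvalue
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)
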