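import dataclasses

import numpy as np
import pandas as pd
import pytest

import rootmix as rm


def _frame(fractions, **factors):
    n = len(fractions)
    data = {"fraction": fractions, "derived": [False] * n}
    for name, values in factors.items():
        data[name] = values
    return pd.DataFrame(data)


@pytest.fixture(scope="module")
def joined_frame(baseline_study, canonical_pair):
    table, _, _ = baseline_study
    results = rm.run_mixing(table, canonical_pair, draws=0)
    augmented = rm.augment_with_pooled(table, results, canonical_pair)
    return rm.results_frame(augmented, results)


class TestSummarize:
    def test_single_cell_arithmetic(self):
        frame = _frame([0.4, 0.6], depth=["D1", "D1"])
        (s,) = rm.summarize(frame, ["depth"])
        assert s.mean == pytest.approx(0.5)
        assert s.se == pytest.approx(0.1)
        assert s.n == 2

    def test_singleton_cell_has_no_se(self):
        frame = _frame([0.4], depth=["D1"])
        (s,) = rm.summarize(frame, ["depth"])
        assert s.mean == 0.4 and s.se is None and s.n == 1

    def test_unknown_factor(self, joined_frame):
        with pytest.raises(rm.SpecificationError):
            rm.summarize(joined_frame, ["horizon"])

    def test_weighted_grand_mean_conservation(self, joined_frame):
        cells = rm.summarize(joined_frame, ["treatment", "depth"])
        total = sum(s.mean * s.n for s in cells)
        n = sum(s.n for s in cells)
        assert total / n == pytest.approx(joined_frame["fraction"].mean())


class TestPermutationMainEffect:
    def test_all_equal_gives_p_one(self):
        frame = _frame([0.5] * 12,
                       depth=["D1", "D2", "D3"] * 4,
                       plot_id=[f"P{i//3}" for i in range(12)],
                       block=[1] * 12)
        ft = rm.permutation_main_effect(frame, "depth", B=199, seed=0)
        assert ft.p_perm == 1.0

    def test_extreme_position_effect_hits_floor(self):
        # 12 plots x 3 depths, two positions per cell, maximal separation:
        # the permutation minimum 1/(B+1) is attained
        rows = []
        for p in range(12):
            for d in ("D1", "D2", "D3"):
                rows.append((f"P{p:02d}", d, "row", 0.9))
                rows.append((f"P{p:02d}", d, "inter_row", 0.1))
        frame = pd.DataFrame(rows, columns=["plot_id", "depth", "position",
                                            "fraction"])
        ft = rm.permutation_main_effect(frame, "position", B=999, seed=0)
        assert ft.p_perm == pytest.approx(1 / 1000)

    def test_exact_enumeration_for_tiny_designs(self, caplog):
        # 2 plots, one sample per position cell: 2^2 = 4 < 20 permutations
        frame = pd.DataFrame({
            "plot_id": ["P1", "P1", "P2", "P2"],
            "depth": ["D1", "D1", "D1", "D1"],
            "position": ["row", "inter_row"] * 2,
            "fraction": [0.9, 0.1, 0.8, 0.2],
        })
        with caplog.at_level("INFO", logger="rootmix"):
            ft = rm.permutation_main_effect(frame, "position", B=999)
        assert any("enumerating" in r.message for r in caplog.records)
        assert ft.B == 4
        # the identity and the full swap tie the observed statistic
        assert ft.p_perm == pytest.approx(2 / 4)

    def test_invariant_to_level_relabeling(self, joined_frame):
        sub = rm.subset_frame(joined_frame, "positions")
        a = rm.permutation_main_effect(sub, "position", B=499, seed=7)
        renamed = sub.assign(position=sub["position"].map(
            {"row": "z_row", "inter_row": "a_between"}))
        b = rm.permutation_main_effect(renamed, "position", B=499, seed=7)
        assert a.p_perm == b.p_perm
        assert a.statistic == pytest.approx(b.statistic)

    def test_bit_reproducible(self, joined_frame):
        sub = rm.subset_frame(joined_frame, "full")
        a = rm.permutation_main_effect(sub, "treatment", B=499, seed=3)
        b = rm.permutation_main_effect(sub, "treatment", B=499, seed=3)
        assert a == b

    def test_single_level_factor_rejected(self):
        frame = _frame([0.5, 0.6], depth=["D1", "D1"],
                       plot_id=["P1", "P1"], block=[1, 1])
        with pytest.raises(rm.DesignError):
            rm.permutation_main_effect(frame, "depth", B=199)


class TestPermutationInteraction:
    def test_crossover_truth_hits_floor(self):
        # effect of position reverses across depth: strong interaction
        rng = np.random.default_rng(0)
        rows = []
        for p in range(12):
            for d, sign in (("D1", 1.0), ("D2", -1.0)):
                rows.append((f"P{p:02d}", d, "row",
                             0.5 + 0.3 * sign + rng.normal(0, 0.01)))
                rows.append((f"P{p:02d}", d, "inter_row",
                             0.5 - 0.3 * sign + rng.normal(0, 0.01)))
        frame = pd.DataFrame(rows, columns=["plot_id", "depth", "position",
                                            "fraction"])
        ft = rm.permutation_interaction(frame, "depth", "position",
                                        B=999, seed=0)
        assert ft.p_perm == pytest.approx(1 / 1000)
        assert ft.effect == "depth:position"

    def test_single_level_factor_rejected(self, joined_frame):
        sub = rm.subset_frame(joined_frame, "positions")
        one_depth = sub[sub["depth"] == "D1"]
        with pytest.raises(rm.DesignError):
            rm.permutation_interaction(one_depth, "depth", "position", B=199)

    def test_empty_cell_rejected(self, joined_frame):
        sub = rm.subset_frame(joined_frame, "positions")
        holed = sub[~((sub["depth"] == "D1") & (sub["position"] == "row"))]
        with pytest.raises(rm.DesignError):
            rm.permutation_interaction(holed, "depth", "position", B=199)

    def test_bit_reproducible(self, joined_frame):
        sub = rm.subset_frame(joined_frame, "positions")
        a = rm.permutation_interaction(sub, "depth", "position", B=499,
                                       seed=11)
        b = rm.permutation_interaction(sub, "depth", "position", B=499,
                                       seed=11)
        assert a == b


class TestReporting:
    def test_cell_formatting(self):
        assert rm.format_cell(0.44, 0.07, 16) == "0.44 ± 0.07 (16)"
        assert rm.format_cell(0.4, None, 1) == "0.40 (1)"

    def test_table_grid(self, joined_frame):
        report = rm.report_table2(rm.subset_frame(joined_frame, "full"))
        lines = report.splitlines()
        assert len(lines) == 4  # header + 3 depth rows
        assert lines[0].split()[-3:] == ["BIOORG1", "BIOORG2", "CONFYM2"]
        assert report.count("±") == 9

    def test_missing_treatment_column_omitted(self, joined_frame, caplog):
        partial = joined_frame[joined_frame["treatment"] != "CONFYM2"]
        with caplog.at_level("WARNING", logger="rootmix"):
            report = rm.report_table2(rm.subset_frame(partial, "full"))
        assert "CONFYM2" not in report
        assert any("CONFYM2" in r.message for r in caplog.records)
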