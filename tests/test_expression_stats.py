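import numpy as np
import pandas as pd
import pytest

from roidriver.expression_stats import (
    assign_mutation_groups,
    diff_expression,
    filter_expressed,
    has_min_roi_mutations,
    s_score,
)
from roidriver.region_model import Region
from roidriver.synthetic_data import simulate_expression

from conftest import mutation_table


@pytest.fixture
def hotspot_region():
    return Region(protein_id="P1", gene="G1", start=10, end=20, region_class="IDR")


class TestAssignMutationGroups:
    def test_within_takes_precedence_over_outside(self, hotspot_region):
        muts = mutation_table([("S1", "G1", 15), ("S1", "G1", 200)])
        groups = assign_mutation_groups(muts, hotspot_region, "G1", ["S1", "S2"])
        assert groups == {"within_ROI": {"S1"}, "outside_ROI": set(), "wild_type": {"S2"}}

    def test_absent_sample_is_wild_type(self, hotspot_region):
        muts = mutation_table([("S1", "G1", 200)])
        groups = assign_mutation_groups(muts, hotspot_region, "G1", ["S1", "S2"])
        assert groups["outside_ROI"] == {"S1"}
        assert groups["wild_type"] == {"S2"}

    def test_partition_is_exhaustive_and_disjoint(self, hotspot_region):
        rng = np.random.default_rng(2)
        samples = [f"S{i}" for i in range(50)]
        events = [
            (samples[int(rng.integers(0, 50))], "G1", int(rng.integers(1, 300)))
            for _ in range(80)
        ]
        groups = assign_mutation_groups(mutation_table(events), hotspot_region, "G1", samples)
        parts = [groups["within_ROI"], groups["outside_ROI"], groups["wild_type"]]
        assert sum(len(p) for p in parts) == 50
        assert set().union(*parts) == set(samples)

    def test_min_roi_mutation_rule(self, hotspot_region):
        muts = mutation_table([("S1", "G1", 15), ("S2", "G1", 16)])
        groups = assign_mutation_groups(muts, hotspot_region, "G1", ["S1", "S2", "S3"])
        assert not has_min_roi_mutations(groups)
        assert has_min_roi_mutations(groups, min_within=2)


def _matrix(values, samples):
    return pd.DataFrame(values, index=[f"G{i}" for i in range(len(values))],
                        columns=samples)


class TestDiffExpression:
    def test_expression_missingness_filter(self):
        samples = [f"A{i}" for i in range(8)] + [f"B{i}" for i in range(8)]
        # G0: zero in 5/16 = 31% of samples -> excluded; G1 expressed everywhere
        g0 = [0, 0, 0, 0, 0] + [2.0] * 11
        g1 = [3.0] * 16
        out = diff_expression(_matrix([g0, g1], samples), samples[:8], samples[8:])
        assert list(out.index) == ["G1"]

    def test_identical_groups_are_ns_with_unit_fold_change(self):
        samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
        values = [[1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]]
        out = diff_expression(_matrix(values, samples), samples[:4], samples[4:])
        assert out.iloc[0]["fold_change"] == pytest.approx(1.0)
        assert out.iloc[0]["direction"] == "ns"

    def test_direction_invariant_under_global_scaling(self):
        expr, groups = simulate_expression(
            [f"G{i}" for i in range(40)], 15, 15, de_genes=["G0", "G1"],
            effect=3.0, seed=21,
        )
        base = diff_expression(expr, groups["in"], groups["out"])
        scaled = diff_expression(expr * 7.5, groups["in"], groups["out"])
        assert (base["direction"] == scaled["direction"]).all()

    def test_small_group_errors(self):
        samples = ["A0", "B0", "B1"]
        with pytest.raises(ValueError):
            diff_expression(_matrix([[1.0, 2.0, 3.0]], samples), ["A0"], ["B0", "B1"])

    def test_null_calibration_raw_p(self):
        # both groups drawn from the same distribution: raw p < 0.05 for ~5%
        expr, groups = simulate_expression(
            [f"G{i}" for i in range(2000)], 20, 20, effect=1.0, seed=33
        )
        out = diff_expression(expr, groups["in"], groups["out"])
        frac = (out["p_value"] < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert 0.05 - half < frac < 0.05 + half

    def test_two_fold_effect_detected_as_up(self):
        hits = 0
        for rep in range(50):
            expr, groups = simulate_expression(
                [f"G{i}" for i in range(30)], 30, 30, de_genes=["G0"],
                effect=2.0, seed=1000 + rep,
            )
            out = diff_expression(expr, groups["in"], groups["out"])
            hits += out.loc["G0", "direction"] == "up"
        assert hits >= 48


class TestSScore:
    def test_zero_when_group_means_equal(self):
        samples = ["A0", "A1", "B0", "B1"]
        out = s_score(_matrix([[2.0, 4.0, 4.0, 2.0]], samples), samples[:2], samples[2:])
        assert out.loc[0, "S"] == 0.0

    def test_antisymmetric_under_group_swap(self):
        expr, groups = simulate_expression(
            [f"G{i}" for i in range(60)], 12, 12, de_genes=["G3", "G4"],
            effect=2.5, seed=17,
        )
        fwd = s_score(expr, groups["in"], groups["out"]).set_index("gene")["S"]
        rev = s_score(expr, groups["out"], groups["in"]).set_index("gene")["S"]
        assert fwd.sort_index().to_numpy() == pytest.approx(
            -rev.sort_index().to_numpy(), abs=1e-12
        )

    def test_equal_p_opposite_direction_gives_opposite_scores(self):
        samples = ["A0", "A1", "A2", "B0", "B1", "B2"]
        up = [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]
        down = [1.0, 2.0, 3.0, 5.0, 6.0, 7.0]
        out = s_score(_matrix([up, down], samples), samples[:3], samples[3:])
        scores = out.set_index("gene")["S"]
        assert scores["G0"] == pytest.approx(-scores["G1"])
        assert scores["G0"] > 0 > scores["G1"]

    def test_sorted_descending_with_gene_tie_break(self):
        expr, groups = simulate_expression([f"G{i}" for i in range(30)], 10, 10,
                                           effect=1.0, seed=5)
        out = s_score(expr, groups["in"], groups["out"])
        s = out["S"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        ties = out.groupby("S", sort=False)["gene"].apply(list)
        for genes in ties:
            assert genes == sorted(genes)

    def test_natural_log_scale(self):
        # a gene with rank-sum p = 0.05 and higher in-group mean: S = -ln(0.05)
        samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
        row = [4.0, 5.0, 6.0, 1.0, 2.0, 3.0]  # extreme arrangement, exact p = 0.1
        out = s_score(_matrix([row], samples), samples[:3], samples[3:])
        assert out.loc[0, "S"] == pytest.approx(-np.log(0.1), rel=1e-9)


def test_filter_expressed_boundary():
    samples = [f"S{i}" for i in range(10)]
    exactly_30 = [0.0] * 3 + [1.0] * 7
    just_over = [0.0] * 4 + [1.0] * 6
    expr = _matrix([exactly_30, just_over], samples)
    kept = filter_expressed(expr)
    assert list(kept.index) == ["G0"]
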