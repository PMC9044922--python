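import numpy as np
import pandas as pd
import pytest

from gfam.datasets import load_wheat_heat_qpcr
from gfam.qpcr_expression import (
    CONTROL,
    HEAT,
    SUSCEPTIBLE,
    TOLERANT,
    CtTable,
    class_fold_change,
    classify_group,
    classify_trait,
    expression_results,
    relative_expression,
    result_from_log2fc,
    significance,
    summarize_regulation,
)
from gfam.synthetic_data import generate_ct_table


def small_table(gene_heat_dcts, control_dct=3.0, reference="actin"):
    """One-genotype Ct table: heat dCt values planted per replicate."""
    rows = []
    for rep in (1, 2, 3):
        for treatment in (CONTROL, HEAT):
            rows.append(
                dict(genotype="G1", cls=TOLERANT, treatment=treatment,
                     replicate=rep, gene=reference, ct=20.0)
            )
    for rep, heat_dct in enumerate(gene_heat_dcts, start=1):
        rows.append(dict(genotype="G1", cls=TOLERANT, treatment=CONTROL,
                         replicate=rep, gene="g", ct=20.0 + control_dct))
        rows.append(dict(genotype="G1", cls=TOLERANT, treatment=HEAT,
                         replicate=rep, gene="g", ct=20.0 + heat_dct))
    return CtTable(data=pd.DataFrame(rows), reference_gene=reference)


class TestRelativeExpression:
    def test_no_effect_gives_ratio_one(self):
        ratios = relative_expression(small_table([3.0, 3.0, 3.0]))
        assert ratios["ratio"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_one_cycle_drop_doubles_expression(self):
        ratios = relative_expression(small_table([2.0, 2.0, 2.0]))
        assert ratios["ratio"].tolist() == pytest.approx([2.0, 2.0, 2.0])

    def test_planted_effect_reproduced_per_replicate(self):
        table, _ = generate_ct_table({"g": (2.62, -1.20)}, noise_sd=0.0, seed=4)
        ratios = relative_expression(table)
        tol = ratios.loc[ratios["cls"] == TOLERANT, "ratio"]
        assert tol.tolist() == pytest.approx([2 ** 2.62] * len(tol))

    def test_missing_reference_is_an_error(self):
        table = small_table([3.0, 3.0, 3.0])
        broken = table.data[~((table.data["gene"] == "actin") & (table.data["replicate"] == 2))]
        with pytest.raises(ValueError, match="reference"):
            CtTable(data=broken, reference_gene="actin")

    def test_technical_repeats_are_averaged(self):
        table = small_table([2.0, 2.0, 2.0])
        doubled = pd.concat([table.data, table.data], ignore_index=True)
        again = CtTable(data=doubled, reference_gene="actin")
        assert len(again.data) == len(table.data)


class TestClassFoldChange:
    def test_null_table(self):
        ratios = relative_expression(small_table([3.0, 3.0, 3.0]))
        fold = class_fold_change(ratios)
        assert fold.loc[0, "fc"] == pytest.approx(1.0)
        assert fold.loc[0, "log2fc"] == pytest.approx(0.0)

    def test_arithmetic_by_hand_shows_fc_neq_two_to_log2fc(self):
        rows = []
        for genotype, ratio in (("G1", 4.0), ("G2", 8.0)):
            for rep in (1, 2, 3):
                rows.append(dict(gene="g", genotype=genotype, cls=TOLERANT,
                                 replicate=rep, ratio=ratio))
        fold = class_fold_change(pd.DataFrame(rows))
        assert fold.loc[0, "fc"] == pytest.approx(6.0)  # mean of {4, 8}
        assert fold.loc[0, "log2fc"] == pytest.approx(2.5)  # mean of {2,2,2,3,3,3}
        assert fold.loc[0, "log2fc"] < np.log2(fold.loc[0, "fc"])

    def test_log2fc_never_exceeds_log2_of_fc(self, rng):
        # AM >= GM on the ratio scale
        for _ in range(20):
            rows = [
                dict(gene="g", genotype=f"G{k}", cls=TOLERANT, replicate=r,
                     ratio=float(rng.lognormal(0, 1)))
                for k in (1, 2) for r in (1, 2, 3)
            ]
            fold = class_fold_change(pd.DataFrame(rows))
            assert fold.loc[0, "log2fc"] <= np.log2(fold.loc[0, "fc"]) + 1e-12

    def test_nonpositive_ratio_rejected(self):
        frame = pd.DataFrame(
            [dict(gene="g", genotype="G1", cls=TOLERANT, replicate=1, ratio=0.0)]
        )
        with pytest.raises(ValueError):
            class_fold_change(frame)


class TestThresholdRules:
    @pytest.mark.parametrize(
        "log2fc,expected",
        [(2.62, "UP"), (-0.52, "NS"), (1.0, "UP"), (-1.0, "DOWN"), (0.99, "NS"), (-0.99, "NS")],
    )
    def test_significance_boundaries(self, log2fc, expected):
        assert significance(log2fc) == expected

    @pytest.mark.parametrize(
        "tol,sus,group",
        [
            (0.07, -2.42, 1),
            (1.91, 1.20, 2),
            (-1.02, 2.20, 3),
            (-1.15, -1.45, 4),
            (0.0, 0.0, 2),  # zero counts as up
            (0.0, -0.1, 1),
        ],
    )
    def test_group_from_sign_pair(self, tol, sus, group):
        assert classify_group(tol, sus) == group

    @pytest.mark.parametrize(
        "tol,sus,trait",
        [
            (2.62, -1.20, "highly heat-tolerant"),
            (1.84, -0.52, "moderately highly heat-tolerant"),
            (1.86, 0.15, "heat-tolerant"),
            (0.07, -2.42, "heat-tolerant"),
            (-2.08, 1.71, "highly heat-susceptible"),
            (-1.02, 0.94, "moderately highly heat-susceptible"),
            (0.04, 2.74, "heat-susceptible"),
            (1.79, 1.56, "neutral"),
            (-1.15, -1.45, "neutral"),
            (0.5, 0.5, "not-DE"),
        ],
    )
    def test_trait_rule(self, tol, sus, trait):
        assert classify_trait(tol, sus) == trait

    def test_trait_rule_is_total_over_the_plane(self):
        from gfam.qpcr_expression import TRAIT_LABELS

        grid = np.arange(-2.5, 2.6, 0.25)
        for tol in grid:
            for sus in grid:
                assert classify_trait(float(tol), float(sus)) in TRAIT_LABELS


class TestPublishedTableReproduction:
    def test_footer_traits_and_groups(self):
        df = load_wheat_heat_qpcr()
        results = [
            result_from_log2fc(r.gene, r.log2fc_tolerant, r.log2fc_susceptible)
            for r in df.itertuples()
        ]
        summary = summarize_regulation(results)
        assert (summary["up_tolerant"], summary["down_tolerant"]) == (8, 5)
        assert (summary["up_susceptible"], summary["down_susceptible"]) == (7, 4)
        assert summary["total_tolerant"] == 13
        assert summary["total_susceptible"] == 11
        assert summary["deg_union"] == 18
        for result, published in zip(results, df["published_trait"]):
            assert result.trait == published
        for result, published in zip(results, df["published_group"]):
            assert result.group == published


class TestEndToEnd:
    def test_zero_noise_recovery_and_trait(self):
        table, truth = generate_ct_table(
            {"g1": (2.62, -1.20), "g2": (0.0, 0.0)}, noise_sd=0.0, seed=6
        )
        results = {r.gene: r for r in expression_results(table)}
        assert results["g1"].log2fc_tolerant == pytest.approx(2.62)
        assert results["g1"].log2fc_susceptible == pytest.approx(-1.20)
        assert results["g1"].fc_tolerant == pytest.approx(2 ** 2.62)
        assert results["g1"].trait == "highly heat-tolerant"
        assert results["g2"].trait == "not-DE"

    def test_all_ns_summary_is_zero(self):
        table, _ = generate_ct_table({"g": (0.2, -0.3)}, noise_sd=0.0, seed=7)
        summary = summarize_regulation(expression_results(table))
        assert summary["total_tolerant"] == summary["total_susceptible"] == 0
        assert summary["deg_union"] == 0

    def test_table1_footer_from_planted_effects(self):
        df = load_wheat_heat_qpcr()
        effects = {
            r.gene: (r.log2fc_tolerant, r.log2fc_susceptible) for r in df.itertuples()
        }
        table, _ = generate_ct_table(effects, noise_sd=0.0, seed=8)
        summary = summarize_regulation(expression_results(table))
        assert (summary["up_tolerant"], summary["down_tolerant"]) == (8, 5)
        assert (summary["up_susceptible"], summary["down_susceptible"]) == (7, 4)
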