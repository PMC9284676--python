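"""Independent contrasts, correlations, and pairwise genome-size contributions."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from repeatome_kit import (
    SimulationConfig,
    independent_contrasts,
    pairwise_contribution,
    parse_newick,
    pearson_test,
    repeat_gs_correlation,
    simulate_repeatome,
    simulate_tree,
)
from repeatome_kit.signal import phylo_covariance
from repeatome_kit.simulate import simulate_bm_traits


def gls_cross_products(tree, x_map, y_map):
    """Independent GLS oracle: x' P y with P the covariance projector that
    removes the GLS mean (equals the sum of products of contrasts)."""
    labels, v = phylo_covariance(tree)
    vinv = np.linalg.inv(v)
    ones = np.ones(len(labels))
    p = vinv - np.outer(vinv @ ones, ones @ vinv) / (ones @ vinv @ ones)
    x = np.array([x_map[t] for t in labels])
    y = np.array([y_map[t] for t in labels])
    return x @ p @ y


class TestIndependentContrasts:
    def test_two_tip_closed_form(self):
        t = parse_newick("(A:1,B:1);")
        cs = independent_contrasts(t, {"A": 3, "B": 1})
        assert cs.contrasts == pytest.approx([2 / np.sqrt(2)])

    def test_three_tip_hand_pruning(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        cs = independent_contrasts(t, {"A": 2, "B": 0, "C": 1})
        assert sorted(np.round(np.abs(cs.contrasts), 5)) == [0.0, 1.41421]
        assert sorted(cs.variances) == pytest.approx([2.0, 3.5])

    def test_constant_trait_gives_zero_contrasts(self):
        t = simulate_tree(6, seed=1)
        cs = independent_contrasts(t, {lb: 7.0 for lb in "s01 s02 s03 s04 s05 s06".split()})
        assert np.allclose(cs.contrasts, 0.0)

    def test_affine_trait_scales_contrasts(self):
        t = simulate_tree(7, seed=2)
        x = simulate_bm_traits(t, 1.0, 0.0, seed=3)
        c1 = independent_contrasts(t, x).contrasts
        c2 = independent_contrasts(t, {k: 3.0 + 2.0 * v for k, v in x.items()}).contrasts
        assert np.allclose(c2, 2.0 * c1)

    def test_polytomy_rejected_with_instruction(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        with pytest.raises(ValueError, match="bifurcating"):
            independent_contrasts(t, dict.fromkeys("ABCD", 1.0))

    @pytest.mark.parametrize("n_tips", [4, 6, 8])
    def test_contrast_products_match_gls_oracle(self, n_tips):
        tree = simulate_tree(n_tips, seed=n_tips)
        x = simulate_bm_traits(tree, 1.0, 0.0, seed=10 + n_tips)
        y = simulate_bm_traits(tree, 2.0, 1.0, seed=20 + n_tips)
        cx = independent_contrasts(tree, x).contrasts
        cy = independent_contrasts(tree, y).contrasts
        assert float(cx @ cy) == pytest.approx(
            gls_cross_products(tree, x, y), abs=1e-10
        )
        r_pic = float(cx @ cy) / np.sqrt(float(cx @ cx) * float(cy @ cy))
        r_gls = gls_cross_products(tree, x, y) / np.sqrt(
            gls_cross_products(tree, x, x) * gls_cross_products(tree, y, y)
        )
        assert r_pic == pytest.approx(r_gls, abs=1e-8)

    def test_matches_ape_pic_reference(self, tmp_path):
        """Cross-check against the R ape implementation on a fixed tree."""
        newick = "((s01:0.3,s02:0.3):0.7,(s03:0.5,s04:0.5):0.5);"
        script = textwrap.dedent(
            """
            suppressMessages(library(ape))
            tr <- read.tree(text="%s")
            x <- c(s01=1.2, s02=0.7, s03=-0.3, s04=0.1)
            cat(sort(pic(x, tr)), sep="\\n")
            """
            % newick
        )
        path = tmp_path / "pic.R"
        path.write_text(script)
        out = subprocess.run(
            ["Rscript", str(path)], capture_output=True, text=True, check=True
        )
        expected = sorted(float(v) for v in out.stdout.split())
        cs = independent_contrasts(
            parse_newick(newick), {"s01": 1.2, "s02": 0.7, "s03": -0.3, "s04": 0.1}
        )
        assert sorted(cs.contrasts) == pytest.approx(expected, abs=1e-6)


class TestPearson:
    def test_perfect_correlation(self):
        res = pearson_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert (res.r, res.r2, res.p_value) == (1.0, 1.0, 0.0)

    def test_hand_computed_value(self):
        res = pearson_test([1, 2, 3], [1, 2, 4])
        assert res.r == pytest.approx(0.9820, abs=5e-5)
        assert res.r2 == pytest.approx(0.9643, abs=5e-5)

    def test_anticorrelation(self):
        res = pearson_test([1, 2, 3], [3, 2, 1])
        assert res.r == pytest.approx(-1.0, abs=1e-12)
        assert res.p_value < 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_test([1, 1, 1], [1, 2, 3])


class TestRepeatGsCorrelation:
    def test_dominant_family_recovered(self):
        # one family tracks genome size; it should dominate the correlation
        rng = np.random.default_rng(0)
        tree = simulate_tree(10, seed=5)
        tips = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        gs = pd.Series(
            {t: v for t, v in zip(tips, 2000 + 1500 * rng.random(10))}
        )
        amounts = pd.DataFrame(
            {
                "tracking": 0.9 * gs + rng.normal(0, 20, 10),
                "random": rng.uniform(50, 250, 10),
            },
            index=tips,
        )
        res = repeat_gs_correlation(amounts, gs, tree)
        assert res["tracking"].r2 > 0.9
        assert res["tracking"].r2 > res["random"].r2

    def test_constant_family_not_testable(self):
        tree = simulate_tree(5, seed=1)
        tips = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        gs = pd.Series(dict(zip(tips, [1000.0, 1200, 1400, 1600, 1800])))
        amounts = pd.DataFrame({"flat": [100.0] * 5}, index=tips)
        assert repeat_gs_correlation(amounts, gs, tree)["flat"] is None

    def test_exact_composition_gives_r2_one(self):
        cfg = SimulationConfig(tree_seed=6, data_seed=7, unclassified_fraction=0.0)
        ds = simulate_repeatome(cfg)
        summed = ds.amounts_mbp.sum(axis=1).to_frame("all_repeats")
        res = repeat_gs_correlation(summed, ds.genome_size_mbp, ds.tree)
        assert res["all_repeats"].r2 == pytest.approx(1.0, abs=1e-9)

    def test_too_few_tips_rejected(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gs = pd.Series({"A": 1.0, "B": 2.0})
        amounts = pd.DataFrame({"f": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="4 tips"):
            repeat_gs_correlation(amounts, gs, tree)


class TestPairwiseContribution:
    def test_single_family_explains_whole_difference(self):
        amounts = pd.DataFrame({"f": [200.0, 100.0]}, index=["a", "b"])
        gs = pd.Series({"a": 1100.0, "b": 1000.0})
        res = pairwise_contribution(amounts, gs)
        assert res.contribution_pct["f"] == pytest.approx(100.0)

    def test_constant_family_contributes_nothing(self):
        amounts = pd.DataFrame({"f": [150.0, 150.0]}, index=["a", "b"])
        gs = pd.Series({"a": 1100.0, "b": 1000.0})
        assert pairwise_contribution(amounts, gs).contribution_pct["f"] == 0.0

    def test_three_species_hand_mean(self):
        amounts = pd.DataFrame({"f": [10.0, 20.0, 40.0]}, index=list("abc"))
        gs = pd.Series({"a": 100.0, "b": 140.0, "c": 200.0})
        res = pairwise_contribution(amounts, gs)
        assert res.contribution_pct["f"] == pytest.approx(29.44, abs=5e-3)

    def test_summed_contribution_complements_unclassified_share(self):
        ds = simulate_repeatome(
            SimulationConfig(tree_seed=8, data_seed=9, unclassified_fraction=0.2)
        )
        res = pairwise_contribution(ds.amounts_mbp, ds.genome_size_mbp)
        assert float(res.contribution_pct.sum()) == pytest.approx(80.0, abs=1e-9)

    def test_near_equal_sizes_excluded(self):
        amounts = pd.DataFrame({"f": [10.0, 10.5, 40.0]}, index=list("abc"))
        gs = pd.Series({"a": 1000.0, "b": 1000.5, "c": 2000.0})
        res = pairwise_contribution(amounts, gs)
        assert res.n_pairs_excluded == 1
        with pytest.raises(ValueError, match="excluded"):
            pairwise_contribution(
                amounts.loc[["a", "b"]], gs[["a", "b"]]
            )
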