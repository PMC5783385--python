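"""Nee branch lengths, independent contrasts, regression and prediction."""

import math

import numpy as np
import pytest

from pacavoc import phylo, synth
from conftest import gls_contrast_oracle, random_binary_tree


class TestNeeBranchLengths:
    def test_cherry_and_root_depths(self, seven_species_tree):
        tree = seven_species_tree
        depths = {
            frozenset(n.tip_labels()): n.depth for n in tree.root.postorder()
        }
        assert tree.root.depth == pytest.approx(math.log10(7))
        cherry = depths[frozenset({"Ctenomys_talarum", "Spalacopus_cyanus"})]
        assert cherry == pytest.approx(0.30103, abs=1e-5)
        for node in tree.root.postorder():
            if node.is_tip:
                assert node.depth == 0.0

    def test_idempotent_and_edges_are_depth_differences(self, seven_species_tree):
        again = phylo.nee_branch_lengths(seven_species_tree)
        for a, b in zip(seven_species_tree.root.postorder(), again.root.postorder()):
            assert a.depth == pytest.approx(b.depth)
            if a.length is not None:
                assert a.length == pytest.approx(b.length)
                assert a.length > 0

    def test_rejects_polytomy(self):
        root = phylo.Node(children=[phylo.Node("a"), phylo.Node("b"), phylo.Node("c")])
        with pytest.raises(phylo.PhylogenyError, match="binary"):
            phylo.Phylogeny(root)


class TestPic:
    def test_cherry_hand_value(self):
        """(0.9031 - 0.3010) / sqrt(2 * log10 2) = 0.7760."""
        tree = phylo.nee_branch_lengths(
            phylo.Phylogeny.from_newick("(A,B);")
        )
        cs = phylo.pic(tree, {"A": 0.9031, "B": 0.3010})
        assert cs.contrasts[0].standardized == pytest.approx(0.7760, abs=5e-4)

    def test_equal_tip_values_give_zero_contrasts(self, seven_species_tree):
        traits = {l: 2.5 for l in seven_species_tree.tip_labels}
        cs = phylo.pic(seven_species_tree, traits)
        assert np.allclose(cs.standardized, 0.0)
        assert len(cs) == 6

    def test_matches_gls_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            tree = random_binary_tree(rng, n)
            traits = {l: float(rng.normal()) for l in tree.tip_labels}
            cs = phylo.pic(tree, traits)
            oracle = gls_contrast_oracle(tree, traits)
            assert len(cs) == n - 1
            for c in cs:
                assert c.standardized == pytest.approx(oracle[c.clade], rel=1e-9), (
                    "pruning recursion disagrees with Brownian-GLS algebra"
                )

    def test_missing_trait_and_missing_lengths_raise(self, seven_species_tree):
        with pytest.raises(phylo.PhylogenyError, match="no trait value"):
            phylo.pic(seven_species_tree, {"Octodon_degus": 1.0})
        bare = phylo.load_caviomorph_tree(include_focal=False)
        with pytest.raises(phylo.PhylogenyError, match="branch lengths"):
            phylo.pic(bare, {l: 1.0 for l in bare.tip_labels})

    def test_standardized_contrasts_are_iid_standard_normal(self):
        """Under unit-rate Brownian motion, standardized contrasts are ~N(0,1)."""
        import scipy.stats

        rng = np.random.default_rng(7)
        vals = []
        tree = phylo.nee_branch_lengths(phylo.load_caviomorph_tree(include_focal=False))
        for r in range(400):
            tr = synth.simulate_brownian_traits(
                tree, synth.BrownianSpec(sigma2=1.0), seed=int(rng.integers(2**31))
            )
            vals.extend(phylo.pic(tree, tr["trait_x"].to_dict()).standardized)
        ks = scipy.stats.kstest(vals, "norm")
        assert ks.pvalue > 0.01


class TestContrastRegression:
    def test_collinear_contrasts_give_r2_one(self, seven_species_tree):
        rng = np.random.default_rng(1)
        traits = {l: float(rng.normal()) for l in seven_species_tree.tip_labels}
        cx = phylo.pic(seven_species_tree, traits)
        doubled = {l: 2.0 * v + 1.0 for l, v in traits.items()}
        cy = phylo.pic(seven_species_tree, doubled)
        reg = phylo.fit_contrast_regression(cx, cy)
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.slope == pytest.approx(2.0)

    def test_slope_invariant_to_tree_depth_scale(self, seven_species_tree):
        rng = np.random.default_rng(2)
        tr = synth.simulate_brownian_traits(
            seven_species_tree, synth.BrownianSpec(slope=1.2, noise_sd=0.1), seed=5
        )
        scaled = seven_species_tree.copy()
        for node in scaled.root.postorder():
            if node.length is not None:
                node.length *= 3.7
        args = (tr["trait_x"].to_dict(), tr["trait_y"].to_dict())
        reg1 = phylo.fit_contrast_regression(
            phylo.pic(seven_species_tree, args[0]), phylo.pic(seven_species_tree, args[1])
        )
        reg2 = phylo.fit_contrast_regression(
            phylo.pic(scaled, args[0]), phylo.pic(scaled, args[1])
        )
        assert reg1.slope == pytest.approx(reg2.slope)
        assert reg1.r_squared == pytest.approx(reg2.r_squared)

    def test_slope_recovery_from_brownian_coupling(self, seven_species_tree):
        """Traits coupled with slope 1.59 recover that slope in the mean."""
        slopes = []
        for r in range(100):
            tr = synth.simulate_brownian_traits(
                seven_species_tree,
                synth.BrownianSpec(sigma2=1.0, slope=1.59, noise_sd=0.05),
                seed=1000 + r,
            )
            reg = phylo.fit_contrast_regression(
                phylo.pic(seven_species_tree, tr["trait_x"].to_dict()),
                phylo.pic(seven_species_tree, tr["trait_y"].to_dict()),
            )
            slopes.append(reg.slope)
        assert abs(np.mean(slopes) - 1.59) / 1.59 < 0.05

    def test_degenerate_predictor_raises(self, seven_species_tree):
        traits = {l: 1.0 for l in seven_species_tree.tip_labels}
        cx = phylo.pic(seven_species_tree, traits)
        with pytest.raises(phylo.PhylogenyError, match="degenerate"):
            phylo.fit_contrast_regression(cx, cx)


class TestPrediction:
    def test_zero_contrast_predicts_intercept(self, seven_species_tree):
        rng = np.random.default_rng(3)
        rep = {l: float(rng.normal()) for l in seven_species_tree.tip_labels}
        gs = {l: float(rng.normal()) for l in seven_species_tree.tip_labels}
        reg = phylo.fit_contrast_regression(
            phylo.pic(seven_species_tree, rep), phylo.pic(seven_species_tree, gs)
        )
        assert reg.predict(0.0) == pytest.approx(reg.intercept)

    def test_focal_errors(self, seven_species_tree):
        reg_traits = {l: float(i) for i, l in enumerate(seven_species_tree.tip_labels)}
        reg = phylo.fit_contrast_regression(
            phylo.pic(seven_species_tree, reg_traits),
            phylo.pic(seven_species_tree, {k: v + 1 for k, v in reg_traits.items()}),
        )
        full = phylo.nee_branch_lengths(phylo.load_caviomorph_tree())
        rep = {l: 1.0 for l in full.tip_labels}
        gs = {l: 1.0 for l in full.tip_labels}
        with pytest.raises(phylo.PhylogenyError, match="must not have"):
            phylo.predict_group_size(reg, full, rep, gs)
        gs.pop(phylo.FOCAL_SPECIES)
        with pytest.raises(phylo.PhylogenyError, match="not in tree"):
            phylo.predict_group_size(reg, full, rep, gs, focal="Mus_musculus")

    def test_prediction_error_shrinks_with_noise(self, seven_species_tree):
        """Hide one tip's response, predict it, compare: error shrinks as the
        trait coupling tightens."""
        errors = {}
        for noise in (0.5, 0.01):
            errs = []
            for r in range(40):
                tr = synth.simulate_brownian_traits(
                    seven_species_tree,
                    synth.BrownianSpec(sigma2=1.0, slope=1.59, noise_sd=noise),
                    seed=200 + r,
                )
                x = tr["trait_x"].to_dict()
                y = tr["trait_y"].to_dict()
                focal = "Dasyprocta_leporina"
                truth = 10 ** y[focal]
                yk = {k: v for k, v in y.items() if k != focal}
                # regression on the remaining six species' contrasts
                pruned = phylo.nee_branch_lengths(
                    _prune(phylo.load_caviomorph_tree(include_focal=False), focal)
                )
                reg = phylo.fit_contrast_regression(
                    phylo.pic(pruned, x), phylo.pic(pruned, yk)
                )
                pred = phylo.predict_group_size(
                    reg, seven_species_tree, x, yk, focal=focal
                )
                errs.append(abs(pred.group_size - truth))
            errors[noise] = np.median(errs)
        assert errors[0.01] < errors[0.5]


def _prune(tree, label):
    out = tree.copy()
    tip = out.find_tip(label)
    parent = out.parent_of(tip)
    grand = out.parent_of(parent)
    sister = parent.children[0] if parent.children[1] is tip else parent.children[1]
    if grand is None:
        sister.length = None
        return phylo.Phylogeny(sister)
    grand.children[grand.children.index(parent)] = sister
    return phylo.Phylogeny(out.root)


class TestConfigurationScan:
    def test_scan_covers_documented_space(self):
        df = phylo.scan_configurations()
        assert len(df) == 2 * len(phylo.ATTACHMENTS)
        assert set(df["sign_convention"]) == {"positivized", "raw"}
        # regression statistics depend only on the sign convention
        assert df.groupby("sign_convention")["slope"].nunique().max() == 1

    def test_reference_ranking_orders_by_distance(self):
        df = phylo.scan_configurations(reference={"x_contrast": 0.17})
        assert df["reference_distance"].is_monotonic_increasing
        top = df.iloc[0]
        assert top["sign_convention"] == "positivized"
        assert top["attachment"] == "dasyprocta_cherry"
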