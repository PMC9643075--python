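"""Generator correctness: trees, trait models, ordinal draws, rendering."""

import numpy as np
import pytest
from scipy.special import expit

import phylorisk as pr
from phylorisk.synthetic import default_wings, shoelace_area


class TestSimulateTree:
    def test_three_tips_shape_and_ultrametric(self):
        tree = pr.simulate_tree(3, seed=0)
        internal = [n for n in tree if not n.is_leaf()]
        assert len(internal) == 2
        depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
        assert np.allclose(depths, 1.0)

    def test_fixed_seed_gives_identical_newick(self):
        nw = [pr.simulate_tree(100, seed=1).as_string(schema="newick")
              for _ in range(2)]
        assert nw[0] == nw[1]

    def test_covariance_is_symmetric_positive_definite(self):
        cov = pr.phylo_covariance(pr.simulate_tree(200, seed=11))
        assert np.allclose(cov.matrix, cov.matrix.T)
        assert np.linalg.eigvalsh(cov.matrix).min() > 0

    def test_rejects_fewer_than_three_tips(self):
        with pytest.raises(ValueError):
            pr.simulate_tree(2, seed=0)


class TestLambdaTrait:
    def test_lambda_zero_gives_uncorrelated_tips(self, rng):
        tree = pr.simulate_tree(10, seed=3)
        cov = pr.phylo_covariance(tree)
        draws = np.array([
            pr.simulate_lambda_trait(cov, 0.0, seed=r).to_numpy()
            for r in pr.spawn_rngs(99, 2000)])
        corr = np.corrcoef(draws, rowvar=False)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_zero_rate_gives_constant_mu(self):
        tree = pr.simulate_tree(8, seed=4)
        y = pr.simulate_lambda_trait(tree, 0.5, sigma2=0.0, mu=3.25, seed=0)
        assert (y == 3.25).all()

    def test_lambda_one_matches_pure_brownian_covariance(self, tree20):
        # λ = 1 and the mixed model with σ²ₑ = 0 share the same law:
        # both covariances equal σ²·C on a depth-1 tree
        cov = pr.phylo_covariance(tree20)
        Cl = pr.lambda_transform(cov.matrix, 1.0)
        assert np.allclose(Cl, cov.correlation() * cov.depth)

    def test_determinism(self, tree20):
        a = pr.simulate_lambda_trait(tree20, 0.7, seed=5)
        b = pr.simulate_lambda_trait(tree20, 0.7, seed=5)
        assert (a == b).all()


class TestLynchTrait:
    def test_zero_residual_variance_returns_additive_exactly(self, tree20):
        y, a = pr.simulate_lynch_trait(tree20, 1.0, 0.0, mu=2.0, seed=6)
        assert np.allclose(y - 2.0, a)

    def test_zero_phylo_variance_uncorrelated_with_distance(self, tree50,
                                                            cov50):
        draws = np.array([
            pr.simulate_lynch_trait(cov50, 0.0, 1.0, seed=r)[0].to_numpy()
            for r in pr.spawn_rngs(123, 400)])
        # trait-distance vs phylogenetic-distance correlation ≈ 0
        iu = np.triu_indices(50, 1)
        pd_ = (np.diag(cov50.matrix)[:, None] + np.diag(cov50.matrix)[None]
               - 2 * cov50.matrix)[iu]
        td = np.mean((draws[:, iu[0]] - draws[:, iu[1]]) ** 2, axis=0)
        r = np.corrcoef(pd_, td)[0, 1]
        assert abs(r) < 0.1

    def test_both_variances_zero_warns_constant(self, tree20):
        with pytest.warns(UserWarning):
            y, _ = pr.simulate_lynch_trait(tree20, 0.0, 0.0, mu=1.0, seed=0)
        assert (y == 1.0).all()


class TestOrdinalResponse:
    def test_beta_zero_frequencies_match_threshold_probabilities(self):
        zeta = np.array([0.4, 1.1, 2.0])
        X = np.zeros((100_000, 1))
        y = pr.simulate_ordinal_response(X, [0.0], zeta, seed=8)
        cum = expit(zeta)
        expected = np.diff(np.concatenate(([0.0], cum, [1.0])))
        freq = np.bincount(y, minlength=4) / len(y)
        assert np.max(np.abs(freq - expected)) < 0.01

    def test_two_categories_equal_bernoulli_under_shared_seed(self, rng):
        X = rng.standard_normal((500, 1))
        zeta = [0.3]
        y = pr.simulate_ordinal_response(X, [0.8], zeta, seed=17)
        u = np.random.default_rng(17).uniform(size=500)
        bern = (u > expit(zeta[0] - X[:, 0] * 0.8)).astype(int)
        assert (y == bern).all()

    def test_non_monotone_zeta_rejected(self):
        with pytest.raises(ValueError):
            pr.simulate_ordinal_response(np.zeros((5, 1)), [1.0],
                                         [1.0, 0.5], seed=0)


class TestRendering:
    def test_body_mask_is_exact_rectangle(self):
        spec = pr.SpecimenSpec(body_length_cm=1.2, body_width_cm=0.12,
                               dpi=1200)
        img, _ = pr.render_specimen_image(spec)
        rows = img.body_mask.any(axis=1).sum()
        cols = img.body_mask.any(axis=0).sum()
        assert cols == round(0.12 * 1200 / 2.54)
        assert rows == round(1.2 * 1200 / 2.54)

    def test_all_white_specimen_has_lightness_255(self):
        spec = pr.SpecimenSpec(body_gray=255,
                               wing_polygons=default_wings(0.12),
                               wing_gray_profile=[255] * 4)
        img, _ = pr.render_specimen_image(spec)
        assert pr.color_lightness(img.pixels, img.body_mask,
                                  img.wing_mask) == 255.0

    def test_rendered_volume_within_two_percent_of_cylinder(self):
        spec = pr.SpecimenSpec(body_length_cm=1.2, body_width_cm=0.12,
                               dpi=1200)
        img, truth = pr.render_specimen_image(spec)
        vol = pr.body_volume(img.body_mask, img.dpi)
        assert abs(vol - truth["body_volume_cm3"]) \
            < 0.02 * truth["body_volume_cm3"]

    def test_subpixel_body_rejected(self):
        with pytest.raises(ValueError):
            pr.render_specimen_image(
                pr.SpecimenSpec(body_width_cm=0.001, dpi=300))

    def test_ground_truth_area_equals_shoelace(self):
        poly = [(0.0, 0.0), (1.0, 0.0), (1.0, 2.0), (0.0, 1.5)]
        spec = pr.SpecimenSpec(wing_polygons=[poly], dpi=300)
        _, truth = pr.render_specimen_image(spec)
        # shoelace by hand: trapezoid area 1.75
        assert abs(truth["wing_areas_cm2"][0] - 1.75) < 1e-12
        assert abs(shoelace_area(poly) - 1.75) < 1e-12

    def test_self_intersecting_polygon_rejected(self):
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(ValueError):
            pr.SpecimenSpec(wing_polygons=[bowtie])

    def test_specimen_roundtrip_and_determinism(self, tmp_path):
        imgs, truth = pr.simulate_specimens(["s1", "s2"], seed=3, dpi=300)
        imgs2, _ = pr.simulate_specimens(["s1", "s2"], seed=3, dpi=300)
        assert (imgs["s1"].pixels == imgs2["s1"].pixels).all()
        from phylorisk.synthetic import read_specimen, write_specimen
        write_specimen(tmp_path, "s1", imgs["s1"], {"dpi": 300})
        back, meta = read_specimen(tmp_path, "s1")
        assert (back.pixels == imgs["s1"].pixels).all()
        assert (back.body_mask == imgs["s1"].body_mask).all()
        assert meta["dpi"] == 300


def test_simulation_config_validation():
    with pytest.raises(ValueError):
        pr.SimulationConfig(n_tips=2)
    with pytest.raises(ValueError):
        pr.SimulationConfig(sigma2_a=-1.0)
    with pytest.raises(ValueError):
        pr.SimulationConfig(zeta=(1.0, 0.5))


def test_study_is_deterministic_given_seed():
    a = pr.simulate_study(pr.SimulationConfig(n_tips=20, seed=5))
    b = pr.simulate_study(pr.SimulationConfig(n_tips=20, seed=5))
    assert a["traits"].equals(b["traits"])
    assert (a["status"] == b["status"]).all()
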