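"""The sum-of-trees sampler: conjugacy oracles, MH kernel, fitting, prediction."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from srscape.bart import (
    BartConfig,
    BartPosterior,
    GrowMove,
    PruneMove,
    ChangeMove,
    Tree,
    _Cutpoints,
    _apply,
    calibrate_lambda,
    draw_sigma,
    fit_bart,
    leaf_log_marginal,
    leaf_posterior,
    mh_log_ratio,
    predict_draws,
    variable_importance,
)
from srscape.samples import BoundedLogitTransform


# ---------------------------------------------------------------------------
# conjugacy oracles

class TestLeafMarginal:
    def test_single_zero_residual_unit_variances(self):
        # closed form: N(0 | 0, sigma^2 + sigma_mu^2) = N(0 | 0, 2)
        expected = stats.norm.logpdf(0.0, scale=math.sqrt(2.0))
        assert leaf_log_marginal(1, 0.0, 0.0, 1.0, 1.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.26551, abs=1e-5)

    def test_empty_leaf_is_log_one(self):
        assert leaf_log_marginal(0, 0.0, 0.0, 1.0, 1.0) == 0.0

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_adaptive_quadrature(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(1, 6))
        r = rng.normal(0, 1.0, n)
        sigma = float(rng.uniform(0.3, 2.0))
        sigma_mu = float(rng.uniform(0.3, 2.0))

        def integrand(mu):
            return np.exp(stats.norm.logpdf(r, mu, sigma).sum()) * stats.norm.pdf(
                mu, 0.0, sigma_mu)

        val, _ = integrate.quad(integrand, -12 * sigma_mu, 12 * sigma_mu,
                                epsabs=1e-14, epsrel=1e-12)
        closed = leaf_log_marginal(n, float(r.sum()), float(r @ r), sigma, sigma_mu)
        assert closed == pytest.approx(math.log(val), rel=1e-8)

    def test_non_finite_sums_rejected(self):
        with pytest.raises(ValueError):
            leaf_log_marginal(2, float("nan"), 1.0, 1.0, 1.0)


class TestLeafFullConditional:
    @pytest.mark.parametrize("trial", range(5))
    def test_moments_match_quadrature(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(1, 6))
        r = rng.normal(0.5, 1.0, n)
        sigma, sigma_mu = float(rng.uniform(0.4, 1.5)), float(rng.uniform(0.4, 1.5))

        def unnorm(mu):
            return np.exp(stats.norm.logpdf(r, mu, sigma).sum()) * stats.norm.pdf(
                mu, 0.0, sigma_mu)

        lim = 12.0
        z0, _ = integrate.quad(unnorm, -lim, lim, epsabs=1e-14, epsrel=1e-12)
        z1, _ = integrate.quad(lambda m: m * unnorm(m), -lim, lim,
                               epsabs=1e-14, epsrel=1e-12)
        z2, _ = integrate.quad(lambda m: m * m * unnorm(m), -lim, lim,
                               epsabs=1e-14, epsrel=1e-12)
        mean_q, var_q = z1 / z0, z2 / z0 - (z1 / z0) ** 2
        mean_c, sd_c = leaf_posterior(n, float(r.sum()), sigma, sigma_mu)
        assert mean_c == pytest.approx(mean_q, rel=1e-8)
        assert sd_c**2 == pytest.approx(var_q, rel=1e-8)


class TestSigmaDraw:
    def test_prior_moments_on_empty_residuals(self):
        # n = 0: sigma^2 ~ nu*lam / chi2_nu with mean nu*lam/(nu-2)
        nu, lam = 6.0, 0.7
        rng = np.random.default_rng(0)
        draws = np.array([draw_sigma(np.empty(0), nu, lam, rng) ** 2
                          for _ in range(100_000)])
        assert draws.mean() == pytest.approx(nu * lam / (nu - 2.0), rel=0.02)

    def test_posterior_concentrates_with_zero_residuals(self):
        rng = np.random.default_rng(1)
        draws = [draw_sigma(np.zeros(5000), 3.0, 0.1, rng) for _ in range(200)]
        assert max(draws) < 0.02

    def test_seed_reproducibility(self):
        r = np.random.default_rng(2).normal(size=50)
        a = draw_sigma(r, 3.0, 0.5, np.random.default_rng(7))
        b = draw_sigma(r, 3.0, 0.5, np.random.default_rng(7))
        assert a == b

    def test_lambda_calibration_quantile(self):
        # prior P(sigma^2 <= sigma_hat^2) should equal q
        nu, q, sigma_hat = 3.0, 0.90, 0.8
        lam = calibrate_lambda(sigma_hat, nu, q)
        # scaled inverse-chi-square CDF via the chi-square tail
        p = stats.chi2.sf(nu * lam / sigma_hat**2, nu)
        assert p == pytest.approx(q, abs=1e-12)


# ---------------------------------------------------------------------------
# MH kernel

def _stump_setup(n=6, p=2, seed=0, n_cutpoints=5):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, p))
    r = rng.normal(0, 1, n)
    cuts = _Cutpoints(X, n_cutpoints)
    cfg = BartConfig(m=1, n_burn=1, n_draw=1)
    return X, r, cuts, cfg


def _tree_log_prior(tree, X, cuts, cfg):
    """Independent whole-tree prior: depth terms x uniform rule terms."""
    total = 0.0
    stack = [tree.root]
    while stack:
        node = stack.pop()
        d = node.depth
        p_split = cfg.alpha * (1.0 + d) ** (-cfg.beta)
        if node.is_leaf:
            total += math.log(1.0 - p_split)
        else:
            idx = tree.subtree_idx(node)
            adm_vars = cuts.admissible_vars(X, idx)
            n_cuts = cuts.admissible(X, idx, node.var).size
            total += (math.log(p_split) - math.log(len(adm_vars))
                      - math.log(n_cuts))
            stack.append(node.left)
            stack.append(node.right)
    return total


def _tree_log_marginal_oracle(tree, r, sigma, sigma_mu):
    """Independent marginal likelihood: per-leaf multivariate normal."""
    total = 0.0
    for leaf in tree.leaves():
        k = leaf.idx.size
        if k == 0:
            continue
        cov = sigma**2 * np.eye(k) + sigma_mu**2 * np.ones((k, k))
        total += stats.multivariate_normal.logpdf(r[leaf.idx], mean=np.zeros(k),
                                                  cov=cov)
    return total


class TestMhEnumerationOracle:
    """Acceptance ratios vs exhaustive enumeration on a 6-point fixture."""

    def test_all_grows_from_stump(self):
        X, r, cuts, cfg = _stump_setup()
        sigma, sigma_mu = 0.8, 0.5
        p_grow, p_prune = cfg.move_probs[0], cfg.move_probs[1]
        tree = Tree(6)
        log_post_stump = (_tree_log_prior(tree, X, cuts, cfg)
                          + _tree_log_marginal_oracle(tree, r, sigma, sigma_mu))
        adm_root = cuts.admissible_vars(X, tree.root.idx)
        for var in adm_root:
            for cut in cuts.admissible(X, tree.root.idx, var):
                move = GrowMove(tree.root, var, float(cut))
                lr = mh_log_ratio(tree, move, X, r, sigma, sigma_mu, cfg, cuts)
                grown = Tree(6)
                _apply(grown, GrowMove(grown.root, var, float(cut)), X)
                log_post_grown = (_tree_log_prior(grown, X, cuts, cfg)
                                  + _tree_log_marginal_oracle(grown, r, sigma, sigma_mu))
                # forward: grow is the only leaf; reverse: prune the only prunable
                log_fwd = (math.log(p_grow) - math.log(1)
                           - math.log(len(adm_root))
                           - math.log(cuts.admissible(X, tree.root.idx, var).size))
                log_rev = math.log(p_prune) - math.log(1)
                expected = (log_post_grown - log_post_stump) + (log_rev - log_fwd)
                assert lr == pytest.approx(expected, abs=1e-10)

    def test_second_level_grow_against_oracle(self):
        X, r, cuts, cfg = _stump_setup(seed=3)
        sigma, sigma_mu = 0.8, 0.5
        p_grow, p_prune = cfg.move_probs[0], cfg.move_probs[1]
        tree = Tree(6)
        var0 = cuts.admissible_vars(X, tree.root.idx)[0]
        cut0 = float(np.median(cuts.admissible(X, tree.root.idx, var0)))
        _apply(tree, GrowMove(tree.root, var0, cut0), X)
        log_post_t1 = (_tree_log_prior(tree, X, cuts, cfg)
                       + _tree_log_marginal_oracle(tree, r, sigma, sigma_mu))
        for leaf in list(tree.leaves()):
            for var in cuts.admissible_vars(X, leaf.idx):
                for cut in cuts.admissible(X, leaf.idx, var):
                    move = GrowMove(leaf, var, float(cut))
                    lr = mh_log_ratio(tree, move, X, r, sigma, sigma_mu, cfg, cuts)
                    n_leaves = len(tree.leaves())
                    n_adm_vars = len(cuts.admissible_vars(X, leaf.idx))
                    n_adm_cuts = cuts.admissible(X, leaf.idx, var).size
                    _apply(tree, move, X)
                    log_post_t2 = (_tree_log_prior(tree, X, cuts, cfg)
                                   + _tree_log_marginal_oracle(tree, r, sigma, sigma_mu))
                    n_prunable = len(tree.prunable())
                    log_fwd = (math.log(p_grow) - math.log(n_leaves)
                               - math.log(n_adm_vars) - math.log(n_adm_cuts))
                    log_rev = math.log(p_prune) - math.log(n_prunable)
                    expected = (log_post_t2 - log_post_t1) + (log_rev - log_fwd)
                    assert lr == pytest.approx(expected, abs=1e-10)
                    _apply(tree, PruneMove(leaf), X)  # revert


class TestDetailedBalance:
    def test_grow_prune_reversibility_over_seeded_trace(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, (50, 3))
        r = rng.normal(0, 1, 50)
        cuts = _Cutpoints(X, 20)
        cfg = BartConfig(m=1, n_burn=1, n_draw=1)
        sigma, sigma_mu = 0.9, 0.4
        tree = Tree(50)
        checked = 0
        while checked < 1000:
            growable = [lf for lf in tree.leaves()
                        if cuts.admissible_vars(X, lf.idx)]
            if not growable:
                # tree saturated: prune somewhere and continue the trace
                cand = tree.prunable()
                _apply(tree, PruneMove(cand[rng.integers(len(cand))]), X)
                continue
            leaf = growable[rng.integers(len(growable))]
            adm_vars = cuts.admissible_vars(X, leaf.idx)
            var = adm_vars[rng.integers(len(adm_vars))]
            adm = cuts.admissible(X, leaf.idx, var)
            cut = float(adm[rng.integers(adm.size)])
            lr_grow = mh_log_ratio(tree, GrowMove(leaf, var, cut), X, r,
                                   sigma, sigma_mu, cfg, cuts)
            _apply(tree, GrowMove(leaf, var, cut), X)
            lr_prune = mh_log_ratio(tree, PruneMove(leaf), X, r,
                                    sigma, sigma_mu, cfg, cuts)
            assert abs(lr_grow + lr_prune) < 1e-10
            checked += 1
            if rng.uniform() < 0.6:          # revert often enough to vary shapes
                _apply(tree, PruneMove(leaf), X)
        assert checked == 1000

    def test_change_to_identical_rule_is_neutral(self):
        X, r, cuts, cfg = _stump_setup(n=20, seed=5, n_cutpoints=10)
        tree = Tree(20)
        var = cuts.admissible_vars(X, tree.root.idx)[0]
        cut = float(cuts.admissible(X, tree.root.idx, var)[0])
        _apply(tree, GrowMove(tree.root, var, cut), X)
        lr = mh_log_ratio(tree, ChangeMove(tree.root, var, cut), X, r,
                          0.8, 0.5, cfg, cuts)
        assert lr == pytest.approx(0.0, abs=1e-12)

    def test_inadmissible_moves_error(self):
        X, r, cuts, cfg = _stump_setup()
        tree = Tree(6)
        with pytest.raises(ValueError):
            mh_log_ratio(tree, PruneMove(tree.root), X, r, 1.0, 1.0, cfg, cuts)


# ---------------------------------------------------------------------------
# fitting

class TestFit:
    def test_constant_response_is_reproduced(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (40, 3))
        z = np.full(40, -2.5)
        post = fit_bart(X, z, BartConfig(m=10, n_burn=50, n_draw=50, seed=1))
        preds = predict_draws(post, X)
        np.testing.assert_allclose(preds, -2.5, atol=1e-6)

    def test_step_function_recovery(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, (500, 5))
        z = (X[:, 0] > 0).astype(float) + rng.normal(0, 0.1, 500)
        post = fit_bart(X, z, BartConfig(m=50, n_burn=300, n_draw=300, seed=2))
        Xt = rng.uniform(-1, 1, (300, 5))
        truth = (Xt[:, 0] > 0).astype(float)
        rmse = float(np.sqrt(np.mean((predict_draws(post, Xt).mean(axis=1) - truth) ** 2)))
        assert rmse <= 0.15

    def test_same_seed_gives_bit_identical_sigma_draws(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (60, 2))
        z = np.sin(3 * X[:, 0]) + rng.normal(0, 0.2, 60)
        cfg = BartConfig(m=5, n_burn=30, n_draw=30, seed=9)
        a = fit_bart(X, z, cfg)
        b = fit_bart(X, z, cfg)
        assert np.array_equal(a.sigma_draws, b.sigma_draws)

    def test_increasing_draws_preserves_earlier_draws(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (50, 2))
        z = X[:, 0] + rng.normal(0, 0.1, 50)
        a = fit_bart(X, z, BartConfig(m=5, n_burn=20, n_draw=20, seed=3))
        b = fit_bart(X, z, BartConfig(m=5, n_burn=20, n_draw=40, seed=3))
        assert np.array_equal(a.sigma_draws, b.sigma_draws[:20])

    def test_degenerate_design_rejected(self):
        X = np.ones((10, 2))
        z = np.arange(10.0)
        with pytest.raises(ValueError, match="cutpoint"):
            fit_bart(X, z, BartConfig(m=2, n_burn=5, n_draw=5))

    def test_non_finite_response_rejected(self):
        X = np.random.default_rng(0).uniform(size=(10, 2))
        z = np.arange(10.0)
        z[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_bart(X, z, BartConfig(m=2, n_burn=5, n_draw=5))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BartConfig(m=0)
        with pytest.raises(ValueError):
            BartConfig(alpha=1.5)
        with pytest.raises(ValueError):
            BartConfig(move_probs=(0.5, 0.5, 0.5, 0.5))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    X = rng.uniform(0, 1, (100, 3))
    z = 2.0 * X[:, 0] + rng.normal(0, 0.2, 100)
    post = fit_bart(X, z, BartConfig(m=10, n_burn=100, n_draw=100, seed=4))
    return X, post


class TestPredict:
    def test_duplicated_rows_predict_identically(self, fitted):
        X, post = fitted
        Xd = np.vstack([X[:1], X[:1], X[:1]])
        d = predict_draws(post, Xd)
        assert np.array_equal(d[0], d[1]) and np.array_equal(d[1], d[2])

    def test_quantiles_are_ordered(self, fitted):
        X, post = fitted
        d = predict_draws(post, X, include_noise=True, rng=1)
        q = np.quantile(d, [0.025, 0.25, 0.5, 0.75, 0.975], axis=1)
        assert np.all(np.diff(q, axis=0) >= 0)

    def test_column_mismatch_rejected(self, fitted):
        X, post = fitted
        with pytest.raises(ValueError, match="columns"):
            predict_draws(post, X[:, :2])

    def test_noise_increases_spread(self, fitted):
        X, post = fitted
        quiet = predict_draws(post, X[:20]).std(axis=1).mean()
        noisy = predict_draws(post, X[:20], include_noise=True, rng=2).std(axis=1).mean()
        assert noisy > quiet


class TestImportance:
    def test_single_informative_predictor_takes_all_splits(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (80, 1))
        z = (X[:, 0] > 0.5).astype(float)
        post = fit_bart(X, z, BartConfig(m=5, n_burn=50, n_draw=50, seed=5))
        imp = variable_importance(post)
        assert imp["x0"] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, (80, 4))
        z = X[:, 0] + rng.normal(0, 0.1, 80)
        post = fit_bart(X, z, BartConfig(m=10, n_burn=50, n_draw=50, seed=6))
        assert sum(variable_importance(post).values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_stump_posterior_warns_with_zero_vector(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 1, (30, 2))
        z = rng.normal(size=30)
        post = fit_bart(X, z, BartConfig(m=2, n_burn=5, n_draw=5, seed=7))
        post.split_counts = np.zeros_like(post.split_counts)
        with pytest.warns(UserWarning, match="no splits"):
            imp = variable_importance(post)
        assert set(imp.values()) == {0.0}


class TestSerialization:
    def test_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, (50, 3))
        z = X[:, 1] + rng.normal(0, 0.2, 50)
        post = fit_bart(X, z, BartConfig(m=5, n_burn=20, n_draw=20, seed=8),
                        transform=BoundedLogitTransform())
        p = tmp_path / "post.json.gz"
        post.save(p)
        back = BartPosterior.load(p)
        assert np.array_equal(back.sigma_draws, post.sigma_draws)
        assert np.array_equal(back.split_counts, post.split_counts)
        assert back.column_names == post.column_names
        Xt = rng.uniform(0, 1, (20, 3))
        assert np.array_equal(predict_draws(back, Xt), predict_draws(post, Xt))

    def test_save_is_byte_identical(self, tmp_path):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, (30, 2))
        z = X[:, 0] + rng.normal(0, 0.1, 30)
        post = fit_bart(X, z, BartConfig(m=3, n_burn=10, n_draw=10, seed=9))
        p1, p2 = tmp_path / "a.json.gz", tmp_path / "b.json.gz"
        post.save(p1)
        post.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_foreign_file_rejected(self, tmp_path):
        import gzip, json
        p = tmp_path / "x.json.gz"
        with gzip.open(p, "wt") as fh:
            json.dump({"format": "something_else"}, fh)
        with pytest.raises(ValueError, match="not a srscape"):
            BartPosterior.load(p)
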