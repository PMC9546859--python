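"""The bivariate Gibbs sampler: design building, closed-form limits, pooling."""

import numpy as np
import pytest

from ornmeta import dataset as ds
from ornmeta import mcmc, simulate
from ornmeta.mcmc import (
    MCMCSettings,
    Priors,
    RankDeficientDesign,
    build_design,
    contrast,
    gibbs_sample,
    hpd,
    model_registry,
    pool_over_trees,
    sensitivity_refit,
    summarize,
)
from ornmeta.phylo import correlation_from_tree


def tiny_fixed():
    return {k: np.eye(2) * 1e-12 for k in ("Sigma_sp", "Sigma_ph", "Sigma_e")}


def make_gls_problem(seed=5, n_rows=120):
    cfg = simulate.SimConfig(
        n_species=15, n_rows=n_rows, paired_rows=n_rows, seed=seed,
        Sigma_ph=np.eye(2) * 1e-12, Sigma_sp=np.eye(2) * 1e-12,
        Sigma_e=np.eye(2) * 1e-12)
    df, trees, _ = simulate.simulate_dataset(cfg)
    dset = ds.build_dataset(df)
    spec, _ = model_registry()["1"]
    design = build_design(dset, spec)
    import dendropy
    tree = dendropy.Tree.get(data=trees[0], schema="newick",
                             preserve_underscores=True)
    return design, correlation_from_tree(tree, design.species)


def gls_oracle(design):
    X = design.X.reshape(-1, design.n_params)
    y = design.y.reshape(-1)
    w = 1.0 / design.D.reshape(-1)
    XtW = X.T * w
    return np.linalg.solve(XtW @ X, XtW @ y)


# ---------------------------------------------------------------------------
# design construction


def test_intercept_only_design_has_one_cell_per_sex(small_dataset):
    spec, _ = model_registry()["1-noyear"]
    design = build_design(small_dataset, spec)
    assert design.colnames == ["mean:female", "mean:male"]
    # every row loads exactly one column per sex
    assert np.allclose(design.X.sum(axis=2), 1.0)


def test_domain_model_builds_four_cell_means(small_dataset):
    spec, _ = model_registry()["3"]
    design = build_design(small_dataset, spec)
    cells = [c for c in design.colnames if ":" in c]
    assert sorted(cells) == ["condition:female", "condition:male",
                             "fitness:female", "fitness:male"]


def test_all_male_cell_is_flagged_rank_deficient(small_sim):
    _, df, _, _ = small_sim
    # remove every male condition effect: the condition:male cell is empty
    keep = ~((df["sex"] == "male") & (df["domain"] == "condition"))
    dset = ds.build_dataset(df[keep])
    spec, _ = model_registry()["3"]
    with pytest.raises(RankDeficientDesign, match="condition:male"):
        build_design(dset, spec)


def test_missing_moderator_raises(small_sim):
    _, df, _, _ = small_sim
    dset = ds.build_dataset(df)  # no dimorphism attached
    spec, _ = model_registry()["dimorphism-condition"]
    with pytest.raises(ValueError, match="dimorphism_d"):
        build_design(dset, spec)


# ---------------------------------------------------------------------------
# posterior summaries


def test_hpd_matches_exhaustive_search():
    rng = np.random.default_rng(0)
    x = rng.gamma(2.0, 1.0, size=400)
    lo, hi = hpd(x, 0.9)
    xs = np.sort(x)
    m = int(np.ceil(0.9 * len(xs)))
    widths = [(xs[i + m - 1] - xs[i], xs[i], xs[i + m - 1])
              for i in range(len(xs) - m + 1)]
    best = min(widths)
    assert (lo, hi) == (best[1], best[2])
    assert hpd(np.full(10, 3.3)) == (3.3, 3.3)
    with pytest.raises(ValueError):
        hpd(x, 1.5)
    with pytest.raises(ValueError):
        hpd(np.array([1.0]))


def test_contrast_is_linear_per_draw(small_fit):
    draws, _ = small_fit
    p = len(draws.colnames)
    a = np.zeros(p); a[0] = 1.0
    b = np.zeros(p); b[1] = -1.0
    ca = draws.beta @ a
    cb = draws.beta @ b
    cab = draws.beta @ (a + b)
    assert np.allclose(ca + cb, cab)
    zero = contrast(draws, np.zeros(p))
    assert zero["mean"] == 0.0 and zero["lower"] == zero["upper"] == 0.0
    with pytest.raises(ValueError):
        contrast(draws, [1.0])


def test_pooling_concatenates_and_checks_layout(small_dataset, small_trees):
    spec, _ = model_registry()["1-noyear"]
    settings = MCMCSettings(n_iter=200, burn_in=100, thin=10, n_trees=2)
    design = build_design(small_dataset, spec)
    per_tree = []
    for j, t in enumerate(small_trees):
        A = correlation_from_tree(t, design.species)
        per_tree.append(gibbs_sample(design, A, settings=settings, seed=j,
                                     tree_id=str(j)))
    pooled = pool_over_trees(per_tree)
    assert pooled.n_draws == sum(d.n_draws for d in per_tree)
    assert set(pooled.tree_ids) == {"0", "1"}
    # pooled mean equals draw-count-weighted mean of per-tree means
    ref = np.mean([d.beta.mean(axis=0) for d in per_tree], axis=0)
    assert np.allclose(pooled.beta.mean(axis=0), ref)
    assert np.array_equal(pool_over_trees([per_tree[0]]).beta, per_tree[0].beta)
    bad = per_tree[1]
    bad.colnames = ["x", "y"]
    with pytest.raises(ValueError):
        pool_over_trees([per_tree[0], bad])


# ---------------------------------------------------------------------------
# sampler correctness


def test_gls_limit_small():
    """With variances pinned ~0 and no missing data, beta is the GLS estimate."""
    design, A = make_gls_problem()
    settings = MCMCSettings(n_iter=1500, burn_in=500, thin=1)
    draws = gibbs_sample(design, A, settings=settings, seed=42,
                         fixed=tiny_fixed())
    assert np.abs(draws.beta.mean(axis=0) - gls_oracle(design)).max() < 1.5e-3


def test_same_seed_is_bit_identical(small_dataset, small_trees):
    spec, _ = model_registry()["1"]
    design = build_design(small_dataset, spec)
    A = correlation_from_tree(small_trees[0], design.species)
    settings = MCMCSettings(n_iter=150, burn_in=50, thin=5)
    d1 = gibbs_sample(design, A, settings=settings, seed=99)
    d2 = gibbs_sample(design, A, settings=settings, seed=99)
    assert np.array_equal(d1.beta, d2.beta)
    assert np.array_equal(d1.Sigma_ph, d2.Sigma_ph)
    d3 = gibbs_sample(design, A, settings=settings, seed=100)
    assert not np.array_equal(d1.beta, d3.beta)


def test_drawn_covariances_are_pd_with_valid_correlations(small_fit):
    draws, _ = small_fit
    for S in (draws.Sigma_sp, draws.Sigma_ph, draws.Sigma_e):
        dets = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] ** 2
        assert (S[:, 0, 0] > 0).all() and (S[:, 1, 1] > 0).all()
        assert (dets > 0).all()
    for name in ("r_sp", "r_ph", "r_e"):
        r = draws.param(name)
        assert (np.abs(r) <= 1.0).all()


def test_fixed_effect_prior_variance_is_inert():
    """1e6 vs 1e10 prior variance moves beta by far less than 1e-3."""
    design, A = make_gls_problem(seed=8, n_rows=80)
    settings = MCMCSettings(n_iter=400, burn_in=100, thin=3)
    res = {}
    for v in (1e6, 1e10):
        draws = gibbs_sample(design, A, priors=Priors(beta_var=v),
                             settings=settings, seed=21, fixed=tiny_fixed())
        res[v] = draws.beta.mean(axis=0)
    assert np.abs(res[1e6] - res[1e10]).max() < 1e-3


def test_masking_one_sex_barely_moves_fixed_effects(small_trees):
    """Augmentation sanity: masking 20% of male responses shifts posterior
    means by < 2 posterior SDs."""
    cfg = simulate.SimConfig(n_species=20, n_rows=150, paired_rows=150, seed=31)
    df, trees, _ = simulate.simulate_dataset(cfg)
    spec, _ = model_registry()["1-noyear"]
    settings = MCMCSettings(n_iter=1000, burn_in=250, thin=5)

    full = ds.build_dataset(df)
    rng = np.random.default_rng(0)
    males = df.index[df["sex"] == "male"]
    drop = rng.choice(males, size=int(0.2 * len(males)), replace=False)
    masked = ds.build_dataset(df.drop(index=drop))

    import dendropy
    tree = dendropy.Tree.get(data=trees[0], schema="newick",
                             preserve_underscores=True)
    out = {}
    for name, dset in (("full", full), ("masked", masked)):
        design = build_design(dset, spec)
        A = correlation_from_tree(tree, design.species)
        out[name] = gibbs_sample(design, A, settings=settings, seed=5)
    diff = np.abs(out["full"].beta.mean(axis=0) - out["masked"].beta.mean(axis=0))
    sd = out["full"].beta.std(axis=0)
    assert (diff < 2.0 * sd).all()


def test_sensitivity_refit_drops_named_rows(small_dataset, small_trees):
    spec, _ = model_registry()["1-noyear"]
    settings = MCMCSettings(n_iter=150, burn_in=50, thin=10, n_trees=1)
    target = small_dataset.effects[0]
    res = sensitivity_refit(small_dataset, [(target.species, target.ornament_id)],
                            small_trees[:1], spec, settings=settings, seed=3)
    assert res["n_reduced"] < res["n_full"]
    # empty exclusion list reproduces the full fit exactly (same seed)
    res0 = sensitivity_refit(small_dataset, [], small_trees[:1], spec,
                             settings=settings, seed=3)
    assert np.array_equal(res0["full"].beta, res0["reduced"].beta)
    every = [(pe.species, pe.ornament_id) for pe in small_dataset.effects]
    with pytest.raises(ValueError):
        sensitivity_refit(small_dataset, every, small_trees[:1], spec,
                          settings=settings, seed=3)


def test_summarize_reports_mean_and_hpd():
    rng = np.random.default_rng(1)
    x = rng.normal(2.0, 1.0, 20000)
    s = summarize(x)
    assert s["mean"] == pytest.approx(2.0, abs=0.05)
    assert s["lower"] == pytest.approx(2 - 1.96, abs=0.1)
    assert s["upper"] == pytest.approx(2 + 1.96, abs=0.1)
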