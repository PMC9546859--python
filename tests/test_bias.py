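"""Heterogeneity I² and the publication-bias detectors."""

import numpy as np
import pytest

from ornmeta import bias as bm
from ornmeta import dataset as ds
from ornmeta import mcmc, simulate
from ornmeta.bias import (
    egger_test,
    heterogeneity_report,
    i_squared,
    meta_residuals,
    timelag_slope,
    trim_and_fill,
    typical_sampling_variance,
)


# ---------------------------------------------------------------------------
# typical sampling variance and I²


def test_typical_sampling_variance_formula():
    # equal variances: the typical variance is that variance
    assert typical_sampling_variance([0.05] * 10) == pytest.approx(0.05)
    # direct evaluation of s2 = sum(w)(k-1) / (sum(w)^2 - sum(w^2))
    w = np.array([1 / 0.01, 1 / 0.04])
    expected = w.sum() * 1 / (w.sum() ** 2 - (w**2).sum())
    assert typical_sampling_variance([0.01, 0.04]) == pytest.approx(expected)
    # homogeneity: scaling all variances scales the result
    base = typical_sampling_variance([0.01, 0.03, 0.07])
    assert typical_sampling_variance([0.03, 0.09, 0.21]) == pytest.approx(3 * base)
    with pytest.raises(ValueError):
        typical_sampling_variance([0.05])


def constant_draws(s_sp, s_ph, s_e, n=50):
    eye = lambda v: np.tile(np.diag([v, v]), (n, 1, 1))
    return mcmc.PosteriorDraws(
        beta=np.zeros((n, 2)), colnames=["mean:female", "mean:male"],
        Sigma_sp=eye(s_sp), Sigma_ph=eye(s_ph), Sigma_e=eye(s_e),
        tree_ids=np.zeros(n), species=["a"], u_mean=np.zeros((1, 2)))


def test_i_squared_closed_forms():
    # single nonzero component equal to the sampling variance -> I2 = 0.5
    d = constant_draws(0.0, 0.0, 0.05)
    rep = i_squared(d, 0.05, "female")
    assert rep["I2_total"]["mean"] == pytest.approx(0.5)
    # all components -> 0 gives I2 -> 0
    d0 = constant_draws(1e-12, 1e-12, 1e-12)
    assert i_squared(d0, 0.05, "male")["I2_total"]["mean"] < 1e-9


def test_i_squared_bounds_and_component_additivity(small_fit):
    draws, design = small_fit
    rep = heterogeneity_report(draws, design)
    for sex in ("female", "male"):
        r = rep[sex]
        for key in ("I2_total", "I2_phylo", "I2_species"):
            assert 0.0 <= r[key]["lower"] <= r[key]["upper"] <= 1.0
        # per-draw component I2 never exceeds total I2
        k = 0 if sex == "female" else 1
        s2 = r["typical_sampling_variance"]
        tot = (draws.Sigma_ph[:, k, k] + draws.Sigma_sp[:, k, k]
               + draws.Sigma_e[:, k, k])
        i2_tot = tot / (tot + s2)
        for comp in (draws.Sigma_ph[:, k, k], draws.Sigma_sp[:, k, k]):
            assert np.all(comp / (tot + s2) <= i2_tot + 1e-12)


# ---------------------------------------------------------------------------
# Egger


def test_egger_zero_on_mirror_image_funnel():
    x = np.array([-0.4, -0.2, -0.1, 0.1, 0.2, 0.4])
    res = egger_test(x, np.full(6, 0.2))
    assert res["intercept"] == pytest.approx(0.0, abs=1e-12)
    # also exact with varying but mirror-paired SEs
    se = np.array([0.3, 0.2, 0.1, 0.1, 0.2, 0.3])
    assert egger_test(x, se)["intercept"] == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(ValueError):
        egger_test(x[:2], se[:2])


def test_egger_detects_injected_suppression():
    """Suppressing negative small-n effects (severity 0.8, k=200, zero true
    mean) produces funnel asymmetry that Egger flags in >= 80% of runs."""
    import pandas as pd
    from ornmeta.simulate import inject_publication_bias

    rng = np.random.default_rng(2)
    hits = 0
    reps = 40
    for _ in range(reps):
        n = np.clip(np.exp(rng.normal(3.7, 0.6, 200)), 10, 200).astype(int)
        se = 1 / np.sqrt(n - 3)
        df = pd.DataFrame({"zr": se * rng.standard_normal(200),
                           "se": se, "n": n})
        out = inject_publication_bias(df, 0.8, rng=rng)
        hits += egger_test(out["zr"].to_numpy(), out["se"].to_numpy())["p"] < 0.05
    assert hits >= 0.8 * reps


# ---------------------------------------------------------------------------
# trim and fill


def test_trim_and_fill_symmetric_set_unchanged():
    x = np.array([-0.6, -0.3, -0.1, 0.1, 0.3, 0.6, 0.0])
    se = np.array([0.3, 0.2, 0.1, 0.1, 0.2, 0.3, 0.15])
    res = trim_and_fill(x, se, side="left")
    assert res.k0 == 0
    assert res.mean_adjusted == pytest.approx(res.mean_original)
    assert res.p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        trim_and_fill(x[:2], se[:2])
    with pytest.raises(ValueError):
        trim_and_fill(x, se, side="up")


def pinned_centre_case(rng, k0_true, m=12):
    """High-precision symmetric bulk + low-precision mirrored extremes;
    the k0 left extremes are then suppressed."""
    mu = 0.3
    d_bulk = np.sort(rng.uniform(0.02, 0.3, m))
    se_bulk = rng.uniform(0.05, 0.10, m)
    d_ext = np.sort(rng.uniform(0.6, 1.2, k0_true))
    se_ext = rng.uniform(0.25, 0.40, k0_true)
    x = np.concatenate([mu + d_bulk, mu - d_bulk, mu + d_ext, mu - d_ext])
    se = np.concatenate([se_bulk, se_bulk, se_ext, se_ext])
    keep = np.ones(x.size, bool)
    keep[2 * m + k0_true:] = False
    return x, se, keep


@pytest.mark.parametrize("estimator", ["L0", "R0"])
def test_trim_and_fill_recovers_constructed_k0(estimator):
    rng = np.random.default_rng(5)
    hits = 0
    reps = 30
    for _ in range(reps):
        k0t = int(rng.integers(2, 6))
        x, se, keep = pinned_centre_case(rng, k0t)
        res = trim_and_fill(x[keep], se[keep], side="left", estimator=estimator,
                            weights="fixed")
        hits += abs(res.k0 - k0t) <= 1
        # imputed points are on the missing side and counted by k0
        assert len(res.imputed_effects) == res.k0
        if res.k0:
            assert res.mean_adjusted < res.mean_original
    assert hits >= 0.8 * reps


def test_trim_and_fill_moves_mean_toward_truth():
    rng = np.random.default_rng(17)
    closer = 0
    for _ in range(50):
        k0t = int(rng.integers(2, 6))
        x, se, keep = pinned_centre_case(rng, k0t)
        w = 1 / se**2
        pre = (w * x).sum() / w.sum()
        wk = 1 / se[keep] ** 2
        biased = (wk * x[keep]).sum() / wk.sum()
        res = trim_and_fill(x[keep], se[keep], side="left", weights="fixed")
        closer += abs(res.mean_adjusted - pre) <= abs(biased - pre)
    assert closer >= 45


# ---------------------------------------------------------------------------
# residuals and time lag


def test_meta_residuals_near_zero_without_noise():
    cfg = simulate.SimConfig(
        n_species=12, n_rows=80, paired_rows=80, seed=2,
        Sigma_ph=np.eye(2) * 1e-12, Sigma_sp=np.eye(2) * 1e-12,
        Sigma_e=np.eye(2) * 1e-12, n_log_mean=9.0, n_log_sd=0.01,
        n_max=20000, year_slope=0.0,
        domain_offsets={"condition": (0, 0), "fitness": (0, 0)})
    df, trees, _ = simulate.simulate_dataset(cfg)
    dset = ds.build_dataset(df)
    spec, _ = mcmc.model_registry()["1-noyear"]
    design = mcmc.build_design(dset, spec)
    import dendropy
    from ornmeta.phylo import correlation_from_tree
    tree = dendropy.Tree.get(data=trees[0], schema="newick",
                             preserve_underscores=True)
    A = correlation_from_tree(tree, design.species)
    draws = mcmc.gibbs_sample(design, A, settings=mcmc.MCMCSettings(600, 200, 4),
                              seed=4, fixed={k: np.eye(2) * 1e-12 for k in
                                             ("Sigma_sp", "Sigma_ph", "Sigma_e")})
    res = meta_residuals(draws, design)
    for sex in ("female", "male"):
        assert np.abs(res[sex]["residual"]).max() < 0.05
        assert abs(res[sex]["residual"].mean()) < 0.01


def test_timelag_slope_requires_year_moderator(small_fit):
    draws, _ = small_fit
    out = timelag_slope(draws)
    assert out["lower"] <= out["mean"] <= out["upper"]
    noyear = mcmc.PosteriorDraws(
        beta=draws.beta[:, :2], colnames=["mean:female", "mean:male"],
        Sigma_sp=draws.Sigma_sp, Sigma_ph=draws.Sigma_ph, Sigma_e=draws.Sigma_e,
        tree_ids=draws.tree_ids, species=draws.species, u_mean=draws.u_mean)
    with pytest.raises(KeyError):
        timelag_slope(noyear)


def test_bias_report_shape(small_fit):
    draws, design = small_fit
    rep = bm.bias_report(draws, design)
    for sex in ("female", "male"):
        assert {"egger", "trim_and_fill"} <= set(rep[sex])
        assert rep[sex]["trim_and_fill"]["k0"] >= 0
    assert rep["timelag"] is not None
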