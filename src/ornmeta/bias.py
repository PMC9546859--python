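"""Heterogeneity (multilevel I²) and the publication-bias suite.

I² is the proportion of effect-size variance not attributable to sampling
error.  With phylogenetic, species and residual variance components and a
"typical" sampling variance s̄² it decomposes per posterior draw as

    I²_total = (σ²_ph + σ²_sp + σ²_e) / (σ²_ph + σ²_sp + σ²_e + s̄²)

with each component I² replacing the numerator by its own σ².  Because the
variance components are posterior draws, I² is itself a posterior
distribution and is reported as mean plus HPD interval.

Publication bias is assessed on meta-analytic residuals (observed Zr minus
fixed-effect fit minus posterior-mean species-level effects), separately per
sex: Egger's regression for funnel asymmetry, Duval–Tweedie trim-and-fill to
estimate and impute suppressed effects, a Z-test for the induced mean shift,
and the publication-year moderator as the time-lag-bias slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .mcmc import Design, PosteriorDraws, hpd, summarize

__all__ = [
    "typical_sampling_variance",
    "i_squared",
    "meta_residuals",
    "egger_test",
    "trim_and_fill",
    "TrimFillResult",
    "timelag_slope",
    "bias_report",
    "heterogeneity_report",
]

_SEX_INDEX = {"female": 0, "male": 1, "f": 0, "m": 1}


def typical_sampling_variance(se2: Sequence[float]) -> float:
    """Typical (weighted-harmonic) sampling variance of a set of effects.

        s̄² = Σw (k − 1) / ((Σw)² − Σw²),   w = 1/SE²

    the standard meta-analytic summary of within-study error used in I².
    """
    v = np.asarray(se2, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 effects")
    if (v <= 0).any():
        raise ValueError("all sampling variances must be positive")
    w = 1.0 / v
    k = v.size
    return float(w.sum() * (k - 1) / (w.sum() ** 2 - (w**2).sum()))


def i_squared(draws: PosteriorDraws, sbar2: float, sex: str, prob: float = 0.95) -> dict:
    """Multilevel I² (total, phylogenetic, species) for one sex.

    Computed per posterior draw and summarised as mean + HPD, so interval
    endpoints reflect posterior uncertainty in the variance components.
    """
    k = _SEX_INDEX[sex]
    s_ph = draws.Sigma_ph[:, k, k]
    s_sp = draws.Sigma_sp[:, k, k]
    s_e = draws.Sigma_e[:, k, k]
    total = s_ph + s_sp + s_e
    denom = total + sbar2
    return {
        "sex": "female" if k == 0 else "male",
        "typical_sampling_variance": sbar2,
        "I2_total": summarize(total / denom, prob),
        "I2_phylo": summarize(s_ph / denom, prob),
        "I2_species": summarize(s_sp / denom, prob),
    }


def heterogeneity_report(draws: PosteriorDraws, design: Design, prob: float = 0.95) -> dict:
    """Per-sex I² using each sex's own typical sampling variance."""
    out = {}
    for sex, k in (("female", 0), ("male", 1)):
        se2 = design.D[design.mask[:, k], k]
        out[sex] = i_squared(draws, typical_sampling_variance(se2), sex, prob)
    return out


def meta_residuals(draws: PosteriorDraws, design: Design) -> dict:
    """Per-effect meta-analytic residuals, split by sex.

    residual = observed Zr − (fixed-effect fit at the posterior-mean beta
    + posterior-mean species and phylogenetic deviations).  Only observed
    (non-imputed) effects are returned, each with its SE.
    """
    beta_hat = draws.beta.mean(axis=0)
    fit = np.einsum("nsp,p->ns", design.X, beta_hat)
    fit = fit + draws.u_mean[design.species_idx]
    out = {}
    for sex, k in (("female", 0), ("male", 1)):
        obs = design.mask[:, k]
        out[sex] = {
            "residual": design.y[obs, k] - fit[obs, k],
            "se": np.sqrt(design.D[obs, k]),
        }
    return out


def egger_test(residuals: np.ndarray, se: np.ndarray, prob: float = 0.95) -> dict:
    """Egger's regression test for funnel asymmetry.

    Weighted regression of the effect (here: meta-analytic residual) on its
    standard error with weights 1/SE² — equivalent to regressing
    residual/SE on 1/SE — whose coefficient on SE is the classic Egger
    intercept; its two-sided t-test indicates asymmetry.
    """
    r = np.asarray(residuals, dtype=float)
    s = np.asarray(se, dtype=float)
    if r.size < 3:
        raise ValueError("Egger's test needs at least 3 effects")
    if np.ptp(s) < 1e-12 * s.mean():
        # no SE variation: the regression is collinear and the asymmetry
        # coefficient degenerates to the mean standardised effect
        z = r / s
        m = float(z.mean())
        sem = float(z.std(ddof=1) / math.sqrt(z.size)) if z.size > 1 else math.inf
        tcrit = sps.t.ppf(0.5 + prob / 2, z.size - 1)
        pval = 2 * sps.t.sf(abs(m) / sem, z.size - 1) if sem > 0 else 1.0
        return {"intercept": m, "ci": (m - tcrit * sem, m + tcrit * sem),
                "p": float(pval), "pooled_mean": float(np.mean(r)), "k": int(r.size)}
    Xd = sm.add_constant(s)
    fit = sm.WLS(r, Xd, weights=1.0 / s**2).fit()
    ci = fit.conf_int(alpha=1 - prob)
    return {
        "intercept": float(fit.params[1]),
        "ci": (float(ci[1][0]), float(ci[1][1])),
        "p": float(fit.pvalues[1]),
        "pooled_mean": float(fit.params[0]),
        "k": int(r.size),
    }


@dataclass
class TrimFillResult:
    """Outcome of the Duval–Tweedie trim-and-fill correction."""

    k0: int
    side: str
    mean_original: float
    se_original: float
    mean_adjusted: float
    se_adjusted: float
    z: float
    p: float
    imputed_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    imputed_se: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "k0": self.k0,
            "side": self.side,
            "mean_original": self.mean_original,
            "mean_adjusted": self.mean_adjusted,
            "z": self.z,
            "p": self.p,
        }


def _tau2_dl(x: np.ndarray, se: np.ndarray) -> float:
    """DerSimonian–Laird between-study variance estimate (non-negative)."""
    w = 1.0 / se**2
    xbar = (w * x).sum() / w.sum()
    Q = (w * (x - xbar) ** 2).sum()
    C = w.sum() - (w**2).sum() / w.sum()
    return max(0.0, (Q - (x.size - 1)) / C) if C > 0 else 0.0


def _weighted_mean(x: np.ndarray, se: np.ndarray, tau2: float = 0.0
                   ) -> tuple[float, float]:
    w = 1.0 / (se**2 + tau2)
    return float((w * x).sum() / w.sum()), float(1.0 / math.sqrt(w.sum()))


def _k0_estimate(dev: np.ndarray, estimator: str) -> int:
    """Rank-based estimators of the number of suppressed studies.

    Deviations are from the current centre; suppression is assumed on the
    *left*, so the excess being counted is on the right.  L0 uses the
    Wilcoxon-type rank sum of positive deviations; R0 uses the length of the
    rightmost run of positive deviations among the largest |deviations|.
    """
    k = dev.size
    ranks = sps.rankdata(np.abs(dev))
    if estimator == "L0":
        Tn = ranks[dev > 0].sum()
        est = (4.0 * Tn - k * (k + 1)) / (2.0 * k - 1.0)
        return max(0, int(round(est)))
    if estimator == "R0":
        order = np.argsort(-ranks)  # largest |dev| first
        run = 0
        for idx in order:
            if dev[idx] > 0:
                run += 1
            else:
                break
        return max(0, run - 1)
    raise ValueError(f"unknown estimator {estimator!r}")


def trim_and_fill(
    effects: Sequence[float],
    se: Sequence[float],
    side: Optional[str] = None,
    estimator: str = "L0",
    max_iter: int = 50,
    weights: str = "random",
) -> TrimFillResult:
    """Duval–Tweedie trim-and-fill funnel-plot correction.

    Iteratively estimates the number k0 of suppressed effects with a
    rank-based estimator, trims the k0 most extreme effects on the opposite
    side, re-estimates the fixed-effect centre from the trimmed funnel, and
    repeats until k0 stabilises.  The suppressed effects are then "filled"
    as exact reflections of the k0 most extreme observed effects about the
    final centre (with their SEs), and the adjusted mean is the
    inverse-variance mean of observed + filled.  A two-sided Z-test compares
    original and adjusted means.

    ``side`` is where the *missing* studies are assumed to lie ("left" or
    "right"); by default it is chosen from the sign of Egger's intercept on
    the input set (a positive small-study surplus implies suppression on the
    left).  ``weights`` selects the meta-analytic centre: "random" (default)
    re-estimates a DerSimonian–Laird between-study variance on each trimmed
    set and weights by 1/(SE² + τ²) — the random-effects centre, which keeps
    the rank estimators stable when heterogeneity dwarfs the sampling
    variances; "fixed" uses 1/SE².
    """
    x = np.asarray(effects, dtype=float)
    s = np.asarray(se, dtype=float)
    if x.size < 3:
        raise ValueError("trim-and-fill needs at least 3 effects")
    if side is None:
        # suppression of negative small studies leaves a positive small-study
        # surplus (positive Egger coefficient) and missing effects on the left
        side = "left" if egger_test(x, s)["intercept"] > 0 else "right"
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")

    # missing on the left <=> surplus of extreme positive deviations, which is
    # what the rank estimators count; mirror for missing on the right
    flip = 1.0 if side == "left" else -1.0
    xf = flip * x

    if weights not in ("random", "fixed"):
        raise ValueError("weights must be 'random' or 'fixed'")

    def centre_of(x_, s_):
        t2 = _tau2_dl(x_, s_) if weights == "random" else 0.0
        return _weighted_mean(x_, s_, t2)[0], t2

    tau2 = _tau2_dl(xf, s) if weights == "random" else 0.0
    m_orig, se_orig = _weighted_mean(xf, s, tau2)
    k0, centre = 0, m_orig
    for _ in range(max_iter):
        keep = np.ones(xf.size, dtype=bool)
        if k0 > 0:
            # trim the k0 largest effects (the asymmetric right tail)
            trim_idx = np.argsort(xf)[-k0:]
            keep[trim_idx] = False
            if keep.sum() < 2:
                raise RuntimeError("trim-and-fill trimmed away almost all effects")
        centre, _ = centre_of(xf[keep], s[keep])
        new_k0 = min(_k0_estimate(xf - centre, estimator), xf.size - 2)
        if new_k0 == k0:
            break
        k0 = new_k0
    else:
        raise RuntimeError(f"trim-and-fill did not converge in {max_iter} iterations")

    if k0 > 0:
        mirror_idx = np.argsort(xf)[-k0:]
        imp_x = 2.0 * centre - xf[mirror_idx]
        imp_se = s[mirror_idx]
        x_aug = np.concatenate([xf, imp_x])
        s_aug = np.concatenate([s, imp_se])
        tau2_adj = _tau2_dl(x_aug, s_aug) if weights == "random" else 0.0
        m_adj, se_adj = _weighted_mean(x_aug, s_aug, tau2_adj)
    else:
        imp_x = np.empty(0)
        imp_se = np.empty(0)
        m_adj, se_adj = m_orig, se_orig

    z = (m_orig - m_adj) / math.sqrt(se_orig**2 + se_adj**2)
    p = 2.0 * sps.norm.sf(abs(z))
    return TrimFillResult(
        k0=int(k0),
        side=side,
        mean_original=flip * m_orig,
        se_original=se_orig,
        mean_adjusted=flip * m_adj,
        se_adjusted=se_adj,
        z=flip * z,
        p=float(p),
        imputed_effects=flip * imp_x,
        imputed_se=imp_se,
    )


def timelag_slope(draws: PosteriorDraws, prob: float = 0.95) -> dict:
    """Posterior summary of the publication-year moderator.

    A negative slope means reported effects decline with publication year —
    the time-lag bias signature (large early effects, smaller later ones).
    """
    name = "publication_year_centred"
    if name not in draws.colnames:
        raise KeyError(
            "model was fitted without the publication-year moderator; "
            f"fixed effects are {draws.colnames}"
        )
    out = summarize(draws.param(name), prob)
    out["interpretation"] = (
        "negative slope = declining effects over time (time-lag bias)")
    return out


def bias_report(draws: PosteriorDraws, design: Design, prob: float = 0.95) -> dict:
    """Full per-sex publication-bias report plus the time-lag slope."""
    res = meta_residuals(draws, design)
    report: dict = {}
    for sex in ("female", "male"):
        r, s = res[sex]["residual"], res[sex]["se"]
        egger = egger_test(r, s, prob)
        tf = trim_and_fill(r, s)
        report[sex] = {"egger": egger, "trim_and_fill": tf.to_dict()}
    try:
        report["timelag"] = timelag_slope(draws, prob)
    except KeyError:
        report["timelag"] = None
    return report
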