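"""Bivariate phylogenetic mixed-effects meta-analysis fitted by Gibbs sampling.

Model
-----
Each paired observation i contributes a 2-vector of responses
``y_i = (Zr_female, Zr_male)``, either of which may be missing:

    y_i = X_i beta + u_sp[s(i)] + u_ph[s(i)] + e_i + m_i

with species random effects ``u_sp ~ N(0, Sigma_sp)`` (iid across species),
phylogenetic effects ``u_ph`` correlated across species through the tree
correlation matrix ``A`` (``cov(u_ph[s,a], u_ph[t,b]) = A[s,t] Sigma_ph[a,b]``),
a bivariate residual ``e_i ~ N(0, Sigma_e)``, and known measurement error
``m_i ~ N(0, diag(se2_f, se2_m))`` from the Fisher-Zr sampling variances.

All full conditionals are conjugate, so the sampler is blocked Gibbs:

* missing responses are drawn from their bivariate-normal conditional given
  the observed twin (row covariance ``Sigma_e + diag(se2)``);
* all location effects — ``beta`` and the species and phylogenetic levels —
  are drawn in ONE joint Gaussian block from the mixed-model equations with
  the residual marginalised into the row covariance; separate per-block
  updates mix poorly here because a grand shift of the species levels is
  nearly collinear with the intercepts;
* the bivariate residuals ``e_i`` are then drawn given the completed rows
  and location effects;
* covariance matrices are inverse-Wishart updates, with the random-effect
  terms parameter-expanded: levels are stored as ``u = diag(alpha) eta`` with
  ``eta ~ N(0, Psi)`` and a Gaussian working scale ``alpha`` — the redundant
  multiplicative reparameterisation that keeps variance components mixing
  when they are near zero.

Priors follow the (V, nu) inverse-Wishart convention in which the prior is
a standard IW with scale ``nu * V`` and ``nu`` degrees of freedom (prior
mode ``nu*V/(nu + dim + 1)``); the parameter-expanded prior adds
``alpha ~ N(alpha_mu, alpha_V)``.  Defaults: ``V = I2, nu = 2,
alpha_mu = 0, alpha_V = 625 I2`` for random terms, ``V = I2, nu = 2`` for
the residual, and independent N(0, 1e8) for fixed effects.

Tree uncertainty is handled by running one chain per tree (seed offset by
the tree index) and concatenating retained draws, e.g. 50 trees x 100
retained draws = 5000 pooled posterior samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg as sla

from .dataset import AnalysisDataset, PairedEffect
from .phylo import PhyloCorrelation, correlation_from_tree

__all__ = [
    "ModelSpec",
    "Priors",
    "MCMCSettings",
    "Design",
    "PosteriorDraws",
    "build_design",
    "gibbs_sample",
    "fit_model",
    "pool_over_trees",
    "hpd",
    "summarize",
    "contrast",
    "sensitivity_refit",
    "model_registry",
]


# ---------------------------------------------------------------------------
# model specification and design construction


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect layout of one bivariate model.

    ``cell_moderator`` (a :class:`~ornmeta.dataset.PairedEffect` field name)
    crosses its levels with sex into cell means; ``None`` gives the
    intercept-only layout (one mean per sex).  ``continuous_additive``
    columns get one slope shared by the sexes; ``continuous_sex_interaction``
    columns get a shared slope plus a male-offset slope (the sex-by-moderator
    interaction coefficient).  ``categorical_additive`` columns are
    treatment-coded with the first level as reference, shared across sexes.
    """

    name: str = "custom"
    cell_moderator: Optional[str] = None
    continuous_additive: tuple = ()
    continuous_sex_interaction: tuple = ()
    categorical_additive: tuple = ()


def model_registry() -> dict:
    """Named model layouts: (ModelSpec, row-subset predicate or None).

    1: sex-specific grand means; 2: sex x ornament type; 3: sex x
    condition/fitness domain; 4: sex x condition subcategory (condition rows);
    5: sex x fitness subcategory (fitness rows); dimorphism-condition /
    dimorphism-fitness: sex means plus a dimorphism slope and its sex
    interaction, on rows with a dimorphism score.  All include the
    mean-centred publication year as an additive moderator (time-lag
    control); the ``-noyear`` variants drop it.
    """
    year = ("publication_year_centred",)
    reg: dict = {
        "1": (ModelSpec("model1", None, year), None),
        "1-noyear": (ModelSpec("model1-noyear", None), None),
        "1-design": (ModelSpec("model1-design", None, year, (), ("study_design",)), None),
        "2": (ModelSpec("model2", "ornament_type", year), None),
        "3": (ModelSpec("model3", "domain", year), None),
        "4": (ModelSpec("model4", "subcategory", year),
              lambda pe: pe.domain == "condition"),
        "5": (ModelSpec("model5", "subcategory", year),
              lambda pe: pe.domain == "fitness"),
        "dimorphism-condition": (
            ModelSpec("dimorphism-condition", None, year, ("dimorphism_d",)),
            lambda pe: pe.domain == "condition" and pe.dimorphism_d is not None),
        "dimorphism-fitness": (
            ModelSpec("dimorphism-fitness", None, year, ("dimorphism_d",)),
            lambda pe: pe.domain == "fitness" and pe.dimorphism_d is not None),
    }
    return reg


@dataclass
class Design:
    """Stacked design for the sampler: X is (N, 2, p), sex 0 = female."""

    X: np.ndarray
    y: np.ndarray           # (N, 2), nan where missing
    mask: np.ndarray        # (N, 2) bool, True = observed
    D: np.ndarray           # (N, 2) known sampling variances (SE^2)
    species_idx: np.ndarray # (N,) int
    species: list
    colnames: list
    spec: ModelSpec
    rows: list = field(default_factory=list)  # the PairedEffect rows

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[2]


class RankDeficientDesign(ValueError):
    pass


def build_design(dataset: AnalysisDataset, spec: ModelSpec) -> Design:
    """Design matrices and index maps for one model layout.

    Responses are stacked (female, male) per paired observation with a
    missingness mask; column order is deterministic: sex cells (levels in
    sorted order, female before male), then treatment-coded additive
    categoricals, then shared slopes, then sex-interaction slopes.
    """
    rows = dataset.effects
    N = len(rows)
    if N == 0:
        raise ValueError("empty dataset")

    def col(pe: PairedEffect, name: str):
        v = getattr(pe, name)
        if v is None:
            raise ValueError(f"moderator {name!r} missing on a row "
                             f"({pe.study_id}/{pe.species}); subset first")
        return v

    colnames: list[str] = []
    if spec.cell_moderator is None:
        cells = [None]
        colnames += ["mean:female", "mean:male"]
    else:
        cells = sorted({str(col(pe, spec.cell_moderator)) for pe in rows})
        for lvl in cells:
            colnames += [f"{lvl}:female", f"{lvl}:male"]
    cat_levels = {}
    for c in spec.categorical_additive:
        lv = sorted({str(col(pe, c)) for pe in rows})
        cat_levels[c] = lv
        colnames += [f"{c}={l}" for l in lv[1:]]
    colnames += list(spec.continuous_additive)
    for c in spec.continuous_sex_interaction:
        colnames += [c, f"male:{c}"]
    p = len(colnames)
    cindex = {c: j for j, c in enumerate(colnames)}

    X = np.zeros((N, 2, p))
    y = np.full((N, 2), np.nan)
    D = np.empty((N, 2))
    species = sorted({pe.species for pe in rows})
    sp_index = {s: i for i, s in enumerate(species)}
    species_idx = np.empty(N, dtype=np.int64)
    mask = np.zeros((N, 2), dtype=bool)

    for i, pe in enumerate(rows):
        lvl = "mean" if spec.cell_moderator is None else str(col(pe, spec.cell_moderator))
        X[i, 0, cindex[f"{lvl}:female"]] = 1.0
        X[i, 1, cindex[f"{lvl}:male"]] = 1.0
        for c in spec.categorical_additive:
            v = str(col(pe, c))
            if v != cat_levels[c][0]:
                X[i, :, cindex[f"{c}={v}"]] = 1.0
        for c in spec.continuous_additive:
            X[i, :, cindex[c]] = float(col(pe, c))
        for c in spec.continuous_sex_interaction:
            v = float(col(pe, c))
            X[i, :, cindex[c]] = v
            X[i, 1, cindex[f"male:{c}"]] = v
        if pe.zr_f is not None:
            y[i, 0] = pe.zr_f
            mask[i, 0] = True
        if pe.zr_m is not None:
            y[i, 1] = pe.zr_m
            mask[i, 1] = True
        if pe.se2_f is None or pe.se2_m is None:
            raise ValueError("SE^2 missing: run augment_missing_uncertainty first")
        D[i] = (pe.se2_f, pe.se2_m)
        species_idx[i] = sp_index[pe.species]

    Xobs = X[mask]
    rank = np.linalg.matrix_rank(Xobs)
    if rank < p:
        # name the aliased columns via pivoted QR on the observed rows
        _, _, piv = sla.qr(Xobs, pivoting=True, mode="economic")
        aliased = [colnames[j] for j in piv[rank:]]
        raise RankDeficientDesign(
            f"design is rank deficient (rank {rank} < {p}); aliased columns: {aliased}"
        )
    return Design(X, y, mask, D, species_idx, species, colnames, spec, list(rows))


# ---------------------------------------------------------------------------
# priors and settings


@dataclass(frozen=True)
class Priors:
    """(V, nu) inverse-Wishart constants and the fixed-effect prior variance."""

    V_random: np.ndarray = field(default_factory=lambda: np.eye(2))
    nu_random: float = 2.0
    alpha_mu: np.ndarray = field(default_factory=lambda: np.zeros(2))
    alpha_V: np.ndarray = field(default_factory=lambda: 625.0 * np.eye(2))
    V_resid: np.ndarray = field(default_factory=lambda: np.eye(2))
    nu_resid: float = 2.0
    beta_var: float = 1e8


@dataclass(frozen=True)
class MCMCSettings:
    """Chain length per tree; defaults give (11000-1000)/100 = 100 retained draws."""

    n_iter: int = 11000
    burn_in: int = 1000
    thin: int = 100
    seed: int = 0
    n_trees: int = 50

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


# ---------------------------------------------------------------------------
# posterior container


def hpd(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws (ties -> lowest start)."""
    if not 0.0 < prob < 1.0:
        raise ValueError(f"prob must be in (0, 1), got {prob}")
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws for an HPD interval")
    m = int(math.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    return float(x[i]), float(x[i + m - 1])


def summarize(draws: np.ndarray, prob: float = 0.95) -> dict:
    """Posterior mean and HPD interval of a 1-d draw vector."""
    lo, hi = hpd(draws, prob)
    return {"mean": float(np.mean(draws)), "lower": lo, "upper": hi, "prob": prob}


@dataclass
class PosteriorDraws:
    """Retained draws of the fixed effects and (co)variance components.

    ``beta`` is (draws, p); each Sigma is (draws, 2, 2) ordered
    (female, male).  ``u_mean`` holds the posterior-mean species-level
    deviation (species + phylogenetic effect combined, per sex), used for
    meta-analytic residuals.  ``tree_ids`` records per-draw provenance.
    """

    beta: np.ndarray
    colnames: list
    Sigma_sp: np.ndarray
    Sigma_ph: np.ndarray
    Sigma_e: np.ndarray
    tree_ids: np.ndarray
    species: list
    u_mean: np.ndarray
    n_effects: int = 0
    n_species: int = 0

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def param(self, name: str) -> np.ndarray:
        """1-d draw vector by name.

        Fixed effects by column name; variance components as
        ``sigma2_{sp|ph|e}_{f|m}``; cross-sex correlations as
        ``r_{sp|ph|e}``.
        """
        if name in self.colnames:
            return self.beta[:, self.colnames.index(name)]
        comp = {"sp": self.Sigma_sp, "ph": self.Sigma_ph, "e": self.Sigma_e}
        parts = name.split("_")
        if parts[0] == "sigma2" and parts[1] in comp and parts[2] in ("f", "m"):
            k = 0 if parts[2] == "f" else 1
            return comp[parts[1]][:, k, k]
        if parts[0] == "r" and len(parts) == 2 and parts[1] in comp:
            S = comp[parts[1]]
            return S[:, 0, 1] / np.sqrt(S[:, 0, 0] * S[:, 1, 1])
        raise KeyError(f"unknown parameter {name!r}; fixed effects: {self.colnames}")

    def summary(self, prob: float = 0.95) -> dict:
        names = list(self.colnames) + [
            f"sigma2_{c}_{s}" for c in ("sp", "ph", "e") for s in ("f", "m")
        ] + ["r_sp", "r_ph", "r_e"]
        return {n: summarize(self.param(n), prob) for n in names}


def contrast(draws: PosteriorDraws, weights: Sequence[float], prob: float = 0.95) -> dict:
    """Posterior summary of a linear combination of the fixed effects."""
    w = np.asarray(weights, dtype=float)
    if w.size != len(draws.colnames):
        raise ValueError(f"need {len(draws.colnames)} weights, got {w.size}")
    vals = draws.beta @ w
    if np.allclose(w, 0.0):
        return {"mean": 0.0, "lower": 0.0, "upper": 0.0, "prob": prob}
    return summarize(vals, prob)


def pool_over_trees(per_tree: Sequence[PosteriorDraws]) -> PosteriorDraws:
    """Concatenate per-tree posteriors (phylogenetic-uncertainty pooling)."""
    if len(per_tree) == 0:
        raise ValueError("no posteriors to pool")
    first = per_tree[0]
    for d in per_tree[1:]:
        if d.colnames != first.colnames or d.species != first.species:
            raise ValueError("parameter layouts differ across trees; cannot pool")
    counts = np.array([d.n_draws for d in per_tree], dtype=float)
    u_mean = sum(d.u_mean * c for d, c in zip(per_tree, counts)) / counts.sum()
    return PosteriorDraws(
        beta=np.concatenate([d.beta for d in per_tree]),
        colnames=first.colnames,
        Sigma_sp=np.concatenate([d.Sigma_sp for d in per_tree]),
        Sigma_ph=np.concatenate([d.Sigma_ph for d in per_tree]),
        Sigma_e=np.concatenate([d.Sigma_e for d in per_tree]),
        tree_ids=np.concatenate([d.tree_ids for d in per_tree]),
        species=first.species,
        u_mean=u_mean,
        n_effects=first.n_effects,
        n_species=first.n_species,
    )


# ---------------------------------------------------------------------------
# vectorised 2x2 utilities


def _inv2(M: np.ndarray) -> np.ndarray:
    a, b = M[..., 0, 0], M[..., 0, 1]
    c, d = M[..., 1, 0], M[..., 1, 1]
    det = a * d - b * c
    out = np.empty_like(M)
    out[..., 0, 0] = d / det
    out[..., 0, 1] = -b / det
    out[..., 1, 0] = -c / det
    out[..., 1, 1] = a / det
    return out


def _chol2(M: np.ndarray) -> np.ndarray:
    """Lower Cholesky of a batch of 2x2 SPD matrices."""
    l11 = np.sqrt(M[..., 0, 0])
    l21 = M[..., 1, 0] / l11
    l22 = np.sqrt(np.maximum(M[..., 1, 1] - l21**2, 1e-300))
    out = np.zeros_like(M)
    out[..., 0, 0] = l11
    out[..., 1, 0] = l21
    out[..., 1, 1] = l22
    return out


def _mvn2(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Batch of bivariate normal draws; mean (...,2), cov (...,2,2)."""
    L = _chol2(cov)
    z = rng.standard_normal(mean.shape)
    return mean + np.einsum("...ij,...j->...i", L, z)


def _invwishart2(scale: np.ndarray, df: float, rng: np.random.Generator) -> np.ndarray:
    """One 2x2 inverse-Wishart draw via the Bartlett decomposition.

    If W ~ Wishart(df, scale^{-1}) then W^{-1} ~ IW(scale, df).
    """
    Sinv = _inv2(scale)
    L = _chol2(Sinv)
    B = np.zeros((2, 2))
    B[0, 0] = math.sqrt(rng.chisquare(df))
    B[1, 1] = math.sqrt(rng.chisquare(df - 1))
    B[1, 0] = rng.standard_normal()
    LB = L @ B
    W = LB @ LB.T
    return _inv2(W)


# ---------------------------------------------------------------------------
# the sampler


def gibbs_sample(
    design: Design,
    A: PhyloCorrelation | np.ndarray,
    priors: Priors = Priors(),
    settings: MCMCSettings = MCMCSettings(),
    seed: Optional[int] = None,
    tree_id: str = "0",
    fixed: Optional[dict] = None,
) -> PosteriorDraws:
    """Run one Gibbs chain for one tree and return the retained draws.

    ``fixed`` may pin covariance components to known 2x2 matrices (keys
    ``"Sigma_sp"``, ``"Sigma_ph"``, ``"Sigma_e"``); a pinned component is
    not sampled and its parameter-expansion scale is held at 1.  Pinning all
    three near zero reduces the model to weighted least squares — the
    closed-form check used in the tests.
    """
    rng = np.random.default_rng(settings.seed if seed is None else seed)
    fixed = fixed or {}

    if isinstance(A, PhyloCorrelation):
        if A.species != design.species:
            A = A.submatrix(design.species)
        Amat = A.A
    else:
        Amat = np.asarray(A)
    S = len(design.species)
    N = design.n_rows
    p = design.n_params
    if Amat.shape != (S, S):
        raise ValueError(f"A must be {S}x{S} for this dataset")
    A_chol = np.linalg.cholesky(Amat + 1e-12 * np.eye(S))
    A_inv = sla.cho_solve((A_chol, True), np.eye(S))

    X = design.X                      # (N,2,p)
    D = design.D                      # (N,2)
    Dinv = 1.0 / D
    mask = design.mask
    miss = ~mask
    sp = design.species_idx
    has_missing = bool(miss.any())

    S0_rand = priors.nu_random * priors.V_random
    S0_resid = priors.nu_resid * priors.V_resid
    alpha_V_inv_diag = 1.0 / np.diag(priors.alpha_V)

    # state
    beta = np.zeros(p)
    eta_sp = np.zeros((S, 2))
    eta_ph = np.zeros((S, 2))
    alpha_sp = np.ones(2)
    alpha_ph = np.ones(2)
    Psi_sp = fixed.get("Sigma_sp", 0.1 * np.eye(2)).copy()
    Psi_ph = fixed.get("Sigma_ph", 0.1 * np.eye(2)).copy()
    Sigma_e = fixed.get("Sigma_e", 0.1 * np.eye(2)).copy()
    e = np.zeros((N, 2))
    y = np.where(mask, design.y, 0.0)

    n_ret = settings.n_retained
    out_beta = np.empty((n_ret, p))
    out_sp = np.empty((n_ret, 2, 2))
    out_ph = np.empty((n_ret, 2, 2))
    out_e = np.empty((n_ret, 2, 2))
    u_accum = np.zeros((S, 2))

    # joint location block layout: [beta | eta_sp (S,2) | eta_ph (S,2)]
    dim = p + 4 * S
    sl_b = slice(0, p)
    sl_sp = slice(p, p + 2 * S)
    sl_ph = slice(p + 2 * S, dim)

    for it in range(settings.n_iter):
        u_row = (alpha_sp * eta_sp + alpha_ph * eta_ph)[sp]   # (N,2)
        mu = np.einsum("nsp,p->ns", X, beta) + u_row

        # -- impute missing responses from the conditional given the observed twin
        if has_missing:
            for m_side in (0, 1):
                o_side = 1 - m_side
                rows = miss[:, m_side]
                if not rows.any():
                    continue
                r_mo = Sigma_e[m_side, o_side]
                r_oo = Sigma_e[o_side, o_side] + D[rows, o_side]
                cond_mean = mu[rows, m_side] + r_mo / r_oo * (
                    y[rows, o_side] - mu[rows, o_side])
                cond_var = Sigma_e[m_side, m_side] + D[rows, m_side] - r_mo**2 / r_oo
                y[rows, m_side] = cond_mean + np.sqrt(cond_var) * rng.standard_normal(
                    rows.sum())

        # -- joint location update (beta, eta_sp, eta_ph) with e marginalised:
        #    per-row covariance R_i = Sigma_e + diag(se2_i)
        R = np.broadcast_to(Sigma_e, (N, 2, 2)).copy()
        R[:, 0, 0] += D[:, 0]
        R[:, 1, 1] += D[:, 1]
        Rinv = _inv2(R)

        RinvX = np.einsum("nij,njp->nip", Rinv, X)      # (N,2,p)
        XtRX = np.einsum("nip,niq->pq", RinvX, X)
        Rinv_sum = np.zeros((S, 2, 2))                  # per-species sum of Rinv
        np.add.at(Rinv_sum, sp, Rinv)
        XtRZ = np.zeros((S, 2, p))                      # per-species sum of Rinv X
        np.add.at(XtRZ, sp, RinvX)
        Rinv_y = np.einsum("nij,nj->ni", Rinv, y)
        rhs_sp = np.zeros((S, 2))
        np.add.at(rhs_sp, sp, Rinv_y)

        P = np.zeros((dim, dim))
        P[sl_b, sl_b] = XtRX + np.eye(p) / priors.beta_var
        # cross blocks: X vs species/phylo levels (scaled by working alphas)
        Zx_sp = (alpha_sp[:, None] * XtRZ).reshape(2 * S, p)
        Zx_ph = (alpha_ph[:, None] * XtRZ).reshape(2 * S, p)
        P[sl_sp, sl_b] = Zx_sp
        P[sl_b, sl_sp] = Zx_sp.T
        P[sl_ph, sl_b] = Zx_ph
        P[sl_b, sl_ph] = Zx_ph.T
        # level blocks: per-species 2x2 (Rinv_sum) scaled by alphas
        a_sp_outer = np.outer(alpha_sp, alpha_sp)
        a_ph_outer = np.outer(alpha_ph, alpha_ph)
        a_cross = np.outer(alpha_sp, alpha_ph)
        blk_sp = Rinv_sum * a_sp_outer
        blk_ph = Rinv_sum * a_ph_outer
        blk_x = Rinv_sum * a_cross
        idx = np.arange(S) * 2
        for a in range(2):
            for b_ in range(2):
                P[sl_sp, sl_sp][idx + a, idx + b_] = blk_sp[:, a, b_]
                P[sl_ph, sl_ph][idx + a, idx + b_] = blk_ph[:, a, b_]
                P[sl_sp, sl_ph][idx + a, idx + b_] = blk_x[:, a, b_]
                P[sl_ph, sl_sp][idx + b_, idx + a] = blk_x[:, a, b_]
        # prior precisions of the levels
        Psi_sp_inv = _inv2(Psi_sp)
        Psi_ph_inv = _inv2(Psi_ph)
        for a in range(2):
            for b_ in range(2):
                P[sl_sp, sl_sp][idx + a, idx + b_] += Psi_sp_inv[a, b_]
        P[sl_ph, sl_ph] += (A_inv[:, None, :, None] *
                            Psi_ph_inv[None, :, None, :]).reshape(2 * S, 2 * S)

        rhs = np.empty(dim)
        rhs[sl_b] = np.einsum("nip,ni->p", RinvX, y)
        rhs[sl_sp] = (alpha_sp * rhs_sp).reshape(-1)
        rhs[sl_ph] = (alpha_ph * rhs_sp).reshape(-1)

        L = np.linalg.cholesky(P)
        theta_hat = sla.cho_solve((L, True), rhs, check_finite=False)
        theta = theta_hat + sla.solve_triangular(
            L.T, rng.standard_normal(dim), lower=False, check_finite=False)
        beta = theta[sl_b]
        eta_sp = theta[sl_sp].reshape(S, 2)
        eta_ph = theta[sl_ph].reshape(S, 2)

        # -- residual effects e_i | completed y and locations
        u_row = (alpha_sp * eta_sp + alpha_ph * eta_ph)[sp]
        Xb = np.einsum("nsp,p->ns", X, beta)
        resid = y - Xb - u_row
        Sigma_e_inv = _inv2(Sigma_e)
        Ve_prec = np.broadcast_to(Sigma_e_inv, (N, 2, 2)).copy()
        Ve_prec[:, 0, 0] += Dinv[:, 0]
        Ve_prec[:, 1, 1] += Dinv[:, 1]
        Ve = _inv2(Ve_prec)
        e_mean = np.einsum("nij,nj->ni", Ve, Dinv * resid)
        e = _mvn2(e_mean, Ve, rng)

        # -- working scales (parameter expansion) and covariance updates
        if "Sigma_sp" not in fixed:
            w = y - Xb - (alpha_ph * eta_ph)[sp] - e
            prec_a = alpha_V_inv_diag + ((eta_sp[sp] ** 2) * Dinv).sum(axis=0)
            lin_a = (eta_sp[sp] * Dinv * w).sum(axis=0) + \
                alpha_V_inv_diag * priors.alpha_mu
            var_a = 1.0 / prec_a
            alpha_sp = var_a * lin_a + np.sqrt(var_a) * rng.standard_normal(2)
            Psi_sp = _invwishart2(S0_rand + eta_sp.T @ eta_sp,
                                  priors.nu_random + S, rng)

        if "Sigma_ph" not in fixed:
            w = y - Xb - alpha_sp * eta_sp[sp] - e
            prec_a = alpha_V_inv_diag + ((eta_ph[sp] ** 2) * Dinv).sum(axis=0)
            lin_a = (eta_ph[sp] * Dinv * w).sum(axis=0) + \
                alpha_V_inv_diag * priors.alpha_mu
            var_a = 1.0 / prec_a
            alpha_ph = var_a * lin_a + np.sqrt(var_a) * rng.standard_normal(2)
            Psi_ph = _invwishart2(S0_rand + eta_ph.T @ A_inv @ eta_ph,
                                  priors.nu_random + S, rng)

        # -- residual covariance
        if "Sigma_e" not in fixed:
            Sigma_e = _invwishart2(S0_resid + e.T @ e, priors.nu_resid + N, rng)

        k = it + 1 - settings.burn_in
        if k > 0 and k % settings.thin == 0:
            j = k // settings.thin - 1
            if j < n_ret:
                out_beta[j] = beta
                Da = np.diag(alpha_sp)
                out_sp[j] = Da @ Psi_sp @ Da if "Sigma_sp" not in fixed else Psi_sp
                Da = np.diag(alpha_ph)
                out_ph[j] = Da @ Psi_ph @ Da if "Sigma_ph" not in fixed else Psi_ph
                out_e[j] = Sigma_e
                u_accum += alpha_sp * eta_sp + alpha_ph * eta_ph

    n_eff = int(design.mask.sum())
    return PosteriorDraws(
        beta=out_beta,
        colnames=list(design.colnames),
        Sigma_sp=out_sp,
        Sigma_ph=out_ph,
        Sigma_e=out_e,
        tree_ids=np.array([tree_id] * n_ret),
        species=list(design.species),
        u_mean=u_accum / max(n_ret, 1),
        n_effects=n_eff,
        n_species=S,
    )


def fit_model(
    dataset: AnalysisDataset,
    trees: Sequence,
    spec: ModelSpec,
    priors: Priors = Priors(),
    settings: MCMCSettings = MCMCSettings(),
    seed: int = 0,
    aliases: Optional[dict] = None,
    fixed: Optional[dict] = None,
) -> PosteriorDraws:
    """Fit one model over a set of trees and pool the posteriors.

    One chain per tree, seeded ``seed + tree_index`` so the pooled sample is
    reproducible and per-draw provenance is retained.
    """
    design = build_design(dataset, spec)
    per_tree = []
    for j, tree in enumerate(trees[: settings.n_trees or len(trees)]):
        if isinstance(tree, PhyloCorrelation):
            A = tree
        else:
            A = correlation_from_tree(tree, design.species, aliases=aliases,
                                      tree_id=str(j))
        per_tree.append(
            gibbs_sample(design, A, priors, settings, seed=seed + j,
                         tree_id=str(j), fixed=fixed)
        )
    return pool_over_trees(per_tree)


def sensitivity_refit(
    dataset: AnalysisDataset,
    exclusions: Sequence[tuple],
    trees: Sequence,
    spec: ModelSpec,
    priors: Priors = Priors(),
    settings: MCMCSettings = MCMCSettings(),
    seed: int = 0,
) -> dict:
    """Refit after excluding rows by (species, ornament_id); returns both fits.

    Used for outlier checks such as dropping a single highly dimorphic
    ornament and comparing the moderator estimate before/after.
    """
    excl = {(s, str(o)) for s, o in exclusions}
    reduced = dataset.subset(lambda pe: (pe.species, str(pe.ornament_id)) not in excl)
    if len(reduced.effects) == 0:
        raise ValueError("exclusion list removes every row")
    full_fit = fit_model(dataset, trees, spec, priors, settings, seed)
    red_fit = fit_model(reduced, trees, spec, priors, settings, seed)
    return {
        "full": full_fit,
        "reduced": red_fit,
        "n_full": full_fit.n_effects,
        "n_reduced": red_fit.n_effects,
    }
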