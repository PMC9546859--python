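"""Seeded synthetic datasets with the structure the bivariate model assumes.

The generator emulates a comparative meta-analytic dataset of paired
female/male ornament effect sizes: per-species bivariate deviations that are
phylogenetically correlated (Sigma_ph through a tree correlation matrix A)
and independent (Sigma_sp), a bivariate residual per association (Sigma_e),
known Fisher-Zr sampling error 1/(n-3), categorical moderators with
realistic proportions, a mean-centred publication-year trend, an optional
sexual-dimorphism moderator, and a missingness pattern that leaves a chosen
number of associations observed in one sex only.

Defaults mirror the scale of the empirical study the model targets:
64 species, 746 associations (235 paired + 511 single-sex = 981 effects,
470 of them in pairs), sex means 0.19/0.22, a publication-year slope of
-0.006, small phylogenetic/species variances and a dominant residual
variance.  Optional switches inject funnel asymmetry (small-study
suppression of negative effects) so the bias detectors have a known signal
to find.

Everything is driven by one ``numpy`` Generator, so a fixed seed yields a
byte-identical CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .phylo import PhyloCorrelation, correlation_from_tree
import dendropy

__all__ = ["SimConfig", "SimTruth", "simulate_tree", "simulate_dataset",
           "inject_publication_bias"]


ORNAMENT_TYPE_PROBS = {
    "carotenoid": 285, "melanin": 188, "structural": 148,
    "morphological": 129, "unpigmented": 118, "other": 113,
}
CONDITION_SUBCATS = ["body_condition", "body_size", "immunity", "stress",
                     "environment", "parasites"]
FITNESS_SUBCATS = ["reproductive_success", "offspring_quality",
                   "parental_quality", "timing_of_breeding", "survival"]


def _cov(var_f: float, var_m: float, r: float) -> np.ndarray:
    c = r * np.sqrt(var_f * var_m)
    return np.array([[var_f, c], [c, var_m]])


@dataclass
class SimConfig:
    """Generating parameters; defaults are the emulated study conditions."""

    n_species: int = 64
    n_rows: int = 746          # associations (bivariate rows)
    paired_rows: int = 235     # rows observed in both sexes
    beta_f: float = 0.19
    beta_m: float = 0.22
    # additive true-mean offsets per domain, (female, male)
    domain_offsets: dict = field(default_factory=lambda: {
        "condition": (0.04, 0.04), "fitness": (-0.05, -0.06)})
    year_slope: float = -0.006
    year_range: tuple = (1987, 2019)
    Sigma_ph: np.ndarray = field(default_factory=lambda: _cov(0.015, 0.015, 0.3))
    Sigma_sp: np.ndarray = field(default_factory=lambda: _cov(0.008, 0.008, 0.3))
    Sigma_e: np.ndarray = field(default_factory=lambda: _cov(0.135, 0.135, 0.3))
    # per-effect sample sizes: lognormal, clipped
    n_log_mean: float = 3.7
    n_log_sd: float = 0.6
    n_min: int = 10
    n_max: int = 200
    condition_fraction: float = 421 / 981
    dimorphism_fraction: float = 0.6   # fraction of paired ornaments with a d score
    dimorphism_mean: float = 0.69
    dimorphism_sd: float = 1.0
    dimorphism_slope: float = 0.0      # true sex-by-dimorphism interaction
    funnel_severity: float = 0.0
    mnar_missingness: bool = False     # drop the weaker (not a random) side
    n_trees: int = 1
    tree_jitter: float = 0.1           # branch-length log-sd for extra trees
    seed: int = 0

    @property
    def fraction_paired(self) -> float:
        """Fraction of single-sex effects that belong to a pair."""
        return 2 * self.paired_rows / (self.n_rows + self.paired_rows)

    def validate(self) -> None:
        for name in ("Sigma_ph", "Sigma_sp", "Sigma_e"):
            M = np.asarray(getattr(self, name))
            if np.linalg.eigvalsh(M).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        if not 0 <= self.paired_rows <= self.n_rows:
            raise ValueError("paired_rows must be in [0, n_rows]")
        if not 0.0 <= self.funnel_severity <= 1.0:
            raise ValueError("funnel_severity must be in [0, 1]")


@dataclass
class SimTruth:
    """Everything needed for parameter-recovery checks."""

    config: SimConfig
    species: list
    u_ph: np.ndarray   # (S, 2) realised phylogenetic deviations
    u_sp: np.ndarray   # (S, 2) realised species deviations
    true_means: dict   # per (sex, domain) true cell mean
    row_mu: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    # per-association realised mean (incl. species, phylo and residual parts),
    # indexed like the generated rows; observed zr = row_mu + known noise

    def to_json(self) -> str:
        d = asdict(self.config)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps({
            "config": d,
            "species": self.species,
            "u_ph": self.u_ph.tolist(),
            "u_sp": self.u_sp.tolist(),
            "row_mu": np.asarray(self.row_mu).round(8).tolist(),
            "true_means": {f"{s}:{dom}": m for (s, dom), m in self.true_means.items()},
        }, indent=2)


def simulate_tree(n_species: int, seed_or_rng=0) -> str:
    """Random ultrametric tree (Newick, unit height) by sequential pair joins.

    Lineages are merged two at a time at exponentially increasing depths —
    a Yule-shaped topology — then node ages are rescaled so every
    root-to-tip path has length 1.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    labels = [f"sp{i:03d}" for i in range(n_species)]
    nodes = [(lab, 0.0) for lab in labels]  # (newick fragment, age)
    age = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        age += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, aa), (nb, ab) = nodes[i], nodes[j]
        merged = (f"({na}:{age - aa:.10f},{nb}:{age - ab:.10f})", age)
        nodes = [nodes[m] for m in range(k) if m not in (i, j)] + [merged]
    newick, root_age = nodes[0]
    # rescale to unit height by rewriting branch lengths
    tree = dendropy.Tree.get(data=newick + ";", schema="newick",
                             preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / root_age
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def _jitter_tree(newick: str, log_sd: float, rng: np.random.Generator) -> str:
    """Branch-length jittered copy (emulates posterior tree uncertainty)."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * float(np.exp(rng.normal(0.0, log_sd)))
    # renormalise to unit mean tip height
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    h = float(np.mean(depths))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / h
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, list, SimTruth]:
    """Generate (effects table, Newick trees, truth record).

    The effects table has one row per single-sex effect in the prepared-
    dataset schema consumed by :func:`ornmeta.dataset.build_dataset`
    (columns study_id, species, sex, ornament_id, ornament_type, domain,
    subcategory, parameter, zr, se, n, publication_year, study_design,
    dimorphism columns via the companion table in ``attrs``).
    """
    config.validate()
    # independent streams: the missingness pattern must not perturb the
    # structural draws, so changing paired_rows keeps the same effects
    ss = np.random.SeedSequence(config.seed)
    rng, rng_miss, rng_bias = (np.random.default_rng(c) for c in ss.spawn(3))
    S, R = config.n_species, config.n_rows

    trees = [simulate_tree(S, rng)]
    for _ in range(config.n_trees - 1):
        trees.append(_jitter_tree(trees[0], config.tree_jitter, rng))

    species = [f"sp{i:03d}" for i in range(S)]
    base = dendropy.Tree.get(data=trees[0], schema="newick", preserve_underscores=True)
    A = correlation_from_tree(base, species, tree_id="generating").A

    # species-level deviations: matrix-normal draws
    L_A = np.linalg.cholesky(A + 1e-12 * np.eye(S))
    L_ph = np.linalg.cholesky(np.asarray(config.Sigma_ph))
    L_sp = np.linalg.cholesky(np.asarray(config.Sigma_sp))
    u_ph = L_A @ rng.standard_normal((S, 2)) @ L_ph.T
    u_sp = rng.standard_normal((S, 2)) @ L_sp.T

    # rows per species: guaranteed >= 1, skewed across species
    weights = rng.dirichlet(np.full(S, 0.5))
    extra = rng.multinomial(R - S, weights)
    rows_per_species = 1 + extra
    sp_of_row = np.repeat(np.arange(S), rows_per_species)

    otypes = list(ORNAMENT_TYPE_PROBS)
    oprobs = np.array(list(ORNAMENT_TYPE_PROBS.values()), dtype=float)
    oprobs /= oprobs.sum()

    L_e = np.linalg.cholesky(np.asarray(config.Sigma_e))
    e = rng.standard_normal((R, 2)) @ L_e.T

    is_cond = rng.random(R) < config.condition_fraction
    years = rng.integers(config.year_range[0], config.year_range[1] + 1, size=R)
    year_c = years - years.mean()
    otype_of_row = rng.choice(len(otypes), size=R, p=oprobs)
    subcat = [
        (CONDITION_SUBCATS if c else FITNESS_SUBCATS)[
            rng.integers(0, 6 if c else 5)]
        for c in is_cond
    ]
    # which rows carry a dimorphism score, and its value
    has_d = rng.random(R) < config.dimorphism_fraction
    d_vals = rng.normal(config.dimorphism_mean, config.dimorphism_sd, size=R)

    # paired rows: choose exactly `paired_rows` of them
    paired = np.zeros(R, dtype=bool)
    paired[rng_miss.choice(R, size=config.paired_rows, replace=False)] = True

    ns = np.clip(
        np.exp(rng.normal(config.n_log_mean, config.n_log_sd, size=(R, 2))),
        config.n_min, config.n_max).astype(int)

    true_means = {}
    rows = []
    truth_mu = np.empty((R, 2))
    for i in range(R):
        dom = "condition" if is_cond[i] else "fitness"
        off_f, off_m = config.domain_offsets.get(dom, (0.0, 0.0))
        d_term_m = config.dimorphism_slope * d_vals[i] if has_d[i] else 0.0
        mu_f = config.beta_f + off_f + config.year_slope * year_c[i]
        mu_m = config.beta_m + off_m + config.year_slope * year_c[i] + d_term_m
        s = sp_of_row[i]
        truth_mu[i] = (mu_f + u_ph[s, 0] + u_sp[s, 0] + e[i, 0],
                       mu_m + u_ph[s, 1] + u_sp[s, 1] + e[i, 1])
        true_means[("female", dom)] = config.beta_f + off_f
        true_means[("male", dom)] = config.beta_m + off_m

    se = 1.0 / np.sqrt(ns - 3)
    zr_obs = truth_mu + se * rng.standard_normal((R, 2))

    # missingness: unpaired rows keep exactly one sex
    keep = np.ones((R, 2), dtype=bool)
    unpaired_idx = np.flatnonzero(~paired)
    if config.mnar_missingness:
        drop_side = np.argmin(np.abs(zr_obs[unpaired_idx]), axis=1)
    else:
        drop_side = rng_miss.integers(0, 2, size=unpaired_idx.size)
    keep[unpaired_idx, drop_side] = False

    dim_table = []
    for i in range(R):
        s = sp_of_row[i]
        study = f"study_{species[s]}"
        orn = f"orn_{i:04d}"
        if has_d[i]:
            dim_table.append({"species": species[s], "ornament_id": orn,
                              "cohens_d": round(float(d_vals[i]), 6)})
        for sex_idx, sex in ((0, "female"), (1, "male")):
            if not keep[i, sex_idx]:
                continue
            rows.append({
                "study_id": study,
                "species": species[s],
                "sex": sex,
                "ornament_id": orn,
                "ornament_type": otypes[otype_of_row[i]],
                "domain": "condition" if is_cond[i] else "fitness",
                "subcategory": subcat[i],
                "parameter": f"param_{i:04d}",
                "zr": round(float(zr_obs[i, sex_idx]), 8),
                "se": round(float(se[i, sex_idx]), 8),
                "n": int(ns[i, sex_idx]),
                "publication_year": int(years[i]),
                "study_design": "correlational",
            })

    df = pd.DataFrame(rows)
    if config.funnel_severity > 0:
        df = inject_publication_bias(df, config.funnel_severity, rng=rng_bias)
    df.attrs["dimorphism"] = pd.DataFrame(dim_table)
    truth = SimTruth(config=config, species=species, u_ph=u_ph, u_sp=u_sp,
                     true_means=true_means, row_mu=truth_mu)
    return df, trees, truth


def inject_publication_bias(
    df: pd.DataFrame, severity: float, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Suppress negative low-powered effects with probability ``severity``.

    "Low-powered" means sample size below the table's median — the
    small-study suppression that produces a one-sided funnel plot.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    if severity == 0.0:
        return df.copy()
    rng = rng or np.random.default_rng(0)
    small = df["n"] < df["n"].median()
    at_risk = (df["zr"] < 0) & small
    drop = at_risk & (rng.random(len(df)) < severity)
    out = df.loc[~drop].reset_index(drop=True)
    out.attrs.update(df.attrs)
    return out


def write_simulation(df: pd.DataFrame, trees: list, truth: SimTruth,
                     csv_path, trees_path, truth_path) -> None:
    """Write dataset CSV, multi-Newick tree file and truth JSON."""
    df.to_csv(csv_path, index=False)
    with open(trees_path, "w") as fh:
        fh.write("\n".join(trees) + "\n")
    with open(truth_path, "w") as fh:
        fh.write(truth.to_json())
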