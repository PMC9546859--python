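"""Conversion of published test statistics into correlation-scale effect sizes.

Meta-analyses of ornament–quality associations must pool results reported
as *F*, chi-square, *t*, *z*, Mann–Whitney *U*, R², raw correlations, or
comparisons between group means.  Every statistic is first converted to a
signed correlation coefficient *r*, then to Fisher's Zr = atanh(r) with
sampling variance 1/(n − 3).  Sexual-dimorphism contrasts are expressed as
Cohen's *d* (positive = male-biased ornamentation) instead.

Sign conventions
----------------
Positive Zr always means "more ornamented individuals have better condition
or higher fitness".  Magnitude-only statistics (F, chi-square, U, R²) take
their sign from the reported direction of the association.  Parameters whose
raw scale runs opposite to quality — parasite loads, physiological stress,
and timing of breeding (earlier breeders do better) — have their signs
flipped by :func:`apply_sign_policy`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatKind",
    "Direction",
    "Sex",
    "OrnamentType",
    "Domain",
    "Subcategory",
    "RawStatistic",
    "EffectRecord",
    "DimorphismRecord",
    "ConversionError",
    "DegenerateStatisticError",
    "r_from_stat",
    "zr_from_r",
    "apply_sign_policy",
    "d_from_summary",
    "r_from_d",
    "welch_t_from_summary",
    "convert_table",
    "SIGN_REVERSED_SUBCATEGORIES",
]


class ConversionError(ValueError):
    """Raised when a raw statistic cannot be converted (missing df/n, bad domain)."""


class DegenerateStatisticError(ConversionError):
    """Raised when a conversion lands on |r| >= 1 or a zero-variance summary."""


class StatKind(str, enum.Enum):
    F = "F"
    CHI2 = "chi2"
    T = "t"
    Z = "z"
    U = "U"
    R = "r"
    R2 = "R2"
    MEANS_COMPARISON = "means_comparison"


class Direction(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class OrnamentType(str, enum.Enum):
    CAROTENOID = "carotenoid"
    MELANIN = "melanin"
    STRUCTURAL = "structural"
    UNPIGMENTED = "unpigmented"
    MORPHOLOGICAL = "morphological"
    OTHER = "other"


class Domain(str, enum.Enum):
    CONDITION = "condition"
    FITNESS = "fitness"


class Subcategory(str, enum.Enum):
    # condition
    BODY_CONDITION = "body_condition"
    BODY_SIZE = "body_size"
    IMMUNITY = "immunity"
    STRESS = "stress"
    ENVIRONMENT = "environment"
    PARASITES = "parasites"
    # fitness
    REPRODUCTIVE_SUCCESS = "reproductive_success"
    OFFSPRING_QUALITY = "offspring_quality"
    PARENTAL_QUALITY = "parental_quality"
    TIMING_OF_BREEDING = "timing_of_breeding"
    SURVIVAL = "survival"


CONDITION_SUBCATEGORIES = frozenset(
    {
        Subcategory.BODY_CONDITION,
        Subcategory.BODY_SIZE,
        Subcategory.IMMUNITY,
        Subcategory.STRESS,
        Subcategory.ENVIRONMENT,
        Subcategory.PARASITES,
    }
)
FITNESS_SUBCATEGORIES = frozenset(
    {
        Subcategory.REPRODUCTIVE_SUCCESS,
        Subcategory.OFFSPRING_QUALITY,
        Subcategory.PARENTAL_QUALITY,
        Subcategory.TIMING_OF_BREEDING,
        Subcategory.SURVIVAL,
    }
)

#: Subcategories whose raw scale runs opposite to individual quality.
SIGN_REVERSED_SUBCATEGORIES = frozenset(
    {Subcategory.PARASITES, Subcategory.STRESS, Subcategory.TIMING_OF_BREEDING}
)

# |r| this close to 1 is clipped rather than rejected (avoids silent infinities
# from rounded published statistics); anything further out is an error.
_CLIP_TOL = 1e-9
_CLIP_VALUE = 0.999999


@dataclass(frozen=True)
class RawStatistic:
    """A raw published test statistic plus the metadata needed to convert it.

    ``direction`` is the reported direction of the ornament–parameter
    association; it supplies the sign for magnitude-only statistics
    (F, chi-square, U, R²).  ``n_total`` is the total sample size behind the
    statistic.  ``m1/s1/m2/s2`` are only used for ``means_comparison``.
    """

    kind: StatKind
    value: float = math.nan
    df1: Optional[float] = None
    df2: Optional[float] = None
    n1: Optional[int] = None
    n2: Optional[int] = None
    n_total: int = 0
    direction: Optional[Direction] = None
    m1: Optional[float] = None
    s1: Optional[float] = None
    m2: Optional[float] = None
    s2: Optional[float] = None


@dataclass
class EffectRecord:
    """One published association on the Fisher-Zr scale, with metadata."""

    study_id: str
    species: str
    sex: Sex
    ornament_id: str
    ornament_type: OrnamentType
    domain: Domain
    subcategory: Subcategory
    parameter: str
    zr: float
    se: float
    n: int
    publication_year: int
    study_design: str = "correlational"

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.ornament_type = OrnamentType(self.ornament_type)
        self.domain = Domain(self.domain)
        self.subcategory = Subcategory(self.subcategory)
        if self.se <= 0:
            raise ValueError(f"se must be positive, got {self.se}")
        ok = (
            self.subcategory in CONDITION_SUBCATEGORIES
            if self.domain is Domain.CONDITION
            else self.subcategory in FITNESS_SUBCATEGORIES
        )
        if not ok:
            raise ValueError(
                f"subcategory {self.subcategory.value!r} inconsistent with "
                f"domain {self.domain.value!r}"
            )


@dataclass
class DimorphismRecord:
    """Sexual dimorphism of one ornament as Cohen's d (positive = male-biased)."""

    species: str
    ornament_id: str
    cohens_d: float
    var_d: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.var_d <= 0:
            raise ValueError(f"var_d must be positive, got {self.var_d}")


def _signed(magnitude: float, direction: Optional[Direction], kind: StatKind) -> float:
    if direction is None:
        raise ConversionError(
            f"{kind.value} is magnitude-only: a reported direction is required"
        )
    return magnitude if Direction(direction) is Direction.POSITIVE else -magnitude


def _check_r(r: float) -> float:
    if abs(r) >= 1.0:
        if abs(r) - 1.0 < _CLIP_TOL:
            return math.copysign(_CLIP_VALUE, r)
        raise DegenerateStatisticError(f"conversion produced |r| >= 1 (r={r})")
    return r


def r_from_stat(stat: RawStatistic) -> float:
    """Convert a raw statistic to a signed correlation coefficient in (−1, 1).

    t and z (and r itself) carry their own sign; F, chi-square, U and R² are
    magnitude-only and take the sign of ``stat.direction``.  Chi-square and F
    are only convertible for 1 numerator degree of freedom (a multi-df
    statistic has no single underlying contrast).  Mann–Whitney U goes through
    the large-sample normal approximation (no continuity correction) and then
    r = z/sqrt(n); comparisons between means go through Cohen's d with the
    unequal-n correction.
    """
    kind = StatKind(stat.kind)

    if kind is StatKind.T:
        if stat.df2 is None or stat.df2 <= 0:
            raise ConversionError("t requires df2 > 0")
        r = stat.value / math.sqrt(stat.value**2 + stat.df2)
    elif kind is StatKind.Z:
        if stat.n_total <= 0:
            raise ConversionError("z requires n_total > 0")
        r = stat.value / math.sqrt(stat.n_total)
    elif kind is StatKind.F:
        if stat.df2 is None or stat.df2 <= 0:
            raise ConversionError("F requires df2 > 0")
        if stat.df1 is not None and stat.df1 != 1:
            raise ConversionError(
                f"F with df1={stat.df1} cannot be converted to a single r; "
                "only df1=1 statistics are accepted"
            )
        if stat.value < 0:
            raise ConversionError("F must be non-negative")
        r = _signed(math.sqrt(stat.value / (stat.value + stat.df2)), stat.direction, kind)
    elif kind is StatKind.CHI2:
        if stat.df1 is not None and stat.df1 != 1:
            raise ConversionError(
                f"chi2 with df={stat.df1} cannot be converted to a single r; "
                "only df=1 statistics are accepted"
            )
        if stat.n_total <= 0:
            raise ConversionError("chi2 requires n_total > 0")
        if stat.value < 0:
            raise ConversionError("chi2 must be non-negative")
        r = _signed(math.sqrt(stat.value / stat.n_total), stat.direction, kind)
    elif kind is StatKind.U:
        if not stat.n1 or not stat.n2:
            raise ConversionError("U requires group sizes n1 and n2")
        n1, n2 = stat.n1, stat.n2
        n = stat.n_total or (n1 + n2)
        mu = n1 * n2 / 2.0
        sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = abs(stat.value - mu) / sd
        r = _signed(z / math.sqrt(n), stat.direction, kind)
    elif kind is StatKind.R:
        r = stat.value
    elif kind is StatKind.R2:
        if stat.value < 0 or stat.value > 1:
            raise ConversionError("R2 must lie in [0, 1]")
        r = _signed(math.sqrt(stat.value), stat.direction, kind)
    elif kind is StatKind.MEANS_COMPARISON:
        if None in (stat.m1, stat.s1, stat.m2, stat.s2) or not stat.n1 or not stat.n2:
            raise ConversionError("means_comparison requires m1, s1, m2, s2, n1, n2")
        d, _ = d_from_summary(stat.m1, stat.s1, stat.n1, stat.m2, stat.s2, stat.n2)
        r = r_from_d(d, stat.n1, stat.n2)
        if stat.direction is not None:
            r = _signed(abs(r), stat.direction, kind) if d != 0 else 0.0
    else:  # pragma: no cover - enum is exhaustive
        raise ConversionError(f"unknown statistic kind {stat.kind!r}")

    return _check_r(r)


def zr_from_r(r: float, n: int) -> tuple[float, float]:
    """Fisher's Zr = atanh(r) and its standard error 1/sqrt(n − 3)."""
    if n < 4:
        raise ConversionError(f"n must be >= 4 for SE = 1/sqrt(n-3); got n={n}")
    if abs(r) >= 1.0:
        r = _check_r(r)
    return math.atanh(r), 1.0 / math.sqrt(n - 3)


def apply_sign_policy(zr: float, subcategory: Subcategory | str) -> float:
    """Flip the sign for parasites, stress and timing-of-breeding effects.

    Higher parasite load / stress means worse condition and later breeding
    means lower reproductive success, so these categories are negated to keep
    "positive Zr = more ornamented, higher quality" uniform.
    """
    sub = Subcategory(subcategory)
    return -zr if sub in SIGN_REVERSED_SUBCATEGORIES else zr


def d_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Cohen's d from two group summaries, with its sampling variance.

    d = (m1 − m2)/s_pooled;  var(d) = (n1+n2)/(n1 n2) + d²/(2(n1+n2)).
    Convention here: group 1 = males, group 2 = females, so positive d means
    the male trait is larger (male-biased dimorphism).
    """
    if n1 < 2 or n2 < 2:
        raise ConversionError("d_from_summary requires n1, n2 >= 2")
    if s1 < 0 or s2 < 0:
        raise ConversionError("standard deviations must be non-negative")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise DegenerateStatisticError("both group SDs are zero")
    d = (m1 - m2) / math.sqrt(sp2)
    var_d = (n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))
    return d, var_d


def r_from_d(d: float, n1: int, n2: int) -> float:
    """Point-biserial r from Cohen's d with the unequal-n correction a = (n1+n2)²/(n1 n2)."""
    a = (n1 + n2) ** 2 / (n1 * n2)
    return d / math.sqrt(d**2 + a)


def welch_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from group summaries.

    Returns (t, Welch–Satterthwaite df, two-sided p).  Used when only figure-
    extracted means, dispersions and sample sizes are available for a
    male/female trait comparison.
    """
    if n1 < 2 or n2 < 2:
        raise ConversionError("welch_t_from_summary requires n1, n2 >= 2")
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        raise DegenerateStatisticError("zero variance in both groups")
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


# ---------------------------------------------------------------------------
# Table-level conversion

#: Columns expected in a raw-statistics CSV (one row per extracted statistic).
RAW_TABLE_COLUMNS = [
    "study_id", "species", "sex", "ornament_id", "ornament_type", "domain",
    "subcategory", "parameter", "stat_kind", "stat_value", "df1", "df2",
    "n1", "n2", "n_total", "direction", "m1", "s1", "m2", "s2",
    "publication_year", "study_design",
]


def convert_table(raw: pd.DataFrame, apply_signs: bool = True) -> pd.DataFrame:
    """Convert a raw-statistics table into an effect-size table.

    Each row of ``raw`` (columns as in :data:`RAW_TABLE_COLUMNS`) is pushed
    through statistic → r → Zr; rows that cannot be converted are returned in
    a ``rejected`` column of diagnostics rather than raised, so a whole
    extraction sheet can be processed in one pass.

    Returns a DataFrame with the metadata columns plus ``r``, ``zr``, ``se``
    and ``n``; the attribute ``result.attrs["rejected"]`` holds a list of
    (row index, reason) pairs.  ``U``-statistic rows are flagged in a
    ``conversion_note`` column with the normal-approximation convention used.
    """
    out_rows = []
    rejected: list[tuple[int, str]] = []
    for idx, row in raw.iterrows():
        try:
            def opt(col, cast=float):
                v = row.get(col)
                if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                    return None
                return cast(v)

            stat = RawStatistic(
                kind=StatKind(row["stat_kind"]),
                value=float(row["stat_value"]) if opt("stat_value") is not None else math.nan,
                df1=opt("df1"), df2=opt("df2"),
                n1=opt("n1", int), n2=opt("n2", int),
                n_total=int(row["n_total"]),
                direction=Direction(row["direction"]) if opt("direction", str) else None,
                m1=opt("m1"), s1=opt("s1"), m2=opt("m2"), s2=opt("s2"),
            )
            r = r_from_stat(stat)
            zr, se = zr_from_r(r, stat.n_total)
            if apply_signs:
                zr = apply_sign_policy(zr, row["subcategory"])
            note = (
                "U->z normal approximation, no tie or continuity correction"
                if stat.kind is StatKind.U
                else ""
            )
            out_rows.append(
                {
                    "study_id": row["study_id"],
                    "species": row["species"],
                    "sex": row["sex"],
                    "ornament_id": row["ornament_id"],
                    "ornament_type": row["ornament_type"],
                    "domain": row["domain"],
                    "subcategory": row["subcategory"],
                    "parameter": row["parameter"],
                    "r": r,
                    "zr": zr,
                    "se": se,
                    "n": stat.n_total,
                    "publication_year": int(row["publication_year"]),
                    "study_design": row.get("study_design", "correlational"),
                    "conversion_note": note,
                }
            )
        except (ConversionError, ValueError, KeyError) as exc:
            rejected.append((idx, str(exc)))
    result = pd.DataFrame(out_rows)
    result.attrs["rejected"] = rejected
    return result
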