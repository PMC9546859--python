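"""Assembly of the bivariate analysis table.

Female and male effects measured for the same ornament and the same
condition/fitness parameter are merged into one paired observation; effects
with no opposite-sex twin remain in the table with one response missing.
Because the bivariate model requires a sampling variance for both responses
of every row, a missing side inherits the available side's SE² (uncertainty
augmentation) — the missing response itself is later imputed by the sampler.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .effect_sizes import EffectRecord, Sex

__all__ = [
    "PairedEffect",
    "AnalysisDataset",
    "DuplicateKeyError",
    "pair_effects",
    "augment_missing_uncertainty",
    "centre_year",
    "summarize_counts",
    "build_dataset",
    "normalize_species",
    "records_from_frame",
]


class DuplicateKeyError(ValueError):
    """Two same-sex effects share an identical pairing key."""


#: Fields that identify "the same association measured in both sexes".
PAIR_KEY_FIELDS = ("study_id", "species", "ornament_id", "domain", "subcategory", "parameter")


def normalize_species(name: str) -> str:
    """Canonical underscore-separated binomial ('Lagopus lagopus' -> 'Lagopus_lagopus')."""
    return "_".join(str(name).strip().split())


@dataclass
class PairedEffect:
    """One bivariate observation: the female and male Zr for one association.

    Either ``zr_f`` or ``zr_m`` may be ``None`` (unpaired data); after
    :func:`augment_missing_uncertainty` both SE² fields are always present.
    """

    study_id: str
    species: str
    ornament_id: str
    ornament_type: str
    domain: str
    subcategory: str
    parameter: str
    zr_f: Optional[float] = None
    se2_f: Optional[float] = None
    n_f: Optional[int] = None
    zr_m: Optional[float] = None
    se2_m: Optional[float] = None
    n_m: Optional[int] = None
    publication_year: Optional[int] = None
    publication_year_centred: Optional[float] = None
    dimorphism_d: Optional[float] = None
    study_design: str = "correlational"

    @property
    def is_paired(self) -> bool:
        return self.zr_f is not None and self.zr_m is not None

    @property
    def n_effects(self) -> int:
        return int(self.zr_f is not None) + int(self.zr_m is not None)


@dataclass
class AnalysisDataset:
    """The analysis-ready table plus bookkeeping counts."""

    effects: list[PairedEffect]
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            self.species = sorted({pe.species for pe in self.effects})

    @property
    def counts(self) -> dict:
        n_paired = sum(2 for pe in self.effects if pe.is_paired)
        n_effects = sum(pe.n_effects for pe in self.effects)
        return {
            "n_effects": n_effects,
            "n_paired": n_paired,
            "n_unpaired": n_effects - n_paired,
            "n_rows": len(self.effects),
            "n_species": len(self.species),
            "n_studies": len({pe.study_id for pe in self.effects}),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(pe) for pe in self.effects])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnalysisDataset":
        cols = {f for f in PairedEffect.__dataclass_fields__}
        records = []
        for _, row in df.iterrows():
            kw = {k: (None if pd.isna(v) else v) for k, v in row.items() if k in cols}
            for int_col in ("n_f", "n_m", "publication_year"):
                if kw.get(int_col) is not None:
                    kw[int_col] = int(kw[int_col])
            records.append(PairedEffect(**kw))
        return cls(records)

    def subset(self, keep) -> "AnalysisDataset":
        """New dataset from rows where ``keep(pe)`` is true."""
        return AnalysisDataset([pe for pe in self.effects if keep(pe)])


def records_from_frame(df: pd.DataFrame) -> list[EffectRecord]:
    """Validated :class:`EffectRecord` list from an effect-size table."""
    records = []
    for _, row in df.iterrows():
        records.append(
            EffectRecord(
                study_id=str(row["study_id"]),
                species=normalize_species(row["species"]),
                sex=row["sex"],
                ornament_id=str(row["ornament_id"]),
                ornament_type=row["ornament_type"],
                domain=row["domain"],
                subcategory=row["subcategory"],
                parameter=str(row["parameter"]),
                zr=float(row["zr"]),
                se=float(row["se"]),
                n=int(row["n"]),
                publication_year=int(row["publication_year"]),
                study_design=str(row.get("study_design", "correlational")),
            )
        )
    return records


def pair_effects(
    records: Sequence[EffectRecord],
    cross_study_overrides: Optional[dict[str, str]] = None,
) -> list[PairedEffect]:
    """Merge opposite-sex effects sharing a pairing key into bivariate rows.

    The key is (study, species, ornament, domain, subcategory, verbatim
    parameter label); matching is exact and deterministic.  The total number
    of single-sex effects is conserved: every record lands in exactly one
    :class:`PairedEffect`, alone or with its twin.

    ``cross_study_overrides`` maps study_id -> study_id for the rare case of
    a pair assembled from two studies of the same population; both studies
    are keyed under the target id for pairing (the original id is kept on
    the row).
    """
    overrides = cross_study_overrides or {}
    buckets: dict[tuple, dict[Sex, EffectRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        study_key = overrides.get(rec.study_id, rec.study_id)
        key = (study_key, rec.species, rec.ornament_id, rec.domain.value,
               rec.subcategory.value, rec.parameter)
        if key not in buckets:
            buckets[key] = {}
            order.append(key)
        if rec.sex in buckets[key]:
            raise DuplicateKeyError(
                f"two {rec.sex.value} effects share pairing key {key!r}"
            )
        buckets[key][rec.sex] = rec

    paired = []
    for key in order:
        pair = buckets[key]
        f, m = pair.get(Sex.FEMALE), pair.get(Sex.MALE)
        ref = f or m
        paired.append(
            PairedEffect(
                study_id=ref.study_id,
                species=ref.species,
                ornament_id=ref.ornament_id,
                ornament_type=ref.ornament_type.value,
                domain=ref.domain.value,
                subcategory=ref.subcategory.value,
                parameter=ref.parameter,
                zr_f=f.zr if f else None,
                se2_f=f.se**2 if f else None,
                n_f=f.n if f else None,
                zr_m=m.zr if m else None,
                se2_m=m.se**2 if m else None,
                n_m=m.n if m else None,
                publication_year=ref.publication_year,
                study_design=ref.study_design,
            )
        )
    return paired


def augment_missing_uncertainty(pe: PairedEffect) -> PairedEffect:
    """Give a missing side the available side's SE² (idempotent; new object)."""
    if pe.se2_f is None and pe.se2_m is None:
        raise ValueError("both sides missing: no uncertainty to propagate")
    se2_f = pe.se2_f if pe.se2_f is not None else pe.se2_m
    se2_m = pe.se2_m if pe.se2_m is not None else pe.se2_f
    return replace(pe, se2_f=se2_f, se2_m=se2_m)


def centre_year(dataset: AnalysisDataset) -> AnalysisDataset:
    """Mean-centre publication year over single-sex effects (paired rows count twice)."""
    years, weights = [], []
    for pe in dataset.effects:
        if pe.publication_year is None:
            raise ValueError(f"missing publication year on {pe.study_id}")
        years.append(pe.publication_year)
        weights.append(pe.n_effects)
    mean = float(np.average(years, weights=weights))
    out = [replace(pe, publication_year_centred=pe.publication_year - mean)
           for pe in dataset.effects]
    return AnalysisDataset(out, species=dataset.species)


def summarize_counts(dataset: AnalysisDataset) -> dict:
    """Effect counts by sex, ornament type, domain and subcategory.

    Counts are of single-sex effects (a fully paired row contributes one
    female and one male effect), so every partition sums to ``n_effects``.
    """
    by_sex = Counter()
    by_type = Counter()
    by_domain = Counter()
    by_subcategory = Counter()
    for pe in dataset.effects:
        k = pe.n_effects
        if pe.zr_f is not None:
            by_sex["female"] += 1
        if pe.zr_m is not None:
            by_sex["male"] += 1
        by_type[pe.ornament_type] += k
        by_domain[pe.domain] += k
        by_subcategory[pe.subcategory] += k
    return {
        **dataset.counts,
        "by_sex": dict(by_sex),
        "by_ornament_type": dict(by_type),
        "by_domain": dict(by_domain),
        "by_subcategory": dict(by_subcategory),
    }


def build_dataset(
    effects_frame: pd.DataFrame,
    dimorphism: Optional[pd.DataFrame] = None,
    cross_study_overrides: Optional[dict[str, str]] = None,
) -> AnalysisDataset:
    """Full build: validate -> pair -> augment SE² -> centre year -> attach dimorphism.

    ``dimorphism``, if given, needs columns (species, ornament_id, cohens_d);
    d is attached by exact (species, ornament) match.
    """
    records = records_from_frame(effects_frame)
    paired = [augment_missing_uncertainty(pe) for pe in pair_effects(records, cross_study_overrides)]
    if dimorphism is not None:
        lookup = {
            (normalize_species(r["species"]), str(r["ornament_id"])): float(r["cohens_d"])
            for _, r in dimorphism.iterrows()
        }
        paired = [
            replace(pe, dimorphism_d=lookup.get((pe.species, pe.ornament_id)))
            for pe in paired
        ]
    return centre_year(AnalysisDataset(paired))


def write_outputs(dataset: AnalysisDataset, csv_path, counts_path=None) -> None:
    """Write the analysis-ready CSV and (optionally) a JSON counts report."""
    dataset.to_frame().to_csv(csv_path, index=False)
    if counts_path is not None:
        with open(counts_path, "w") as fh:
            json.dump(summarize_counts(dataset), fh, indent=2)
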