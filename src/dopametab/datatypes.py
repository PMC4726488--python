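"""Shared data model for the serum-metabolomics case-control pipeline.

The central containers are thin, validated wrappers around pandas objects:

* :class:`MetaboliteMatrix` — samples × metabolites intensity grid with
  per-sample run-day labels and an explicit processing-scale tag,
* :class:`SampleAnnotation` — per-sample phenotype/covariate record,
* :class:`GenotypeMatrix` — samples × SNPs additive dosage grid,
* :class:`Contrast` — a named two-group comparison with its covariate list.

Missing values are represented as ``NaN`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "Group",
    "Sex",
    "MetaboliteMatrix",
    "SampleAnnotation",
    "annotation_frame",
    "GenotypeMatrix",
    "Contrast",
]


class Scale(Enum):
    """Processing stage of a metabolite matrix.

    Transitions are one-way: RAW → NORMALIZED → LOG → STANDARDIZED.
    """

    RAW = "raw"
    NORMALIZED = "normalized"
    LOG = "log"
    STANDARDIZED = "standardized"


_SCALE_ORDER = [Scale.RAW, Scale.NORMALIZED, Scale.LOG, Scale.STANDARDIZED]


class Group(Enum):
    CONTROL = "CONTROL"
    PD = "PD"
    RLS = "RLS"


class Sex(Enum):
    # Fixed numeric coding so regression coefficients are reproducible.
    MALE = 0
    FEMALE = 1


@dataclass
class MetaboliteMatrix:
    """Samples × metabolites intensity matrix with run-day labels.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with one column per metabolite.
        ``NaN`` marks a missing measurement.
    run_day:
        Series of opaque run-day labels indexed identically to ``data``.
    scale:
        Processing stage of the values (see :class:`Scale`).
    """

    data: pd.DataFrame
    run_day: pd.Series
    scale: Scale = Scale.RAW

    def __post_init__(self) -> None:
        if not isinstance(self.scale, Scale):
            self.scale = Scale(self.scale)
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dupes}")
        self.run_day = self.run_day.reindex(self.data.index)
        if self.run_day.isna().any():
            missing = self.run_day.index[self.run_day.isna()].tolist()
            raise ValueError(f"samples without a run-day label: {missing}")
        self.run_day = self.run_day.astype(str)
        if self.scale in (Scale.RAW, Scale.NORMALIZED):
            vals = self.data.to_numpy()
            observed = ~np.isnan(vals)
            if np.any(vals[observed] <= 0):
                raise ValueError(
                    f"{self.scale.name} intensities must be strictly positive "
                    "where observed"
                )

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def metabolite_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def with_values(self, data: pd.DataFrame, scale: Scale) -> "MetaboliteMatrix":
        """Return a copy holding ``data`` at ``scale``, enforcing the one-way
        RAW → NORMALIZED → LOG → STANDARDIZED transition order."""
        cur = _SCALE_ORDER.index(self.scale)
        new = _SCALE_ORDER.index(scale)
        if new < cur:
            raise ValueError(
                f"illegal scale transition {self.scale.name} → {scale.name}"
            )
        return MetaboliteMatrix(
            data=data, run_day=self.run_day.loc[data.index].copy(), scale=scale
        )

    def subset(
        self,
        samples: Optional[Sequence] = None,
        metabolites: Optional[Sequence] = None,
    ) -> "MetaboliteMatrix":
        data = self.data
        if samples is not None:
            data = data.loc[list(samples)]
        if metabolites is not None:
            data = data[list(metabolites)]
        return replace(
            self, data=data.copy(), run_day=self.run_day.loc[data.index].copy()
        )


@dataclass
class SampleAnnotation:
    """Phenotype/covariate record for one sample.

    ``age`` is in years, ``bmi`` in kg/m², the lipid panel in the source
    assay's concentration units; ``hypertension`` and ``diabetes`` are 0/1
    indicators. Lipid and comorbidity fields are optional but every sample
    entering the metabogenomic scan must carry the full set.
    """

    sample_id: str
    group: Group
    age: float
    sex: Sex
    bmi: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    total_cholesterol: Optional[float] = None
    triglycerides: Optional[float] = None
    hypertension: Optional[bool] = None
    diabetes: Optional[bool] = None

    def __post_init__(self) -> None:
        if not isinstance(self.group, Group):
            self.group = Group(str(self.group).upper())
        if not isinstance(self.sex, Sex):
            self.sex = Sex[str(self.sex).upper()]
        if not (self.age > 0):
            raise ValueError(f"sample {self.sample_id}: age must be positive")


#: Cofactor set of the metabogenomic regression.
MGWAS_COFACTORS = [
    "bmi",
    "age",
    "sex",
    "hdl",
    "ldl",
    "total_cholesterol",
    "triglycerides",
    "hypertension",
    "diabetes",
]


def annotation_frame(records: Iterable[SampleAnnotation]) -> pd.DataFrame:
    """Tabulate annotation records into a numeric covariate frame.

    Categorical fields are numerically coded (sex: MALE=0/FEMALE=1;
    hypertension/diabetes: 0/1) so the frame can enter design matrices
    directly; ``group`` stays a string column.
    """
    rows = []
    seen = set()
    for rec in records:
        if rec.sample_id in seen:
            raise ValueError(f"duplicate annotation for sample {rec.sample_id}")
        seen.add(rec.sample_id)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "group": rec.group.value,
                "age": float(rec.age),
                "sex": float(rec.sex.value),
                "bmi": np.nan if rec.bmi is None else float(rec.bmi),
                "hdl": np.nan if rec.hdl is None else float(rec.hdl),
                "ldl": np.nan if rec.ldl is None else float(rec.ldl),
                "total_cholesterol": np.nan
                if rec.total_cholesterol is None
                else float(rec.total_cholesterol),
                "triglycerides": np.nan
                if rec.triglycerides is None
                else float(rec.triglycerides),
                "hypertension": np.nan
                if rec.hypertension is None
                else float(bool(rec.hypertension)),
                "diabetes": np.nan
                if rec.diabetes is None
                else float(bool(rec.diabetes)),
            }
        )
    frame = pd.DataFrame(rows).set_index("sample_id")
    return frame


@dataclass
class GenotypeMatrix:
    """Samples × SNPs additive dosage matrix (0/1/2 alternate-allele counts,
    fractional dosages permitted for imputed data, ``NaN`` missing)."""

    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = self.dosages.astype(float)
        vals = self.dosages.to_numpy()
        observed = ~np.isnan(vals)
        if np.any((vals[observed] < 0) | (vals[observed] > 2)):
            raise ValueError("dosages must lie in [0, 2]")
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicate sample ids in genotype matrix")

    @property
    def sample_ids(self) -> list:
        return self.dosages.index.tolist()

    @property
    def snp_ids(self) -> list:
        return self.dosages.columns.tolist()

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class Contrast:
    """A named two-group comparison adjusted for a covariate list."""

    name: str
    case_group: Group
    reference_group: Group
    covariates: tuple = ("age", "sex")

    def __post_init__(self) -> None:
        if not isinstance(self.case_group, Group):
            self.case_group = Group(str(self.case_group).upper())
        if not isinstance(self.reference_group, Group):
            self.reference_group = Group(str(self.reference_group).upper())
        if self.case_group == self.reference_group:
            raise ValueError("case and reference group must differ")
        self.covariates = tuple(self.covariates)


def default_contrasts() -> list:
    """The three study contrasts, each adjusted for age and sex."""
    return [
        Contrast("PD_vs_CONTROL", Group.PD, Group.CONTROL),
        Contrast("RLS_vs_CONTROL", Group.RLS, Group.CONTROL),
        Contrast("PD_vs_RLS", Group.PD, Group.RLS),
    ]
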