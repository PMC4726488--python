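"""Readers and writers for the pipeline's tabular and graph formats.

Conventions: CSV/TSV matrices carry sample ids in the first column; the
metabolite matrix has a dedicated ``run_day`` column; missing cells are an
empty string or ``NA`` on input and are always written as ``NA``. Networks
are exported as GraphML or a plain edge list.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Union

import numpy as np
import pandas as pd
import networkx as nx

from .datatypes import (
    Group,
    GenotypeMatrix,
    MetaboliteMatrix,
    SampleAnnotation,
    Scale,
    Sex,
)

logger = logging.getLogger(__name__)

RUN_DAY_COLUMN = "run_day"
NA_VALUES = ["", "NA"]


def _read_table(path: Union[str, Path], dialect: str = None) -> pd.DataFrame:
    path = Path(path)
    if dialect is None:
        dialect = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(
        path, sep=dialect, na_values=NA_VALUES, keep_default_na=False, dtype=str
    )


def read_metabolite_matrix(
    path: Union[str, Path],
    dialect: str = None,
    scale: Scale = Scale.RAW,
) -> MetaboliteMatrix:
    """Read a samples × metabolites intensity table.

    The first column holds sample ids, one column must be named
    ``run_day``, and every remaining column is a metabolite. Unparseable
    cells become missing with a logged count.
    """
    raw = _read_table(path, dialect)
    cols = list(raw.columns)
    if RUN_DAY_COLUMN not in cols:
        raise ValueError(
            f"{path}: required column '{RUN_DAY_COLUMN}' is absent"
        )
    sample_col = cols[0]
    if raw[sample_col].duplicated().any():
        dupes = raw[sample_col][raw[sample_col].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    raw = raw.set_index(sample_col)
    run_day = raw.pop(RUN_DAY_COLUMN)
    values = raw.apply(pd.to_numeric, errors="coerce")
    n_unparseable = int((values.isna() & raw.notna()).sum().sum())
    if n_unparseable:
        logger.warning(
            "%s: %d unparseable cells treated as missing", path, n_unparseable
        )
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        logger.info("%s: %d missing cells", path, n_missing)
    return MetaboliteMatrix(data=values, run_day=run_day, scale=scale)


def write_metabolite_matrix(
    matrix: MetaboliteMatrix, path: Union[str, Path], dialect: str = None
) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    out = matrix.data.copy()
    out.insert(0, RUN_DAY_COLUMN, matrix.run_day)
    out.index.name = "sample_id"
    out.to_csv(path, sep=dialect, na_rep="NA")


_BOOL_MAP = {
    "0": False, "1": True, "true": True, "false": False,
    "yes": True, "no": False,
}

_OPTIONAL_FLOAT = ["bmi", "hdl", "ldl", "total_cholesterol", "triglycerides"]
_OPTIONAL_BOOL = ["hypertension", "diabetes"]


def read_annotation(path: Union[str, Path], dialect: str = None) -> List[SampleAnnotation]:
    """Read the sample annotation table (required columns: sample_id,
    group, age, sex; optional: bmi, lipid panel, comorbidity flags)."""
    raw = _read_table(path, dialect)
    required = ["sample_id", "group", "age", "sex"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    allowed_groups = {g.value for g in Group}
    records = []
    for _, row in raw.iterrows():
        group = str(row["group"]).upper()
        if group not in allowed_groups:
            raise ValueError(
                f"{path}: unknown group '{row['group']}' for sample "
                f"{row['sample_id']}; allowed: {sorted(allowed_groups)}"
            )
        kwargs = {
            "sample_id": str(row["sample_id"]),
            "group": Group(group),
            "age": float(row["age"]),
            "sex": Sex[str(row["sex"]).upper()],
        }
        for col in _OPTIONAL_FLOAT:
            if col in raw.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        for col in _OPTIONAL_BOOL:
            if col in raw.columns and pd.notna(row[col]):
                token = str(row[col]).strip().lower()
                if token not in _BOOL_MAP:
                    raise ValueError(
                        f"{path}: cannot parse boolean '{row[col]}' in {col}"
                    )
                kwargs[col] = _BOOL_MAP[token]
        records.append(SampleAnnotation(**kwargs))
    return records


def write_annotation(
    records: Iterable[SampleAnnotation], path: Union[str, Path], dialect: str = None
) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    rows = []
    for rec in records:
        rows.append(
            {
                "sample_id": rec.sample_id,
                "group": rec.group.value,
                "age": rec.age,
                "sex": rec.sex.name,
                "bmi": rec.bmi,
                "hdl": rec.hdl,
                "ldl": rec.ldl,
                "total_cholesterol": rec.total_cholesterol,
                "triglycerides": rec.triglycerides,
                "hypertension": None if rec.hypertension is None else int(rec.hypertension),
                "diabetes": None if rec.diabetes is None else int(rec.diabetes),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=dialect, index=False, na_rep="NA")


def read_genotypes(path: Union[str, Path], format: str = None) -> GenotypeMatrix:
    """Read an additive-dosage genotype matrix from a table or a VCF.

    Table layout: first column sample ids, one column per SNP, cells in
    [0, 2] or missing. VCF: dosage is the alternate-allele count from the
    GT field; half-missing genotypes are missing; multi-allelic records
    are skipped with a warning.
    """
    path = Path(path)
    if format is None:
        format = "VCF" if path.suffix.lower() in (".vcf", ".gz") else "TABLE"
    format = format.upper()
    if format == "TABLE":
        raw = _read_table(path)
        raw = raw.set_index(raw.columns[0])
        values = raw.apply(pd.to_numeric, errors="coerce")
        return GenotypeMatrix(dosages=values)
    if format == "VCF":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list = []
    columns: list = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "%s: skipping multi-allelic record %s:%d",
                path, variant.CHROM, variant.POS,
            )
            continue
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types are unreliable for half-calls; decode from genotypes.
        col = np.full(len(samples), np.nan)
        for k, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1]]
            if any(a < 0 for a in alleles):
                continue
            col[k] = float(sum(1 for a in alleles if a == 1))
        snp_ids.append(snp_id)
        columns.append(col)
    dosages = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=samples,
        columns=snp_ids,
    )
    return GenotypeMatrix(dosages=dosages)


def write_genotypes(genotypes: GenotypeMatrix, path: Union[str, Path]) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    out = genotypes.dosages.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep, na_rep="NA")


def write_association_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write an association (or ratio / mGWAS) table as TSV with a stable
    column order."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_association_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)


def write_network(
    graph: nx.Graph, path: Union[str, Path], format: str = "GRAPHML"
) -> None:
    """Export an annotated network as GraphML or a plain edge list TSV."""
    path = Path(path)
    format = format.upper()
    if format == "GRAPHML":
        # GraphML cannot serialize None attribute values.
        clean = graph.copy()
        for _, attrs in clean.nodes(data=True):
            for key in [k for k, v in attrs.items() if v is None]:
                del attrs[key]
        nx.write_graphml(clean, path)
    elif format == "EDGELIST":
        rows = [
            {"metabolite_a": a, "metabolite_b": b, **attrs}
            for a, b, attrs in graph.edges(data=True)
        ]
        cols = ["metabolite_a", "metabolite_b", "pearson_r", "pearson_p",
                "partial_r", "partial_p"]
        frame = pd.DataFrame(rows)
        if not frame.empty:
            ordered = [c for c in cols if c in frame.columns]
            rest = [c for c in frame.columns if c not in ordered]
            frame = frame[ordered + rest]
        else:
            frame = pd.DataFrame(columns=cols)
        frame.to_csv(path, sep="\t", index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: Union[str, Path]) -> nx.Graph:
    return nx.read_graphml(Path(path))
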