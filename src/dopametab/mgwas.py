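"""Candidate-SNP metabogenomic scan.

Each (SNP, metabolite) pair is tested in the general-population control
arm by OLS of the log metabolite concentration on the additive allele
dosage plus nine cofactors (BMI, age, sex, HDL, LDL, total cholesterol,
triglycerides, hypertension, diabetes). Significance is Bonferroni
corrected over SNPs × metabolites: with 32 candidate SNPs and 456
metabolites the threshold is 0.05 / (32 · 456) ≈ 3.43 × 10⁻⁶. SNPs
failing the minor-allele-frequency floor or a Hardy–Weinberg equilibrium
chi-square test are excluded beforehand.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .association import _as_frame, bonferroni_threshold, ols_scan
from .datatypes import (
    MGWAS_COFACTORS,
    GenotypeMatrix,
    MetaboliteMatrix,
    SampleAnnotation,
)

logger = logging.getLogger(__name__)

__all__ = ["hwe_filter", "snp_metabolite_scan"]


def hwe_filter(
    genotypes: GenotypeMatrix, p_threshold: float = 5e-6
) -> GenotypeMatrix:
    """Drop SNPs out of Hardy–Weinberg equilibrium.

    Requires hard calls (dosages in {0, 1, 2}); fractional (imputed)
    dosages skip the filter with a warning. The test is the 1-df
    chi-square of observed genotype counts against p̂²/2p̂q̂/q̂²
    expectations.
    """
    dosages = genotypes.dosages
    vals = dosages.to_numpy()
    observed = ~np.isnan(vals)
    hard = np.isin(vals[observed], (0.0, 1.0, 2.0)).all()
    if not hard:
        logger.warning(
            "fractional dosages present; Hardy–Weinberg filter skipped"
        )
        return genotypes
    keep = []
    for snp in dosages.columns:
        col = dosages[snp].dropna().to_numpy()
        n = len(col)
        if n == 0:
            keep.append(snp)
            continue
        counts = np.array([(col == 0).sum(), (col == 1).sum(), (col == 2).sum()],
                          dtype=float)
        q_hat = (counts[1] + 2 * counts[2]) / (2 * n)  # alt allele frequency
        expected = n * np.array(
            [(1 - q_hat) ** 2, 2 * q_hat * (1 - q_hat), q_hat ** 2]
        )
        nonzero = expected > 0
        chi2 = float(np.sum(
            (counts[nonzero] - expected[nonzero]) ** 2 / expected[nonzero]
        ))
        p = float(stats.chi2.sf(chi2, df=1))
        if p < p_threshold:
            logger.warning("SNP %s removed: HWE p=%.3g", snp, p)
        else:
            keep.append(snp)
    return GenotypeMatrix(dosages=dosages[keep].copy())


def snp_metabolite_scan(
    genotypes: GenotypeMatrix,
    matrix: MetaboliteMatrix,
    annotation: Union[pd.DataFrame, Sequence[SampleAnnotation]],
    alpha: float = 0.05,
    maf_min: float = 0.01,
    n_tests: Optional[int] = None,
    cofactors: Sequence[str] = tuple(MGWAS_COFACTORS),
) -> pd.DataFrame:
    """Scan every (SNP, metabolite) pair in the control arm.

    Samples are restricted to controls with a complete cofactor record
    and an observed dosage (listwise deletion). ``n_tests`` overrides the
    Bonferroni denominator, which defaults to SNPs tested × metabolites.
    """
    annotation = _as_frame(annotation)
    controls = annotation[annotation["group"] == "CONTROL"]
    cof = controls[list(cofactors)].apply(pd.to_numeric, errors="coerce")
    cof = cof.dropna()
    common = cof.index.intersection(matrix.data.index).intersection(
        genotypes.dosages.index
    )
    if len(common) == 0:
        raise ValueError("no control samples with complete cofactors")
    cof = cof.loc[common]
    Y_all = matrix.data.loc[common]

    tested = []
    skipped = []
    frames = []
    for snp in genotypes.snp_ids:
        dose = genotypes.dosages.loc[common, snp]
        ok = dose.notna()
        d = dose[ok].to_numpy()
        if len(d) == 0 or np.var(d) == 0:
            skipped.append(snp)
            logger.warning("SNP %s skipped: monomorphic or unobserved", snp)
            continue
        maf = float(np.mean(d) / 2.0)
        maf = min(maf, 1.0 - maf)
        if maf < maf_min:
            skipped.append(snp)
            logger.warning("SNP %s skipped: MAF %.4f < %.4f", snp, maf, maf_min)
            continue
        tested.append(snp)
        idx = dose.index[ok]
        X = np.column_stack(
            [np.ones(len(idx)), d, cof.loc[idx].to_numpy()]
        )
        Y = Y_all.loc[idx]
        yv = Y.to_numpy()
        if not np.isnan(yv).any():
            res = ols_scan(X, yv)
            frame = pd.DataFrame(
                {
                    "snp_id": snp,
                    "metabolite_id": matrix.metabolite_ids,
                    "beta": res.coef[1],
                    "se": res.se,
                    "t_stat": res.t,
                    "p_value": res.p,
                    "n_used": res.n,
                }
            )
        else:
            rows = []
            for j, met in enumerate(matrix.metabolite_ids):
                mask = ~np.isnan(yv[:, j])
                r = ols_scan(X[mask], yv[mask, j])
                rows.append(
                    {
                        "snp_id": snp,
                        "metabolite_id": met,
                        "beta": r.coef[1, 0],
                        "se": r.se[0],
                        "t_stat": r.t[0],
                        "p_value": r.p[0],
                        "n_used": r.n,
                    }
                )
            frame = pd.DataFrame(rows)
        frames.append(frame)
    if not tested:
        raise ValueError("no SNPs survive the MAF filter")
    if n_tests is None:
        n_tests = len(tested) * matrix.n_metabolites
    threshold = bonferroni_threshold(alpha, n_tests)
    table = pd.concat(frames, ignore_index=True)
    table["significant"] = table["p_value"] < threshold
    table = table.sort_values(
        ["p_value", "snp_id", "metabolite_id"], kind="mergesort"
    ).reset_index(drop=True)
    return table
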