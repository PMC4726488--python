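"""Metabolome-wide association scans.

For each contrast (PD vs controls, RLS vs controls, PD vs RLS) every
metabolite's log concentration is modelled by ordinary least squares on a
case indicator plus covariates (age and sex by default); the two-sided
t-test on the case coefficient is compared against the Bonferroni
threshold over all profiled metabolites. A set-logic step then classifies
metabolites into shared-unidirectional, disease-unique and discordant
groups.

The scan path solves all metabolites against one design matrix in a
single QR factorization; :func:`fit_metabolite_model` provides the
equivalent single-metabolite fit through statsmodels and is used as an
internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .datatypes import (
    Contrast,
    MetaboliteMatrix,
    SampleAnnotation,
    annotation_frame,
)

__all__ = [
    "AssociationRecord",
    "MetaboliteClassification",
    "bonferroni_threshold",
    "fit_metabolite_model",
    "run_scan",
    "classify",
]

_P_FLOOR = 1e-300  # keep p-values strictly positive under extreme signals


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


@dataclass
class AssociationRecord:
    metabolite_id: str
    contrast_name: str
    beta: float
    se: float
    t_stat: float
    p_value: float
    n_used: int
    direction: str  # UP / DOWN
    significant: bool


@dataclass
class MetaboliteClassification:
    """Set logic over the three contrasts' significant metabolites."""

    shared_unidirectional: Set[str] = field(default_factory=set)
    pd_unique: Set[str] = field(default_factory=set)
    rls_unique: Set[str] = field(default_factory=set)
    pd_vs_rls: Set[str] = field(default_factory=set)
    discordant: Set[str] = field(default_factory=set)


def _as_frame(
    annotation: Union[pd.DataFrame, Sequence[SampleAnnotation]]
) -> pd.DataFrame:
    if isinstance(annotation, pd.DataFrame):
        return annotation
    return annotation_frame(annotation)


class OLSResult:
    """Coefficientwise OLS statistics for many responses sharing a design."""

    __slots__ = ("coef", "se", "t", "p", "logp", "df_resid", "n", "rss",
                 "degenerate")

    def __init__(self, coef, se, t, p, logp, df_resid, n, rss, degenerate):
        self.coef = coef
        self.se = se
        self.t = t
        self.p = p
        self.logp = logp
        self.df_resid = df_resid
        self.n = n
        self.rss = rss
        self.degenerate = degenerate


def ols_scan(X: np.ndarray, Y: np.ndarray, coef_index: int = 1) -> OLSResult:
    """OLS of every column of ``Y`` on the shared design ``X``.

    Returns statistics for the coefficient at ``coef_index``. Responses
    with (numerically) zero residual variance are flagged degenerate and
    reported with p = 1.
    """
    n, k = X.shape
    if Y.ndim == 1:
        Y = Y[:, None]
    if n <= k:
        raise ValueError(f"n={n} too small for {k} design columns")
    Q, R = np.linalg.qr(X)
    rdiag = np.abs(np.diag(R))
    if rdiag.min() < 1e-10 * max(rdiag.max(), 1.0):
        bad = list(np.where(rdiag < 1e-10 * max(rdiag.max(), 1.0))[0])
        raise ValueError(f"rank-deficient design; collinear columns at {bad}")
    coef = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    df = n - k
    scale = np.mean(Y * Y, axis=0) + 1.0
    degenerate = rss <= 1e-12 * scale * n
    sigma2 = rss / df
    Rinv = np.linalg.inv(R)
    xtx_inv_diag = np.einsum("ij,ij->i", Rinv, Rinv)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(xtx_inv_diag[coef_index] * sigma2)
        t = np.where(se > 0, coef[coef_index] / np.where(se > 0, se, 1.0), 0.0)
        logp = np.log(2.0) + stats.t.logsf(np.abs(t), df)
        p = np.exp(logp)
    p = np.clip(p, _P_FLOOR, 1.0)
    p[degenerate] = 1.0
    t[degenerate] = 0.0
    logp[degenerate] = 0.0
    return OLSResult(
        coef=coef, se=se, t=t, p=p, logp=logp, df_resid=df, n=n, rss=rss,
        degenerate=degenerate,
    )


def build_design(
    annotation: pd.DataFrame,
    contrast: Contrast,
    covariates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Design frame [intercept, case, covariates...] for the contrast's
    samples, dropping samples with missing covariates (listwise)."""
    covariates = list(contrast.covariates if covariates is None else covariates)
    missing_cols = [c for c in covariates if c not in annotation.columns]
    if missing_cols:
        raise ValueError(f"covariates absent from annotation: {missing_cols}")
    in_contrast = annotation["group"].isin(
        [contrast.case_group.value, contrast.reference_group.value]
    )
    sub = annotation.loc[in_contrast]
    design = pd.DataFrame(index=sub.index)
    design["intercept"] = 1.0
    design["case"] = (sub["group"] == contrast.case_group.value).astype(float)
    for cov in covariates:
        design[cov] = pd.to_numeric(sub[cov], errors="coerce")
    design = design.dropna()
    return design


def fit_metabolite_model(
    y: pd.Series,
    annotation: Union[pd.DataFrame, Sequence[SampleAnnotation]],
    contrast: Contrast,
    threshold: float = 0.05,
) -> AssociationRecord:
    """Single-metabolite OLS association fit (statsmodels backend).

    Samples are restricted to the contrast's two groups; samples with a
    missing response or covariate are list-wise deleted.
    """
    annotation = _as_frame(annotation)
    design = build_design(annotation, contrast)
    common = design.index.intersection(y.dropna().index)
    design = design.loc[common]
    yv = y.loc[common].astype(float)
    k = design.shape[1]
    if len(common) <= k + 1:
        raise ValueError(
            f"too few usable samples (n={len(common)}) for {k - 2} covariates"
        )
    model = sm.OLS(yv.to_numpy(), design.to_numpy())
    # statsmodels raises on perfect collinearity only at inference time;
    # check explicitly so the error names the columns.
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < k:
        raise ValueError(
            f"rank-deficient design among columns {list(design.columns)}"
        )
    res = model.fit()
    beta = float(res.params[1])
    p = float(np.clip(res.pvalues[1], _P_FLOOR, 1.0))
    return AssociationRecord(
        metabolite_id=str(y.name),
        contrast_name=contrast.name,
        beta=beta,
        se=float(res.bse[1]),
        t_stat=float(res.tvalues[1]),
        p_value=p,
        n_used=int(len(common)),
        direction="UP" if beta > 0 else "DOWN",
        significant=bool(p < threshold),
    )


def run_scan(
    matrix: MetaboliteMatrix,
    annotation: Union[pd.DataFrame, Sequence[SampleAnnotation]],
    contrasts: Sequence[Contrast],
    alpha: float = 0.05,
    n_tests: Optional[int] = None,
) -> pd.DataFrame:
    """Association scan over all metabolites and contrasts.

    ``n_tests`` sets the Bonferroni denominator; it defaults to the
    number of metabolites in the matrix but can be fixed to the number
    profiled before QC.
    """
    annotation = _as_frame(annotation)
    if n_tests is None:
        n_tests = matrix.n_metabolites
    threshold = bonferroni_threshold(alpha, n_tests)
    frames = []
    for contrast in contrasts:
        design = build_design(annotation, contrast)
        design = design.loc[design.index.intersection(matrix.data.index)]
        if design["case"].sum() == 0 or (1 - design["case"]).sum() == 0:
            raise ValueError(f"contrast {contrast.name}: empty group")
        frames.append(
            _scan_one_contrast(matrix, design, contrast, threshold)
        )
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(
        ["contrast", "p_value", "metabolite_id"], kind="mergesort"
    ).reset_index(drop=True)
    return table


def _scan_one_contrast(
    matrix: MetaboliteMatrix,
    design: pd.DataFrame,
    contrast: Contrast,
    threshold: float,
) -> pd.DataFrame:
    Y = matrix.data.reindex(design.index)
    X = design.to_numpy()
    yv = Y.to_numpy()
    has_nan = np.isnan(yv).any()
    ids = matrix.metabolite_ids
    if not has_nan:
        res = ols_scan(X, yv)
        beta, se, t, p = res.coef[1], res.se, res.t, res.p
        n_used = np.full(len(ids), res.n)
    else:
        beta = np.empty(len(ids))
        se = np.empty(len(ids))
        t = np.empty(len(ids))
        p = np.empty(len(ids))
        n_used = np.empty(len(ids), dtype=int)
        for j in range(len(ids)):
            ok = ~np.isnan(yv[:, j])
            if ok.sum() <= X.shape[1] + 1:
                raise ValueError(
                    f"metabolite {ids[j]}: too few usable samples"
                )
            r = ols_scan(X[ok], yv[ok, j])
            beta[j], se[j], t[j], p[j] = r.coef[1, 0], r.se[0], r.t[0], r.p[0]
            n_used[j] = r.n
    return pd.DataFrame(
        {
            "metabolite_id": ids,
            "contrast": contrast.name,
            "beta": beta,
            "se": se,
            "t_stat": t,
            "p_value": p,
            "n_used": n_used,
            "direction": np.where(beta > 0, "UP", "DOWN"),
            "significant": p < threshold,
        }
    )


def classify(
    table: pd.DataFrame,
    pd_contrast: str = "PD_vs_CONTROL",
    rls_contrast: str = "RLS_vs_CONTROL",
    direct_contrast: str = "PD_vs_RLS",
) -> MetaboliteClassification:
    """Classify metabolites by their significance pattern.

    Shared-unidirectional: significant versus controls in both diseases
    with the same direction; unique: significant in exactly one disease;
    discordant: significant in both with opposite directions.
    """
    present = set(table["contrast"].unique())
    needed = {pd_contrast, rls_contrast, direct_contrast}
    if not needed <= present:
        raise ValueError(f"table lacks contrasts {sorted(needed - present)}")

    def _sig(contrast: str) -> pd.DataFrame:
        sub = table[(table["contrast"] == contrast) & table["significant"]]
        return sub.set_index("metabolite_id")

    pd_sig = _sig(pd_contrast)
    rls_sig = _sig(rls_contrast)
    both = set(pd_sig.index) & set(rls_sig.index)
    shared = {
        m for m in both
        if pd_sig.loc[m, "direction"] == rls_sig.loc[m, "direction"]
    }
    discordant = both - shared
    return MetaboliteClassification(
        shared_unidirectional=shared,
        pd_unique=set(pd_sig.index) - set(rls_sig.index),
        rls_unique=set(rls_sig.index) - set(pd_sig.index),
        pd_vs_rls=set(_sig(direct_contrast).index),
        discordant=discordant,
    )
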