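"""Run-day normalization, log transform, missingness QC, chained-equations
imputation and standardization.

The fixed pipeline order is normalize → log → filter → impute →
standardize. Filtering and imputation operate on the log scale, where the
chained regressions' normality assumption is closest to holding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import linalg

from .datatypes import MetaboliteMatrix, Scale

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessReport",
    "run_day_normalize",
    "log_transform",
    "filter_missingness",
    "impute_chained",
    "standardize",
    "preprocess_pipeline",
]


@dataclass
class PreprocessReport:
    """QC bookkeeping of one preprocessing run."""

    dropped_metabolites: List[str] = field(default_factory=list)
    dropped_samples: List[str] = field(default_factory=list)
    imputed_cell_count: int = 0
    day_median_table: Optional[pd.DataFrame] = None  # days × metabolites

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"item": m, "kind": "metabolite_dropped"} for m in self.dropped_metabolites
        ] + [{"item": s, "kind": "sample_dropped"} for s in self.dropped_samples]
        rows.append({"item": str(self.imputed_cell_count), "kind": "imputed_cells"})
        return pd.DataFrame(rows, columns=["item", "kind"])


def run_day_normalize(
    matrix: MetaboliteMatrix, return_medians: bool = False
):
    """Remove day-level instrument drift.

    Each observed value is divided by the median of its metabolite on its
    run day and multiplied by the metabolite's overall median, both taken
    over observed values only. Afterwards every day's median equals the
    metabolite's pre-normalization overall median. Days on which a
    metabolite was never observed are left missing with a warning.
    """
    if matrix.scale is not Scale.RAW:
        raise ValueError(f"expected RAW matrix, got {matrix.scale.name}")
    data = matrix.data
    overall = data.median(axis=0, skipna=True)
    day_medians = data.groupby(matrix.run_day).median()  # days × metabolites

    if (day_medians <= 0).any().any():
        bad = day_medians.stack()
        bad = bad[bad <= 0]
        raise ValueError(
            "non-positive day median encountered (raw intensities must be "
            f"positive): {bad.index.tolist()[:5]}"
        )
    fully_missing = day_medians.isna()
    if fully_missing.any().any():
        n_gaps = int(fully_missing.sum().sum())
        logger.warning(
            "%d (day, metabolite) pairs have no observed values; those cells "
            "stay missing", n_gaps,
        )

    per_row_daymed = day_medians.reindex(matrix.run_day.to_numpy()).to_numpy()
    normalized = data.to_numpy() / per_row_daymed * overall.to_numpy()[None, :]
    out = matrix.with_values(
        pd.DataFrame(normalized, index=data.index, columns=data.columns),
        Scale.NORMALIZED,
    )
    if return_medians:
        return out, day_medians
    return out


def log_transform(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Natural log, elementwise; missing cells preserved."""
    if matrix.scale is not Scale.NORMALIZED:
        raise ValueError(f"expected NORMALIZED matrix, got {matrix.scale.name}")
    vals = matrix.data.to_numpy()
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            "non-positive value at sample "
            f"{matrix.sample_ids[r]}, metabolite {matrix.metabolite_ids[c]}"
        )
    return matrix.with_values(np.log(matrix.data), Scale.LOG)


def filter_missingness(
    matrix: MetaboliteMatrix,
    metabolite_threshold: float = 0.20,
    sample_threshold: float = 0.10,
) -> Tuple[MetaboliteMatrix, PreprocessReport]:
    """Drop metabolites, then samples, with excess missingness.

    A metabolite is dropped when its missing fraction is strictly greater
    than ``metabolite_threshold``; samples are then assessed over the
    retained metabolites against ``sample_threshold``.
    """
    for thr in (metabolite_threshold, sample_threshold):
        if not (0 <= thr <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
    mask = matrix.data.isna()
    met_frac = mask.mean(axis=0)
    drop_mets = met_frac.index[met_frac > metabolite_threshold].tolist()
    kept_mets = [m for m in matrix.metabolite_ids if m not in set(drop_mets)]
    if not kept_mets:
        raise ValueError("all metabolites exceed the missingness threshold")
    sample_frac = mask[kept_mets].mean(axis=1)
    drop_samples = sample_frac.index[sample_frac > sample_threshold].tolist()
    kept_samples = [s for s in matrix.sample_ids if s not in set(drop_samples)]
    if not kept_samples:
        raise ValueError("all samples exceed the missingness threshold")
    out = matrix.subset(samples=kept_samples, metabolites=kept_mets)
    report = PreprocessReport(
        dropped_metabolites=drop_mets, dropped_samples=drop_samples
    )
    return out, report


def impute_chained(
    matrix: MetaboliteMatrix,
    max_iter: int = 20,
    seed: Optional[int] = None,
    tol: float = 1e-4,
    draws: bool = False,
) -> MetaboliteMatrix:
    """Chained-equations imputation on the log scale.

    Missing cells are initialized at per-metabolite observed means and
    then refined by sweeps of per-metabolite linear regressions on all
    other metabolites. Each metabolite's regression is fitted on the
    rows where that metabolite is *observed* (the standard chained-
    equations scheme — fitting on the completed matrix instead lets
    imputed cells inflate the correlations they were predicted from,
    which runs away at high p/n). Sweeps stop at ``max_iter`` or when
    the largest absolute change of any imputed cell falls below ``tol``.
    The default is deterministic conditional-mean imputation; with
    ``draws=True`` a residual-scale Gaussian draw is added to each
    imputed cell at the end (seeded).

    Per sweep, one Gram matrix and its inverse are shared by all
    regressions; each column's observed-row fit is recovered from them
    by a low-rank Woodbury downdate (removing the column's missing rows
    and re-centering on its observed-row means), which is algebraically
    identical to fitting that regression separately. A singular design
    triggers a ridge fallback with a logged warning.
    """
    if matrix.scale is not Scale.LOG:
        raise ValueError(f"expected LOG matrix, got {matrix.scale.name}")
    X = matrix.data.to_numpy().copy()
    miss = np.isnan(X)
    if not miss.any():
        return matrix
    n, p = X.shape
    n_obs = (~miss).sum(axis=0)
    if (n_obs < 2).any():
        bad = [matrix.metabolite_ids[j] for j in np.where(n_obs < 2)[0]]
        raise ValueError(f"metabolites with fewer than 2 observed values: {bad}")

    col_means = np.nanmean(X, axis=0)
    X[miss] = np.broadcast_to(col_means, X.shape)[miss]
    miss_cols = np.where(miss.any(axis=0))[0]

    resid_var = np.ones(p)
    best_change = np.inf
    best_state = None
    rising = 0
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        Xc = X - mu
        gram = Xc.T @ Xc
        omega = _invert_gram(gram, matrix.metabolite_ids)
        max_change = 0.0
        for j in miss_cols:
            rows = miss[:, j]
            m = int(rows.sum())
            mu_obs = (n * mu - X[rows].sum(axis=0)) / (n - m)
            # downdate: remove the missing rows and re-center on the
            # observed-row means -> observed-row centered Gram
            B = np.vstack(
                [X[rows] - mu, np.sqrt(n - m) * (mu_obs - mu)[None, :]]
            )
            T = omega @ B.T  # p x (m+1)
            S = np.eye(m + 1) - B @ T
            try:
                # column j of inv(gram - B^T B) is all we need
                col_j = omega[:, j] + T @ linalg.solve(
                    S, T[j], assume_a="sym", check_finite=False
                )
            except linalg.LinAlgError:
                logger.warning(
                    "unstable downdate for metabolite %s; direct fit",
                    matrix.metabolite_ids[j],
                )
                sub = X[~rows] - mu_obs
                gram_j = sub.T @ sub
                col_j = _invert_gram(gram_j, matrix.metabolite_ids)[:, j]
            beta = -col_j / col_j[j]
            beta[j] = 0.0
            resid_var[j] = 1.0 / col_j[j] / max(n - m - p, 1)
            pred = mu_obs[j] + (X[rows] - mu_obs) @ beta
            max_change = max(max_change, float(np.max(np.abs(pred - X[rows, j]))))
            X[rows, j] = pred
        # Deterministic conditional-mean sweeps can drift toward a
        # degenerate completed matrix at high p/n (imputed cells satisfy
        # their regressions exactly, deflating the smallest eigenvalues
        # sweep after sweep); the useful fixed point is where the sweep
        # change bottoms out, so keep the best state and stop once the
        # change stops decreasing.
        if max_change < best_change:
            best_change = max_change
            best_state = (X.copy(), resid_var.copy())
            rising = 0
        else:
            rising += 1
            if rising >= 2:
                logger.warning(
                    "imputation sweeps stopped at change %.3g (no longer "
                    "decreasing)", best_change,
                )
                break
        if max_change < tol:
            break
    if best_state is not None:
        X, resid_var = best_state

    if draws:
        rng = np.random.default_rng(seed)
        for j in miss_cols:
            rows = miss[:, j]
            X[rows, j] += rng.normal(
                0.0, np.sqrt(max(resid_var[j], 0.0)), size=int(rows.sum())
            )

    out = pd.DataFrame(X, index=matrix.data.index, columns=matrix.data.columns)
    return matrix.with_values(out, Scale.LOG)


def _invert_gram(gram: np.ndarray, metabolite_ids) -> np.ndarray:
    try:
        cho = linalg.cho_factor(gram, check_finite=False)
        return linalg.cho_solve(cho, np.eye(gram.shape[0]), check_finite=False)
    except linalg.LinAlgError:
        ridge = 1e-10 * float(np.mean(np.diag(gram)))
        logger.warning(
            "singular design in chained imputation; ridge fallback (lambda=%.3g)",
            ridge,
        )
        return np.linalg.inv(gram + ridge * np.eye(gram.shape[0]))


def standardize(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Center each metabolite to mean 0 and scale to sample SD 1."""
    if matrix.scale is not Scale.LOG:
        raise ValueError(f"expected LOG matrix, got {matrix.scale.name}")
    if matrix.data.isna().any().any():
        raise ValueError("standardize requires a complete matrix; impute first")
    sd = matrix.data.std(axis=0, ddof=1)
    zero = sd.index[(sd == 0) | sd.isna()].tolist()
    if zero:
        raise ValueError(f"zero-variance metabolites: {zero}")
    out = (matrix.data - matrix.data.mean(axis=0)) / sd
    return matrix.with_values(out, Scale.STANDARDIZED)


def preprocess_pipeline(
    matrix: MetaboliteMatrix,
    metabolite_threshold: float = 0.20,
    sample_threshold: float = 0.10,
    impute: str = "chained",
    max_iter: int = 20,
    seed: Optional[int] = None,
) -> Tuple[MetaboliteMatrix, MetaboliteMatrix, PreprocessReport]:
    """Full preprocessing chain.

    Returns ``(standardized, log_complete, report)``: the standardized
    matrix feeds network inference, the complete log matrix feeds the
    association, ratio and metabogenomic scans.
    """
    normalized, day_medians = run_day_normalize(matrix, return_medians=True)
    logged = log_transform(normalized)
    filtered, report = filter_missingness(
        logged, metabolite_threshold, sample_threshold
    )
    report.day_median_table = day_medians
    report.imputed_cell_count = int(filtered.data.isna().sum().sum())
    if impute == "chained":
        complete = impute_chained(filtered, max_iter=max_iter, seed=seed)
    elif impute == "mean":
        filled = filtered.data.fillna(filtered.data.mean(axis=0))
        complete = filtered.with_values(filled, Scale.LOG)
    else:
        raise ValueError(f"unknown imputation method {impute!r}")
    standardized = standardize(complete)
    return standardized, complete, report
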