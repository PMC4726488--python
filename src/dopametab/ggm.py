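"""Gaussian graphical model inference with shrinkage partial correlations.

The metabolite network is the undirected graph of nonzero partial
correlations of the (approximately) multivariate-normal log metabolome.
Because the metabolite count approaches the usable sample count, the
sample correlation matrix R is shrunk toward the identity,

    R* = (1 − λ*) R + λ* I,

with the analytic shrinkage intensity

    λ* = Σ_{i<j} Var̂(r_ij) / Σ_{i<j} r_ij²   (clamped to [0, 1]),

where Var̂(r_ij) is the unbiased empirical variance of the standardized
product terms. Partial correlations follow from the scaled inverse
Ω = (R*)⁻¹ as ρ_ij = −Ω_ij / √(Ω_ii Ω_jj).

Edges require BOTH the marginal Pearson correlation and the partial
correlation to pass a Bonferroni-corrected significance level (the
dual-significance rule), and pairs whose Pearson correlation is
(numerically) zero while the partial correlation is negative are flagged
as collider artifacts and excluded. Confounders (age, sex and the two
disease indicators) are regressed out of every metabolite beforehand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .association import _as_frame
from .datatypes import MetaboliteMatrix, SampleAnnotation, Scale

logger = logging.getLogger(__name__)

__all__ = [
    "ShrinkageEstimate",
    "GGMNetworkResult",
    "residualize",
    "estimate_shrinkage",
    "edge_pvalues",
    "build_network",
    "annotate_network",
]

#: Confounders regressed out before correlation: the two standard
#: covariates plus the disease-status indicators.
DEFAULT_GGM_COVARIATES = ("age", "sex", "pd", "rls")


@dataclass
class ShrinkageEstimate:
    """Shrinkage correlation estimate and implied partial correlations."""

    lambda_star: float
    correlation: np.ndarray
    shrunk_correlation: np.ndarray
    partial_correlation: np.ndarray
    n: int


@dataclass
class GGMNetworkResult:
    """All-pairs audit table plus the underlying shrinkage estimate.

    ``edges`` has one row per unordered metabolite pair with Pearson and
    partial correlations, their p-values, the collider-artifact flag and
    the dual-rule verdict; ``alpha_per_test`` is the Bonferroni-corrected
    per-pair level.
    """

    edges: pd.DataFrame
    estimate: ShrinkageEstimate
    alpha_per_test: float

    @property
    def passing_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["passes_dual_rule"]].reset_index(drop=True)


def _covariate_design(annotation: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(annotation))]
    for cov in covariates:
        key = cov.lower()
        if key in ("pd", "rls"):
            cols.append((annotation["group"] == key.upper()).to_numpy(float))
        elif cov in annotation.columns:
            vals = pd.to_numeric(annotation[cov], errors="coerce").to_numpy()
            if np.isnan(vals).any():
                raise ValueError(f"covariate {cov} missing for some samples")
            cols.append(vals)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return np.column_stack(cols)


def residualize(
    matrix: MetaboliteMatrix,
    annotation: Union[pd.DataFrame, Sequence[SampleAnnotation]],
    covariates: Sequence[str] = DEFAULT_GGM_COVARIATES,
) -> MetaboliteMatrix:
    """Regress confounders out of every metabolite and re-standardize.

    With an empty covariate list the input is returned unchanged. A
    metabolite whose residual is (numerically) constant — e.g. one that
    coincides with a covariate — raises a zero-variance error naming it.
    """
    if not covariates:
        return matrix
    annotation = _as_frame(annotation).reindex(matrix.data.index)
    X = _covariate_design(annotation, covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"collinear covariates among {list(covariates)}")
    Y = matrix.data.to_numpy()
    if np.isnan(Y).any():
        raise ValueError("residualize requires a complete matrix")
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    sd = resid.std(axis=0, ddof=1)
    tiny = sd <= 1e-12 * max(1.0, float(np.abs(Y).max()))
    if tiny.any():
        bad = [matrix.metabolite_ids[j] for j in np.where(tiny)[0]]
        raise ValueError(
            f"zero residual variance after removing covariates: {bad}"
        )
    resid = (resid - resid.mean(axis=0)) / sd
    out = pd.DataFrame(resid, index=matrix.data.index, columns=matrix.data.columns)
    return MetaboliteMatrix(
        data=out, run_day=matrix.run_day.copy(), scale=Scale.STANDARDIZED
    )


def _as_array(data) -> np.ndarray:
    if isinstance(data, MetaboliteMatrix):
        return data.data.to_numpy()
    return np.asarray(data, dtype=float)


def estimate_shrinkage(data) -> ShrinkageEstimate:
    """Shrinkage correlation and partial correlations.

    Accepts a complete :class:`MetaboliteMatrix` or a plain n × p array.
    """
    X = _as_array(data)
    n, p = X.shape
    if n < 3:
        raise ValueError("shrinkage estimation needs at least 3 samples")
    if np.isnan(X).any():
        raise ValueError("shrinkage estimation requires a complete matrix")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance columns present")
    Xs = (X - X.mean(axis=0)) / sd

    S = Xs.T @ Xs  # (n-1) * correlation
    r = S / (n - 1)
    # Var-hat(r_ij) from the standardized products w_kij = x_ki x_kj:
    # sum_k w² is an elementwise-squared cross-product, so no n×p×p tensor.
    sum_w2 = (Xs * Xs).T @ (Xs * Xs)
    var_r = n / (n - 1.0) ** 3 * (sum_w2 - S * S / n)

    iu = np.triu_indices(p, k=1)
    denom = float(np.sum(r[iu] ** 2))
    numer = float(np.sum(var_r[iu]))
    lam = 1.0 if denom == 0 else min(1.0, max(0.0, numer / denom))

    shrunk = (1.0 - lam) * r + lam * np.eye(p)
    np.fill_diagonal(shrunk, 1.0)
    try:
        omega = np.linalg.inv(shrunk)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "shrunk correlation matrix is singular (lambda = "
            f"{lam:.3g}); enforce a positive shrinkage floor"
        ) from exc
    d = np.sqrt(np.diag(omega))
    partial = np.clip(-omega / np.outer(d, d), -1.0, 1.0)
    np.fill_diagonal(partial, 1.0)
    partial = (partial + partial.T) / 2.0
    return ShrinkageEstimate(
        lambda_star=lam,
        correlation=r,
        shrunk_correlation=shrunk,
        partial_correlation=partial,
        n=n,
    )


def _fisher_p(r: np.ndarray, n: int, q: int) -> np.ndarray:
    df_term = n - 3 - q
    if df_term < 1:
        raise ValueError("infeasible Fisher-z degrees of freedom")
    rc = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(rc) * np.sqrt(df_term)
    return np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)


def edge_pvalues(
    estimate: ShrinkageEstimate,
    n: Optional[int] = None,
    method: str = "FISHER_Z",
    data: Optional[np.ndarray] = None,
    permutations: int = 1000,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pair p-values for the Pearson and the partial correlations.

    FISHER_Z uses z = atanh(r)·√(n − 3 − q) with q = 0 for marginal and
    q = p − 2 for full-order partial correlations, against a standard
    normal. PERMUTATION permutes one variable of each pair ``permutations``
    times, recomputing both correlation kinds, with the add-one correction
    p = (b + 1) / (B + 1); it requires the data matrix. When Fisher-z
    degrees of freedom are infeasible the permutation test is used
    automatically (with a warning).
    """
    if n is None:
        n = estimate.n
    p = estimate.correlation.shape[0]
    method = method.upper()
    if method == "FISHER_Z":
        try:
            pearson_p = _fisher_p(estimate.correlation, n, 0)
            partial_p = _fisher_p(estimate.partial_correlation, n, p - 2)
            return pearson_p, partial_p
        except ValueError:
            if data is None:
                raise
            logger.warning(
                "Fisher-z degrees of freedom infeasible (n=%d, p=%d); "
                "falling back to permutation test", n, p,
            )
            method = "PERMUTATION"
    if method != "PERMUTATION":
        raise ValueError(f"unknown edge test {method!r}")
    if data is None:
        raise ValueError("permutation test requires the data matrix")
    return _permutation_pvalues(
        _as_array(data), estimate, permutations, seed
    )


def _permutation_pvalues(
    X: np.ndarray, estimate: ShrinkageEstimate, B: int, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pair permutation test: break pair (i, j) by permuting the
    sample order of variable j, recompute the Pearson correlation and the
    full shrinkage partial correlation, and count exceedances."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    Xs = (X - X.mean(axis=0)) / sd
    lam = estimate.lambda_star
    r_obs = estimate.correlation
    rho_obs = estimate.partial_correlation
    pearson_p = np.ones((p, p))
    partial_p = np.ones((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            count_r = 0
            count_rho = 0
            for _ in range(B):
                perm = rng.permutation(n)
                xj = Xs[perm, j]
                r_perm = r_obs.copy()
                col = (Xs.T @ xj) / (n - 1)
                col[j] = 1.0
                r_perm[:, j] = col
                r_perm[j, :] = col
                if abs(col[i]) >= abs(r_obs[i, j]) - 1e-15:
                    count_r += 1
                shrunk = (1.0 - lam) * r_perm + lam * np.eye(p)
                np.fill_diagonal(shrunk, 1.0)
                omega = np.linalg.inv(shrunk)
                d = np.sqrt(np.diag(omega))
                rho_ij = -omega[i, j] / (d[i] * d[j])
                if abs(rho_ij) >= abs(rho_obs[i, j]) - 1e-15:
                    count_rho += 1
            pearson_p[i, j] = pearson_p[j, i] = (count_r + 1) / (B + 1)
            partial_p[i, j] = partial_p[j, i] = (count_rho + 1) / (B + 1)
    return pearson_p, partial_p


def build_network(
    matrix: MetaboliteMatrix,
    annotation: Union[pd.DataFrame, Sequence[SampleAnnotation], None] = None,
    alpha: float = 0.05,
    covariates: Sequence[str] = DEFAULT_GGM_COVARIATES,
    edge_test: str = "FISHER_Z",
    permutations: int = 1000,
    artifact_eps: float = 0.05,
    seed: int = 0,
) -> GGMNetworkResult:
    """Infer the metabolite network with the dual-significance edge rule.

    Pipeline: residualize confounders → shrinkage estimate → per-pair
    p-values → Bonferroni level alpha / n_pairs applied to BOTH the
    Pearson and the partial correlation → collider-artifact exclusion
    (|pearson_r| < ``artifact_eps`` and partial_r < 0). The returned
    audit table keeps every pair with its flags. Pass ``annotation=None``
    (or an empty covariate list) to skip residualization.
    """
    if annotation is not None and covariates:
        work = residualize(matrix, annotation, covariates)
    else:
        work = matrix
    est = estimate_shrinkage(work)
    pearson_p, partial_p = edge_pvalues(
        est, method=edge_test, data=work.data.to_numpy(),
        permutations=permutations, seed=seed,
    )
    p = matrix.n_metabolites
    n_pairs = p * (p - 1) // 2
    level = alpha / n_pairs
    ia, ib = np.triu_indices(p, k=1)
    pr = est.correlation[ia, ib]
    rho = est.partial_correlation[ia, ib]
    pe_p = pearson_p[ia, ib]
    pa_p = partial_p[ia, ib]
    artifact = (np.abs(pr) < artifact_eps) & (rho < 0)
    passes = (pe_p < level) & (pa_p < level) & ~artifact
    ids = np.asarray(matrix.metabolite_ids, dtype=object)
    edges = pd.DataFrame(
        {
            "metabolite_a": ids[ia],
            "metabolite_b": ids[ib],
            "pearson_r": pr,
            "pearson_p": pe_p,
            "partial_r": rho,
            "partial_p": pa_p,
            "artifact_flag": artifact,
            "passes_dual_rule": passes,
        }
    )
    return GGMNetworkResult(edges=edges, estimate=est, alpha_per_test=level)


def annotate_network(
    edges: Union[pd.DataFrame, GGMNetworkResult],
    association_table: pd.DataFrame,
    only_passing: bool = True,
):
    """Overlay association results onto the network.

    Returns a :mod:`networkx` graph whose nodes carry, per contrast, the
    effect direction, regression coefficient and −log10 p-value, and
    whose edges carry both correlation kinds and their p-values.
    Metabolites absent from the association table get no attributes and a
    warning.
    """
    import networkx as nx

    if isinstance(edges, GGMNetworkResult):
        edges = edges.edges
    graph = nx.Graph()
    nodes = sorted(
        set(edges["metabolite_a"]).union(edges["metabolite_b"])
    )
    graph.add_nodes_from(nodes)
    assoc = association_table.set_index(["metabolite_id", "contrast"])
    missing = set()
    for node in nodes:
        try:
            sub = assoc.xs(node, level="metabolite_id")
        except KeyError:
            missing.add(node)
            continue
        for contrast, row in sub.iterrows():
            graph.nodes[node][f"{contrast}_direction"] = str(row["direction"])
            graph.nodes[node][f"{contrast}_beta"] = float(row["beta"])
            graph.nodes[node][f"{contrast}_neglog10_p"] = float(
                -np.log10(max(row["p_value"], _tiny_p()))
            )
    if missing:
        logger.warning(
            "%d metabolites absent from the association table: %s",
            len(missing), sorted(missing)[:5],
        )
    rows = edges[edges["passes_dual_rule"]] if only_passing else edges
    for _, row in rows.iterrows():
        graph.add_edge(
            row["metabolite_a"],
            row["metabolite_b"],
            pearson_r=float(row["pearson_r"]),
            pearson_p=float(row["pearson_p"]),
            partial_r=float(row["partial_r"]),
            partial_p=float(row["partial_p"]),
        )
    return graph


def _tiny_p() -> float:
    return 1e-300
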