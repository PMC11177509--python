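"""Single-cell association between regional copy-number estimates and MYC counts.

Cancer cells are selected by cell-type label, dichotomized by mean
copy-number estimate over the MCR-overlapping regions, and for each region a
Poisson regression with log link is fitted by IRLS:

    E[count] = exp(b0 + b1 * CN * I(with loss) + b2 * CN * I(without loss))

Wald 95% confidence intervals come from the observed-information covariance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from pmnpipe.exceptions import ValidationError
from pmnpipe.intervals import overlap_len
from pmnpipe.io import CellCNMatrix

__all__ = [
    "PoissonFitResult",
    "WITH_LOSS",
    "WITHOUT_LOSS",
    "select_cancer_cells",
    "classify_cell_mcr_status",
    "fit_poisson_interaction",
    "fit_all_regions",
    "aggregate_mcr_expression_vs_myc",
    "write_fit_results",
]

WITH_LOSS = "WITH_LOSS"
WITHOUT_LOSS = "WITHOUT_LOSS"

DEFAULT_CANCER_LABELS = frozenset({"Cancer stem cells"})


@dataclass
class PoissonFitResult:
    region: tuple[str, int, int]
    beta0: float
    beta1: float
    beta2: float
    ci95_beta0: tuple[float, float]
    ci95_beta1: tuple[float, float]
    ci95_beta2: tuple[float, float]
    converged: bool
    n_cells: int
    loglik: float
    n_iter: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cis = (
            (self.beta0, self.ci95_beta0),
            (self.beta1, self.ci95_beta1),
            (self.beta2, self.ci95_beta2),
        )
        for est, (lo, hi) in cis:
            if not math.isnan(est) and not (lo <= est <= hi):
                raise ValidationError(f"CI ({lo}, {hi}) does not contain estimate {est}")


def select_cancer_cells(
    cn: CellCNMatrix, cancer_labels: frozenset[str] | set[str] = DEFAULT_CANCER_LABELS
) -> CellCNMatrix:
    """Restrict to cells whose type is in ``cancer_labels``."""
    available = sorted(set(cn.cell_type))
    unknown = sorted(set(cancer_labels) - set(available))
    if unknown:
        raise ValidationError(
            f"cell-type labels {unknown} not present; available labels: {available}"
        )
    mask = np.array([t in cancer_labels for t in cn.cell_type])
    if not mask.any():
        raise ValidationError("no cancer cells after filtering")
    return cn.subset_cells(mask)


def classify_cell_mcr_status(
    cn: CellCNMatrix,
    mcr_intervals: Sequence[tuple[str, int, int]],
    loss_threshold: float = -0.05,
) -> np.ndarray:
    """Dichotomize cells by mean CN estimate over MCR-overlapping regions.

    A cell is WITH_LOSS iff its mean estimate across the overlapping regions
    is below ``loss_threshold``.
    """
    idx = [
        i
        for i, (c, s, e) in enumerate(cn.regions)
        if any(c == mc and overlap_len(s, e, ms, me) > 0 for mc, ms, me in mcr_intervals)
    ]
    if not idx:
        raise ValidationError("no CN region overlaps the MCR intervals")
    means = cn.cn_estimates[idx, :].mean(axis=0)
    return np.where(means < loss_threshold, WITH_LOSS, WITHOUT_LOSS)


def _poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float((y * eta - np.exp(eta) - gammaln(y + 1)).sum())


def _irls_poisson(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Poisson/log-link IRLS. Returns (beta, cov, loglik, converged, n_iter)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8))
    ll_old = _poisson_loglik(y, X @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu  # Poisson working weights
        z = eta + (y - mu) / mu
        XtW = X.T * W
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        ll = _poisson_loglik(y, X @ beta)
        if abs(ll - ll_old) <= tol * (abs(ll_old) + tol):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    cov = np.linalg.inv((X.T * mu) @ X)
    return beta, cov, ll_old, converged, it


def fit_poisson_interaction(
    cn: CellCNMatrix,
    status: Sequence[str],
    region_index: int,
    tol: float = 1e-8,
    max_iter: int = 100,
    min_cells_per_group: int = 10,
) -> PoissonFitResult:
    """Fit the per-region Poisson interaction model of MYC counts on CN.

    Design columns: [1, CN * I(WITH_LOSS), CN * I(WITHOUT_LOSS)]. A design
    column that is identically zero (e.g. CN constant at 0) makes its
    coefficient inestimable: the model falls back to the remaining columns
    and the dropped coefficients are NaN with a flag.
    """
    status = np.asarray(status)
    if status.shape[0] != cn.n_cells:
        raise ValidationError("status vector does not match number of cells")
    if not 0 <= region_index < cn.n_regions:
        raise ValidationError(f"region_index {region_index} out of range")
    n_with = int((status == WITH_LOSS).sum())
    n_without = int((status == WITHOUT_LOSS).sum())
    if min(n_with, n_without) < min_cells_per_group:
        raise ValidationError(
            f"need >= {min_cells_per_group} cells per status group "
            f"(got {n_with} WITH_LOSS, {n_without} WITHOUT_LOSS)"
        )

    y = cn.myc_counts.astype(float)
    cnvec = cn.cn_estimates[region_index, :]
    x1 = cnvec * (status == WITH_LOSS)
    x2 = cnvec * (status == WITHOUT_LOSS)
    flags: list[str] = []
    for grp, name in ((status == WITH_LOSS, WITH_LOSS), (status == WITHOUT_LOSS, WITHOUT_LOSS)):
        if y[grp].sum() == 0:
            flags.append(f"separation: all counts zero in {name} group")

    cols = [np.ones_like(y)]
    estimable = [True, False, False]
    if np.any(x1 != 0):
        cols.append(x1)
        estimable[1] = True
    else:
        flags.append("beta1 inestimable: CN*I(with loss) identically zero")
    if np.any(x2 != 0):
        cols.append(x2)
        estimable[2] = True
    else:
        flags.append("beta2 inestimable: CN*I(without loss) identically zero")
    X = np.column_stack(cols)

    beta, cov, ll, converged, n_iter = _irls_poisson(X, y, tol=tol, max_iter=max_iter)
    se = np.sqrt(np.diag(cov))
    zcrit = stats.norm.ppf(0.975)

    full_beta = [float("nan")] * 3
    full_ci = [(float("nan"), float("nan"))] * 3
    j = 0
    for k in range(3):
        if estimable[k]:
            full_beta[k] = float(beta[j])
            full_ci[k] = (float(beta[j] - zcrit * se[j]), float(beta[j] + zcrit * se[j]))
            j += 1
    if not converged:
        flags.append("IRLS did not converge")

    return PoissonFitResult(
        region=cn.regions[region_index],
        beta0=full_beta[0],
        beta1=full_beta[1],
        beta2=full_beta[2],
        ci95_beta0=full_ci[0],
        ci95_beta1=full_ci[1],
        ci95_beta2=full_ci[2],
        converged=converged,
        n_cells=cn.n_cells,
        loglik=ll,
        n_iter=n_iter,
        flags=flags,
    )


def fit_all_regions(
    cn: CellCNMatrix, status: Sequence[str], **kwargs
) -> list[PoissonFitResult]:
    """One Poisson interaction fit per CN region."""
    return [fit_poisson_interaction(cn, status, i, **kwargs) for i in range(cn.n_regions)]


def aggregate_mcr_expression_vs_myc(
    cell_expr: pd.DataFrame,
    mcr_genes: Sequence[str],
    myc_counts: Sequence[int],
    status: Sequence[str],
) -> dict:
    """Aggregate MCR-gene expression per cell vs MYC counts.

    ``cell_expr`` is genes x cells (log-normalized). Reports the Spearman
    correlation between the per-cell mean MCR-gene expression and MYC,
    per-status medians, and per-gene Spearman correlations.
    """
    present = [g for g in mcr_genes if g in cell_expr.index]
    if not present:
        raise ValidationError(f"none of the MCR genes {list(mcr_genes)} found in expression input")
    myc = np.asarray(myc_counts, dtype=float)
    status = np.asarray(status)
    if cell_expr.shape[1] != len(myc) or len(status) != len(myc):
        raise ValidationError("cell expression, counts and status must align")

    agg = cell_expr.loc[present].mean(axis=0).to_numpy()
    rho, p = stats.spearmanr(agg, myc)
    per_status = {
        s: {
            "n": int((status == s).sum()),
            "median_aggregate": float(np.median(agg[status == s])),
            "median_myc": float(np.median(myc[status == s])),
        }
        for s in sorted(set(status.tolist()))
    }
    per_gene = {}
    for g in present:
        gr, gp = stats.spearmanr(cell_expr.loc[g].to_numpy(), myc)
        per_gene[g] = {"spearman_rho": float(gr), "p": float(gp)}
    return {
        "genes_used": present,
        "spearman_rho": float(rho),
        "p": float(p),
        "per_status": per_status,
        "per_gene": per_gene,
    }


def write_fit_results(results: Iterable[PoissonFitResult], path: str) -> None:
    payload = [
        {
            "region": list(r.region),
            "beta0": r.beta0,
            "beta1": r.beta1,
            "beta2": r.beta2,
            "ci95_beta0": list(r.ci95_beta0),
            "ci95_beta1": list(r.ci95_beta1),
            "ci95_beta2": list(r.ci95_beta2),
            "converged": r.converged,
            "n_cells": r.n_cells,
            "loglik": r.loglik,
            "flags": r.flags,
        }
        for r in results
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
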