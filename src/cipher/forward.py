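"""The forward problem: fit perturbation forcings against an observed response.

Linear response couples the mean expression change to the applied forcing
through the unperturbed covariance, Delta X = Sigma u. Given a known perturbed
gene i, the optimal scalar forcing is the least-squares projection onto the
i-th covariance column,

    u_i* = (Sigma_i . Delta X) / (Sigma_i . Sigma_i + eps),

and the fit quality is the coefficient of determination

    R^2 = 1 - ||Delta X - Sigma u||^2 / (||Delta X||^2 + eps)

computed only over genes with nonzero response (exact zeros of the mean
difference are masked out so silent genes cannot dilute the score). eps = 1e-8
regularizes every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .covariance import CovarianceModel
from .data_io import DeltaExpression, align_genes

__all__ = [
    "ForwardResult",
    "NoResponseError",
    "compute_r2",
    "per_gene_r2",
    "optimal_single_perturbation",
    "optimal_subset_perturbation",
    "additive_prediction",
    "baseline_mean_response",
    "cross_covariance_forward",
]

REG_EPS = 1e-8


class NoResponseError(ValueError):
    """Delta X is identically zero on the mask; R^2 is undefined."""


@dataclass
class ForwardResult:
    """A fitted forcing and its predicted response."""

    u: np.ndarray                     # full-length, nonzero only on fitted_indices
    predicted_delta: np.ndarray
    r2: float
    response_mask: np.ndarray
    fitted_indices: list[int]
    reg_eps: float = REG_EPS
    gene_ids: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)
    n_shared_genes: int | None = None  # set by cross-covariance transfer

    @property
    def forcing_values(self) -> np.ndarray:
        return self.u[self.fitted_indices]


def _mask(dx_values: np.ndarray) -> np.ndarray:
    # exact comparison: a gene is silent iff its count sums match exactly
    return dx_values != 0.0


def compute_r2(dx: DeltaExpression | np.ndarray, predicted: np.ndarray,
               reg_eps: float = REG_EPS) -> float:
    """Masked coefficient of determination of a predicted response."""
    values = dx.values if isinstance(dx, DeltaExpression) else np.asarray(dx, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if values.shape != predicted.shape:
        raise ValueError("prediction and response lengths differ")
    mask = _mask(values)
    if not mask.any():
        raise NoResponseError("all genes have exactly zero response")
    resid = values[mask] - predicted[mask]
    return 1.0 - float(resid @ resid) / (float(values[mask] @ values[mask]) + reg_eps)


def per_gene_r2(dx: DeltaExpression | np.ndarray, predicted: np.ndarray,
                reg_eps: float = REG_EPS) -> np.ndarray:
    """Diagnostic per-gene score 1 - (dx_i - pred_i)^2 / (dx_i^2 + eps).

    Non-canonical: a convenience for inspecting which genes a fit explains.
    """
    values = dx.values if isinstance(dx, DeltaExpression) else np.asarray(dx, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return 1.0 - (values - predicted) ** 2 / (values ** 2 + reg_eps)


def _check_aligned(sigma: CovarianceModel, dx: DeltaExpression) -> None:
    if sigma.n_genes != len(dx.gene_ids) or not np.array_equal(sigma.gene_ids, dx.gene_ids):
        raise ValueError("sigma and delta-expression are not gene-aligned; use align_genes")


def optimal_single_perturbation(sigma: CovarianceModel, dx: DeltaExpression,
                                gene_index: int) -> ForwardResult:
    """Optimal scalar forcing on one gene: u_i* = Sigma_i.dX / (Sigma_i.Sigma_i + eps)."""
    _check_aligned(sigma, dx)
    if not 0 <= gene_index < sigma.n_genes:
        raise IndexError(f"gene_index {gene_index} out of range")
    eps = sigma.reg_eps
    col = sigma.column(gene_index)
    denom = float(col @ col)
    warnings_ = []
    if denom == 0.0:
        warnings_.append("degenerate-column")
    ui = float(col @ dx.values) / (denom + eps)
    u = np.zeros(sigma.n_genes)
    u[gene_index] = ui
    predicted = col * ui
    return ForwardResult(
        u=u, predicted_delta=predicted, r2=compute_r2(dx, predicted, eps),
        response_mask=_mask(dx.values), fitted_indices=[gene_index],
        reg_eps=eps, gene_ids=sigma.gene_ids, warnings=warnings_,
    )


def optimal_subset_perturbation(sigma: CovarianceModel, dx: DeltaExpression,
                                gene_indices) -> ForwardResult:
    """Joint least-squares forcing over a gene subset S.

    Solves min_u ||dX - Sigma_S u||^2 over the columns Sigma_S through the
    normal equations with ``reg_eps`` added to the Gram diagonal. The joint
    solve couples the coefficients through off-diagonal covariance entries,
    which is where epistasis lives in this model.
    """
    _check_aligned(sigma, dx)
    requested = [int(i) for i in gene_indices]
    idx = list(dict.fromkeys(requested))
    if len(idx) != len(requested):
        raise ValueError("gene_indices must be distinct")
    if not 1 <= len(idx) <= sigma.n_genes:
        raise ValueError("need between 1 and n_genes indices")
    eps = sigma.reg_eps
    cols = sigma.sigma[:, idx]                      # G x |S|
    gram = cols.T @ cols + eps * np.eye(len(idx))
    rhs = cols.T @ dx.values
    warnings_ = []
    cond = np.linalg.cond(cols.T @ cols) if len(idx) > 1 else None
    if cond is not None and (not np.isfinite(cond) or cond > 1e12):
        warnings_.append("ill-conditioned")
    coeffs = scipy.linalg.solve(gram, rhs, assume_a="pos")
    u = np.zeros(sigma.n_genes)
    u[idx] = coeffs
    predicted = cols @ coeffs
    return ForwardResult(
        u=u, predicted_delta=predicted, r2=compute_r2(dx, predicted, eps),
        response_mask=_mask(dx.values), fitted_indices=idx, reg_eps=eps,
        gene_ids=sigma.gene_ids, warnings=warnings_,
    )


def additive_prediction(sigma: CovarianceModel, dx: DeltaExpression,
                        i: int, j: int) -> ForwardResult:
    """Additive double-perturbation model: independent single-gene optima summed.

    Each coefficient is fit alone against the same dX; the prediction is the
    sum. With collinear columns this double-counts, so the joint fit
    (:func:`optimal_subset_perturbation`) can only do better.
    """
    if i == j:
        raise ValueError("additive prediction needs two distinct genes")
    res_i = optimal_single_perturbation(sigma, dx, i)
    res_j = optimal_single_perturbation(sigma, dx, j)
    u = res_i.u + res_j.u
    predicted = res_i.predicted_delta + res_j.predicted_delta
    return ForwardResult(
        u=u, predicted_delta=predicted, r2=compute_r2(dx, predicted, sigma.reg_eps),
        response_mask=_mask(dx.values), fitted_indices=[i, j], reg_eps=sigma.reg_eps,
        gene_ids=sigma.gene_ids, warnings=res_i.warnings + res_j.warnings,
    )


def baseline_mean_response(dx_a: DeltaExpression, dx_b: DeltaExpression,
                           mode: str = "average") -> DeltaExpression:
    """Null multi-perturbation model: average (or sum) of single responses."""
    if mode not in ("average", "sum"):
        raise ValueError("mode must be 'average' or 'sum'")
    if not np.array_equal(dx_a.gene_ids, dx_b.gene_ids):
        raise ValueError("responses are not gene-aligned; use align_genes")
    combined = dx_a.values + dx_b.values
    if mode == "average":
        combined = combined / 2.0
    return DeltaExpression(
        values=combined, gene_ids=dx_a.gene_ids.copy(),
        perturbation_name=f"{dx_a.perturbation_name}+{dx_b.perturbation_name} ({mode})",
        n_control=min(dx_a.n_control, dx_b.n_control),
        n_perturbed=min(dx_a.n_perturbed, dx_b.n_perturbed),
    )


def cross_covariance_forward(sigma_foreign: CovarianceModel, dx_host: DeltaExpression,
                             gene: int | str) -> ForwardResult:
    """Single-gene forward fit using a covariance transferred from another dataset.

    Both objects are restricted to their shared genes first; ``gene`` may be a
    gene id or an index into the host response. The intersection size is
    reported on the result.
    """
    gene_id = dx_host.gene_ids[gene] if isinstance(gene, (int, np.integer)) else gene
    sig_al, dx_al = align_genes(sigma_foreign, dx_host)
    where = np.where(sig_al.gene_ids == gene_id)[0]
    if len(where) == 0:
        raise ValueError(f"perturbed gene {gene_id!r} is not in the shared gene set")
    result = optimal_single_perturbation(sig_al, dx_al, int(where[0]))
    result.n_shared_genes = sig_al.n_genes
    return result
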