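"""Eigengene (soft-mode) interpretation and gene-contribution accounting.

Diagonalizing the covariance, Sigma = V Lambda V', yields eigengenes —
orthogonal co-expression modules ordered by explained variance. A response
dX is interpreted through its projections alpha_i = v_i . dX: the normalized
squared projections say *where* the response lives, the participation ratio
(sum alpha^2)^2 / sum alpha^4 says in how many modes, and the contribution
fractions c_i = sum_j |Sigma_ij u_j| say which genes carry it (absolute
summands, so cancellation between positive and negative correlations is
counted as work done, not hidden).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd

from .covariance import CovarianceModel
from .data_io import DeltaExpression

__all__ = [
    "EigenDecomposition",
    "ResponseProjection",
    "ContributionProfile",
    "eigendecompose",
    "project_response",
    "participation_ratio",
    "top_loading_genes",
    "contribution_fractions",
    "entropy_effective_size",
    "EnrichmentBackend",
    "StaticEnrichmentBackend",
]

DEFAULT_N_COMPONENTS = 30  # projections default to the top 30 eigengenes


@dataclass
class EigenDecomposition:
    eigenvalues: np.ndarray       # non-increasing
    eigenvectors: np.ndarray      # orthonormal columns, G x G
    gene_ids: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def explained_variance_ratio(self) -> np.ndarray:
        lam = np.clip(self.eigenvalues, 0.0, None)
        return lam / lam.sum()


@dataclass
class ResponseProjection:
    alpha: np.ndarray             # projection coefficients on the K retained modes
    alpha_tilde_sq: np.ndarray    # normalized squared projections (sum to 1 at K = G)
    participation_ratio: float
    n_components_99: int


@dataclass
class ContributionProfile:
    c: np.ndarray                 # absolute propagated contribution per gene
    f_global: np.ndarray
    f_target: np.ndarray
    eff_genes_global: float
    eff_genes_target: float
    self_rank: int
    target_gene: int


def eigendecompose(sigma: CovarianceModel) -> EigenDecomposition:
    """Symmetric eigendecomposition, modes sorted by descending eigenvalue.

    Sign convention: each eigenvector's largest-|loading| entry is made
    positive (ties broken toward the lexicographically smallest gene id).
    """
    S = sigma.sigma
    scale = max(1.0, float(np.abs(S).max(initial=0.0)))
    if np.abs(S - S.T).max(initial=0.0) > 1e-8 * scale:
        raise ValueError("sigma is not symmetric")
    lam, V = np.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    for k in range(V.shape[1]):
        col = V[:, k]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            V[:, k] = -col
    return EigenDecomposition(eigenvalues=lam, eigenvectors=V,
                              gene_ids=sigma.gene_ids.copy())


def participation_ratio(alpha) -> float:
    """Effective number of active components: (sum a^2)^2 / sum a^4.

    Evaluates to 1 for a single nonzero entry and to K when all K entries
    have equal magnitude; invariant under global rescaling.
    """
    a = np.abs(np.asarray(alpha, dtype=float))
    peak = a.max(initial=0.0)
    if peak == 0:
        raise ValueError("participation ratio of the zero vector is undefined")
    a2 = (a / peak) ** 2    # scale out the magnitude to avoid under/overflow
    total = a2.sum()
    return float(total ** 2 / (a2 @ a2))


def project_response(eig: EigenDecomposition, dx: DeltaExpression | np.ndarray,
                     K: int = DEFAULT_N_COMPONENTS) -> ResponseProjection:
    """Project a response onto the top-K eigengenes.

    alpha_i = v_i . dX; alpha~_i^2 normalizes over the K retained components;
    n_components_99 is the smallest m whose cumulative alpha~^2 reaches 0.99.
    """
    values = dx.values if isinstance(dx, DeltaExpression) else np.asarray(dx, dtype=float)
    if isinstance(dx, DeltaExpression) and not np.array_equal(eig.gene_ids, dx.gene_ids):
        raise ValueError("eigendecomposition and response are not gene-aligned")
    G = eig.n_genes
    if not 1 <= K <= G:
        raise ValueError(f"K must be in [1, {G}]")
    if not values.any():
        raise ValueError("zero response: projection normalization undefined")
    alpha = eig.eigenvectors[:, :K].T @ values
    a2 = alpha ** 2
    alpha_tilde_sq = a2 / a2.sum()
    cum = np.cumsum(alpha_tilde_sq)
    n99 = int(np.searchsorted(cum, 0.99 - 1e-12) + 1)
    return ResponseProjection(
        alpha=alpha, alpha_tilde_sq=alpha_tilde_sq,
        participation_ratio=participation_ratio(alpha),
        n_components_99=n99,
    )


def top_loading_genes(eig: EigenDecomposition, component: int, top_n: int = 200) -> list[str]:
    """Gene ids with the highest absolute loadings on one eigengene.

    Deterministic: |loading| descending, ties broken by gene id. ``top_n`` is
    clipped to the number of genes.
    """
    if not 0 <= component < eig.n_genes:
        raise IndexError("component out of range")
    top_n = min(top_n, eig.n_genes)
    # round away float noise so exact-by-construction ties break by gene id
    loadings = np.round(np.abs(eig.eigenvectors[:, component]), 12)
    order = sorted(range(eig.n_genes), key=lambda i: (-loadings[i], eig.gene_ids[i]))
    return [eig.gene_ids[i] for i in order[:top_n]]


def entropy_effective_size(f) -> float:
    """exp(Shannon entropy) of a probability vector, with 0 log 0 := 0."""
    f = np.asarray(f, dtype=float)
    if (f < 0).any():
        raise ValueError("probability vector has negative entries")
    total = f.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError("probability vector must sum to 1 (within 1e-9)")
    f = f / total
    nz = f[f > 0]
    return float(np.exp(-(nz * np.log(nz)).sum()))


def contribution_fractions(sigma: CovarianceModel, u, target_gene: int) -> ContributionProfile:
    """Per-gene contribution accounting for a forcing vector u.

    c_i = sum_j |Sigma_ij u_j| is the absolute propagated contribution to gene
    i (>= |dX_i|, with equality when no cancellation occurs); f_global
    normalizes c, f_target normalizes the summands of the target gene's own
    row, and self_rank is the target's position within descending f_target
    (ties broken by gene id).
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (sigma.n_genes,):
        raise ValueError("u length must match sigma dimension")
    if not u.any():
        raise ValueError("u is identically zero")
    if not 0 <= target_gene < sigma.n_genes:
        raise IndexError("target_gene out of range")
    absorbed = np.abs(sigma.sigma * u[None, :])   # |Sigma_ij u_j|
    c = absorbed.sum(axis=1)
    if c.sum() == 0:
        raise ValueError("all contributions are zero")
    f_global = c / c.sum()
    row = absorbed[target_gene]
    if row.sum() == 0:
        raise ValueError("target gene receives no contribution")
    f_target = row / row.sum()
    order = sorted(range(sigma.n_genes), key=lambda j: (-f_target[j], sigma.gene_ids[j]))
    self_rank = order.index(target_gene) + 1
    return ContributionProfile(
        c=c, f_global=f_global, f_target=f_target,
        eff_genes_global=entropy_effective_size(f_global),
        eff_genes_target=entropy_effective_size(f_target),
        self_rank=self_rank, target_gene=target_gene,
    )


# ---------------------------------------------------------------------------
# enrichment hook (no network client bundled)
# ---------------------------------------------------------------------------

class EnrichmentBackend(Protocol):
    """Pluggable functional-enrichment interface: gene list in, term table out."""

    def enrich(self, genes: list[str]) -> pd.DataFrame:  # pragma: no cover
        ...


class StaticEnrichmentBackend:
    """Offline stub backend mapping terms to fixed gene sets (for tests/pipelines).

    Scores each term by the hypergeometric-free overlap fraction
    |query & term| / |term|; no p-values are computed.
    """

    def __init__(self, term_to_genes: dict[str, set[str]]):
        self.term_to_genes = {t: set(g) for t, g in term_to_genes.items()}

    def enrich(self, genes: list[str]) -> pd.DataFrame:
        query = set(genes)
        rows = [
            {"term": term, "overlap": len(query & members), "size": len(members),
             "score": len(query & members) / len(members) if members else 0.0}
            for term, members in sorted(self.term_to_genes.items())
        ]
        return pd.DataFrame(rows)
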