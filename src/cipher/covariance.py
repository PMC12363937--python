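"""Gene-gene covariance estimation and its null models.

The covariance Sigma of raw counts over unperturbed cells is the workhorse of
linear response: Delta X ~= Sigma u. Three nulls probe how much of the
predictive power lives in the off-diagonal structure:

* mean-field: each gene column permuted independently over cells (marginals
  preserved exactly, covariance scrambled);
* shuffled: a global permutation over both cells and genes (everything
  scrambled);
* ZINB: per-gene zero-inflated negative binomial refits with a freshly drawn
  variance, resampled independently per gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "CovarianceModel",
    "ZinbFit",
    "InsufficientCellsError",
    "ZinbPathologicalError",
    "estimate_covariance",
    "meanfield_shuffle",
    "full_shuffle",
    "fit_zinb",
    "zinb_resample_covariance",
]

PROVENANCES = ("real", "meanfield", "shuffled", "zinb")


class InsufficientCellsError(ValueError):
    """Fewer than two cells: a sample covariance is undefined."""


class ZinbPathologicalError(RuntimeError):
    """Every gene's ZINB fit was degenerate; the variance-resampled null is undefined."""


@dataclass
class CovarianceModel:
    """A gene-gene covariance matrix with provenance.

    ``reg_eps`` is the scalar regularizer (default 1e-8) added to
    denominators/Gram diagonals downstream to avoid division by zero.
    """

    sigma: np.ndarray
    gene_ids: np.ndarray
    provenance: str = "real"
    reg_eps: float = 1e-8
    n_cells_used: int = 0

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.sigma.ndim != 2 or self.sigma.shape[0] != self.sigma.shape[1]:
            raise ValueError("sigma must be square")
        if len(self.gene_ids) != self.sigma.shape[0]:
            raise ValueError("gene_ids length must match sigma dimension")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        scale = max(1.0, float(np.abs(self.sigma).max(initial=0.0)))
        if np.abs(self.sigma - self.sigma.T).max(initial=0.0) > 1e-8 * scale:
            raise ValueError("sigma is not symmetric")
        if np.diag(self.sigma).min(initial=0.0) < -1e-12 * scale:
            raise ValueError("sigma has negative diagonal entries")

    @property
    def n_genes(self) -> int:
        return self.sigma.shape[0]

    def column(self, i: int) -> np.ndarray:
        return self.sigma[:, i]


def _default_gene_ids(n: int) -> np.ndarray:
    return np.asarray([f"gene_{i:04d}" for i in range(n)], dtype=object)


def estimate_covariance(control_counts, gene_ids=None,
                        provenance: str = "real", reg_eps: float = 1e-8) -> CovarianceModel:
    """Sample covariance of a cells x genes matrix (unbiased, n-1 denominator).

    Sparse input is handled through the moment identity
    ``Cov = (X'X - n mu mu') / (n - 1)`` so the matrix is never densified
    cell-wise.
    """
    if sp.issparse(control_counts):
        X = control_counts.tocsr()
        n = X.shape[0]
        if n < 2:
            raise InsufficientCellsError("need at least 2 cells to estimate a covariance")
        mu = np.asarray(X.mean(axis=0)).ravel()
        gram = np.asarray((X.T @ X).todense(), dtype=float)
        sigma = (gram - n * np.outer(mu, mu)) / (n - 1)
        sigma = (sigma + sigma.T) / 2.0
    else:
        X = np.asarray(control_counts, dtype=float)
        if X.ndim != 2:
            raise ValueError("control_counts must be 2-D (cells x genes)")
        n = X.shape[0]
        if n < 2:
            raise InsufficientCellsError("need at least 2 cells to estimate a covariance")
        sigma = np.cov(X, rowvar=False, ddof=1)
        sigma = np.atleast_2d(sigma)
    if gene_ids is None:
        gene_ids = _default_gene_ids(sigma.shape[0])
    return CovarianceModel(sigma, gene_ids, provenance=provenance,
                           reg_eps=reg_eps, n_cells_used=n)


def _dense(counts) -> np.ndarray:
    return counts.toarray() if sp.issparse(counts) else np.array(counts, dtype=float)


def meanfield_shuffle(control_counts, rng: np.random.Generator) -> np.ndarray:
    """Permute each gene column independently over cells.

    Per-gene marginals (hence means and variances) are preserved exactly,
    while the gene-gene covariance is scrambled.
    """
    X = _dense(control_counts)
    if X.shape[0] < 2:
        raise InsufficientCellsError("need at least 2 cells")
    return rng.permuted(X, axis=0)


def full_shuffle(control_counts, rng: np.random.Generator) -> np.ndarray:
    """Permute all entries across both cells and genes (global multiset preserved)."""
    X = _dense(control_counts)
    if X.shape[0] < 2:
        raise InsufficientCellsError("need at least 2 cells")
    flat = X.ravel().copy()
    rng.shuffle(flat)
    return flat.reshape(X.shape)


# ---------------------------------------------------------------------------
# ZINB variance-resampled control
# ---------------------------------------------------------------------------

@dataclass
class ZinbFit:
    """Intercept-only zero-inflated negative binomial fit of one gene's counts.

    ``mean``/``variance`` are the moments of the full ZINB mixture;
    ``nb_mean``/``size`` parameterize the NB component (variance
    ``nb_mean + nb_mean**2 / size``); ``zero_inflation`` is the structural-zero
    probability. Degenerate fits carry no resampling rights.
    """

    mean: float = np.nan
    variance: float = np.nan
    zero_inflation: float = np.nan
    nb_mean: float = np.nan
    size: float = np.nan
    fit_status: str = "degenerate"

    @property
    def dispersion(self) -> float:
        """NB dispersion alpha = 1/size (variance = mu + alpha mu^2)."""
        return 1.0 / self.size if self.size > 0 else np.nan


def _zinb_moments(pi: float, mu: float, size: float) -> tuple[float, float]:
    nb_var = mu + mu * mu / size
    mean = (1.0 - pi) * mu
    var = (1.0 - pi) * (nb_var + pi * mu * mu)
    return mean, var


def fit_zinb(x: np.ndarray) -> ZinbFit:
    """Maximum-likelihood intercept-only ZINB fit (statsmodels backend).

    Returns a degenerate fit on all-zero columns, zero-variance columns, or
    optimizer failure.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2 or not np.all(np.isfinite(x)):
        return ZinbFit()
    m, v = float(x.mean()), float(x.var(ddof=1))
    if m <= 0 or v <= 0:
        return ZinbFit()
    try:
        import statsmodels.api as sm

        exog = np.ones((x.size, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.ZeroInflatedNegativeBinomialP(x, exog, exog_infl=exog, p=2)
            # method-of-moments style start: logit(small pi), log mean, alpha.
            # Nelder-Mead: the likelihood is flat in alpha near equidispersion
            # and gradient methods diverge there.
            alpha0 = max((v - m) / (m * m), 1e-2)
            res = model.fit(start_params=np.array([-2.0, np.log(m), alpha0]),
                            method="nm", maxiter=2000, disp=0)
        if not res.mle_retvals.get("converged", False):
            return ZinbFit()
        infl_const, log_mu, alpha = res.params
        pi = 1.0 / (1.0 + np.exp(-infl_const))
        mu = float(np.exp(log_mu))
        if not np.isfinite(mu) or not np.isfinite(pi) or not np.isfinite(alpha):
            return ZinbFit()
        alpha = max(float(alpha), 1e-8)  # boundary fits are Poisson-like, not invalid
        size = 1.0 / float(alpha)
        mean, var = _zinb_moments(pi, mu, size)
        return ZinbFit(mean=mean, variance=var, zero_inflation=float(pi),
                       nb_mean=mu, size=size, fit_status="ok")
    except Exception:
        return ZinbFit()


def _sample_zinb(n: int, pi: float, mu: float, size: float,
                 rng: np.random.Generator) -> np.ndarray:
    p = size / (size + mu)  # numpy's negative_binomial success probability
    x = rng.negative_binomial(size, p, size=n).astype(float)
    x[rng.random(n) < pi] = 0.0
    return x


def _size_for_variance(pi: float, mu: float, target_var: float) -> float | None:
    """Solve for the NB size giving the ZINB the target variance (mean, pi fixed)."""
    if pi >= 1.0:
        return None
    nb_var_target = target_var / (1.0 - pi) - pi * mu * mu
    excess = nb_var_target - mu
    if excess <= 0:  # sub-NB variance unreachable without breaking the mean
        return None
    return mu * mu / excess


def zinb_resample_covariance(control_counts, rng: np.random.Generator,
                             gene_ids=None, reg_eps: float = 1e-8,
                             variance_strategy: str = "bootstrap"):
    """Variance-perturbed ZINB null covariance.

    Each gene's counts are fit to a ZINB; a new variance is drawn for the gene
    (``'bootstrap'``: refit on one parametric resample and take that fit's
    implied variance), the NB size is re-solved to hit the new variance while
    keeping the fitted mean and zero-inflation, and the gene's counts are
    resampled independently. Genes whose re-parameterization is infeasible are
    flagged degenerate and kept as observed. Raises
    :class:`ZinbPathologicalError` when every gene is degenerate.
    """
    if variance_strategy != "bootstrap":
        raise ValueError("only the 'bootstrap' variance strategy is implemented")
    X = _dense(control_counts)
    n, g = X.shape
    if n < 2:
        raise InsufficientCellsError("need at least 2 cells")
    out = X.copy()
    fits: list[ZinbFit] = []
    n_ok = 0
    for j in range(g):
        fit = fit_zinb(X[:, j])
        if fit.fit_status == "ok":
            boot = _sample_zinb(n, fit.zero_inflation, fit.nb_mean, fit.size, rng)
            refit = fit_zinb(boot)
            new_var = refit.variance if refit.fit_status == "ok" else np.nan
            size_new = (_size_for_variance(fit.zero_inflation, fit.nb_mean, new_var)
                        if np.isfinite(new_var) else None)
            if size_new is not None:
                out[:, j] = _sample_zinb(n, fit.zero_inflation, fit.nb_mean, size_new, rng)
                n_ok += 1
            else:
                fit = ZinbFit(mean=fit.mean, variance=fit.variance,
                              zero_inflation=fit.zero_inflation, nb_mean=fit.nb_mean,
                              size=fit.size, fit_status="degenerate")
        fits.append(fit)
    if n_ok == 0:
        raise ZinbPathologicalError(
            "all gene ZINB fits were degenerate; dataset cannot support the "
            "variance-resampled control"
        )
    model = estimate_covariance(out, gene_ids=gene_ids, provenance="zinb", reg_eps=reg_eps)
    return model, fits
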