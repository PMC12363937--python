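"""Composed simulation experiments used for validation and reporting.

These tie the simulators, covariance estimators and forward solvers together
into the standard validation protocols: the criticality sweep of the random
linear network (how the variability of linear-response estimates grows toward
and past the May threshold) and the covariance-ablation comparison (how much
predictive power each null covariance destroys on a screen-like dataset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .covariance import estimate_covariance, full_shuffle, meanfield_shuffle
from .data_io import (
    DeltaExpression,
    ExpressionDataset,
    delta_expression,
    normalize_perturbation_labels,
)
from .forward import optimal_single_perturbation
from .simulate import (
    LinearNetworkParams,
    critical_coupling,
    sample_interaction_matrix,
    simulate_linear_network,
)

__all__ = [
    "CriticalityResult",
    "criticality_sweep",
    "forward_r2_by_provenance",
    "compare_null_r2",
]


@dataclass
class CriticalityResult:
    """Per-replicate estimate variability and error across coupling regimes."""

    table: pd.DataFrame            # columns: eps_frac, replicate, cv, rel_error
    p_sub_lt_crit: float
    p_crit_lt_super: float


def _replicate_stats(eps_frac: float, replicate: int, n_genes: int,
                     n_forced_runs: int, forcing: float,
                     base_seed: int) -> tuple[float, float]:
    """CV of the fitted forcing across repeated forced runs, plus mean rel. error."""
    eps = eps_frac * critical_coupling(n_genes)
    tag = int(eps_frac * 100)
    A = sample_interaction_matrix(
        n_genes, eps, np.random.default_rng((base_seed, 0, tag, replicate)))
    u = np.zeros(n_genes)
    u[0] = forcing
    ctrl = simulate_linear_network(
        LinearNetworkParams(n_genes=n_genes, epsilon=eps,
                            seed=abs(hash((base_seed, 1, tag, replicate))) % 2**31),
        A=A)
    sigma = estimate_covariance(ctrl.stationary_states())
    m0 = ctrl.stationary_mean()
    fitted = np.empty(n_forced_runs)
    errors = np.empty(n_forced_runs)
    for r in range(n_forced_runs):
        forced = simulate_linear_network(
            LinearNetworkParams(n_genes=n_genes, epsilon=eps,
                                seed=abs(hash((base_seed, 2, tag, replicate, r))) % 2**31),
            forcing=u, A=A)
        dx = DeltaExpression(forced.stationary_mean() - m0, sigma.gene_ids,
                             "forced", 1, 1)
        res = optimal_single_perturbation(sigma, dx, 0)
        fitted[r] = res.u[0]
        errors[r] = 1.0 - res.r2
    cv = float(np.std(fitted, ddof=1) / max(abs(np.mean(fitted)), 1e-300))
    return cv, float(np.mean(errors))


def criticality_sweep(n_genes: int = 50, n_replicates: int = 50,
                      n_forced_runs: int = 16, forcing: float = 1.0,
                      eps_fracs: tuple[float, float, float] = (0.95, 1.0, 1.05),
                      seed: int = 0) -> CriticalityResult:
    """Variability of linear-response estimates below, at and above criticality.

    For each coupling regime (fractions of the May threshold eps_c = 1/sqrt(N))
    and each network replicate, the forcing on gene 0 is re-fitted on
    ``n_forced_runs`` independent forced simulations against one unforced run's
    covariance; the replicate statistic is the coefficient of variation of the
    fitted forcing (the estimate is stable in the linear regime and erratic at
    and beyond the bifurcation). One-sided Mann-Whitney tests compare
    consecutive regimes. The mean masked relative error is recorded alongside
    as a diagnostic.
    """
    rows = []
    for frac in eps_fracs:
        for rep in range(n_replicates):
            cv, err = _replicate_stats(frac, rep, n_genes, n_forced_runs,
                                       forcing, seed)
            rows.append({"eps_frac": frac, "replicate": rep, "cv": cv,
                         "rel_error": err})
    table = pd.DataFrame(rows)
    groups = [table.loc[table["eps_frac"] == f, "cv"].to_numpy() for f in eps_fracs]
    p1 = float(scipy.stats.mannwhitneyu(groups[0], groups[1], alternative="less").pvalue)
    p2 = float(scipy.stats.mannwhitneyu(groups[1], groups[2], alternative="less").pvalue)
    return CriticalityResult(table=table, p_sub_lt_crit=p1, p_crit_lt_super=p2)


def forward_r2_by_provenance(ds: ExpressionDataset, rng: np.random.Generator,
                             provenances: tuple[str, ...] = ("real", "meanfield", "shuffled"),
                             ) -> pd.DataFrame:
    """Per-perturbation forward R^2 under the real and shuffled covariances.

    The perturbation label must name its target gene (guide suffixes already
    stripped). Returns a tidy frame with one row per (perturbation,
    provenance).
    """
    ctrl = ds.control_counts()
    sigmas = {}
    for prov in provenances:
        if prov == "real":
            counts = ctrl
        elif prov == "meanfield":
            counts = meanfield_shuffle(ctrl, rng)
        elif prov == "shuffled":
            counts = full_shuffle(ctrl, rng)
        else:
            raise ValueError(f"unknown provenance {prov!r}")
        sigmas[prov] = estimate_covariance(counts, gene_ids=ds.gene_ids,
                                           provenance=prov)
    pos = {g: i for i, g in enumerate(ds.gene_ids)}
    rows = []
    for pert in ds.perturbation_names():
        target = normalize_perturbation_labels([pert], ds.control_label)[0]
        if target not in pos:
            continue
        dx = delta_expression(ds, pert)
        for prov, sigma in sigmas.items():
            res = optimal_single_perturbation(sigma, dx, pos[target])
            rows.append({"perturbation": pert, "provenance": prov, "r2": res.r2,
                         "n_masked": int(res.response_mask.sum())})
    return pd.DataFrame(rows)


def compare_null_r2(ds: ExpressionDataset, rng: np.random.Generator) -> pd.DataFrame:
    """Real-vs-null R^2 distributions with KS and one-sided signed-rank tests.

    Mirrors the standard ablation report: for each null covariance, the
    two-sample Kolmogorov-Smirnov statistic against the real-covariance R^2
    distribution and the one-sided Wilcoxon signed-rank p-value (alternative:
    real > null) over paired perturbations.
    """
    table = forward_r2_by_provenance(ds, rng)
    real = table.loc[table["provenance"] == "real"].set_index("perturbation")["r2"]
    rows = []
    for prov in ("meanfield", "shuffled"):
        null = table.loc[table["provenance"] == prov].set_index("perturbation")["r2"]
        null = null.reindex(real.index)
        ks = scipy.stats.ks_2samp(real.to_numpy(), null.to_numpy())
        if len(real) >= 2 and not np.allclose(real.to_numpy(), null.to_numpy()):
            wil = scipy.stats.wilcoxon(real.to_numpy(), null.to_numpy(),
                                       alternative="greater")
            w_p = float(wil.pvalue)
        else:
            w_p = np.nan
        rows.append({"null": prov, "mean_r2_real": float(real.mean()),
                     "mean_r2_null": float(null.mean()),
                     "ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue),
                     "wilcoxon_pvalue_real_gt_null": w_p})
    return pd.DataFrame(rows)
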