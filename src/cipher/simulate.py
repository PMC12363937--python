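"""Ground-truth regulatory-network simulators and analytic oracles.

Three generators with known ground truth exercise the linear-response
machinery end to end:

* a random linear network dx = -A x dt + sqrt(2 D dt) xi with A = I + eps K,
  K off-diagonal standard normal — stable below the May threshold
  eps_c = 1/sqrt(N);
* a deterministic Hill network F_i(x) = -gamma x_i + sum_j G_ij x_j^n /
  (K^n + x_j^n), solved to its fixed point by gradient flow, with an analytic
  Jacobian for linear-response comparisons and a closed-form critical
  homogeneous interaction G*;
* a stochastic hybrid "teams" network of bursty promoters, where genes on the
  same team activate each other and teams mutually inhibit, producing a
  collective bistable switch.

Analytic oracles: the continuous-time Lyapunov equation J S + S J' = -2D for
stationary covariances, its rank-1 soft-mode approximation with higher-mode
corrections, and the negative-binomial moments of the two-state bursting
promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg
import scipy.optimize

from .covariance import CovarianceModel, estimate_covariance
from .data_io import ExpressionDataset

__all__ = [
    "LinearNetworkParams",
    "HillNetworkParams",
    "TeamsNetworkParams",
    "Trajectory",
    "SoftModeApprox",
    "BurstMoments",
    "NotHurwitzError",
    "critical_coupling",
    "sample_interaction_matrix",
    "simulate_linear_network",
    "solve_lyapunov",
    "soft_mode_covariance",
    "hill_force",
    "hill_fixed_point",
    "hill_jacobian",
    "hill_linear_response_error",
    "hill_critical_interaction",
    "simulate_teams_network",
    "trajectory_covariance",
    "burst_model_moments",
    "make_perturbation_fixture",
]

_OVERFLOW_GUARD = 1e9


class NotHurwitzError(ValueError):
    """The Jacobian has an eigenvalue with non-negative real part."""


# ---------------------------------------------------------------------------
# parameters & trajectory container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearNetworkParams:
    """Random linear network around a stationary fixed point (drift -A x)."""

    n_genes: int
    epsilon: float
    diffusion: float = 0.5
    dt: float = 0.1
    total_time: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.total_time <= self.dt:
            raise ValueError("need dt > 0 and total_time > dt")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class HillNetworkParams:
    """Deterministic Hill-regulation network solved by gradient flow."""

    n_genes: int = 10
    g_mean: float = 1.0
    g_sd: float = 0.1
    K: float = 10.0
    n: float = 4.0
    gamma: float = 1.0
    dt: float = 0.01
    max_iter: int = 2000
    tol: float = 1e-12
    seed: int = 0
    init_abundance: float = 10.0  # homogeneous initial guess

    def __post_init__(self) -> None:
        if self.K <= 0 or self.gamma <= 0 or self.n < 0:
            raise ValueError("need K > 0, gamma > 0, n >= 0")

    def interaction_matrix(self) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        return rng.normal(self.g_mean, self.g_sd, size=(self.n_genes, self.n_genes))


@dataclass(frozen=True)
class TeamsNetworkParams:
    """Two mutually-inhibiting teams of bursty genes (stochastic hybrid model)."""

    n_genes: int = 20           # two teams of n_genes // 2
    b_on_scale: float = 0.3
    b_off_scale: float = 0.25
    b_noise_sd: float = 0.45
    K: float = 25.0
    hill_n: float = 2.0
    beta: float = 50.0
    gamma: float = 4.0
    sparsity: float = 0.7
    dt: float = 0.1
    total_time: float = 2e6
    seed: int = 0
    record_every: int = 100     # thin the stored trajectory
    burn_in_frac: float = 0.1
    #: basal (leaky) promoter switching rate added to k_on and k_off. Without
    #: it the all-one-team-on state is absorbing (every Hill-modulated rate
    #: vanishes once the losing team decays to zero) and the collective
    #: bistable toggling cannot occur; ~50x slower than the driven rates.
    basal_rate: float = 0.005

    def __post_init__(self) -> None:
        if not 0 <= self.sparsity <= 1:
            raise ValueError("sparsity must be in [0, 1]")
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        if self.n_genes % 2:
            raise ValueError("n_genes must be even (two equal teams)")


@dataclass
class Trajectory:
    """Time-indexed gene-state record from a simulator."""

    times: np.ndarray
    states: np.ndarray                      # steps x n_genes
    burn_in_index: int
    seed: int
    promoter_states: np.ndarray | None = None
    unstable: bool = False

    def __post_init__(self) -> None:
        if self.burn_in_index >= len(self.times):
            raise ValueError("burn_in_index must be < number of recorded steps")

    @property
    def n_genes(self) -> int:
        return self.states.shape[1]

    def stationary_states(self) -> np.ndarray:
        return self.states[self.burn_in_index:]

    def stationary_mean(self) -> np.ndarray:
        return self.stationary_states().mean(axis=0)


# ---------------------------------------------------------------------------
# random linear network
# ---------------------------------------------------------------------------

def critical_coupling(n_genes: int) -> float:
    """May stability threshold for A = I + eps K: eps_c = 1 / sqrt(N)."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    return 1.0 / np.sqrt(n_genes)


def sample_interaction_matrix(n: int, epsilon: float, rng: np.random.Generator) -> np.ndarray:
    """A = I + eps K with K off-diagonal standard normal (zero diagonal)."""
    if n < 2:
        raise ValueError("need at least 2 genes")
    K = rng.standard_normal((n, n))
    np.fill_diagonal(K, 0.0)
    return np.eye(n) + epsilon * K


def simulate_linear_network(params: LinearNetworkParams, forcing=None,
                            A: np.ndarray | None = None) -> Trajectory:
    """Euler-Maruyama integration of dx = (-A x + forcing) dt + sqrt(2 D dt) xi.

    Starts from the stationary state x = 0. A pre-sampled interaction matrix
    may be supplied so paired (control, forced) runs share a network; the same
    seed then differs only through the noise stream. States exceeding the
    overflow guard (1e9) truncate the run and flag it unstable — expected
    supercritically.
    """
    rng = np.random.default_rng(params.seed)
    if A is None:
        A = sample_interaction_matrix(params.n_genes, params.epsilon, rng)
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    u = np.zeros(n) if forcing is None else np.asarray(forcing, dtype=float)
    n_steps = int(round(params.total_time / params.dt))
    noise_scale = np.sqrt(2.0 * params.diffusion * params.dt)

    states = np.empty((n_steps + 1, n))
    states[0] = 0.0
    x = states[0].copy()
    unstable = False
    for t in range(1, n_steps + 1):
        x = x + (u - A @ x) * params.dt + noise_scale * rng.standard_normal(n)
        if np.abs(x).max() > _OVERFLOW_GUARD:
            states = states[:t]
            unstable = True
            break
        states[t] = x
    times = np.arange(states.shape[0]) * params.dt
    # discard the initial transient (relaxation from x=0) before stationarity
    burn_in = min(states.shape[0] - 1, max(1, states.shape[0] // 10))
    return Trajectory(times=times, states=states, burn_in_index=burn_in,
                      seed=params.seed, unstable=unstable)


# ---------------------------------------------------------------------------
# Lyapunov oracle & soft-mode approximation
# ---------------------------------------------------------------------------

def solve_lyapunov(J: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Stationary covariance of the linearized Langevin system.

    Solves J S + S J' = -2 D for stable J; the unique solution is symmetric
    PSD when D is.
    """
    J = np.asarray(J, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.max(np.linalg.eigvals(J).real) >= 0:
        raise NotHurwitzError("J has an eigenvalue with non-negative real part")
    sigma = scipy.linalg.solve_continuous_lyapunov(J, -2.0 * D)
    return (sigma + sigma.T) / 2.0


@dataclass
class SoftModeApprox:
    """Rank-1 soft-mode covariance with correction diagnostics."""

    dominant_eigenvalue: complex
    right_vector: np.ndarray
    left_vector: np.ndarray
    sigma_rank1: np.ndarray
    correction_norm: float
    gap_ratio: float
    no_spectral_gap: bool


def soft_mode_covariance(J: np.ndarray, D: np.ndarray,
                         gap_warning_ratio: float = 2.0) -> SoftModeApprox:
    """Leading soft-mode approximation Sigma^(0) = -D~_dd / (2 lambda_d) p p'.

    The dominant (slowest) mode is the eigenvalue of J with smallest |Re|;
    D~ = P^-1 D P^-H is the diffusion in the eigenbasis. The correction norm is
    ||Sigma_Lyapunov - Sigma^(0)||_F / ||Sigma_Lyapunov||_F, small when the
    spectral gap is large. A gap ratio below ``gap_warning_ratio`` (or a
    complex dominant pair) raises the no-spectral-gap flag.
    """
    J = np.asarray(J, dtype=float)
    D = np.asarray(D, dtype=float)
    sigma_full = solve_lyapunov(J, D)
    lam, P = np.linalg.eig(J)
    Pinv = np.linalg.inv(P)
    order = np.argsort(np.abs(lam.real))
    d = order[0]
    lam_d = lam[d]
    gap_ratio = float(np.abs(lam[order[1]].real) / max(np.abs(lam_d.real), 1e-300))
    degenerate_pair = bool(abs(lam_d.imag) > 0)
    D_tilde = Pinv @ D @ Pinv.conj().T
    p_d = P[:, d]
    p_d = p_d / np.linalg.norm(p_d)
    q_d = Pinv[d, :].conj()
    q_d = q_d / np.linalg.norm(q_d)
    # D~ recomputed for the normalized right vector so the rank-1 term is scale-free.
    # Noise convention <eta eta'> = 2D gives J S + S J' = -2D, hence the mode
    # amplitude -2 D~_dd / (2 lambda_d) = -D~_dd / lambda_d.
    scale = np.linalg.norm(P[:, d])
    dtdd = D_tilde[d, d] * scale ** 2
    sigma_rank1 = np.real(-dtdd / lam_d * np.outer(p_d, p_d.conj()))
    sigma_rank1 = (sigma_rank1 + sigma_rank1.T) / 2.0
    corr = np.linalg.norm(sigma_full - sigma_rank1) / np.linalg.norm(sigma_full)
    return SoftModeApprox(
        dominant_eigenvalue=lam_d,
        right_vector=np.real_if_close(p_d),
        left_vector=np.real_if_close(q_d),
        sigma_rank1=sigma_rank1,
        correction_norm=float(corr),
        gap_ratio=gap_ratio,
        no_spectral_gap=bool(degenerate_pair or gap_ratio < gap_warning_ratio),
    )


# ---------------------------------------------------------------------------
# Hill network
# ---------------------------------------------------------------------------

def _hill(x: np.ndarray, K: float, n: float) -> np.ndarray:
    if n == 0:
        return np.full_like(np.asarray(x, dtype=float), 0.5)
    xn = np.power(np.maximum(x, 0.0), n)
    return xn / (K ** n + xn)


def hill_force(x: np.ndarray, G: np.ndarray, params: HillNetworkParams,
               forcing=None) -> np.ndarray:
    """F_i(x) = -gamma x_i + sum_j G_ij h(x_j) + forcing_i."""
    f = -params.gamma * x + G @ _hill(x, params.K, params.n)
    if forcing is not None:
        f = f + forcing
    return f


def hill_fixed_point(params: HillNetworkParams, forcing=None,
                     G: np.ndarray | None = None,
                     x0: np.ndarray | None = None) -> tuple[np.ndarray, bool]:
    """Fixed point of the Hill network by deterministic gradient flow.

    Iterates x <- x + F(x) dt for at most ``max_iter`` steps, stopping when the
    maximum change per iteration drops below ``tol``. Returns the last state
    and a convergence flag.
    """
    if G is None:
        G = params.interaction_matrix()
    x = (np.full(params.n_genes, params.init_abundance, dtype=float)
         if x0 is None else np.asarray(x0, dtype=float).copy())
    converged = False
    for _ in range(params.max_iter):
        step = hill_force(x, G, params, forcing) * params.dt
        x = x + step
        if np.abs(step).max() < params.tol:
            converged = True
            break
    return x, converged


def hill_jacobian(x: np.ndarray, G: np.ndarray, params: HillNetworkParams) -> np.ndarray:
    """Analytic Jacobian of the Hill force at state x."""
    n, K = params.n, params.K
    x = np.asarray(x, dtype=float)
    if n == 0:
        dh = np.zeros_like(x)
    else:
        xs = np.maximum(x, 1e-300)
        dh = n * K ** n * xs ** (n - 1) / (K ** n + xs ** n) ** 2
    return -params.gamma * np.eye(len(x)) + G * dh[None, :]


def hill_linear_response_error(params: HillNetworkParams, u,
                               G: np.ndarray | None = None,
                               residual_tol: float = 1e-6) -> float:
    """Relative error of the linear-response prediction -J^-1 u.

    Compares the true fixed-point shift under constant forcing u against the
    prediction from the Jacobian at the unforced fixed point:
    ||dx_true - (-J^-1 u)||^2 / ||dx_true||^2. Fixed points are accepted when
    the force residual ||F||_inf falls below ``residual_tol`` (the per-step
    stopping tolerance alone is stricter than the default iteration budget can
    reach from the standard initial guess); the forced solve warm-starts from
    the unforced fixed point.
    """
    u = np.asarray(u, dtype=float)
    if not u.any():
        raise ValueError("null perturbation: the relative error is undefined")
    if G is None:
        G = params.interaction_matrix()
    x0, _ = hill_fixed_point(params, G=G)
    xu, _ = hill_fixed_point(params, forcing=u, G=G, x0=x0)
    if (np.abs(hill_force(x0, G, params)).max() > residual_tol
            or np.abs(hill_force(xu, G, params, u)).max() > residual_tol):
        raise RuntimeError("fixed-point iteration did not converge")
    dx_true = xu - x0
    J = hill_jacobian(x0, G, params)
    pred = -np.linalg.solve(J, u)
    resid = dx_true - pred
    return float(resid @ resid) / float(dx_true @ dx_true)


def hill_critical_interaction(params: HillNetworkParams) -> float:
    """Critical homogeneous interaction G* destabilizing the zero state.

    For homogeneous coupling G_ij = G the zero state loses stability at
    G* = (gamma / N) min_{x>0} (K^n + x^n) / x^(n-1); for n > 1 the minimizer
    is x = K (n-1)^(1/n) in closed form, otherwise a bounded 1-D minimization
    is used.
    """
    n, K, gamma, N = params.n, params.K, params.gamma, params.n_genes
    if n <= 0:
        raise ValueError("no nontrivial stability threshold for n <= 0")

    def objective(x: float) -> float:
        return (K ** n + x ** n) / x ** (n - 1)

    if n > 1:
        x_min = K * (n - 1.0) ** (1.0 / n)
        return gamma / N * objective(x_min)
    res = scipy.optimize.minimize_scalar(objective, bounds=(1e-9, 1e6), method="bounded")
    return gamma / N * float(res.fun)


# ---------------------------------------------------------------------------
# teams network (numba-jitted core)
# ---------------------------------------------------------------------------

def _build_team_matrices(params: TeamsNetworkParams, rng: np.random.Generator):
    """Sample B_on (within-team activation) and B_off (cross-team inhibition)."""
    n = params.n_genes
    half = n // 2
    team = np.zeros(n, dtype=int)
    team[half:] = 1
    noise = lambda: 1.0 + rng.normal(0.0, params.b_noise_sd, size=(n, n))
    same = team[:, None] == team[None, :]
    b_on = params.b_on_scale * noise() * same
    b_off = params.b_off_scale * noise() * (~same)
    np.fill_diagonal(b_on, 0.0)  # rates take input from the *other* genes
    keep = rng.random((n, n)) >= params.sparsity
    return b_on * keep, b_off * keep


def _teams_core_py(b_on, b_off, beta_vec, gamma, K, hill_n, dt, n_steps,
                   record_every, s0, x0, seed, basal_rate):
    """Reference implementation of the hybrid integrator (jitted when numba is up)."""
    np.random.seed(seed)
    n = b_on.shape[0]
    n_rec = n_steps // record_every
    states = np.empty((n_rec, n))
    promoters = np.empty((n_rec, n), dtype=np.uint8)
    x = x0.copy()
    s = s0.copy()
    rec = 0
    rate_cap = 1.0 / dt
    for step in range(n_steps):
        for i in range(n):
            if s[i] == 0:
                inp = 0.0
                for j in range(n):
                    inp += b_on[i, j] * x[j]
            else:
                inp = 0.0
                for j in range(n):
                    inp += b_off[i, j] * x[j]
            if inp <= 0.0:
                k = basal_rate
            else:
                k = basal_rate + 1.0 / (1.0 + (K / inp) ** hill_n)
            if k > rate_cap:
                k = rate_cap
            if k > 0.0 and np.random.random() < -np.expm1(-k * dt):
                s[i] = 1 - s[i]
        for i in range(n):
            x[i] += (beta_vec[i] * s[i] - gamma * x[i]) * dt
        if (step + 1) % record_every == 0:
            states[rec] = x
            promoters[rec] = s
            rec += 1
    return states, promoters


try:  # jit-compile the hot loop; the pure-Python path stays as fallback
    import numba

    _teams_core = numba.njit(cache=True)(_teams_core_py)
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    _teams_core = _teams_core_py


def simulate_teams_network(params: TeamsNetworkParams,
                           knockout=None) -> Trajectory:
    """Simulate the stochastic hybrid teams model.

    Each gene's promoter switches on with rate
    k_on = 1 / (1 + (K / sum_j B_on_ij x_j)^n) driven by within-team
    activation, and off analogously through cross-team inhibition; expression
    follows dx = (beta s - gamma x) dt. A small basal rate is added to both
    switching rates (see :class:`TeamsNetworkParams.basal_rate`) so the
    collective states remain metastable rather than absorbing. Switching is
    resolved per step as a Bernoulli event with probability 1 - exp(-k dt).
    ``knockout`` (an index or a sequence of indices) sets those genes'
    production rates beta to zero. Sampled interaction entries may be
    negative (the multiplicative noise allows it); rates are clamped to
    [0, 1/dt].
    """
    rng = np.random.default_rng(params.seed)
    b_on, b_off = _build_team_matrices(params, rng)
    n = params.n_genes
    beta_vec = np.full(n, params.beta)
    if knockout is not None:
        for idx in np.atleast_1d(knockout):
            if not 0 <= idx < n:
                raise IndexError("knockout index out of range")
            beta_vec[int(idx)] = 0.0
    s0 = (rng.random(n) < 0.5).astype(np.int64)
    x0 = np.zeros(n)
    n_steps = int(round(params.total_time / params.dt))
    core_seed = int(rng.integers(0, 2**31 - 1))
    states, promoters = _teams_core(
        b_on, b_off, beta_vec, params.gamma, params.K, float(params.hill_n),
        params.dt, n_steps, params.record_every, s0, x0, core_seed,
        float(params.basal_rate),
    )
    times = (np.arange(1, states.shape[0] + 1) * params.record_every) * params.dt
    burn_in = int(params.burn_in_frac * states.shape[0])
    return Trajectory(times=times, states=states, burn_in_index=burn_in,
                      seed=params.seed, promoter_states=promoters)


def trajectory_covariance(traj: Trajectory, gene_ids=None) -> CovarianceModel:
    """Sample covariance over post-burn-in time points (same path as cell data)."""
    if traj.unstable:
        raise ValueError("trajectory flagged unstable; covariance undefined")
    data = traj.stationary_states()
    if data.shape[0] < 2:
        raise ValueError("need at least 2 post-burn-in samples")
    return estimate_covariance(data, gene_ids=gene_ids)


# ---------------------------------------------------------------------------
# bursting-promoter moments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurstMoments:
    """Negative-binomial steady state of the two-state bursting promoter."""

    r: float            # burst-arrival shape k_on / gamma
    p: float            # NB success probability b / (1 + b)
    mean: float         # k_on b / gamma
    burst_size: float   # b = beta / k_off


def burst_model_moments(kon: float, koff: float, beta: float, gamma: float) -> BurstMoments:
    """Steady-state NB parameters of slow-switching, fast-transcribing promoters."""
    if min(kon, koff, beta, gamma) <= 0:
        raise ValueError("all rates must be positive")
    b = beta / koff
    r = kon / gamma
    p = b / (1.0 + b)
    return BurstMoments(r=r, p=p, mean=kon * b / gamma, burst_size=b)


# ---------------------------------------------------------------------------
# labeled count-matrix fixture generator
# ---------------------------------------------------------------------------

def make_perturbation_fixture(
    n_genes: int = 100,
    n_control_cells: int = 500,
    n_cells_per_perturbation: int = 200,
    n_perturbations: int = 5,
    seed: int = 0,
    epsilon_frac: float = 0.9,
    diffusion: float = 0.5,
    baseline: float = 20.0,
    count_scale: float = 5.0,
    forcing: float = 1.0,
    control_label: str = "control",
    guide_suffix: bool = True,
    noise_seed: int | None = None,
) -> tuple[ExpressionDataset, dict]:
    """Emit a labeled control+perturbed count dataset with planted covariance.

    Cells are drawn from the exact stationary Gaussian of a near-critical
    random linear network (eps = ``epsilon_frac`` * eps_c, strong planted
    correlations), shifted to a positive baseline, scaled and rounded to
    counts. Each perturbation applies a constant forcing to one gene, so the
    true mean shift is Sigma_counts . u by construction. Returns the dataset
    plus ground truth (count-scale covariance, per-perturbation forcing
    vectors and target indices). ``noise_seed`` re-seeds only the per-cell
    sampling, so two fixtures can share one network but carry independent
    measurement noise (cross-dataset transfer scenarios).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    cell_rng = np.random.default_rng(np.random.SeedSequence(
        [seed if noise_seed is None else noise_seed, 1]))
    eps = epsilon_frac * critical_coupling(n_genes)
    # resample until stable (near-critical draws occasionally cross the threshold)
    for _ in range(100):
        A = sample_interaction_matrix(n_genes, eps, rng)
        if np.max(np.linalg.eigvals(-A).real) < 0:
            break
    else:
        raise RuntimeError("could not sample a stable near-critical network")
    sigma_state = solve_lyapunov(-A, diffusion * np.eye(n_genes))
    sigma_counts = count_scale ** 2 * sigma_state
    chol = np.linalg.cholesky(sigma_counts + 1e-10 * np.eye(n_genes))

    gene_ids = np.asarray([f"G{i:04d}" for i in range(n_genes)], dtype=object)
    targets = rng.choice(n_genes, size=n_perturbations, replace=False)

    def draw(n_cells: int, mean_shift: np.ndarray) -> np.ndarray:
        z = cell_rng.standard_normal((n_cells, n_genes))
        vals = baseline + mean_shift + z @ chol.T
        return np.rint(np.clip(vals, 0.0, None))

    blocks = [draw(n_control_cells, np.zeros(n_genes))]
    labels = [control_label] * n_control_cells
    truth_u = {}
    for g in targets:
        u = np.zeros(n_genes)
        u[g] = forcing
        truth_u[gene_ids[g]] = u
        blocks.append(draw(n_cells_per_perturbation, sigma_counts @ u))
        lab = gene_ids[g] + ("_g1" if guide_suffix else "")
        labels.extend([lab] * n_cells_per_perturbation)

    counts = np.vstack(blocks)
    cell_ids = np.asarray([f"cell_{i:06d}" for i in range(counts.shape[0])], dtype=object)
    ds = ExpressionDataset(counts, gene_ids, cell_ids,
                           np.asarray(labels, dtype=object), control_label)
    truth = {
        "sigma_counts": sigma_counts,
        "targets": {gene_ids[g]: int(g) for g in targets},
        "forcings": truth_u,
        "epsilon": eps,
        "A": A,
    }
    return ds, truth
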