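"""A self-contained No-U-Turn sampler (NUTS) for differentiable log-densities.

Implements the slice-sampling NUTS variant — trajectory doubling with the
U-turn stopping criterion — iteratively (Stan-style, with per-depth saved
boundary states for the subtree U-turn checks) so the whole transition kernel
can be compiled with numba. Densities are supplied as a callable returning
``(logp, grad_logp)``; pass a numba-jitted callable to get the compiled
kernel, a plain Python callable to get the interpreted one (same algorithm).
Warmup uses dual-averaging step-size adaptation toward a target acceptance
statistic and a single-window diagonal mass-matrix re-estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutsStats", "nuts_sample"]

_DELTA_MAX = 1000.0  # divergence threshold on the joint log-density drop


@dataclass
class NutsStats:
    step_size: float
    divergences: int
    mean_accept: float
    mean_treedepth: float
    inv_mass: np.ndarray


def _find_reasonable_epsilon_py(logp_grad, x, inv_mass):
    """Heuristic initial step size: double/halve until acceptance crosses 0.5."""
    d = x.shape[0]
    eps = 1.0
    logp, grad = logp_grad(x)
    p = np.random.standard_normal(d) / np.sqrt(inv_mass)
    joint0 = logp - 0.5 * np.sum(inv_mass * p * p)

    def one_step(eps):
        p1 = p + 0.5 * eps * grad
        x1 = x + eps * inv_mass * p1
        logp1, grad1 = logp_grad(x1)
        p1 = p1 + 0.5 * eps * grad1
        joint = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(joint):
            joint = -np.inf
        return joint

    a = 1.0 if one_step(eps) - joint0 > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0 ** a
        if a * (one_step(eps) - joint0) <= a * np.log(0.5):
            break
    return eps


def _nuts_kernel_py(logp_grad, x0, n_tune, n_draws, seed, target_accept,
                    max_treedepth, adapt_mass):
    """One NUTS chain (iterative doubling). Compiled with numba when possible."""
    np.random.seed(seed)
    d = x0.shape[0]
    inv_mass = np.ones(d)
    x = x0.copy()
    logp, grad = logp_grad(x)

    eps = _find_reasonable_epsilon(logp_grad, x, inv_mass)
    # dual-averaging state (Hoffman & Gelman defaults)
    mu = np.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma_da = 0.05
    t0_da = 10.0
    kappa = 0.75
    da_iter = 0

    draws = np.empty((n_draws, d))
    divergences = 0
    accept_sum_out = 0.0
    depth_sum_out = 0.0

    # saved boundary states for subtree U-turn checks, one slot per level
    save_x = np.empty((max_treedepth + 1, d))
    save_p = np.empty((max_treedepth + 1, d))

    win_lo = int(0.25 * n_tune)
    win_hi = int(0.75 * n_tune)
    n_win = max(win_hi - win_lo, 1)
    window = np.empty((n_win, d))
    win_count = 0

    total = n_tune + n_draws
    for it in range(total):
        if it == n_tune and n_tune > 0:
            eps = np.exp(log_eps_bar)  # freeze the averaged step size
        p0 = np.random.standard_normal(d) / np.sqrt(inv_mass)
        joint0 = logp - 0.5 * np.sum(inv_mass * p0 * p0)
        log_u = joint0 - np.random.exponential()

        xm = x.copy()
        pm = p0.copy()
        gm = grad.copy()
        xp = x.copy()
        pp = p0.copy()
        gp = grad.copy()
        xprop = x.copy()
        n_valid = 1
        acc_sum = 0.0
        n_acc = 0
        keep = True
        depth = 0
        diverged = False

        while keep and depth < max_treedepth:
            v = 1.0 if np.random.random() < 0.5 else -1.0
            if v > 0:
                cx = xp.copy()
                cp = pp.copy()
                cg = gp.copy()
            else:
                cx = xm.copy()
                cp = pm.copy()
                cg = gm.copy()
            sub_prop = cx.copy()
            sub_n = 0
            sub_ok = True
            n_leaf = 1 << depth
            for i in range(n_leaf):
                # one leapfrog step in direction v (momenta stay physical)
                cp = cp + (0.5 * v * eps) * cg
                cx = cx + (v * eps) * (inv_mass * cp)
                lp_new, cg = logp_grad(cx)
                cp = cp + (0.5 * v * eps) * cg
                joint = lp_new - 0.5 * np.sum(inv_mass * cp * cp)
                if not np.isfinite(joint):
                    joint = -np.inf
                diff = joint - joint0
                if diff > 0.0:
                    diff = 0.0
                acc_sum += np.exp(diff)
                n_acc += 1
                if log_u - _DELTA_MAX > joint:
                    diverged = True
                    sub_ok = False
                    break
                if log_u <= joint:
                    sub_n += 1
                    if np.random.random() < 1.0 / sub_n:
                        sub_prop = cx.copy()
                # record left boundaries of the sub-subtrees starting at leaf i
                for lev in range(depth + 1):
                    if i % (1 << lev) == 0:
                        save_x[lev] = cx
                        save_p[lev] = cp
                # U-turn checks for every sub-subtree completed at leaf i
                for lev in range(1, depth + 1):
                    if (i + 1) % (1 << lev) == 0:
                        span = v * (cx - save_x[lev])
                        if (np.sum(span * (inv_mass * save_p[lev])) < 0.0
                                or np.sum(span * (inv_mass * cp)) < 0.0):
                            sub_ok = False
                            break
                if not sub_ok:
                    break
            # combine subtree with the trajectory so far
            if sub_ok and sub_n > 0:
                if sub_n >= n_valid or np.random.random() < sub_n / n_valid:
                    xprop = sub_prop.copy()
            n_valid += sub_n
            if not sub_ok:
                break
            if v > 0:
                xp = cx
                pp = cp
                gp = cg
            else:
                xm = cx
                pm = cp
                gm = cg
            span = xp - xm
            keep = (np.sum(span * (inv_mass * pm)) >= 0.0
                    and np.sum(span * (inv_mass * pp)) >= 0.0)
            depth += 1

        x = xprop
        logp, grad = logp_grad(x)
        accept_prob = acc_sum / max(n_acc, 1)

        if it < n_tune:
            da_iter += 1
            h_bar = ((1.0 - 1.0 / (da_iter + t0_da)) * h_bar
                     + (target_accept - accept_prob) / (da_iter + t0_da))
            log_eps = mu - np.sqrt(da_iter) / gamma_da * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = np.exp(log_eps)
            if adapt_mass and win_lo <= it < win_hi:
                window[win_count] = x
                win_count += 1
            if adapt_mass and it == win_hi - 1 and win_count >= 10:
                for j in range(d):
                    var_j = np.var(window[:win_count, j])
                    inv_mass[j] = max(var_j * win_count / (win_count - 1), 1e-8)
                eps = _find_reasonable_epsilon(logp_grad, x, inv_mass)
                mu = np.log(10.0 * eps)
                log_eps_bar = 0.0
                h_bar = 0.0
                da_iter = 0
        else:
            draws[it - n_tune] = x
            if diverged:
                divergences += 1
            accept_sum_out += accept_prob
            depth_sum_out += depth

    return draws, eps, divergences, accept_sum_out / max(n_draws, 1), \
        depth_sum_out / max(n_draws, 1), inv_mass


try:
    import numba

    _find_reasonable_epsilon_jit = numba.njit(cache=False)(_find_reasonable_epsilon_py)
    _DISPATCHER = numba.core.dispatcher.Dispatcher

    def _make_jit_kernel():
        # the kernel references _find_reasonable_epsilon by name; bind per flavor
        glb = dict(_nuts_kernel_py.__globals__)
        glb["_find_reasonable_epsilon"] = _find_reasonable_epsilon_jit
        import types

        fn = types.FunctionType(_nuts_kernel_py.__code__, glb,
                                _nuts_kernel_py.__name__)
        return numba.njit(cache=False)(fn)

    _nuts_kernel_jit = _make_jit_kernel()
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False
    _DISPATCHER = ()

_find_reasonable_epsilon = _find_reasonable_epsilon_py  # python-path binding


def nuts_sample(logp_grad, x0, n_tune: int, n_draws: int,
                rng: np.random.Generator | int,
                target_accept: float = 0.95, max_treedepth: int = 10,
                adapt_mass: bool = True) -> tuple[np.ndarray, NutsStats]:
    """Run one NUTS chain; returns post-warmup draws and sampler statistics.

    ``logp_grad(x) -> (logp, grad)`` defines the target. A numba-jitted
    callable routes the whole chain through the compiled kernel (orders of
    magnitude faster); a plain callable runs the identical algorithm in
    Python. ``rng`` seeds the chain (a Generator is reduced to an integer
    seed).
    """
    x0 = np.asarray(x0, dtype=float)
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(0, 2**31 - 1))
    else:
        seed = int(rng)
    lp0, _ = logp_grad(x0)
    if not np.isfinite(lp0):
        raise ValueError("initial point has non-finite log-density")
    use_jit = _HAVE_NUMBA and isinstance(logp_grad, _DISPATCHER)
    kernel = _nuts_kernel_jit if use_jit else _nuts_kernel_py
    draws, eps, div, acc, depth, inv_mass = kernel(
        logp_grad, x0, int(n_tune), int(n_draws), seed, float(target_accept),
        int(max_treedepth), bool(adapt_mass),
    )
    return draws, NutsStats(step_size=float(eps), divergences=int(div),
                            mean_accept=float(acc), mean_treedepth=float(depth),
                            inv_mass=np.asarray(inv_mass))
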