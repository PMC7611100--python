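"""Model fitting: per-subject maximum likelihood and symptom-linked hierarchical MCMC.

The hierarchical ("clinically informed") scheme puts, for each cognitive
parameter theta (on its unconstrained scale), a population layer

    theta_i ~ Normal(w * z(BFNE_i) + theta0, sigma)

with a standard-normal prior on the covariate slope w, a scaled-normal prior on
the intercept theta0 and a half-Cauchy prior on the population SD sigma. The
posterior over w gives the credible interval of each parameter's dependence on
fear of negative evaluation.

Sampling uses a Metropolis-within-Gibbs scheme tailored to this structure:
subject-level parameters move by adaptive random-walk proposals accepted
against the vectorised likelihood kernel; (w, theta0) are drawn exactly from
their conjugate bivariate-normal conditional; log sigma moves by adaptive
random-walk Metropolis. The centered parameterization is used deliberately —
it is what makes the (w, theta0) conditional conjugate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .cohort import CohortDataset, zscore
from .errors import OptimizationError
from .kernels import ModelSpec, loglik_unconstrained, to_native
from .task import SessionArrays, SessionData, sessions_to_arrays

# unconstrained-scale optimisation bounds and multistart boxes per transform
_BOUNDS = {"logit": (-7.0, 7.0), "log": (-6.0, 4.0), "identity": (-5.0, 5.0)}
_START_BOX = {"logit": (-2.0, 2.0), "log": (-3.0, 0.5), "identity": (-1.0, 1.0)}


def _as_arrays(data) -> SessionArrays:
    if isinstance(data, SessionArrays):
        return data
    if isinstance(data, CohortDataset):
        return sessions_to_arrays(data.sessions)
    if isinstance(data, SessionData):
        return sessions_to_arrays([data])
    return sessions_to_arrays(list(data))


# ---------------------------------------------------------------------------
# Maximum likelihood

@dataclass
class MleFit:
    """Per-subject maximum-likelihood fit of one model variant."""

    spec: ModelSpec
    params: pd.DataFrame  # native scale, one row per subject
    unconstrained: np.ndarray  # (S, K)
    total_loglik: np.ndarray  # (S,)
    pointwise_loglik: np.ndarray  # (S, T)
    converged: np.ndarray  # (S,) bool
    n_restarts: int
    participant_ids: list[str]


def fit_mle(
    spec: ModelSpec,
    data,
    n_restarts: int = 10,
    seed: int = 0,
    maxiter: int = 200,
) -> MleFit:
    """Best-of-restarts L-BFGS maximum likelihood, batched across subjects.

    All subjects are optimised jointly (the objective is separable, so the
    joint optimum is the per-subject optimum); restarts draw starting points
    from a seeded Latin hypercube on the unconstrained scale. Deterministic
    given the seed.
    """
    arrays = _as_arrays(data)
    S, K = arrays.n_subjects, spec.n_params
    lo = np.array([_BOUNDS[t][0] for t in spec.transforms])
    hi = np.array([_BOUNDS[t][1] for t in spec.transforms])
    s_lo = np.array([_START_BOX[t][0] for t in spec.transforms])
    s_hi = np.array([_START_BOX[t][1] for t in spec.transforms])
    sampler = qmc.LatinHypercube(d=K, seed=seed)
    starts = s_lo + sampler.random(n_restarts) * (s_hi - s_lo)

    bounds = [(lo[k], hi[k]) for _ in range(S) for k in range(K)]

    def objective(x_flat):
        x = x_flat.reshape(S, K)
        ll, g = loglik_unconstrained(spec, x, arrays, grad=True)
        return -ll.sum(), -g.ravel()

    best_x = None
    best_ll = np.full(S, -np.inf)
    for r in range(n_restarts):
        x0 = np.tile(starts[r], (S, 1)).ravel()
        res = minimize(
            objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "maxcor": 20},
        )
        if not np.all(np.isfinite(res.x)):
            continue
        x = res.x.reshape(S, K)
        ll, _ = loglik_unconstrained(spec, x, arrays, grad=False)
        tot = ll.sum(axis=1)
        better = tot > best_ll
        if best_x is None:
            best_x = x.copy()
            best_ll = tot.copy()
        else:
            best_x[better] = x[better]
            best_ll[better] = tot[better]
    if best_x is None or not np.all(np.isfinite(best_ll)):
        raise OptimizationError("all maximum-likelihood restarts failed")
    # per-subject convergence: small gradient at the best point (interior
    # optima) — subjects pinned at a bound may carry larger gradients
    pointwise, grad = loglik_unconstrained(spec, best_x, arrays, grad=True)
    best_ok = np.abs(grad).max(axis=1) < 0.5
    if best_ok.mean() < 0.5:
        warnings.warn(
            f"only {int(best_ok.sum())}/{S} subjects reached a stationary "
            "optimum; consider more restarts or iterations",
            RuntimeWarning,
        )
    native = to_native(spec, best_x)
    return MleFit(
        spec=spec,
        params=pd.DataFrame(native, columns=list(spec.names)),
        unconstrained=best_x,
        total_loglik=best_ll,
        pointwise_loglik=pointwise,
        converged=best_ok,
        n_restarts=n_restarts,
        participant_ids=list(arrays.participant_ids),
    )


# ---------------------------------------------------------------------------
# Hierarchical MCMC

@dataclass
class McmcOptions:
    """Sampler settings (defaults follow the 4-chain, 1000-burn-in scheme)."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    subject_sampler: str = "hmc"  # 'hmc' (gradient leapfrog) or 'rw'
    leapfrog_steps: int = 4
    subject_steps: int = 2  # random-walk sweeps over subjects per iteration ('rw')
    nc_scale_moves: int = 2  # interweaved scale proposals per parameter per sweep
    prior_scale_w: float = 1.0
    prior_scale_theta0: float = 2.0
    half_cauchy_scale: float = 2.5
    rhat_threshold: float = 1.05
    store_pointwise: bool = True
    freeze_w: tuple[str, ...] = ()  # parameter names whose slope is fixed at 0


@dataclass
class HierFit:
    """Posterior draws and diagnostics of one hierarchical fit."""

    spec: ModelSpec
    param_names: tuple[str, ...]
    w: np.ndarray  # (chains, draws, K)
    theta0: np.ndarray  # (chains, draws, K)
    sigma: np.ndarray  # (chains, draws, K)
    theta_mean: np.ndarray  # (S, K) posterior-mean subject params, unconstrained
    pointwise_loglik: np.ndarray | None  # (chains, draws, S, T)
    rhat: dict[str, np.ndarray]
    ess: dict[str, np.ndarray]
    participant_ids: list[str]
    bfne: np.ndarray
    data_fingerprint: int
    options: McmcOptions
    warnings: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        thr = self.options.rhat_threshold
        return all(np.all(v < thr) for v in self.rhat.values())

    def w_draws(self, name: str) -> np.ndarray:
        """Flattened posterior draws of the slope for one parameter."""
        k = self.param_names.index(name)
        return self.w[:, :, k].ravel()

    def subject_params_native(self) -> pd.DataFrame:
        """Posterior-mean subject parameters mapped to the native scale."""
        native = to_native(self.spec, self.theta_mean)
        df = pd.DataFrame(native, columns=list(self.param_names))
        df.insert(0, "participant_id", self.participant_ids)
        return df

    def to_inference_data(self, unit: str = "trial"):
        """arviz InferenceData with posterior and log_likelihood groups."""
        import arviz as az

        if self.pointwise_loglik is None:
            raise ValueError("fit was run without pointwise log-likelihood storage")
        ll = self.pointwise_loglik
        C, D, S, T = ll.shape
        if unit == "subject":
            obs = ll.sum(axis=3)
        elif unit == "trial":
            obs = ll.reshape(C, D, S * T)
        else:
            raise ValueError("unit must be 'trial' or 'subject'")
        return az.from_dict(
            posterior={"w": self.w, "theta0": self.theta0, "sigma": self.sigma},
            log_likelihood={"obs": obs},
        )


@dataclass(frozen=True)
class SlopeReport:
    """Posterior summary of one parameter's covariate slope."""

    parameter: str
    mean: float
    lower: float
    upper: float
    excludes_zero: bool


def _half_cauchy_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return np.where(x > 0, -np.log1p((x / scale) ** 2), -np.inf)


def fit_hierarchical(
    spec: ModelSpec,
    cohort,
    options: McmcOptions | None = None,
    trial_mask: np.ndarray | None = None,
) -> HierFit:
    """Fit the symptom-linked hierarchical model by Metropolis-within-Gibbs.

    ``cohort`` is a :class:`CohortDataset`, a list of sessions or a
    :class:`SessionArrays`; every subject must carry a BFNE score.
    ``trial_mask`` (S, T boolean) excludes trials from the likelihood (their
    outcomes still drive the learning dynamics), enabling exact
    leave-one-trial-out cross-validation.

    Non-convergence (any R-hat above the threshold) is recorded as a warning on
    the returned fit, not raised.
    """
    import arviz as az

    opts = options or McmcOptions()
    arrays = _as_arrays(cohort)
    S, T, K = arrays.n_subjects, arrays.n_trials, spec.n_params
    if np.any(~np.isfinite(arrays.bfne)):
        raise ValueError("every subject needs a finite BFNE score")
    z = zscore(arrays.bfne)
    mask = np.ones((S, T), dtype=bool) if trial_mask is None else trial_mask.astype(bool)
    frozen = np.array([n in opts.freeze_w for n in spec.names])

    X = np.column_stack([z, np.ones(S)])
    XtX = X.T @ X
    prior_prec = np.diag([1.0 / opts.prior_scale_w**2, 1.0 / opts.prior_scale_theta0**2])

    C, W, D = opts.chains, opts.warmup, opts.draws
    w_out = np.empty((C, D, K))
    t0_out = np.empty((C, D, K))
    sig_out = np.empty((C, D, K))
    theta_sum = np.zeros((S, K))
    ll_out = np.empty((C, D, S, T)) if opts.store_pointwise else None

    use_hmc = opts.subject_sampler == "hmc"
    fmask = mask.astype(float)

    ss = np.random.SeedSequence(opts.seed)
    for c, child in enumerate(ss.spawn(C)):
        rng = np.random.default_rng(child)
        theta = rng.normal(0.0, 0.5, size=(S, K))
        w = np.zeros(K)
        theta0 = rng.normal(0.0, 0.5, size=K)
        sigma = np.full(K, 0.5)
        step = np.full(K, 0.25)
        eps = 0.15  # HMC step multiplier on the population SDs
        sig_step = np.full(K, 0.5)
        nc_sig_step = np.full(K, 0.3)  # interweaved non-centered scale moves
        nc_loc_step = np.full(K, 0.15)  # interweaved non-centered location moves
        nc_sig_acc = np.zeros(K)
        nc_loc_acc = np.zeros(K)
        ll_mat, _ = loglik_unconstrained(spec, theta, arrays, grad=False)
        ll_tot = (ll_mat * fmask).sum(axis=1)
        acc_count = np.zeros(K)
        acc_tries = 0
        sig_acc = np.zeros(K)

        for it in range(W + D):
            mu = np.outer(z, w) + theta0
            if use_hmc:
                # --- subject-level Hamiltonian step, batched over subjects ---
                eps_k = eps * sigma  # population SDs as a diagonal preconditioner
                _, g0 = loglik_unconstrained(
                    spec, theta, arrays, grad=True, grad_mask=mask
                )
                lp0 = ll_tot - 0.5 * (((theta - mu) / sigma) ** 2).sum(axis=1)
                gr = g0 - (theta - mu) / sigma**2
                p = rng.normal(size=(S, K))
                h0 = -lp0 + 0.5 * (p**2).sum(axis=1)
                th = theta.copy()
                pm = p.copy()
                grc = gr
                for _ in range(opts.leapfrog_steps):
                    pm = pm + 0.5 * eps_k * grc
                    th = th + eps_k * pm
                    ll_p, g_p = loglik_unconstrained(
                        spec, th, arrays, grad=True, grad_mask=mask
                    )
                    ll_p_tot = (ll_p * fmask).sum(axis=1)
                    grc = g_p - (th - mu) / sigma**2
                    pm = pm + 0.5 * eps_k * grc
                lp1 = ll_p_tot - 0.5 * (((th - mu) / sigma) ** 2).sum(axis=1)
                h1 = -lp1 + 0.5 * (pm**2).sum(axis=1)
                with np.errstate(invalid="ignore"):
                    accept = np.log(rng.random(S)) < (h0 - h1)
                accept &= np.isfinite(h1)
                theta[accept] = th[accept]
                ll_tot[accept] = ll_p_tot[accept]
                ll_mat[accept] = ll_p[accept]
                acc_count += accept.mean()
                acc_tries += 1
            else:
                # --- subject-level random-walk Metropolis ---
                for _ in range(opts.subject_steps):
                    prop = theta + rng.normal(0.0, 1.0, size=(S, K)) * step
                    ll_p, _ = loglik_unconstrained(spec, prop, arrays, grad=False)
                    ll_p_tot = (ll_p * fmask).sum(axis=1)
                    lp_cur = -0.5 * (((theta - mu) / sigma) ** 2).sum(axis=1)
                    lp_prop = -0.5 * (((prop - mu) / sigma) ** 2).sum(axis=1)
                    log_r = (ll_p_tot + lp_prop) - (ll_tot + lp_cur)
                    accept = np.log(rng.random(S)) < log_r
                    theta[accept] = prop[accept]
                    ll_tot[accept] = ll_p_tot[accept]
                    ll_mat[accept] = ll_p[accept]
                    acc_count += accept.mean()
                    acc_tries += 1
            # --- conjugate Gibbs for (w, theta0) per parameter ---
            for k in range(K):
                if frozen[k]:
                    w[k] = 0.0
                    prec = S / sigma[k] ** 2 + prior_prec[1, 1]
                    mean = theta[:, k].sum() / sigma[k] ** 2 / prec
                    theta0[k] = rng.normal(mean, 1.0 / np.sqrt(prec))
                else:
                    prec = XtX / sigma[k] ** 2 + prior_prec
                    cov = np.linalg.inv(prec)
                    mean = cov @ (X.T @ theta[:, k]) / sigma[k] ** 2
                    draw = rng.multivariate_normal(mean, cov, method="cholesky")
                    w[k], theta0[k] = draw
            # --- Metropolis on log sigma (half-Cauchy prior) ---
            # The conditional is likelihood-free, so iterate it to near-
            # equilibrium; the cross-cut with the subject parameters is
            # handled by the interweaved scale move below.
            resid = theta - (np.outer(z, w) + theta0)
            rss = (resid**2).sum(axis=0)

            def _sig_logpost(s):
                return (
                    -S * np.log(s)
                    - rss / (2.0 * s**2)
                    + _half_cauchy_logpdf(s, opts.half_cauchy_scale)
                    + np.log(s)  # Jacobian of the log transform
                )

            for _ in range(10):
                prop_ls = np.log(sigma) + rng.normal(0.0, 1.0, size=K) * sig_step
                sig_p = np.exp(prop_ls)
                log_r = _sig_logpost(sig_p) - _sig_logpost(sigma)
                acc = np.log(rng.random(K)) < log_r
                sigma[acc] = sig_p[acc]
                sig_acc += acc / 10.0

            # --- interweaved non-centered moves, one parameter at a time ---
            # (break the per-parameter funnel between the population scale /
            # location and the subject parameters)
            for k in range(K):
                mu_k = z * w[k] + theta0[k]
                # scale move: rescale column k's residuals jointly with sigma_k
                for _ in range(opts.nc_scale_moves):
                    ls_p = np.log(sigma[k]) + rng.normal() * nc_sig_step[k]
                    sig_k = np.exp(ls_p)
                    th_p = theta.copy()
                    th_p[:, k] = mu_k + (sig_k / sigma[k]) * (theta[:, k] - mu_k)
                    ll_p, _ = loglik_unconstrained(spec, th_p, arrays, grad=False)
                    ll_p_tot = (ll_p * fmask).sum(axis=1)
                    log_r = (
                        ll_p_tot.sum() - ll_tot.sum()
                        + float(_half_cauchy_logpdf(np.array(sig_k),
                                                    opts.half_cauchy_scale)
                                - _half_cauchy_logpdf(np.array(sigma[k]),
                                                      opts.half_cauchy_scale))
                        + (ls_p - np.log(sigma[k]))  # Jacobian, log transform
                    )
                    if np.log(rng.random()) < log_r:
                        sigma[k] = sig_k
                        theta = th_p
                        ll_mat, ll_tot = ll_p, ll_p_tot
                        nc_sig_acc[k] += 1.0 / opts.nc_scale_moves
                # location move: shift column k with the population line
                dw = 0.0 if frozen[k] else rng.normal() * nc_loc_step[k]
                dt0 = rng.normal() * nc_loc_step[k]
                th_p = theta.copy()
                th_p[:, k] = theta[:, k] + dw * z + dt0
                ll_p, _ = loglik_unconstrained(spec, th_p, arrays, grad=False)
                ll_p_tot = (ll_p * fmask).sum(axis=1)
                w_k, t0_k = w[k] + dw, theta0[k] + dt0
                log_r = (
                    ll_p_tot.sum() - ll_tot.sum()
                    - 0.5 * (w_k**2 - w[k] ** 2) / opts.prior_scale_w**2
                    - 0.5 * (t0_k**2 - theta0[k] ** 2) / opts.prior_scale_theta0**2
                )
                if np.log(rng.random()) < log_r:
                    w[k], theta0[k] = w_k, t0_k
                    theta = th_p
                    ll_mat, ll_tot = ll_p, ll_p_tot
                    nc_loc_acc[k] += 1.0

            # --- warmup adaptation ---
            if it < W and (it + 1) % 25 == 0:
                rate = float(acc_count[0]) / max(acc_tries, 1)
                if use_hmc:
                    eps *= float(np.exp(0.8 * (rate - 0.75)))
                    eps = float(np.clip(eps, 1e-3, 2.0))
                else:
                    step *= np.exp(1.2 * (rate - 0.3))
                    np.clip(step, 1e-3, 2.0, out=step)
                sig_rate = sig_acc / 25.0
                sig_step *= np.exp(1.0 * (sig_rate - 0.44))
                np.clip(sig_step, 1e-3, 3.0, out=sig_step)
                nc_sig_step = np.clip(
                    nc_sig_step * np.exp(1.0 * (nc_sig_acc / 25.0 - 0.35)), 1e-3, 2.0)
                nc_loc_step = np.clip(
                    nc_loc_step * np.exp(1.0 * (nc_loc_acc / 25.0 - 0.35)), 1e-3, 2.0)
                acc_count[:] = 0.0
                acc_tries = 0
                sig_acc[:] = 0.0
                nc_sig_acc[:] = 0.0
                nc_loc_acc[:] = 0.0

            if it >= W:
                d = it - W
                w_out[c, d] = w
                t0_out[c, d] = theta0
                sig_out[c, d] = sigma
                theta_sum += theta
                if opts.store_pointwise:
                    ll_out[c, d] = ll_mat

    # diagnostics on the population quantities
    rhat = {}
    ess = {}
    for name, arr in (("w", w_out), ("theta0", t0_out), ("sigma", sig_out)):
        keep = ~frozen if name == "w" else np.ones(K, dtype=bool)
        if C >= 2 and keep.any():
            rhat[name] = np.array(
                [float(az.rhat(arr[:, :, k])) for k in range(K) if keep[k]]
            )
            ess[name] = np.array(
                [float(az.ess(arr[:, :, k])) for k in range(K) if keep[k]]
            )

    fit = HierFit(
        spec=spec,
        param_names=spec.names,
        w=w_out,
        theta0=t0_out,
        sigma=sig_out,
        theta_mean=theta_sum / (C * D),
        pointwise_loglik=ll_out,
        rhat=rhat,
        ess=ess,
        participant_ids=list(arrays.participant_ids),
        bfne=arrays.bfne.copy(),
        data_fingerprint=int(arrays.choice.sum() + 7919 * arrays.choice.shape[1]),
        options=opts,
    )
    bad = {
        name: v.max() for name, v in rhat.items() if np.any(v > opts.rhat_threshold)
    }
    if bad:
        msg = f"non-convergence: max R-hat per group {bad}"
        fit.warnings.append(msg)
        warnings.warn(msg, RuntimeWarning)
    return fit


def slope_report(fit: HierFit, level: float = 0.95) -> list[SlopeReport]:
    """Central credible interval of each parameter's covariate slope w."""
    reports = []
    n_draws = fit.w.shape[0] * fit.w.shape[1]
    if n_draws < 100:
        warnings.warn(
            f"only {n_draws} posterior draws: interval endpoints are imprecise",
            RuntimeWarning,
        )
    a = (1.0 - level) / 2.0
    for k, name in enumerate(fit.param_names):
        if name in fit.options.freeze_w:
            continue
        draws = fit.w[:, :, k].ravel()
        lo, hi = np.quantile(draws, [a, 1.0 - a])
        reports.append(
            SlopeReport(
                parameter=name,
                mean=float(draws.mean()),
                lower=float(lo),
                upper=float(hi),
                excludes_zero=bool(lo > 0.0 or hi < 0.0),
            )
        )
    return reports


def slope_table(reports: list[SlopeReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "mean_w": r.mean,
                "lower95": r.lower,
                "upper95": r.upper,
                "excludes_zero": r.excludes_zero,
            }
            for r in reports
        ]
    )
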