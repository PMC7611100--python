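"""Vectorised log-likelihood kernels and parameter-space plumbing.

One likelihood implementation per model family serves every caller (MLE,
hierarchical MCMC, model comparison): the kernels evaluate the per-trial
log-likelihood matrix for a whole stack of sessions at once (subject x trial)
and, optionally, the analytic gradient of each subject's total log-likelihood
with respect to that subject's native-scale parameters. Equivalence with the
scalar trial-by-trial operations in :mod:`selearn.associative` and
:mod:`selearn.beliefs` is enforced by tests.

A :class:`ModelSpec` fixes the flat parameter layout of a (family, variant)
combination and the bijections between the unconstrained fitting scale and the
native scale: inverse-logit for learning rates and memory decay, exp for
decision noise and evidence counts, identity for the positivity and initial
Q-value biases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .associative import VARIANT_LAMBDAS, AssocParams
from .beliefs import BeliefParams
from .errors import DegenerateBeliefError, ParameterError
from .task import N_PERSONAS, SessionArrays

# ---------------------------------------------------------------------------
# Parameter layout

#: free-lambda name -> list of (referent, valence) slots it fills
_LAMBDA_SLOTS = {
    "lam": [(0, 0), (0, 1), (1, 0), (1, 1)],
    "lam_pos": [(0, 1), (1, 1)],
    "lam_neg": [(0, 0), (1, 0)],
    "lam_self_pos": [(0, 1)],
    "lam_self_neg": [(0, 0)],
    "lam_other": [(1, 0), (1, 1)],
    "lam_other_pos": [(1, 1)],
    "lam_other_neg": [(1, 0)],
}


@dataclass(frozen=True)
class ModelSpec:
    """Flat parameter layout of one model family/variant combination."""

    family: str  # 'assoc' or 'belief'
    variant: str
    names: tuple[str, ...]
    transforms: tuple[str, ...]  # per name: 'logit' | 'log' | 'identity'
    include_rho: bool = True
    include_initial_bias: bool = True

    @property
    def n_params(self) -> int:
        return len(self.names)


def model_spec(
    family: str,
    variant: str,
    include_rho: bool = True,
    include_initial_bias: bool = True,
) -> ModelSpec:
    """Build the parameter layout for a model family and variant.

    For the associative family, ``include_rho`` / ``include_initial_bias``
    toggle the positivity-bias and initial-Q-value parameters; for the belief
    family ``include_initial_bias`` toggles the initial state evidence
    (``include_rho`` is ignored).
    """
    if family == "assoc":
        if variant not in VARIANT_LAMBDAS:
            raise ParameterError(f"unknown associative variant {variant!r}")
        names = list(VARIANT_LAMBDAS[variant])
        transforms = ["logit"] * len(names)
        names.append("tau")
        transforms.append("log")
        if include_rho:
            names.append("rho")
            transforms.append("identity")
        if include_initial_bias:
            names.append("q0_pos")
            transforms.append("identity")
        return ModelSpec(
            family, variant, tuple(names), tuple(transforms),
            include_rho, include_initial_bias,
        )
    if family == "belief":
        if variant == "shared":
            names = ["alpha_trait", "beta_trait", "eta"]
        elif variant == "selfother":
            names = ["alpha_self", "beta_self", "alpha_other", "beta_other", "eta"]
        elif variant == "selfother_full":
            names = [
                "alpha_self", "beta_self", "alpha_other", "beta_other",
                "eta_self", "eta_other",
            ]
        else:
            raise ParameterError(f"unknown belief variant {variant!r}")
        transforms = ["log" if not n.startswith("eta") else "logit" for n in names]
        names.append("tau")
        transforms.append("log")
        if include_initial_bias:
            names += ["alpha_init", "beta_init"]
            transforms += ["log", "log"]
        return ModelSpec(
            family, variant, tuple(names), tuple(transforms),
            include_rho, include_initial_bias,
        )
    raise ParameterError(f"unknown model family {family!r}")


def to_native(spec: ModelSpec, x_unconstrained: np.ndarray) -> np.ndarray:
    """Map unconstrained parameters (..., K) to the native scale."""
    x = np.asarray(x_unconstrained, dtype=float)
    out = np.empty_like(x)
    for k, tr in enumerate(spec.transforms):
        col = x[..., k]
        if tr == "logit":
            out[..., k] = _sigmoid(col)
        elif tr == "log":
            out[..., k] = np.exp(np.clip(col, -50.0, 50.0))
        else:
            out[..., k] = col
    return out


def native_jacobian(spec: ModelSpec, x_unconstrained: np.ndarray) -> np.ndarray:
    """d(native)/d(unconstrained), elementwise, shape like the input."""
    x = np.asarray(x_unconstrained, dtype=float)
    out = np.empty_like(x)
    for k, tr in enumerate(spec.transforms):
        col = x[..., k]
        if tr == "logit":
            s = _sigmoid(col)
            out[..., k] = s * (1.0 - s)
        elif tr == "log":
            out[..., k] = np.exp(np.clip(col, -50.0, 50.0))
        else:
            out[..., k] = 1.0
    return out


def params_object(spec: ModelSpec, native_row: np.ndarray):
    """Build an :class:`AssocParams` / :class:`BeliefParams` from a native row."""
    v = dict(zip(spec.names, np.asarray(native_row, dtype=float)))
    if spec.family == "assoc":
        return AssocParams(
            variant=spec.variant,
            lambdas={n: v[n] for n in VARIANT_LAMBDAS[spec.variant]},
            tau=v["tau"],
            rho=v.get("rho", 0.0),
            q0_pos=v.get("q0_pos", 0.0),
        )
    if spec.variant == "shared":
        at = {"self": v["alpha_trait"], "other": v["alpha_trait"]}
        bt = {"self": v["beta_trait"], "other": v["beta_trait"]}
    else:
        at = {"self": v["alpha_self"], "other": v["alpha_other"]}
        bt = {"self": v["beta_self"], "other": v["beta_other"]}
    if spec.variant == "selfother_full":
        eta = {"self": v["eta_self"], "other": v["eta_other"]}
    else:
        eta = {"self": v["eta"], "other": v["eta"]}
    return BeliefParams(
        variant=spec.variant,
        alpha_trait=at,
        beta_trait=bt,
        eta=eta,
        tau=v["tau"],
        alpha_init=v.get("alpha_init", 0.0),
        beta_init=v.get("beta_init", 0.0),
    )


# ---------------------------------------------------------------------------
# Numerics

def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def _log_sigmoid(x):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, -np.log1p(np.exp(-np.abs(x))),
                    x - np.log1p(np.exp(-np.abs(x))))


# ---------------------------------------------------------------------------
# Associative kernel

def _expand_lambdas(spec: ModelSpec, native: np.ndarray) -> np.ndarray:
    """Free lambdas (S, n_free) -> full table (S, 2 referents, 2 valences)."""
    S = native.shape[0]
    lam = np.empty((S, 2, 2))
    for j, name in enumerate(VARIANT_LAMBDAS[spec.variant]):
        for (ref, val) in _LAMBDA_SLOTS[name]:
            lam[:, ref, val] = native[:, j]
    return lam


def _block_major(data: SessionArrays):
    """Reshape (S, T) trial arrays to block-major (S*nb, tpb) views.

    Blocks are independent given the parameters (state resets at block start),
    so each block can be iterated as its own row; the persona and referent are
    constant within a row.
    """
    S, T = data.persona.shape
    tpb = data.trials_per_block
    nb = T // tpb
    if nb * tpb != T:
        raise ParameterError("trial count is not a multiple of trials_per_block")
    B = S * nb
    ref = data.referent[:, ::tpb].reshape(B)
    outc = data.outcome.reshape(B, tpb)
    ch = data.choice.reshape(B, tpb)
    fb = data.feedback.reshape(B, tpb)
    subj = np.repeat(np.arange(S), nb)
    return S, nb, tpb, B, ref, outc, ch, fb, subj


def _assoc_loglik(spec: ModelSpec, native: np.ndarray, data: SessionArrays,
                  grad: bool, mask: np.ndarray | None = None):
    S, nb, tpb, B, ref, outc, ch_all, fb, subj = _block_major(data)
    names = spec.names
    lam = _expand_lambdas(spec, native)
    tau = native[:, names.index("tau")]
    rho = native[:, names.index("rho")] if spec.include_rho else np.zeros(S)
    q0 = (native[:, names.index("q0_pos")]
          if spec.include_initial_bias else np.zeros(S))
    if np.any(tau <= 0):
        raise ParameterError("tau must be positive")
    mask_b = None if mask is None else np.asarray(mask, float).reshape(B, tpb)

    lam_b = lam[subj, ref, :]  # (B, 2): row referent's lambdas by outcome valence
    tau_b = tau[subj]
    rho_b = rho[subj]
    q0_b = q0[subj]
    rb = np.arange(B)

    Q = np.zeros((B, 2))
    Q[:, 1] = q0_b
    ll = np.empty((B, tpb))
    if grad:
        # Q sensitivities wrt (lam[ref, neg], lam[ref, pos], q0) of the row's referent
        GQ = np.zeros((B, 2, 3))
        GQ[:, 1, 2] = 1.0
        g_lam_b = np.zeros((B, 2))
        g_tau_b = np.zeros(B)
        g_rho_b = np.zeros(B)
        g_q0_b = np.zeros(B)

    for t in range(tpb):
        val = outc[:, t]
        ch = ch_all[:, t]
        r = fb[:, t]
        d = (Q[:, 1] - Q[:, 0] + rho_b) / tau_b
        ll[:, t] = np.where(ch == 1, _log_sigmoid(d), _log_sigmoid(-d))
        lam_used = lam_b[rb, val]
        qa = Q[rb, ch]
        pe = r - qa
        if grad:
            e = ch - _sigmoid(d)
            if mask_b is not None:
                e = e * mask_b[:, t]
            et = e / tau_b
            dG = (GQ[:, 1, :] - GQ[:, 0, :]) * et[:, None]
            g_lam_b += dG[:, :2]
            g_q0_b += dG[:, 2]
            g_rho_b += et
            g_tau_b += -e * d / tau_b
            Ga = GQ[rb, ch, :]
            Ga *= (1.0 - lam_used)[:, None]
            Ga[rb, val] += pe
            GQ[rb, ch, :] = Ga
        Q[rb, ch] = qa + lam_used * pe

    ll = ll.reshape(S, nb * tpb)
    if not grad:
        return ll, None
    # scatter row gradients to the four (referent, valence) slots, then to names
    g4 = np.zeros((B, 4))
    g4[rb, ref * 2 + 0] = g_lam_b[:, 0]
    g4[rb, ref * 2 + 1] = g_lam_b[:, 1]
    g4 = g4.reshape(S, nb, 4).sum(axis=1)
    g = np.zeros((S, spec.n_params))
    for j, name in enumerate(VARIANT_LAMBDAS[spec.variant]):
        for (rf, vl) in _LAMBDA_SLOTS[name]:
            g[:, j] += g4[:, rf * 2 + vl]
    g[:, names.index("tau")] = g_tau_b.reshape(S, nb).sum(axis=1)
    if spec.include_rho:
        g[:, names.index("rho")] = g_rho_b.reshape(S, nb).sum(axis=1)
    if spec.include_initial_bias:
        g[:, names.index("q0_pos")] = g_q0_b.reshape(S, nb).sum(axis=1)
    return ll, g


# ---------------------------------------------------------------------------
# Belief kernel

def _belief_inputs(spec: ModelSpec, native: np.ndarray):
    S = native.shape[0]
    names = spec.names
    at = np.empty((S, 2))
    bt = np.empty((S, 2))
    eta = np.empty((S, 2))
    if spec.variant == "shared":
        at[:, 0] = at[:, 1] = native[:, names.index("alpha_trait")]
        bt[:, 0] = bt[:, 1] = native[:, names.index("beta_trait")]
    else:
        at[:, 0] = native[:, names.index("alpha_self")]
        at[:, 1] = native[:, names.index("alpha_other")]
        bt[:, 0] = native[:, names.index("beta_self")]
        bt[:, 1] = native[:, names.index("beta_other")]
    if spec.variant == "selfother_full":
        eta[:, 0] = native[:, names.index("eta_self")]
        eta[:, 1] = native[:, names.index("eta_other")]
    else:
        eta[:, 0] = eta[:, 1] = native[:, names.index("eta")]
    tau = native[:, names.index("tau")]
    if spec.include_initial_bias:
        ai = native[:, names.index("alpha_init")]
        bi = native[:, names.index("beta_init")]
    else:
        ai = np.zeros(S)
        bi = np.zeros(S)
    return at, bt, eta, tau, ai, bi


def _belief_loglik(spec: ModelSpec, native: np.ndarray, data: SessionArrays,
                   grad: bool, mask: np.ndarray | None = None):
    S, nb, tpb, B, ref, outc, ch_all, fb, subj = _block_major(data)
    at, bt, eta, tau, ai, bi = _belief_inputs(spec, native)
    if np.any(tau <= 0):
        raise ParameterError("tau must be positive")
    mask_b = None if mask is None else np.asarray(mask, float).reshape(B, tpb)

    at_b = at[subj, ref]
    bt_b = bt[subj, ref]
    eta_b = eta[subj, ref]
    tau_b = tau[subj]
    AS = np.full(B, 1.0) * ai[subj]
    BS = np.full(B, 1.0) * bi[subj]
    ll = np.empty((B, tpb))
    if grad:
        # state sensitivities wrt (eta of the row referent, own init)
        GA = np.zeros((B, 2))
        GA[:, 1] = 1.0
        GB = np.zeros((B, 2))
        GB[:, 1] = 1.0
        g_at_b = np.zeros(B)
        g_bt_b = np.zeros(B)
        g_eta_b = np.zeros(B)
        g_tau_b = np.zeros(B)
        g_ai_b = np.zeros(B)
        g_bi_b = np.zeros(B)

    for t in range(tpb):
        o = outc[:, t]
        ch = ch_all[:, t]
        A = at_b + AS
        Bn = bt_b + BS
        N = A + Bn
        if np.any(N <= 0):
            raise DegenerateBeliefError(
                "zero total evidence encountered in likelihood evaluation"
            )
        p = A / N
        d = (2.0 * p - 1.0) / tau_b
        ll[:, t] = np.where(ch == 1, _log_sigmoid(d), _log_sigmoid(-d))
        if grad:
            e = ch - _sigmoid(d)
            if mask_b is not None:
                e = e * mask_b[:, t]
            dll_dp = e * 2.0 / tau_b
            dA = dll_dp * Bn / N**2
            dB = -dll_dp * A / N**2
            g_at_b += dA
            g_bt_b += dB
            g_eta_b += dA * GA[:, 0] + dB * GB[:, 0]
            g_ai_b += dA * GA[:, 1]
            g_bi_b += dB * GB[:, 1]
            g_tau_b += -e * d / tau_b
            GA[:, 0] = AS + eta_b * GA[:, 0]
            GA[:, 1] *= eta_b
            GB[:, 0] = BS + eta_b * GB[:, 0]
            GB[:, 1] *= eta_b
        AS = eta_b * AS + o
        BS = eta_b * BS + (1 - o)

    ll = ll.reshape(S, nb * tpb)
    if not grad:
        return ll, None

    def _by_ref(gb):
        g2 = np.zeros((B, 2))
        g2[np.arange(B), ref] = gb
        return g2.reshape(S, nb, 2).sum(axis=1)

    g_at = _by_ref(g_at_b)
    g_bt = _by_ref(g_bt_b)
    g_eta = _by_ref(g_eta_b)
    g = np.zeros((S, spec.n_params))
    names = spec.names
    if spec.variant == "shared":
        g[:, names.index("alpha_trait")] = g_at.sum(axis=1)
        g[:, names.index("beta_trait")] = g_bt.sum(axis=1)
    else:
        g[:, names.index("alpha_self")] = g_at[:, 0]
        g[:, names.index("alpha_other")] = g_at[:, 1]
        g[:, names.index("beta_self")] = g_bt[:, 0]
        g[:, names.index("beta_other")] = g_bt[:, 1]
    if spec.variant == "selfother_full":
        g[:, names.index("eta_self")] = g_eta[:, 0]
        g[:, names.index("eta_other")] = g_eta[:, 1]
    else:
        g[:, names.index("eta")] = g_eta.sum(axis=1)
    g[:, names.index("tau")] = g_tau_b.reshape(S, nb).sum(axis=1)
    if spec.include_initial_bias:
        g[:, names.index("alpha_init")] = g_ai_b.reshape(S, nb).sum(axis=1)
        g[:, names.index("beta_init")] = g_bi_b.reshape(S, nb).sum(axis=1)
    return ll, g


# ---------------------------------------------------------------------------
# Public entry points

def loglik_matrix(
    spec: ModelSpec,
    native: np.ndarray,
    data: SessionArrays,
    grad: bool = False,
    grad_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-trial log-likelihood matrix (S, T) for native parameters (S, K).

    With ``grad=True`` also returns the gradient (S, K) of each subject's
    total log-likelihood with respect to that subject's native parameters.
    ``grad_mask`` (S, T) restricts the gradient to the masked total (masked-out
    trials still drive the learning dynamics); the returned matrix is always
    the full per-trial log-likelihood.
    """
    native = np.atleast_2d(np.asarray(native, dtype=float))
    if native.shape != (data.n_subjects, spec.n_params):
        raise ParameterError(
            f"native parameters must be ({data.n_subjects}, {spec.n_params}), "
            f"got {native.shape}"
        )
    if not np.all(np.isfinite(native)):
        raise ParameterError("non-finite value in parameters")
    if spec.family == "assoc":
        return _assoc_loglik(spec, native, data, grad, grad_mask)
    return _belief_loglik(spec, native, data, grad, grad_mask)


def loglik_unconstrained(
    spec: ModelSpec,
    x: np.ndarray,
    data: SessionArrays,
    grad: bool = False,
    grad_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """As :func:`loglik_matrix`, on the unconstrained fitting scale."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    native = to_native(spec, x)
    ll, g = loglik_matrix(spec, native, data, grad, grad_mask)
    if grad:
        g = g * native_jacobian(spec, x)
    return ll, g
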