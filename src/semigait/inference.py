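"""Exact filtering, smoothing and decoding over the composite ``(v, d)`` chain.

All recursions run in log domain: the dynamic range of the per-state
likelihood terms on sharply separated gait data routinely exceeds what
probability-space scaling can represent (posterior support at a hard activity
boundary can sit hundreds of log-units below the filtered mode), and the
per-entry log-sum-exp recursion keeps every state's weight exact.  The
posterior tables handed to callers (filtering, smoothing, responsibilities,
pairwise expectations) are ratio forms and are exported in probability space.

The composite transition is never materialized here: the countdown part is a
column shift of the ``(v, d)``-shaped table and the free part is a small
log-matrix-vector product with the switch matrix followed by adding the
fresh-sojourn log-law, giving ``O(N * (n_v^2 + n_states))`` per pass instead
of ``O(N * n_states^2)``.  The dense matrix
(:func:`semigait.model.joint_transition`) is kept for cross-checks.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .model import (
    ModelParams,
    StateSpace,
    emission_loglik,
)


class UnderflowError(RuntimeError):
    """All composite states received zero likelihood at some step."""

    def __init__(self, step: int):
        super().__init__(
            f"emission likelihood underflowed to zero at step {step}"
        )
        self.step = step


@dataclasses.dataclass
class ObservationSequence:
    """An ``N x w`` feature matrix with timing metadata and optional labels.

    ``labels`` (activities) and ``phase_labels`` are 0-based when present and
    are carried only for supervised initialization and evaluation.
    """

    values: np.ndarray
    rate: Optional[float] = None
    labels: Optional[np.ndarray] = None
    phase_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 1:
            raise ValueError("need at least one observation")
        if not np.isfinite(self.values).all():
            raise ValueError("observations contain non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def w(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class PosteriorSet:
    """Filtered/smoothed posteriors and the E-step expectations.

    Attributes
    ----------
    alpha_hat : (N, n_states) filtering distributions ``p(v_n, d_n | y_1..n)``.
    beta_hat : (N, n_states) scaled backward variables (all ones at ``n = N``).
    log_scale : (N,) per-step log-normalizers; their sum is ``loglik``.
    gamma : (N, n_states) smoothed composite posteriors.
    gamma_v : (N, n_v) smoothed posteriors marginalized over the counter.
    resp : (N, n_v, kappa) joint cell/mixture-component posteriors; summing
        over components recovers ``gamma_v``.
    trans_free : (n_v, n_v, ell+1) pairwise posteriors accumulated over time,
        restricted to transitions out of ``d = 0`` (the only stochastic rows);
        entry ``[v, v', d']`` is ``sum_n p(v_n=v, d_n=0, v_{n+1}=v',
        d_{n+1}=d' | y)``.
    xi_dense : optional (n_states, n_states) accumulated pairwise posteriors
        over all composite pairs (computed on request; used for fidelity
        checks of the factored representation).
    loglik : total ``log p(y_1..N)``.
    """

    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    log_scale: np.ndarray
    gamma: np.ndarray
    gamma_v: np.ndarray
    resp: np.ndarray
    trans_free: np.ndarray
    loglik: float
    xi_dense: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Factored application of the composite transition
# ---------------------------------------------------------------------------


def _safe_log(arr: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(arr)


def _lse(a: np.ndarray, axis=None):
    """log-sum-exp with a max shift; all-(-inf) slices stay -inf."""
    if axis is None:
        m = a.max()
        if not np.isfinite(m):
            return -np.inf
        return float(np.log(np.exp(a - m).sum()) + m)
    m = np.max(a, axis=axis, keepdims=True)
    shift = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.sum(np.exp(a - shift), axis=axis, keepdims=True)) + shift
    return np.squeeze(out, axis=axis)


def _log_trans(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    return _safe_log(params.pstar), _safe_log(params.pdur)


def _predict(dist: np.ndarray, params: ModelParams, space: StateSpace) -> np.ndarray:
    """One push-forward through the composite transition: ``A^T dist``
    (probability space; used where the distribution is well scaled).

    Countdown mass shifts down one column, free mass (``d = 0``)
    redistributes through ``pstar`` and draws a fresh counter from ``pdur``.
    """
    g = dist.reshape(space.n_v, space.n_dur)
    out = np.zeros_like(g)
    if space.ell > 0:
        out[:, :-1] += g[:, 1:]
    fresh = params.pstar.T @ g[:, 0]
    out += fresh[:, None] * params.pdur
    return out.ravel()


def _predict_log(
    la_flat: np.ndarray, logpstar: np.ndarray, logpdur: np.ndarray,
    space: StateSpace,
) -> np.ndarray:
    """Log-domain push-forward ``log(A^T exp(la))``."""
    la = la_flat.reshape(space.n_v, space.n_dur)
    s = _lse(la[:, 0][:, None] + logpstar, axis=0)  # switch mass per target
    free = s[:, None] + logpdur
    out = np.full_like(la, -np.inf)
    if space.ell > 0:
        out[:, :-1] = la[:, 1:]
    return np.logaddexp(out, free).ravel()


def _backward_log(
    g_flat: np.ndarray, logpstar: np.ndarray, logpdur: np.ndarray,
    space: StateSpace,
) -> np.ndarray:
    """Log-domain backward step ``log(A exp(g))`` for
    ``g = logb_{n+1} + lbeta_{n+1}``."""
    g = g_flat.reshape(space.n_v, space.n_dur)
    t = _lse(logpdur + g, axis=1)  # fresh-sojourn average per target cell
    out = np.empty_like(g)
    if space.ell > 0:
        out[:, 1:] = g[:, :-1]
    out[:, 0] = _lse(logpstar + t[None, :], axis=1)
    return out.ravel()


def _log_b_composite(obs: ObservationSequence, params: ModelParams,
                     space: StateSpace) -> tuple[np.ndarray, np.ndarray]:
    """Emission log-densities per cell, plus the per-component table."""
    logB, comp = emission_loglik(obs.values, params)
    return logB, comp


def _expand(b_v: np.ndarray, space: StateSpace) -> np.ndarray:
    """Broadcast per-cell emission values over the counter dimension."""
    return np.repeat(b_v, space.n_dur)


def _correct_log(
    lpred: np.ndarray, logB_row: np.ndarray, space: StateSpace, step: int
) -> tuple[np.ndarray, float]:
    """Bayes correction in log space: returns the normalized log-filter and
    the log normalizer ``log p(y_n | y_1..n-1)``."""
    la = lpred + _expand(logB_row, space)
    c = _lse(la)
    if not np.isfinite(c):
        raise UnderflowError(step)
    return la - c, c


def _forward_log(
    logB: np.ndarray,
    params: ModelParams,
    space: StateSpace,
    init: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized log-filtering table and per-step log normalizers."""
    N = logB.shape[0]
    prior = params.zeta if init is None else np.asarray(init, dtype=float)
    logpstar, logpdur = _log_trans(params)
    la = np.empty((N, space.n_states))
    log_scale = np.empty(N)
    lpred = _safe_log(prior)
    for n in range(N):
        la[n], log_scale[n] = _correct_log(lpred, logB[n], space, n)
        if n + 1 < N:
            lpred = _predict_log(la[n], logpstar, logpdur, space)
    return la, log_scale


# ---------------------------------------------------------------------------
# Forward / backward / smoothing
# ---------------------------------------------------------------------------


def forward(
    obs: ObservationSequence,
    params: ModelParams,
    space: StateSpace,
    *,
    init: Optional[np.ndarray] = None,
    logB: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward pass.

    Returns ``(alpha_hat, log_scale, loglik)`` where ``alpha_hat[n]`` is the
    filtering distribution ``p(v_n, d_n | y_1..n)`` and
    ``loglik = sum(log_scale)``.

    ``init`` overrides the predictive distribution for the first sample
    (defaults to ``params.zeta``); ``logB`` accepts a precomputed (N, n_v)
    emission table.
    """
    if logB is None:
        logB, _ = _log_b_composite(obs, params, space)
    la, log_scale = _forward_log(logB, params, space, init=init)
    return np.exp(la), log_scale, float(log_scale.sum())


def backward(
    obs: ObservationSequence,
    params: ModelParams,
    space: StateSpace,
    log_scale: Optional[np.ndarray] = None,
    *,
    logB: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Backward pass, renormalized per step by its own maximum.

    Every posterior quantity is a ratio in which the per-step scale cancels,
    so the choice of scale is free; the recursion itself runs in log domain.
    ``beta[N] = 1`` everywhere.  ``log_scale`` is accepted for interface
    symmetry with :func:`forward` but not needed.
    """
    if logB is None:
        logB, _ = _log_b_composite(obs, params, space)
    N = logB.shape[0]
    logpstar, logpdur = _log_trans(params)
    lb = np.empty((N, space.n_states))
    lb[N - 1] = 0.0
    for n in range(N - 2, -1, -1):
        g = _expand(logB[n + 1], space) + lb[n + 1]
        lb_un = _backward_log(g, logpstar, logpdur, space)
        mx = lb_un.max()
        if not np.isfinite(mx):
            raise UnderflowError(n)
        lb[n] = lb_un - mx
    return np.exp(lb)


def filter_step(
    prev_filter: np.ndarray,
    y_new: np.ndarray,
    params: ModelParams,
    space: StateSpace,
) -> tuple[np.ndarray, float]:
    """One on-line forward update from the previous filtering distribution.

    Returns the new filtering distribution and the log incremental evidence
    ``log p(y_new | y_past)``.
    """
    logpstar, logpdur = _log_trans(params)
    lpred = _predict_log(
        _safe_log(np.asarray(prev_filter, dtype=float)), logpstar, logpdur, space
    )
    logB, _ = emission_loglik(np.atleast_2d(y_new), params)
    lf, c = _correct_log(lpred, logB[0], space, -1)
    return np.exp(lf), c


def smooth(
    obs: ObservationSequence,
    params: ModelParams,
    space: StateSpace,
    *,
    init: Optional[np.ndarray] = None,
    dense_xi: bool = False,
    logB: Optional[np.ndarray] = None,
    comp: Optional[np.ndarray] = None,
) -> PosteriorSet:
    """Full forward–backward smoothing with E-step expectations.

    ``dense_xi=True`` additionally accumulates the full composite pairwise
    posterior table (quadratic in the state count; for cross-checks only).
    """
    if logB is None or comp is None:
        logB, comp = _log_b_composite(obs, params, space)
    N = logB.shape[0]
    la, log_scale = _forward_log(logB, params, space, init=init)
    loglik = float(log_scale.sum())
    logpstar, logpdur = _log_trans(params)
    lb = np.empty((N, space.n_states))
    lb[N - 1] = 0.0
    trans_free = np.zeros((space.n_v, space.n_v, space.n_dur))
    xi_dense = np.zeros((space.n_states, space.n_states)) if dense_xi else None
    nd = space.n_dur
    for n in range(N - 2, -1, -1):
        g_flat = _expand(logB[n + 1], space) + lb[n + 1]
        lb_un = _backward_log(g_flat, logpstar, logpdur, space)
        if not np.isfinite(lb_un.max()):
            raise UnderflowError(n)
        # pairwise posterior normalizer: log-sum over all (l, k) pairs
        lognorm = _lse(la[n] + lb_un)
        g = g_flat.reshape(space.n_v, nd)
        la0 = la[n].reshape(space.n_v, nd)[:, 0]
        lx = (
            la0[:, None, None] + logpstar[:, :, None]
            + (logpdur + g)[None, :, :] - lognorm
        )
        trans_free += np.exp(lx)
        if dense_xi:
            al = la[n].reshape(space.n_v, nd)
            # countdown rows: (v, d>0) -> (v, d-1), deterministic
            if space.ell > 0:
                for v in range(space.n_v):
                    rows = v * nd + np.arange(1, nd)
                    cols = v * nd + np.arange(0, nd - 1)
                    xi_dense[rows, cols] += np.exp(al[v, 1:] + g[v, :-1] - lognorm)
            for v in range(space.n_v):
                xi_dense[v * nd, :] += np.exp(lx[v]).ravel()
        lb[n] = lb_un - lb_un.max()
    lg = la + lb
    gamma = np.exp(lg - _lse(lg, axis=1)[:, None])
    alpha = np.exp(la)
    beta = np.exp(lb)
    gamma_v = gamma.reshape(N, space.n_v, nd).sum(axis=2)
    # mixture responsibilities: gamma_v split across components (Eq-15 form)
    with np.errstate(divide="ignore"):
        logw = np.log(params.weights)
    logpost = comp + logw[None, :, :] - logB[:, :, None]
    resp = gamma_v[:, :, None] * np.exp(logpost)
    return PosteriorSet(
        alpha_hat=alpha, beta_hat=beta, log_scale=log_scale,
        gamma=gamma, gamma_v=gamma_v, resp=resp,
        trans_free=trans_free, loglik=loglik, xi_dense=xi_dense,
    )


# ---------------------------------------------------------------------------
# Marginals and decoding
# ---------------------------------------------------------------------------


def marginal_activity(post: PosteriorSet, space: StateSpace) -> np.ndarray:
    """Smoothed ``p(x_n | y_1..N)`` — an (N, r) row-stochastic matrix."""
    N = post.gamma_v.shape[0]
    return post.gamma_v.reshape(N, space.r, space.tau).sum(axis=2)


def marginal_phase(post: PosteriorSet, space: StateSpace) -> np.ndarray:
    """Smoothed ``p(u_n | y_1..N)`` — an (N, tau) row-stochastic matrix."""
    N = post.gamma_v.shape[0]
    return post.gamma_v.reshape(N, space.r, space.tau).sum(axis=1)


def filtered_marginals(
    filt: np.ndarray, space: StateSpace
) -> tuple[np.ndarray, np.ndarray]:
    """Activity and phase marginals of one filtering distribution."""
    g = filt.reshape(space.r, space.tau, space.n_dur).sum(axis=2)
    return g.sum(axis=1), g.sum(axis=0)


def mpm_decode(marginals: np.ndarray) -> np.ndarray:
    """Maximum-posterior-mode decoding: per-sample argmax of the marginals.

    Ties break toward the lowest index (``np.argmax`` convention).
    """
    return np.argmax(marginals, axis=-1)


def export_posteriors(
    path, post: PosteriorSet, space: StateSpace
) -> None:
    """Write per-sample activity/phase posteriors and MPM decodes as CSV."""
    import pandas as pd

    act = marginal_activity(post, space)
    ph = marginal_phase(post, space)
    cols = {f"p_activity_{a + 1}": act[:, a] for a in range(space.r)}
    cols.update({f"p_phase_{u + 1}": ph[:, u] for u in range(space.tau)})
    cols["activity_mpm"] = mpm_decode(act) + 1
    cols["phase_mpm"] = mpm_decode(ph) + 1
    pd.DataFrame(cols).to_csv(path, index=False)
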