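"""Batch EM (Baum–Welch) for the semi-Markov triplet model.

Two equivalent M-step routes are provided:

* :func:`m_step` — directly from a :class:`~semigait.inference.PosteriorSet`;
* :func:`complete_stats` + :func:`params_from_stats` — through the five
  running expectation tables ``S1..S5`` of the exponential-family view.  On a
  full sequence the two routes coincide to floating-point precision; the
  statistics route is the one the on-line learner blends incrementally.

Transition estimation works on the factored form: only rows with ``d = 0``
carry free probability, so the accumulated pairwise posteriors restricted to
those rows are renormalized into the switch matrix ``pstar`` (marginalizing
the fresh counter) and the sojourn law ``pdur`` (marginalizing the source
cell).  A dense estimate over all composite rows would re-derive the
deterministic countdown entries exactly, so nothing is lost.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
from scipy.signal import find_peaks
from sklearn.mixture import GaussianMixture

from .model import (
    REG_FLOOR,
    ModelParams,
    StateSpace,
    TransitionMask,
    initial_distribution,
)
from .inference import ObservationSequence, PosteriorSet, smooth

logger = logging.getLogger("semigait")

#: Occupancy below which a cell/component is considered starved and kept at
#: its previous value during the M-step.
EMPTY_EPS = 1e-10


@dataclasses.dataclass
class SufficientStats:
    """Per-sample expectations of the complete-data sufficient statistics.

    All tables are normalized by the number of samples absorbed (``n_eff``),
    i.e. they are expectations per time step, which is the form the on-line
    stochastic-approximation update blends.

    ``s1`` (n_v, n_v, ell+1): free-transition expectations
    ``[v, v', d']`` = mean over n of ``p(v_n=v, d_n=0, v_{n+1}=v',
    d_{n+1}=d' | y)``; ``s2`` (n_states,): composite occupancies;
    ``s2_marg`` (n_v,): occupancies marginalized over the counter;
    ``s3`` (n_v, kappa): cell/component occupancies; ``s4`` (n_v, kappa, w):
    component-weighted observation sums; ``s5`` (n_v, kappa, w, w):
    component-weighted outer-product sums; ``gamma1``: the smoothed posterior
    of the first sample (only used for the initial law in batch mode).
    """

    s1: np.ndarray
    s2: np.ndarray
    s2_marg: np.ndarray
    s3: np.ndarray
    s4: np.ndarray
    s5: np.ndarray
    gamma1: np.ndarray
    n_eff: float

    def blend(self, other: "SufficientStats", rho: float) -> "SufficientStats":
        """Stochastic-approximation update ``S <- (1-rho) S + rho S_new``."""
        keep = 1.0 - rho
        return SufficientStats(
            s1=keep * self.s1 + rho * other.s1,
            s2=keep * self.s2 + rho * other.s2,
            s2_marg=keep * self.s2_marg + rho * other.s2_marg,
            s3=keep * self.s3 + rho * other.s3,
            s4=keep * self.s4 + rho * other.s4,
            s5=keep * self.s5 + rho * other.s5,
            gamma1=other.gamma1,
            n_eff=keep * self.n_eff + rho * other.n_eff,
        )


@dataclasses.dataclass
class FitReport:
    """Outcome of a batch EM run.

    ``final_stats`` holds the pooled expected sufficient statistics of the
    last E-step — the training data's per-sample expectations under the
    fitted model, usable as the warm start of the on-line learner.
    """

    loglik_trace: list[float]
    n_iter: int
    converged: bool
    params: ModelParams
    final_stats: Optional[SufficientStats] = None


# ---------------------------------------------------------------------------
# E-step accumulation -> statistics
# ---------------------------------------------------------------------------


def complete_stats(post: PosteriorSet, obs: ObservationSequence) -> SufficientStats:
    """Expected sufficient statistics of a smoothed sequence, per sample."""
    Y = obs.values
    N = Y.shape[0]
    s3 = post.resp.sum(axis=0)
    s4 = np.einsum("nij,nw->ijw", post.resp, Y)
    s5 = np.einsum("nij,nw,nx->ijwx", post.resp, Y, Y)
    return SufficientStats(
        s1=post.trans_free / N,
        s2=post.gamma.sum(axis=0) / N,
        s2_marg=post.gamma_v.sum(axis=0) / N,
        s3=s3 / N,
        s4=s4 / N,
        s5=s5 / N,
        gamma1=post.gamma[0].copy(),
        n_eff=float(N),
    )


def _floor_cov(cov: np.ndarray, reg: float) -> np.ndarray:
    """Constrained covariance update: clip eigenvalues below ``reg``.

    Clipping in the eigenbasis is the exact maximizer of the expected
    complete-data log-likelihood over covariances whose eigenvalues are at
    least ``reg``, so EM with this floor stays monotone; a healthy covariance
    passes through bit-for-bit.
    """
    cov = 0.5 * (cov + cov.T)
    lam, U = np.linalg.eigh(cov)
    if lam[0] >= reg:
        return cov
    return (U * np.clip(lam, reg, None)) @ U.T


def _normalize_rows(
    num: np.ndarray,
    allowed: Optional[np.ndarray],
    prev: Optional[np.ndarray],
) -> np.ndarray:
    """Row-normalize ``num`` onto ``allowed`` support; starved rows fall back
    to the previous value (or uniform over the support)."""
    out = num.copy()
    if allowed is not None:
        out[~allowed] = 0.0
    sums = out.sum(axis=1)
    for i in np.flatnonzero(sums <= EMPTY_EPS):
        if prev is not None:
            out[i] = prev[i]
        elif allowed is not None:
            out[i] = allowed[i] / allowed[i].sum()
        else:
            out[i] = 1.0 / out.shape[1]
        sums[i] = out[i].sum()
        logger.warning("transition row %d starved; kept fallback value", i)
    return out / sums[:, None]


def params_from_stats(
    stats: SufficientStats,
    space: StateSpace,
    mask: TransitionMask,
    prev: Optional[ModelParams] = None,
    *,
    update_zeta: bool = True,
    reg: float = REG_FLOOR,
) -> ModelParams:
    """Closed-form M-step from the sufficient statistics.

    ``prev`` supplies fallback values for starved cells and the initial law /
    components that are not being updated.
    """
    # de-normalize so starvation thresholds see absolute expected counts,
    # exactly as the direct M-step does
    n_eff = max(stats.n_eff, 1.0)
    pstar = _normalize_rows(
        stats.s1.sum(axis=2) * n_eff, mask.allowed, prev.pstar if prev else None
    )
    pdur = _normalize_rows(
        stats.s1.sum(axis=0) * n_eff, None, prev.pdur if prev else None
    )
    n_v, kappa = stats.s3.shape
    w = stats.s4.shape[2]
    weights = np.empty((n_v, kappa))
    means = np.empty((n_v, kappa, w))
    covs = np.empty((n_v, kappa, w, w))
    eye = np.eye(w)
    for i in range(n_v):
        occ_i = stats.s2_marg[i] * n_eff
        if occ_i <= EMPTY_EPS and prev is not None:
            weights[i] = prev.weights[i]
            means[i] = prev.means[i]
            covs[i] = prev.covs[i]
            logger.warning("cell %d unoccupied; kept previous emission params", i)
            continue
        for j in range(kappa):
            occ = stats.s3[i, j] * n_eff
            weights[i, j] = occ / occ_i
            if occ <= EMPTY_EPS:
                # weight follows the (vanishing) occupancy; moments are kept
                if prev is not None:
                    means[i, j] = prev.means[i, j]
                    covs[i, j] = prev.covs[i, j]
                else:
                    means[i, j] = 0.0
                    covs[i, j] = eye
                logger.debug("component (%d,%d) starved; moments kept", i, j)
                continue
            mu = stats.s4[i, j] / stats.s3[i, j]
            means[i, j] = mu
            cov = stats.s5[i, j] / stats.s3[i, j] - np.outer(mu, mu)
            covs[i, j] = _floor_cov(cov, reg)
        wsum = weights[i].sum()
        if wsum > 0:
            weights[i] /= wsum
    if update_zeta:
        zeta = stats.gamma1.copy()
    elif prev is not None:
        zeta = prev.zeta.copy()
    else:
        zeta = initial_distribution(np.full(n_v, 1.0 / n_v), pdur)
    return ModelParams(zeta, pstar, pdur, weights, means, covs)


def m_step(
    post: PosteriorSet,
    obs: ObservationSequence,
    space: StateSpace,
    mask: TransitionMask,
    prev: Optional[ModelParams] = None,
    *,
    reg: float = REG_FLOOR,
) -> ModelParams:
    """Direct M-step from smoothed posteriors.

    The initial law becomes the first smoothed marginal; ``pstar``/``pdur``
    come from the accumulated free pairwise posteriors; weights, means and
    covariances are responsibility-weighted moments (biased ``1/N``
    covariance, no Bessel correction, plus the diagonal regularization
    floor).
    """
    Y = obs.values
    pstar = _normalize_rows(
        post.trans_free.sum(axis=2), mask.allowed, prev.pstar if prev else None
    )
    pdur = _normalize_rows(
        post.trans_free.sum(axis=0), None, prev.pdur if prev else None
    )
    n_v, kappa = post.resp.shape[1:]
    w = Y.shape[1]
    occ = post.resp.sum(axis=0)          # (n_v, kappa)
    occ_v = post.gamma_v.sum(axis=0)     # (n_v,)
    weights = np.empty((n_v, kappa))
    means = np.empty((n_v, kappa, w))
    covs = np.empty((n_v, kappa, w, w))
    eye = np.eye(w)
    for i in range(n_v):
        if occ_v[i] <= EMPTY_EPS and prev is not None:
            weights[i] = prev.weights[i]
            means[i] = prev.means[i]
            covs[i] = prev.covs[i]
            logger.warning("cell %d unoccupied; kept previous emission params", i)
            continue
        for j in range(kappa):
            weights[i, j] = occ[i, j] / occ_v[i]
            if occ[i, j] <= EMPTY_EPS:
                if prev is not None:
                    means[i, j] = prev.means[i, j]
                    covs[i, j] = prev.covs[i, j]
                else:
                    means[i, j] = 0.0
                    covs[i, j] = eye
                logger.debug("component (%d,%d) starved; moments kept", i, j)
                continue
            r = post.resp[:, i, j]
            mu = r @ Y / occ[i, j]
            means[i, j] = mu
            diff = Y - mu
            cov = (r[:, None] * diff).T @ diff / occ[i, j]
            covs[i, j] = _floor_cov(cov, reg)
        wsum = weights[i].sum()
        if wsum > 0:
            weights[i] /= wsum
    return ModelParams(post.gamma[0].copy(), pstar, pdur, weights, means, covs)


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def pool_stats(stats_list: list[SufficientStats]) -> SufficientStats:
    """Combine per-sequence statistics, weighting by sequence length.

    The per-sample expectation tables pool linearly; the first-sample
    posterior is averaged across sequences (each sequence restarts from the
    initial law).
    """
    n_tot = sum(s.n_eff for s in stats_list)
    acc = stats_list[0]
    out = SufficientStats(
        s1=sum(s.s1 * s.n_eff for s in stats_list) / n_tot,
        s2=sum(s.s2 * s.n_eff for s in stats_list) / n_tot,
        s2_marg=sum(s.s2_marg * s.n_eff for s in stats_list) / n_tot,
        s3=sum(s.s3 * s.n_eff for s in stats_list) / n_tot,
        s4=sum(s.s4 * s.n_eff for s in stats_list) / n_tot,
        s5=sum(s.s5 * s.n_eff for s in stats_list) / n_tot,
        gamma1=sum(s.gamma1 for s in stats_list) / len(stats_list),
        n_eff=float(n_tot),
    )
    return out if len(stats_list) > 1 else acc


def _rescue_dead_components(
    params: ModelParams, resp: np.ndarray, gamma_v: np.ndarray, Y: np.ndarray,
    skip: set = frozenset(),
) -> set:
    """Re-seed mixture components whose weight collapsed to exactly zero.

    A weight-zero component can never regain responsibility (its posterior
    weight is identically zero from then on), so it is re-seeded at the
    observation farthest (Mahalanobis, under the cell's first live component)
    from the cell's occupancy-weighted mean and given a small weight.
    Mutates ``params`` in place.  A merely tiny weight is left alone — EM
    handles it monotonically — so this rescue never fires on healthy fits.
    """
    occ = resp.sum(axis=0)
    n_v, kappa = occ.shape
    done: set = set()
    for i in range(n_v):
        dead = [j for j in np.flatnonzero(params.weights[i] == 0.0)
                if (i, int(j)) not in skip]
        live = np.flatnonzero(params.weights[i] > 0.0)
        if not dead or live.size == 0:
            continue
        gv = gamma_v[:, i]
        if gv.sum() <= EMPTY_EPS:
            continue
        center = gv @ Y / gv.sum()
        ref = live[0]
        prec = np.linalg.inv(params.covs[i, ref])
        diff = Y - center
        d2 = np.einsum("nw,wx,nx->n", diff, prec, diff)
        for j in dead:
            far = int(np.argmax(gv * d2))
            params.means[i, j] = Y[far]
            params.covs[i, j] = params.covs[i, ref].copy()
            params.weights[i, j] = 0.05
            done.add((i, int(j)))
            logger.warning("re-seeded dead component (%d,%d) at sample %d", i, j, far)
        params.weights[i] /= params.weights[i].sum()
    return done


def em_fit(
    obs,
    init: ModelParams,
    space: StateSpace,
    mask: TransitionMask,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
    reg: float = REG_FLOOR,
    rescue_dead: bool = False,
) -> FitReport:
    """Batch EM from ``init``; stops after ``max_iter`` iterations or when the
    relative log-likelihood improvement drops below ``tol``.

    ``obs`` may be a single :class:`ObservationSequence` or a list of them
    (e.g. one recording per subject): each sequence gets its own
    forward–backward pass restarting from the initial law, and the
    expectations pool across sequences before the shared M-step.

    ``rescue_dead`` re-seeds mixture components whose weight collapses to
    exactly zero (at most once per component).  Re-seeding necessarily breaks
    the monotone log-likelihood guarantee for that iteration, so it is off by
    default.
    """
    seqs = list(obs) if isinstance(obs, (list, tuple)) else [obs]
    params = init.copy()
    trace: list[float] = []
    converged = False
    rescued: set = set()
    for it in range(max_iter):
        stats_list = []
        loglik = 0.0
        posts = []
        try:
            for s in seqs:
                post = smooth(s, params, space)
                loglik += post.loglik
                stats_list.append(complete_stats(post, s))
                posts.append(post)
        except Exception as exc:
            raise RuntimeError(f"E-step failed at iteration {it}: {exc}") from exc
        trace.append(loglik)
        if it > 0:
            delta = trace[-1] - trace[-2]
            if delta < -1e-8 * max(1.0, abs(trace[-2])):
                logger.warning(
                    "log-likelihood decreased by %.3g at iteration %d", -delta, it
                )
            if abs(delta) < tol * max(1.0, abs(trace[-1])):
                converged = True
                break
        params = params_from_stats(
            pool_stats(stats_list), space, mask, prev=params, reg=reg
        )
        if rescue_dead:
            rescued |= _rescue_dead_components(
                params,
                np.concatenate([p.resp for p in posts], axis=0),
                np.concatenate([p.gamma_v for p in posts], axis=0),
                np.concatenate([s.values for s in seqs], axis=0),
                skip=rescued,
            )
    return FitReport(trace, len(trace), converged, params,
                     final_stats=pool_stats(stats_list))


# ---------------------------------------------------------------------------
# Supervised initialization
# ---------------------------------------------------------------------------


def infer_phase_labels(
    gyr: np.ndarray,
    activity_labels: np.ndarray,
    rate: float,
    *,
    min_cycle_s: float = 0.4,
    smooth_s: float = 0.15,
) -> np.ndarray:
    """Heuristic gait-phase pseudo-labels from the gyroscope magnitude.

    Each contiguous constant-activity segment is processed independently:
    the smoothed angular-rate magnitude is peak-picked to mark cycle
    boundaries and every cycle is split into four phases by duration
    quartiles.  Margins before the first / after the last peak reuse the
    nearest cycle length.  This is a documented substitute for a fully
    specified segmentation and only needs to be roughly phase-consistent.
    """
    mag = np.linalg.norm(np.asarray(gyr, dtype=float), axis=1)
    win = max(1, int(round(smooth_s * rate)))
    kernel = np.ones(win) / win
    smooth_mag = np.convolve(mag, kernel, mode="same")
    phases = np.zeros(len(mag), dtype=int)
    boundaries = np.flatnonzero(np.diff(activity_labels) != 0) + 1
    seg_starts = np.concatenate([[0], boundaries])
    seg_ends = np.concatenate([boundaries, [len(mag)]])
    for s, e in zip(seg_starts, seg_ends):
        seg = smooth_mag[s:e]
        dist = max(2, int(round(min_cycle_s * rate)))
        peaks, _ = find_peaks(seg, distance=dist)
        if len(peaks) < 2:
            # too short to segment: tile a nominal one-second cycle
            cyc = max(4, int(round(rate)))
            phases[s:e] = (np.arange(e - s) % cyc) * 4 // cyc
            continue
        marks = np.concatenate([[max(0, 2 * peaks[0] - peaks[1])], peaks,
                                [min(e - s, 2 * peaks[-1] - peaks[-2])]])
        idx = np.arange(e - s)
        pos = np.searchsorted(marks, idx, side="right") - 1
        pos = np.clip(pos, 0, len(marks) - 2)
        lo = marks[pos]
        hi = np.maximum(marks[pos + 1], lo + 1)
        frac = (idx - lo) / (hi - lo)
        phases[s:e] = np.clip((frac * 4).astype(int), 0, 3)
    return phases


def _duration_from_runs(v_labels: np.ndarray, n_v: int, ell: int) -> np.ndarray:
    """Estimate ``pdur`` from run lengths: a fresh counter ``d`` guarantees a
    dwell of at least ``d + 1`` samples, so ``min(run - 1, ell)`` is a
    (censored) draw from the sojourn law."""
    counts = np.full((n_v, ell + 1), 0.5)  # pseudo-count smoothing
    change = np.flatnonzero(np.diff(v_labels) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(v_labels)]])
    for s, e in zip(starts, ends):
        counts[v_labels[s], min(e - s - 1, ell)] += 1.0
    return counts / counts.sum(axis=1, keepdims=True)


def init_from_labels(
    raw,
    activity_labels: np.ndarray,
    space: StateSpace,
    mask: TransitionMask,
    *,
    feature_window: int,
    seed: int = 0,
    phase_labels: Optional[np.ndarray] = None,
) -> tuple[ModelParams, ObservationSequence]:
    """Supervised initialization from a labelled raw IMU recording.

    Computes sliding features, induces gait-phase pseudo-labels (unless
    provided), fits a k-means-seeded Gaussian mixture per ``(activity,
    phase)`` cell, and estimates ``pstar``/``pdur`` from pseudo-label
    transition and run-length counts (masked and renormalized).

    Raises ``ValueError`` if any activity has fewer than ``kappa * w``
    samples.
    """
    from .features import sliding_features  # local import to avoid a cycle

    activity_labels = np.asarray(activity_labels, dtype=int)
    obs = sliding_features(raw, feature_window)
    obs.labels = activity_labels
    counts = np.bincount(activity_labels, minlength=space.r)
    need = space.kappa * space.w
    for a in np.flatnonzero(counts < need):
        raise ValueError(
            f"activity {a} has only {counts[a]} samples; "
            f"need at least kappa*w = {need} for initialization"
        )
    if phase_labels is None:
        phase_labels = infer_phase_labels(raw.gyr, activity_labels, raw.rate)
    phase_labels = np.asarray(phase_labels, dtype=int) % space.tau
    obs.phase_labels = phase_labels
    v_labels = activity_labels * space.tau + phase_labels

    Y = obs.values
    rng = np.random.default_rng(seed)
    weights = np.empty((space.n_v, space.kappa))
    means = np.empty((space.n_v, space.kappa, space.w))
    covs = np.empty((space.n_v, space.kappa, space.w, space.w))
    eye = np.eye(space.w)
    for v in range(space.n_v):
        cell = Y[v_labels == v]
        if cell.shape[0] < max(space.kappa + 1, 2):
            a = v // space.tau
            cell = Y[activity_labels == a]  # fall back to the whole activity
        if space.kappa == 1:
            weights[v] = 1.0
            means[v, 0] = cell.mean(axis=0)
            c = np.cov(cell.T, ddof=0).reshape(space.w, space.w)
            covs[v, 0] = _floor_cov(c, REG_FLOOR)
            continue
        gm = GaussianMixture(
            n_components=space.kappa, covariance_type="full",
            reg_covar=REG_FLOOR, random_state=int(rng.integers(2**31 - 1)),
            max_iter=50,
        ).fit(cell)
        weights[v] = gm.weights_
        means[v] = gm.means_
        for j in range(space.kappa):
            covs[v, j] = _floor_cov(gm.covariances_[j], REG_FLOOR)

    # transitions from pseudo-label counts, restricted to the mask
    trans = np.full((space.n_v, space.n_v), 0.0)
    change = np.flatnonzero(np.diff(v_labels) != 0) + 1
    for n in change:
        trans[v_labels[n - 1], v_labels[n]] += 1.0
    # self-transition mass: dwell beyond the minimum sojourn
    run_starts = np.concatenate([[0], change])
    run_ends = np.concatenate([change, [len(v_labels)]])
    for s, e in zip(run_starts, run_ends):
        extra = max((e - s - 1) - space.ell, 0)
        trans[v_labels[s], v_labels[s]] += extra
    trans += 0.5 * mask.allowed  # smoothing on the allowed support
    pstar = _normalize_rows(trans, mask.allowed, None)
    pdur = _duration_from_runs(v_labels, space.n_v, space.ell)
    freq = np.bincount(v_labels, minlength=space.n_v).astype(float)
    freq /= freq.sum()
    zeta = initial_distribution(freq, pdur)
    params = ModelParams(zeta, pstar, pdur, weights, means, covs)
    return params, obs
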