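"""Windowed on-line EM with filtered decoding.

The stream is decoded causally: every sample updates the filtering
distribution (one forward step under the current parameters) and its MPM
activity/phase labels are emitted immediately.  Samples also accumulate in a
buffer; once ``window_len`` samples are collected the window is smoothed
under the current parameters (the filtering distribution at the window start
serves as the prior, so no cross-window backward pass is needed), its expected
sufficient statistics — in expectation-per-sample units — are blended into
the running statistics with stepsize ``rho_m``, and the parameters are
refreshed in closed form.  The initial law is never updated on-line.

The stepsize is indexed per *update* (``rho_m = 1/m`` by default), not per
sample: the statistics are blended once per window, and a per-sample ``1/n``
schedule would shrink the effective steps ``window_len``-fold too fast.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Callable, Optional, Union

import numpy as np

from .model import ModelParams, StateSpace, TransitionMask
from .inference import (
    ObservationSequence,
    UnderflowError,
    _correct_log,
    _lse,
    _log_trans,
    _predict_log,
    _safe_log,
    filtered_marginals,
    smooth,
)
from .batch import SufficientStats, complete_stats, params_from_stats

logger = logging.getLogger("semigait")

StepsizeRule = Union[str, float, Callable[[int], float]]


@dataclasses.dataclass
class OnlineConfig:
    """Configuration of the windowed on-line learner.

    ``window_len`` is the number of samples per update (1000 in the intended
    100 Hz application, i.e. an update every 10 s).  ``stepsize`` maps the
    1-based update index ``m`` to ``rho_m``: the string ``"inv_m"`` gives the
    standard ``1/m`` schedule (divergent sum, summable squares); a float gives
    a constant stepsize; a callable is used as-is.

    ``warmup`` is the weight of a warm-start statistics source, expressed in
    window-equivalents: when the stream starts from a batch-trained model
    whose training expectations seed the running statistics, the
    stochastic-approximation count continues from the training data rather
    than restarting, so the ``inv_m`` schedule becomes ``1/(warmup + m)``.
    With the default ``warmup = 0`` the first update has ``rho_1 = 1`` and
    the first window's own statistics replace anything seeded.
    """

    window_len: int = 1000
    stepsize: StepsizeRule = "inv_m"
    warmup: float = 0.0

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.warmup < 0:
            raise ValueError("warmup must be >= 0")

    def rho(self, m: int) -> float:
        if callable(self.stepsize):
            return float(self.stepsize(m))
        if isinstance(self.stepsize, str):
            if self.stepsize == "inv_m":
                return 1.0 / (self.warmup + m)
            raise ValueError(f"unknown stepsize rule {self.stepsize!r}")
        return float(self.stepsize)


@dataclasses.dataclass
class OnlineState:
    """Mutable state of the on-line learner."""

    params: ModelParams
    space: StateSpace
    mask: TransitionMask
    config: OnlineConfig
    stats: Optional[SufficientStats] = None
    n_updates: int = 0
    filter_dist: Optional[np.ndarray] = None   # posterior of the last sample
    window_prior: Optional[np.ndarray] = None  # predictive at window start
    buffer: list = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class StreamResult:
    """Causal decodes and model snapshots from a streamed recognition run."""

    activity: np.ndarray
    phase: np.ndarray
    n_updates: int
    snapshots: list[tuple[int, ModelParams]]
    final_params: ModelParams


def window_update(state: OnlineState, window_obs: ObservationSequence) -> OnlineState:
    """One on-line EM update from a full window of observations.

    Smooths the window under the current parameters using the carried
    filtering distribution as prior, blends the window's per-sample expected
    statistics into the running ones, and refreshes every parameter except
    the initial law.  Mutates and returns ``state``.
    """
    if len(window_obs) != state.config.window_len:
        raise ValueError(
            f"window has {len(window_obs)} samples, expected {state.config.window_len}"
        )
    m = state.n_updates + 1
    rho = state.config.rho(m)
    state.n_updates = m
    if rho == 0.0:
        return state
    try:
        post = smooth(window_obs, state.params, state.space,
                      init=state.window_prior)
    except UnderflowError as exc:
        logger.warning("window update %d skipped: %s", m, exc)
        return state
    wstats = complete_stats(post, window_obs)
    if state.stats is None or rho >= 1.0:
        state.stats = wstats
    else:
        state.stats = state.stats.blend(wstats, rho)
    state.params = params_from_stats(
        state.stats, state.space, state.mask,
        prev=state.params, update_zeta=False,
    )
    return state


def stream_recognize(
    obs_stream: ObservationSequence,
    init_model: ModelParams,
    space: StateSpace,
    mask: TransitionMask,
    config: Optional[OnlineConfig] = None,
    *,
    init_stats: Optional[SufficientStats] = None,
    collect_snapshots: bool = False,
) -> StreamResult:
    """Decode a stream causally while adapting the model on-line.

    Every sample is decoded from the filtering distribution with zero delay;
    the parameters are refreshed after each complete window (so a parameter
    change lags the data that triggered it by at most ``window_len``
    samples).  A stream shorter than one window is decoded without any
    update (with a warning).

    ``init_stats`` warm-starts the running statistics (typically the
    training-data expectations from ``FitReport.final_stats``); pair it with
    ``config.warmup`` so the stepsize schedule accounts for the data those
    statistics already absorbed.
    """
    from .model import emission_loglik

    config = config or OnlineConfig()
    N = len(obs_stream)
    if N < config.window_len:
        warnings.warn(
            "stream shorter than one window: decoding only, no model update",
            stacklevel=2,
        )
    state = OnlineState(params=init_model.copy(), space=space, mask=mask,
                        config=config, stats=init_stats)
    activity = np.empty(N, dtype=int)
    phase = np.empty(N, dtype=int)
    snapshots: list[tuple[int, ModelParams]] = []
    # predictive (log) distribution for the first sample
    lpred = _safe_log(state.params.zeta)
    logpstar, logpdur = _log_trans(state.params)
    values = obs_stream.values
    pos = 0
    while pos < N:
        hi = min(pos + config.window_len, N)
        chunk = values[pos:hi]
        # parameters are constant within a window: batch the emission table
        logB, _ = emission_loglik(chunk, state.params)
        state.window_prior = np.exp(lpred - _lse(lpred))
        lfilt = lpred
        for t in range(hi - pos):
            lfilt, _ = _correct_log(lpred, logB[t], space, pos + t)
            act_m, ph_m = filtered_marginals(np.exp(lfilt), space)
            activity[pos + t] = int(np.argmax(act_m))
            phase[pos + t] = int(np.argmax(ph_m))
            if t + 1 < hi - pos:
                lpred = _predict_log(lfilt, logpstar, logpdur, space)
        state.filter_dist = np.exp(lfilt)
        if hi - pos == config.window_len:
            window = ObservationSequence(chunk, rate=obs_stream.rate)
            window_update(state, window)
            logpstar, logpdur = _log_trans(state.params)
            if collect_snapshots:
                snapshots.append((hi, state.params.copy()))
        # predictive for the next window, under possibly refreshed parameters
        lpred = _predict_log(lfilt, logpstar, logpdur, space)
        pos = hi
    return StreamResult(
        activity=activity, phase=phase, n_updates=state.n_updates,
        snapshots=snapshots, final_params=state.params,
    )
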