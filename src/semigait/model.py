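"""Core model objects for the triplet semi-Markov chain with Gaussian-mixture emissions.

The model couples three discrete latent processes with the observed features:

* ``X`` — the locomotion activity (walking, running, stair ascent, ...), one of
  ``r`` values;
* ``U`` — the gait/leg phase within the periodic lower-limb cycle, one of
  ``tau`` values (four in the intended application: stance, push-up, swing,
  step-down — or low, lifting, high, dropping for a thigh-mounted sensor);
* ``D`` — a minimum-remaining-sojourn counter in ``{0, ..., ell}`` that makes
  the pair ``V = (X, U)`` semi-Markov: when a regime is (re-)entered a minimum
  dwell ``d`` is drawn, the regime is frozen while ``d`` counts down to zero,
  after which the chain is *free* to stay or switch.  This differs from a
  classic explicit-duration HSMM, which forces an exit when the sojourn
  elapses; here the drawn value is only a lower bound on the dwell, so ``ell``
  can stay small.

Observations are modelled per ``(activity, phase)`` cell by a ``kappa``-component
Gaussian mixture with full covariances, so correlations between sensor axes
are captured.  A latent mixture-indicator process ``H`` carries the component
identity; it has no physical meaning.

Indexing conventions
--------------------
Activities, phases, durations and mixture components are 0-based internally.
The flat ``(activity, phase)`` index is ``v = a * tau + u`` and the flat
composite ``(v, d)`` index is ``s = v * (ell + 1) + d``.  Phases are written
1-based in serialized files and documentation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import yaml
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

logger = logging.getLogger("semigait")

#: Lower bound enforced on covariance eigenvalues: estimation clips
#: eigenvalues up to this floor and validation checks it.
REG_FLOOR = 1e-6

#: Tolerance for "rows sum to one" checks on stochastic matrices.
ROW_TOL = 1e-8


class SingularCovarianceError(ValueError):
    """Raised when a mixture component's covariance is singular."""


# ---------------------------------------------------------------------------
# State space
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class StateSpace:
    """Dimensions of the latent state space and the observations.

    Parameters
    ----------
    r : number of activities.
    tau : number of gait/leg phases per cycle (4 for human gait).
    ell : largest minimum-sojourn value; the counter lives in ``{0..ell}``.
        ``ell = 0`` removes the semi-Markov structure entirely.
    kappa : Gaussian mixture components per ``(activity, phase)`` cell.
    w : observation dimensionality (12 for sliding mean/std of a 6-axis IMU).
    """

    r: int
    tau: int = 4
    ell: int = 9
    kappa: int = 1
    w: int = 12

    def __post_init__(self) -> None:
        for name in ("r", "tau", "kappa", "w"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.ell < 0:
            raise ValueError(f"ell must be >= 0, got {self.ell}")

    @property
    def n_v(self) -> int:
        """Number of ``(activity, phase)`` pairs."""
        return self.r * self.tau

    @property
    def n_dur(self) -> int:
        return self.ell + 1

    @property
    def n_states(self) -> int:
        """Number of composite ``(v, d)`` states."""
        return self.n_v * self.n_dur

    def v_index(self, activity: int, phase: int) -> int:
        return activity * self.tau + phase

    def split_v(self, v: int) -> tuple[int, int]:
        return divmod(v, self.tau)

    def state_index(self, v: int, d: int) -> int:
        return v * self.n_dur + d

    def split_state(self, s: int) -> tuple[int, int]:
        return divmod(s, self.n_dur)


# ---------------------------------------------------------------------------
# Structural transition mask (the cyclic gait-phase graph)
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class TransitionMask:
    """Boolean matrix of allowed ``v -> v'`` moves over (activity, phase) pairs."""

    allowed: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.allowed, dtype=bool)
        object.__setattr__(self, "allowed", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("mask must be square")
        if not a.any(axis=1).all():
            raise ValueError("every row of the mask needs at least one allowed entry")


def build_transition_mask(space: StateSpace) -> TransitionMask:
    """Build the cyclic phase-transition graph.

    Within an activity the phase either stays put or advances cyclically
    ``1 -> 2 -> 3 -> 4 -> 1``.  A change of activity is only allowed from
    phase 1 of the old activity into phase 2 of the new one, so activity
    switches are synchronised with cycle boundaries.
    """
    allowed = np.zeros((space.n_v, space.n_v), dtype=bool)
    cross_phase = 1 % space.tau  # phase "2", or phase 1 when tau == 1
    for a in range(space.r):
        for u in range(space.tau):
            v = space.v_index(a, u)
            allowed[v, v] = True
            allowed[v, space.v_index(a, (u + 1) % space.tau)] = True
        for b in range(space.r):
            if b != a:
                allowed[space.v_index(a, 0), space.v_index(b, cross_phase)] = True
    return TransitionMask(allowed)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ModelParams:
    """Full parameter set ``theta``.

    Attributes
    ----------
    zeta : (n_states,) initial distribution over composite ``(v, d)`` states.
    pstar : (n_v, n_v) regime-switch matrix, used only when the counter hits 0.
    pdur : (n_v, ell+1) distribution of the fresh minimum sojourn drawn on
        entering regime ``v``.
    weights : (n_v, kappa) mixture weights per cell.
    means : (n_v, kappa, w) component means.
    covs : (n_v, kappa, w, w) full component covariances.

    The dense composite transition matrix is never stored: rows with ``d > 0``
    are deterministic countdowns, rows with ``d = 0`` factor as
    ``pstar[v, v'] * pdur[v', d']``.  Use :func:`joint_transition` to
    materialize it.
    """

    zeta: np.ndarray
    pstar: np.ndarray
    pdur: np.ndarray
    weights: np.ndarray
    means: np.ndarray
    covs: np.ndarray

    def __post_init__(self) -> None:
        self.zeta = np.asarray(self.zeta, dtype=float)
        self.pstar = np.asarray(self.pstar, dtype=float)
        self.pdur = np.asarray(self.pdur, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.zeta.copy(), self.pstar.copy(), self.pdur.copy(),
            self.weights.copy(), self.means.copy(), self.covs.copy(),
        )


def initial_distribution(zeta_v: np.ndarray, pdur: np.ndarray) -> np.ndarray:
    """Factor an initial law over composite states as ``zeta_v(v) * pdur(d | v)``.

    The default choice for how the initial sojourn counter is distributed; a
    fully joint ``zeta`` over ``(v, d)`` is equally valid and accepted
    everywhere.
    """
    zeta_v = np.asarray(zeta_v, dtype=float)
    return (zeta_v[:, None] * np.asarray(pdur, dtype=float)).ravel()


def joint_transition(params: ModelParams, space: StateSpace) -> np.ndarray:
    """Materialize the dense composite transition matrix over ``(v, d)``.

    Row ``(v, d > 0)`` puts unit mass on ``(v, d - 1)``; row ``(v, 0)`` is
    ``pstar[v, v'] * pdur[v', d']``.  Raises ``ValueError`` if ``pstar`` or
    ``pdur`` rows are not normalized.
    """
    if not np.allclose(params.pstar.sum(axis=1), 1.0, atol=ROW_TOL):
        raise ValueError("pstar rows must sum to 1")
    if not np.allclose(params.pdur.sum(axis=1), 1.0, atol=ROW_TOL):
        raise ValueError("pdur rows must sum to 1")
    S = space.n_states
    nd = space.n_dur
    A = np.zeros((S, S))
    for v in range(space.n_v):
        for d in range(1, nd):
            A[space.state_index(v, d), space.state_index(v, d - 1)] = 1.0
        row = (params.pstar[v][:, None] * params.pdur).ravel()
        A[space.state_index(v, 0), :] = row
    return A


# ---------------------------------------------------------------------------
# Emission densities
# ---------------------------------------------------------------------------


def component_logpdfs(values: np.ndarray, params: ModelParams) -> np.ndarray:
    """Per-component Gaussian log-densities.

    Computed through Cholesky factors, so any strictly positive-definite
    covariance is accepted regardless of conditioning (the regularization
    floor keeps eigenvalues away from zero); an indefinite or exactly
    singular covariance raises, naming the offending component.

    Parameters
    ----------
    values : (N, w) observation matrix.

    Returns
    -------
    (N, n_v, kappa) array of ``log N(y_n; mu_ij, Sigma_ij)``.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_v, kappa, w = params.means.shape
    out = np.empty((values.shape[0], n_v, kappa))
    const = -0.5 * w * np.log(2 * np.pi)
    for i in range(n_v):
        for j in range(kappa):
            try:
                L = np.linalg.cholesky(params.covs[i, j])
            except np.linalg.LinAlgError as exc:
                raise SingularCovarianceError(
                    f"singular covariance for state {i}, component {j}"
                ) from exc
            diff = values - params.means[i, j]
            z = solve_triangular(L, diff.T, lower=True)
            out[:, i, j] = (
                const - np.log(np.diag(L)).sum() - 0.5 * (z * z).sum(axis=0)
            )
    return out


def emission_loglik(values: np.ndarray, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Mixture emission log-densities per cell.

    Returns ``(logB, comp)`` where ``logB`` is (N, n_v) with
    ``log sum_j c_ij N(y_n; mu_ij, Sigma_ij)`` and ``comp`` is the
    (N, n_v, kappa) per-component log-density table (reused for
    responsibilities).
    """
    comp = component_logpdfs(values, params)
    with np.errstate(divide="ignore"):
        logw = np.log(params.weights)
    logB = logsumexp(comp + logw[None, :, :], axis=2)
    return logB, comp


def emission_logdensity(
    y: np.ndarray, v: int, params: ModelParams
) -> tuple[float, np.ndarray]:
    """Log mixture density of one observation under cell ``v``, plus the
    per-component responsibilities (normalized to sum to one)."""
    logB, comp = emission_loglik(np.atleast_2d(y), params)
    with np.errstate(divide="ignore"):
        logw = np.log(params.weights[v])
    logpost = comp[0, v] + logw - logB[0, v]
    return float(logB[0, v]), np.exp(logpost)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_params(
    params: ModelParams, space: StateSpace, mask: TransitionMask
) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    v = []
    shapes = {
        "zeta": (space.n_states,),
        "pstar": (space.n_v, space.n_v),
        "pdur": (space.n_v, space.n_dur),
        "weights": (space.n_v, space.kappa),
        "means": (space.n_v, space.kappa, space.w),
        "covs": (space.n_v, space.kappa, space.w, space.w),
    }
    for name, shape in shapes.items():
        arr = getattr(params, name)
        if arr.shape != shape:
            v.append(f"{name}: shape {arr.shape} != {shape}")
        elif not np.isfinite(arr).all():
            v.append(f"{name}: non-finite entries")
    if v:
        return v  # further checks assume correct, finite shapes

    if abs(params.zeta.sum() - 1.0) > ROW_TOL:
        v.append(f"zeta: sums to {params.zeta.sum():.6g}, not 1")
    if (params.zeta < -ROW_TOL).any():
        v.append("zeta: negative entries")
    for name in ("pstar", "pdur", "weights"):
        arr = getattr(params, name)
        for i, s in enumerate(arr.sum(axis=1)):
            if abs(s - 1.0) > ROW_TOL:
                v.append(f"{name}: row {i} sums to {s:.6g}, not 1")
        if (arr < -ROW_TOL).any():
            v.append(f"{name}: negative entries")
    bad = params.pstar[~mask.allowed]
    if (np.abs(bad) > 0).any():
        idx = np.argwhere((~mask.allowed) & (params.pstar != 0))
        v.append(f"pstar: nonzero on mask-forbidden entries {idx.tolist()[:5]}")
    for i in range(space.n_v):
        for j in range(space.kappa):
            c = params.covs[i, j]
            if not np.allclose(c, c.T, atol=1e-8):
                v.append(f"covs: ({i},{j}) not symmetric")
                continue
            lam = np.linalg.eigvalsh(c).min()
            if lam < REG_FLOOR * (1 - 1e-6):
                v.append(f"covs: ({i},{j}) min eigenvalue {lam:.3g} < {REG_FLOOR}")
    return v


# ---------------------------------------------------------------------------
# Simulated latent paths
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class StatePath:
    """A simulated latent trajectory (activities, phases, counters, components)."""

    x: np.ndarray
    u: np.ndarray
    d: np.ndarray
    h: np.ndarray

    def v(self, space: StateSpace) -> np.ndarray:
        return self.x * space.tau + self.u

    def check(self, space: StateSpace) -> None:
        """Assert the frozen-countdown invariant and alphabet membership."""
        if not ((self.x >= 0) & (self.x < space.r)).all():
            raise ValueError("activity labels out of range")
        if not ((self.u >= 0) & (self.u < space.tau)).all():
            raise ValueError("phase labels out of range")
        if not ((self.d >= 0) & (self.d <= space.ell)).all():
            raise ValueError("sojourn counters out of range")
        if not ((self.h >= 0) & (self.h < space.kappa)).all():
            raise ValueError("mixture indicators out of range")
        frozen = self.d[:-1] > 0
        ok = (
            (self.x[1:][frozen] == self.x[:-1][frozen]).all()
            and (self.u[1:][frozen] == self.u[:-1][frozen]).all()
            and (self.d[1:][frozen] == self.d[:-1][frozen] - 1).all()
        )
        if not ok:
            raise ValueError("countdown invariant violated")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def model_to_dict(
    params: ModelParams, space: StateSpace, mask: TransitionMask
) -> dict:
    return {
        "version": _FORMAT_VERSION,
        "space": {"r": space.r, "tau": space.tau, "ell": space.ell,
                  "kappa": space.kappa, "w": space.w},
        "mask": mask.allowed.astype(int).tolist(),
        "zeta": params.zeta.tolist(),
        "pstar": params.pstar.tolist(),
        "pdur": params.pdur.tolist(),
        "weights": params.weights.tolist(),
        "means": params.means.tolist(),
        "covs": params.covs.tolist(),
    }


def model_from_dict(doc: dict) -> tuple[ModelParams, StateSpace, TransitionMask]:
    if "version" not in doc:
        raise ValueError("model document lacks a version field")
    if doc["version"] != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc['version']}")
    sp = doc["space"]
    space = StateSpace(r=sp["r"], tau=sp["tau"], ell=sp["ell"],
                       kappa=sp["kappa"], w=sp["w"])
    mask = TransitionMask(np.asarray(doc["mask"], dtype=bool))
    params = ModelParams(
        zeta=np.asarray(doc["zeta"], dtype=float),
        pstar=np.asarray(doc["pstar"], dtype=float),
        pdur=np.asarray(doc["pdur"], dtype=float),
        weights=np.asarray(doc["weights"], dtype=float),
        means=np.asarray(doc["means"], dtype=float),
        covs=np.asarray(doc["covs"], dtype=float),
    )
    return params, space, mask


def save_model(
    path, params: ModelParams, space: StateSpace, mask: TransitionMask
) -> None:
    """Write the model as a single YAML document."""
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(params, space, mask), fh, sort_keys=False)


def load_model(path) -> tuple[ModelParams, StateSpace, TransitionMask]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc)
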