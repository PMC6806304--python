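"""Independent brute-force oracle: exhaustive enumeration of latent paths.

Builds the dense composite transition from first principles (frozen-countdown
semantics spelled out directly, not via the package's matrix builder) and
sums the joint probability over every latent path.  Only feasible for tiny
state counts and lengths; used to pin down filtering/smoothing marginals,
pairwise posteriors and the likelihood.
"""

import numpy as np
from scipy.stats import multivariate_normal


def dense_transition(params, space):
    """Composite transition assembled entry by entry from the dynamics."""
    nd = space.ell + 1
    S = space.n_v * nd
    A = np.zeros((S, S))
    for v in range(space.n_v):
        for d in range(nd):
            row = v * nd + d
            if d > 0:
                A[row, v * nd + (d - 1)] = 1.0  # frozen countdown
            else:
                for v2 in range(space.n_v):
                    for d2 in range(nd):
                        A[row, v2 * nd + d2] = params.pstar[v, v2] * params.pdur[v2, d2]
    return A


def emission_matrix(Y, params, space):
    """(N, S) mixture densities; depends on the cell only."""
    N = Y.shape[0]
    nd = space.ell + 1
    dens_v = np.zeros((N, space.n_v))
    for v in range(space.n_v):
        for j in range(space.kappa):
            if params.weights[v, j] > 0:
                dens_v[:, v] += params.weights[v, j] * multivariate_normal.pdf(
                    Y, mean=params.means[v, j], cov=params.covs[v, j]
                )
    return np.repeat(dens_v, nd, axis=1)


def _enumerate(params, space, Y):
    """All paths of length N over composite states, with joint probabilities."""
    S = space.n_v * (space.ell + 1)
    N = Y.shape[0]
    A = dense_transition(params, space)
    B = emission_matrix(Y, params, space)
    grids = np.meshgrid(*[np.arange(S)] * N, indexing="ij")
    paths = np.stack([g.ravel() for g in grids], axis=1)  # (S^N, N)
    prob = params.zeta[paths[:, 0]] * B[0, paths[:, 0]]
    for t in range(1, N):
        prob = prob * A[paths[:, t - 1], paths[:, t]] * B[t, paths[:, t]]
    return paths, prob


def enumerate_posteriors(params, space, Y):
    """Exhaustive filtering/smoothing marginals, pairwise sums and loglik."""
    S = space.n_v * (space.ell + 1)
    N = Y.shape[0]
    paths, prob = _enumerate(params, space, Y)
    total = prob.sum()
    smoothing = np.stack([
        np.bincount(paths[:, n], weights=prob, minlength=S) / total
        for n in range(N)
    ])
    # pairwise posteriors accumulated over time
    xi = np.zeros((S, S))
    for n in range(N - 1):
        flat = paths[:, n] * S + paths[:, n + 1]
        xi += np.bincount(flat, weights=prob, minlength=S * S).reshape(S, S)
    xi /= total
    # filtering needs prefix enumerations
    filtering = np.empty((N, S))
    for n in range(N):
        p_paths, p_prob = _enumerate(params, space, Y[: n + 1])
        filtering[n] = (
            np.bincount(p_paths[:, n], weights=p_prob, minlength=S) / p_prob.sum()
        )
    return {
        "filtering": filtering,
        "smoothing": smoothing,
        "xi_sum": xi,
        "loglik": float(np.log(total)),
    }
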