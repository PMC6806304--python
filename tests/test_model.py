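import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semigait import (
    ModelParams,
    StateSpace,
    build_transition_mask,
    emission_logdensity,
    joint_transition,
    load_model,
    random_params,
    save_model,
    validate_params,
)


class TestTransitionMask:
    def test_single_activity_cycle(self):
        """One activity, four phases: self-loops plus the 1→2→3→4→1 cycle."""
        space = StateSpace(r=1, tau=4, ell=0, kappa=1, w=1)
        mask = build_transition_mask(space)
        expected = {(u, u) for u in range(4)} | {(0, 1), (1, 2), (2, 3), (3, 0)}
        got = {tuple(ij) for ij in np.argwhere(mask.allowed)}
        assert got == expected

    def test_two_activities_cross_edges(self):
        """Two activities: 8 within-activity edges each plus one cross edge
        per direction, from phase 1 of the old activity into phase 2 of the
        new one."""
        space = StateSpace(r=2, tau=4, ell=0, kappa=1, w=1)
        mask = build_transition_mask(space)
        assert mask.allowed.sum() == 18
        assert mask.allowed[0, 5]   # (act0, phase1) -> (act1, phase2)
        assert mask.allowed[4, 1]
        assert not mask.allowed[1, 5]  # cross from phase 2 forbidden

    def test_degenerate_single_state(self):
        space = StateSpace(r=1, tau=1, ell=0, kappa=1, w=1)
        mask = build_transition_mask(space)
        assert mask.allowed.shape == (1, 1) and mask.allowed[0, 0]


class TestJointTransition:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        r=st.integers(1, 3), tau=st.integers(1, 4), ell=st.integers(0, 3),
        seed=st.integers(0, 100),
    )
    def test_rows_sum_to_one_and_respect_mask(self, r, tau, ell, seed):
        space = StateSpace(r=r, tau=tau, ell=ell, kappa=1, w=1)
        mask = build_transition_mask(space)
        params = random_params(space, mask, seed)
        A = joint_transition(params, space)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-12)
        # zero pattern: countdown rows are unit vectors; free rows only reach
        # mask-allowed cells
        nd = space.n_dur
        for v in range(space.n_v):
            for d in range(1, nd):
                row = A[v * nd + d]
                assert row[v * nd + d - 1] == 1.0 and row.sum() == 1.0
            free = A[v * nd].reshape(space.n_v, nd)
            assert np.all(free[~mask.allowed[v]] == 0.0)

    def test_countdown_row_is_deterministic(self):
        space = StateSpace(r=1, tau=2, ell=3, kappa=1, w=1)
        mask = build_transition_mask(space)
        params = random_params(space, mask, 3)
        A = joint_transition(params, space)
        row = A[space.state_index(1, 3)]
        assert row[space.state_index(1, 2)] == 1.0 and row.sum() == 1.0

    def test_ell_zero_reduces_to_switch_matrix(self):
        space = StateSpace(r=2, tau=2, ell=0, kappa=1, w=1)
        mask = build_transition_mask(space)
        params = random_params(space, mask, 5)
        assert np.allclose(joint_transition(params, space), params.pstar)

    def test_unnormalized_rows_rejected(self):
        space = StateSpace(r=1, tau=2, ell=1, kappa=1, w=1)
        mask = build_transition_mask(space)
        params = random_params(space, mask, 1)
        params.pstar[0] *= 0.9
        with pytest.raises(ValueError):
            joint_transition(params, space)


class TestEmission:
    def test_gaussian_mode_value(self):
        """kappa=1 at the mean with identity covariance: -(w/2) log(2*pi)."""
        w = 3
        space = StateSpace(r=1, tau=1, ell=0, kappa=1, w=w)
        params = ModelParams(
            zeta=np.array([1.0]), pstar=np.array([[1.0]]),
            pdur=np.array([[1.0]]), weights=np.array([[1.0]]),
            means=np.zeros((1, 1, w)), covs=np.eye(w)[None, None],
        )
        logdens, resp = emission_logdensity(np.zeros(w), 0, params)
        assert logdens == pytest.approx(-w / 2 * np.log(2 * np.pi), abs=1e-12)
        assert resp == pytest.approx([1.0])

    def test_identical_components_collapse(self):
        w = 2
        params = ModelParams(
            zeta=np.array([1.0]), pstar=np.array([[1.0]]),
            pdur=np.array([[1.0]]), weights=np.array([[0.5, 0.5]]),
            means=np.ones((1, 2, w)), covs=np.tile(np.eye(w), (1, 2, 1, 1)),
        )
        y = np.array([0.3, -0.2])
        logdens, resp = emission_logdensity(y, 0, params)
        single = ModelParams(
            zeta=np.array([1.0]), pstar=np.array([[1.0]]),
            pdur=np.array([[1.0]]), weights=np.array([[1.0]]),
            means=np.ones((1, 1, w)), covs=np.eye(w)[None, None],
        )
        ref, _ = emission_logdensity(y, 0, single)
        assert logdens == pytest.approx(ref, abs=1e-12)
        assert resp == pytest.approx([0.5, 0.5])

    def test_two_component_scalar_mixture(self):
        """0.3 N(1;0,1) + 0.7 N(1;2,1) = phi(1) = 0.2419707245... (both
        component densities coincide at y=1)."""
        params = ModelParams(
            zeta=np.array([1.0]), pstar=np.array([[1.0]]),
            pdur=np.array([[1.0]]), weights=np.array([[0.3, 0.7]]),
            means=np.array([[[0.0], [2.0]]]), covs=np.ones((1, 2, 1, 1)),
        )
        logdens, resp = emission_logdensity(np.array([1.0]), 0, params)
        assert np.exp(logdens) == pytest.approx(0.24197072451914337, abs=1e-12)
        assert resp == pytest.approx([0.3, 0.7], abs=1e-12)

    def test_singular_covariance_names_component(self):
        space = StateSpace(r=1, tau=2, ell=0, kappa=2, w=2)
        mask = build_transition_mask(space)
        params = random_params(space, mask, 0)
        params.covs[1, 1] = 0.0
        with pytest.raises(ValueError, match="state 1, component 1"):
            emission_logdensity(np.zeros(2), 1, params)


class TestValidation:
    def test_valid_params_pass(self):
        space = StateSpace(r=2, tau=3, ell=2, kappa=2, w=2)
        mask = build_transition_mask(space)
        params = random_params(space, mask, 11)
        assert validate_params(params, space, mask) == []

    def test_detects_unnormalized_row_and_bad_cov(self):
        space = StateSpace(r=1, tau=2, ell=1, kappa=1, w=2)
        mask = build_transition_mask(space)
        params = random_params(space, mask, 2)
        params.pstar[0] *= 0.9
        v = validate_params(params, space, mask)
        assert len(v) == 1 and "pstar" in v[0] and "row 0" in v[0]
        params = random_params(space, mask, 2)
        params.covs[0, 0] = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalue -1
        v = validate_params(params, space, mask)
        assert len(v) == 1 and "covs" in v[0]

    def test_detects_mask_violation(self):
        space = StateSpace(r=2, tau=4, ell=0, kappa=1, w=1)
        mask = build_transition_mask(space)
        params = random_params(space, mask, 4)
        params.pstar[1, 5] = 0.1  # forbidden cross edge from phase 2
        params.pstar[1] /= params.pstar[1].sum()
        v = validate_params(params, space, mask)
        assert any("forbidden" in s for s in v)


def test_model_roundtrip(tmp_path):
    space = StateSpace(r=2, tau=4, ell=3, kappa=2, w=4)
    mask = build_transition_mask(space)
    params = random_params(space, mask, 9)
    path = tmp_path / "model.yaml"
    save_model(path, params, space, mask)
    params2, space2, mask2 = load_model(path)
    assert space2 == space
    assert np.array_equal(mask2.allowed, mask.allowed)
    for field in ("zeta", "pstar", "pdur", "weights", "means", "covs"):
        np.testing.assert_allclose(
            getattr(params2, field), getattr(params, field), rtol=0, atol=0
        )
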