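"""Transfer-matrix normalization, Laplacian seeds, the restart walk against
its closed-form oracle, and whole-model score properties."""

import numpy as np
import pytest

from grwlda import (
    ConvergenceError,
    GrwParams,
    column_normalize,
    grwlda_scores,
    initial_vector,
    laplacian_score,
    rwr,
    rwr_solve,
)
from grwlda.propagation import _laplacian_all

from conftest import random_stochastic


class TestColumnNormalize:
    def test_uniform_column(self):
        assert column_normalize(np.array([[1.0], [1.0]])).tolist() == [[0.5], [0.5]]

    def test_zero_column_stays_zero(self):
        M = np.array([[1.0, 0.0], [3.0, 0.0]])
        W = column_normalize(M)
        assert W[:, 1].tolist() == [0.0, 0.0]
        assert W[:, 0].sum() == pytest.approx(1.0)

    def test_idempotent_on_stochastic_input(self):
        W = random_stochastic(np.random.default_rng(0), 5)
        assert np.allclose(column_normalize(W), W)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            column_normalize(np.array([[1.0], [-0.1]]))

    def test_input_not_mutated(self):
        M = np.array([[2.0], [2.0]])
        column_normalize(M)
        assert M.tolist() == [[2.0], [2.0]]


class TestLaplacianScore:
    def test_identity_network_returns_indicator(self):
        v = laplacian_score(np.eye(4), 2, balance=0.3, form="inverse")
        expected = np.zeros(4)
        expected[2] = 1.0  # (1-b)/(1-b)
        assert np.allclose(v, expected)

    def test_tiny_balance_approaches_indicator(self):
        W = random_stochastic(np.random.default_rng(1), 5)
        for form in ("inverse", "literal"):
            v = laplacian_score(W, 0, balance=1e-9, form=form)
            assert np.allclose(v, np.eye(5)[0], atol=1e-6)

    def test_inverse_matches_neumann_series(self):
        """(1-b)(I-bW)^-1 e == (1-b) sum_k b^k W^k e on a 3-node chain."""
        W = column_normalize(np.array([[0.0, 1.0, 0.0],
                                       [1.0, 0.0, 1.0],
                                       [0.0, 1.0, 0.0]]))
        b = 0.4
        v = laplacian_score(W, 0, balance=b, form="inverse")
        series = np.zeros(3)
        term = np.eye(3)[0]
        for _ in range(200):
            series += term
            term = b * (W @ term)
        assert np.allclose(v, (1 - b) * series, atol=1e-10)

    def test_inverse_form_nonnegative(self):
        W = random_stochastic(np.random.default_rng(2), 8)
        v = laplacian_score(W, 3, balance=0.9, form="inverse")
        assert v.min() >= 0.0

    def test_literal_form_as_printed(self):
        W = random_stochastic(np.random.default_rng(3), 4)
        b = 0.1
        v = laplacian_score(W, 1, balance=b, form="literal")
        assert np.allclose(v, (1 - b) * (np.eye(4) - b * W) @ np.eye(4)[1])


class TestInitialVector:
    def test_sums_to_one_when_nonzero(self):
        rng = np.random.default_rng(4)
        WA = column_normalize(rng.random((6, 4)))
        v = initial_vector(WA, rng.random(4), 2)
        assert v.sum() == pytest.approx(1.0)

    def test_isolated_entity_seeded_through_similar_neighbors(self):
        # column 1 of WA is all-zero (isolated disease); the seed must come
        # entirely from WA @ lap and still be a distribution
        WA = np.array([[0.5, 0.0], [0.5, 0.0]])
        lap = np.array([0.2, 0.8])
        v = initial_vector(WA, lap, 1)
        assert v.sum() == pytest.approx(1.0)
        assert np.allclose(v, [0.5, 0.5])

    def test_single_nonzero_column_keeps_direction(self):
        WA = np.array([[0.25, 0.0], [0.75, 0.0]])
        v = initial_vector(WA, np.array([1.0, 0.0]), 0)
        assert np.allclose(v, [0.25, 0.75])

    def test_all_zero_stays_zero(self):
        v = initial_vector(np.zeros((3, 2)), np.zeros(2), 0)
        assert v.tolist() == [0.0, 0.0, 0.0]


class TestRwr:
    def test_full_restart_returns_seed(self):
        W = random_stochastic(np.random.default_rng(5), 4)
        p0 = np.array([0.25, 0.25, 0.25, 0.25])
        assert np.allclose(rwr(W, p0, gamma=1.0), p0)

    def test_zero_seed_zero_steady_state(self):
        W = random_stochastic(np.random.default_rng(6), 4)
        assert rwr(W, np.zeros(4), gamma=0.5).tolist() == [0.0] * 4

    @pytest.mark.parametrize("gamma", [0.3, 0.5, 0.9])
    def test_matches_linear_solve_oracle(self, gamma):
        rng = np.random.default_rng(7)
        for _ in range(10):
            W = random_stochastic(rng, 20)
            p0 = rng.random(20)
            p0 /= p0.sum()
            it = rwr(W, p0, gamma, tol=1e-12, max_iter=10000)
            assert np.allclose(it, rwr_solve(W, p0, gamma), atol=1e-10)

    def test_steady_vector_conserves_mass(self):
        rng = np.random.default_rng(8)
        W = random_stochastic(rng, 15)
        p0 = rng.random(15)
        p0 /= p0.sum()
        assert rwr(W, p0, gamma=0.7, tol=1e-12).sum() == pytest.approx(1.0, abs=1e-9)

    def test_nonconvergence_carries_residual(self):
        W = random_stochastic(np.random.default_rng(9), 10)
        p0 = np.ones(10) / 10
        with pytest.raises(ConvergenceError) as exc:
            rwr(W, p0, gamma=0.01, tol=1e-15, max_iter=2)
        assert exc.value.residual > 0


class TestGrwldaScores:
    def _inputs(self, seed=0, nl=6, nd=8):
        rng = np.random.default_rng(seed)
        AS = (rng.random((nl, nd)) < 0.3).astype(float)
        AS[0, 0] = 1  # at least one association
        LL = rng.random((nl, nl))
        LL = (LL + LL.T) / 2
        np.fill_diagonal(LL, 1.0)
        DD = rng.random((nd, nd))
        DD = (DD + DD.T) / 2
        np.fill_diagonal(DD, 1.0)
        return AS, LL, DD

    def test_eta_endpoints(self):
        AS, LL, DD = self._inputs()
        s_hi = grwlda_scores(AS, LL, DD, GrwParams(eta=1.0))
        s_lo = grwlda_scores(AS, LL, DD, GrwParams(eta=0.0))
        assert np.allclose(s_hi.FS, s_hi.S1)
        assert np.allclose(s_lo.FS, s_lo.S2)

    def test_eta_linearity(self):
        AS, LL, DD = self._inputs(1)
        s = {e: grwlda_scores(AS, LL, DD, GrwParams(eta=e)) for e in (0.0, 0.35, 1.0)}
        assert np.allclose(s[0.35].FS, 0.35 * s[1.0].FS + 0.65 * s[0.0].FS)

    def test_toy_walk_concentrates_on_associated_lncrna(self):
        """AS=[[1,0],[0,0]], LL=DD=I: disease 1's walk lands on lncRNA 1."""
        AS = np.array([[1.0, 0.0], [0.0, 0.0]])
        s = grwlda_scores(AS, np.eye(2), np.eye(2), GrwParams())
        assert int(np.argmax(s.FS[:, 0])) == 0

    def test_scores_bounded_and_columns_conserved(self):
        AS, LL, DD = self._inputs(2)
        s = grwlda_scores(AS, LL, DD, GrwParams())
        assert s.FS.min() >= 0.0 and s.FS.max() <= 1.0
        assert np.allclose(s.S1.sum(axis=0), 1.0, atol=1e-9)

    def test_label_permutation_equivariance(self):
        AS, LL, DD = self._inputs(3)
        rng = np.random.default_rng(13)
        pl, pd = rng.permutation(AS.shape[0]), rng.permutation(AS.shape[1])
        s = grwlda_scores(AS, LL, DD, GrwParams())
        s_perm = grwlda_scores(AS[np.ix_(pl, pd)], LL[np.ix_(pl, pl)],
                               DD[np.ix_(pd, pd)], GrwParams())
        assert np.allclose(s_perm.FS, s.FS[np.ix_(pl, pd)], atol=1e-9)

    def test_deterministic(self):
        AS, LL, DD = self._inputs(4)
        a = grwlda_scores(AS, LL, DD, GrwParams()).FS
        b = grwlda_scores(AS, LL, DD, GrwParams()).FS
        assert np.array_equal(a, b)

    def test_solve_engine_matches_iterative(self):
        AS, LL, DD = self._inputs(5)
        it = grwlda_scores(AS, LL, DD, GrwParams(tol=1e-13, max_iter=20000)).FS
        sv = grwlda_scores(AS, LL, DD, GrwParams(engine="solve")).FS
        assert np.allclose(it, sv, atol=1e-9)

    def test_literal_laplacian_form_runs(self):
        AS, LL, DD = self._inputs(6)
        s = grwlda_scores(AS, LL, DD, GrwParams(laplacian_form="literal"))
        assert s.FS.shape == AS.shape

    def test_laplacian_all_matches_per_index(self):
        W = random_stochastic(np.random.default_rng(10), 6)
        M = _laplacian_all(W, 0.1, "inverse")
        for j in range(6):
            assert np.allclose(M[:, j], laplacian_score(W, j, 0.1, "inverse"))


class TestGrwParams:
    @pytest.mark.parametrize("kw", [{"gamma": 0.0}, {"gamma": 1.5},
                                    {"alpha": 1.0}, {"beta": -0.1},
                                    {"eta": 1.2}, {"tol": 0.0},
                                    {"max_iter": 0},
                                    {"laplacian_form": "bogus"},
                                    {"engine": "bogus"}])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            GrwParams(**kw)

    def test_defaults(self):
        p = GrwParams()
        assert (p.gamma, p.alpha, p.beta, p.eta) == (0.9, 0.1, 0.1, 0.7)
        assert p.tol == 1e-6
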