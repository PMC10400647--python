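"""Constraint losses and the three differentiable flux solvers."""

import numpy as np
import pytest

from amn.fba import solve_fba
from amn.model_io import MetabolicModel, build_projections
from amn.solvers import (compute_losses, loss_gradient, lp_solve, qp_solve,
                         wr_from_reference, wt_solve)
from amn.synthetic import make_random_network, make_toy_network


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

class TestLosses:
    def test_zero_everywhere(self, chain, chain_projections):
        L = compute_losses(np.zeros(2), chain, chain_projections,
                           V_in=np.zeros(1), V_ref=np.zeros(1))
        assert L.total == 0.0

    def test_bound_violation_term(self, chain, chain_projections):
        # uptake flux 2 against bound 1: L3 = (2-1)^2 / 1 = 1
        L = compute_losses(np.array([2.0, 2.0]), chain, chain_projections,
                           V_in=np.array([1.0]))
        assert L.L3 == pytest.approx(1.0)
        assert L.L2 == pytest.approx(0.0)

    def test_stoichiometry_term(self, chain, chain_projections):
        # V = (2, 1): S V = (1), m = 1, so L2 = 1
        L = compute_losses(np.array([2.0, 1.0]), chain, chain_projections,
                           V_in=np.array([2.0]))
        assert L.L2 == pytest.approx(1.0)

    def test_negativity_and_ko_terms(self, chain):
        P = build_projections(chain, ko_ids=["bio"])
        V = np.array([-1.0, 2.0])
        L = compute_losses(V, chain, P, V_in=np.array([2.0]),
                           R_KO=np.array([0.0]))
        assert L.L4 == pytest.approx(1.0 / 2)      # |(-V)+|^2 / n
        assert L.L5 == pytest.approx(4.0)          # (2-0)^2 / 1
        assert L.total == L.L1 + L.L2 + L.L3 + L.L4 + L.L5

    def test_ko_entry_one_grants_unit_allowance(self, chain):
        # replicating the printed formula: R_KO=1 penalizes only flux > 1
        P = build_projections(chain, ko_ids=["bio"])
        L = compute_losses(np.array([1.0, 1.0]), chain, P,
                           V_in=np.array([1.0]), R_KO=np.array([1.0]))
        assert L.L5 == 0.0

    def test_dimension_mismatch(self, chain, chain_projections):
        with pytest.raises(ValueError):
            compute_losses(np.zeros(3), chain, chain_projections,
                           V_in=np.zeros(1))

    @pytest.mark.parametrize("with_ref,with_ko", [(True, True),
                                                  (True, False),
                                                  (False, False)])
    def test_gradient_matches_finite_differences(self, with_ref, with_ko):
        """Analytic gradient of every loss term vs central differences."""
        model = make_random_network(n_mets=4, seed=1)
        ko_ids = [model.reaction_ids[2]] if with_ko else []
        P = build_projections(model, ko_ids=ko_ids)
        rng = np.random.default_rng(0)
        V_in = np.array([2.0])
        V_ref = np.array([1.0]) if with_ref else None
        R_KO = np.array([0.0]) if with_ko else None
        for trial in range(5):
            V = rng.normal(0.5, 1.0, size=model.n)
            g = loss_gradient(V, model, P, V_in, V_ref, R_KO)
            fd = np.zeros_like(g)
            eps = 1e-6
            for j in range(model.n):
                Vp, Vm = V.copy(), V.copy()
                Vp[j] += eps
                Vm[j] -= eps
                fd[j] = (compute_losses(Vp, model, P, V_in, V_ref, R_KO).total
                         - compute_losses(Vm, model, P, V_in, V_ref,
                                          R_KO).total) / (2 * eps)
            np.testing.assert_allclose(g, fd, atol=1e-5)


# ---------------------------------------------------------------------------
# Wt-solver
# ---------------------------------------------------------------------------

class TestWtSolver:
    def test_chain_fixed_point(self, chain, chain_projections):
        V_ref = np.array([2.0, 2.0])
        W = wr_from_reference(chain, chain_projections, V_ref)
        st = wt_solve(chain, chain_projections, W, V0=np.array([2.0, 0.0]),
                      n_iter=50)
        np.testing.assert_allclose(st.V, [2.0, 2.0], atol=1e-12)

    def test_branch_even_split(self, branch):
        """Branching ratios (0.5, 0.5): uptake 2 yields branch fluxes (1, 1).

        Closed form: the fixed point of the linear recursion distributes
        the metabolite production M_A = 2 over both consumers equally.
        """
        P = build_projections(branch)
        V_ref = np.array([2.0, 1.0, 1.0, 1.0, 1.0])
        W = wr_from_reference(branch, P, V_ref)
        st = wt_solve(branch, P, W, V0=np.array([2.0, 0, 0, 0, 0.0]),
                      n_iter=100)
        j = branch.reaction_index
        assert st.V[j("b0")] == pytest.approx(1.0, abs=1e-10)
        assert st.V[j("b1")] == pytest.approx(1.0, abs=1e-10)

    def test_zero_iterations_returns_v0(self, chain, chain_projections):
        V0 = np.array([2.0, 0.5])
        st = wt_solve(chain, chain_projections, np.ones((2, 1)), V0, n_iter=0)
        np.testing.assert_array_equal(st.V, V0)

    def test_negative_weights_rejected(self, chain, chain_projections):
        with pytest.raises(ValueError, match="nonnegative"):
            wt_solve(chain, chain_projections, -np.ones((2, 1)),
                     np.zeros(2))

    def test_divergence_reported_with_iteration(self):
        # amplifying weights around a cycle blow the recursion up
        cyc = MetabolicModel(
            ["up_A_i", "rAB", "rBA", "bio"], ["A", "B"],
            np.array([[1.0, -1.0, 1.0, -1.0],
                      [0.0, 1.0, -1.0, 0.0]]),
            np.zeros(4), np.full(4, 1000.0), objective_id="bio",
            uptake_ids=["up_A_i"])
        P = build_projections(cyc)
        with pytest.raises(FloatingPointError, match="diverged"):
            wt_solve(cyc, P, np.full((4, 2), 50.0),
                     V0=np.array([2.0, 0, 0, 0.0]), n_iter=500)

    def test_single_wr_cannot_satisfy_two_eb_distributions(self):
        """Known limitation: with exact bounds, one branching matrix cannot
        reproduce flux distributions that split a node differently."""
        branch, _ = make_toy_network("branch", n_branches=2)
        P = build_projections(branch)
        # two EB media whose optimal-flux references use different ratios
        refs = [np.array([2.0, 2.0, 0.0, 2.0, 0.0]),   # all via b0
                np.array([2.0, 0.5, 1.5, 0.5, 1.5])]   # mostly via b1
        fits = []
        for W_src in refs:
            W = wr_from_reference(branch, P, W_src)
            errs = []
            for ref in refs:
                V0 = np.zeros(branch.n)
                V0[0] = ref[0]
                st = wt_solve(branch, P, W, V0, n_iter=100)
                errs.append(np.max(np.abs(st.V - ref)))
            fits.append(errs)
        # each W_r reproduces its own source but fails the other
        assert fits[0][0] < 1e-9 and fits[1][1] < 1e-9
        assert fits[0][1] > 0.1 and fits[1][0] > 0.1


# ---------------------------------------------------------------------------
# LP-solver
# ---------------------------------------------------------------------------

class TestLPSolver:
    def test_chain_eb(self, chain, chain_projections):
        st = lp_solve(chain, chain_projections, np.array([2.0]), mode="EB",
                      n_iter=5000)
        assert st.V[chain.reaction_index("bio")] == pytest.approx(2.0,
                                                                  abs=1e-4)

    def test_zero_objective_keeps_value_zero(self, chain, chain_projections):
        st = lp_solve(chain, chain_projections, np.array([2.0]), mode="EB",
                      c_FBA=np.zeros(2), n_iter=3000)
        # any feasible point is optimal; the objective value is 0
        assert float(np.zeros(2) @ st.V) == 0.0

    def test_eb_uptake_components_never_move(self, chain, chain_projections):
        V_in = np.array([1.7])
        st = lp_solve(chain, chain_projections, V_in, mode="EB", n_iter=200)
        assert st.V[0] == V_in[0]  # bit-identical

    def test_oracle_equivalence_random_networks(self):
        """Growth matches the simplex optimum (relative 1e-3) on >= 20
        random positive-flux networks, in both UB and EB modes."""
        for seed in range(20):
            model = make_random_network(n_mets=4, seed=seed)
            P = build_projections(model)
            ub = 1.0 + (seed % 4)
            ref = solve_fba(model, [ub]).objective_value
            st = lp_solve(model, P, np.array([float(ub)]), mode="UB",
                          n_iter=20000)
            got = st.V[model.reaction_index("bio")]
            assert got == pytest.approx(ref, rel=1e-3, abs=1e-4), \
                f"seed {seed}: UB growth {got} vs simplex {ref}"

    def test_divergence_error(self, chain, chain_projections):
        with pytest.raises(FloatingPointError, match="diverged"):
            lp_solve(chain, chain_projections, np.array([2.0]), mode="EB",
                     dt=1e8, n_iter=5000)


# ---------------------------------------------------------------------------
# QP-solver
# ---------------------------------------------------------------------------

class TestQPSolver:
    def test_gradient_vanishes_at_optimum(self, chain, chain_projections):
        V_opt = np.array([2.0, 2.0])
        g = loss_gradient(V_opt, chain, chain_projections,
                          V_in=np.array([2.0]), V_ref=np.array([2.0]))
        assert np.max(np.abs(g)) < 1e-12
        st = qp_solve(chain, chain_projections, np.array([2.0]),
                      V_ref=np.array([2.0]), V0=V_opt, n_iter=5)
        np.testing.assert_allclose(st.V, V_opt, atol=1e-9)

    def test_chain_converges_to_reference(self, chain, chain_projections):
        st = qp_solve(chain, chain_projections, np.array([2.0]),
                      V_ref=np.array([2.0]), mode="UB", n_iter=5000)
        np.testing.assert_allclose(st.V, [2.0, 2.0], atol=1e-3)
        assert st.loss_trace[-1] < 1e-6

    def test_matches_quadratic_program_oracle(self):
        """Terminal loss agrees with an independent quasi-Newton minimizer."""
        from scipy.optimize import minimize

        model = make_random_network(n_mets=3, seed=5)
        P = build_projections(model)
        V_in = np.array([2.0])
        ref = solve_fba(model, V_in).objective_value
        V_ref = np.array([ref])

        def fun(V):
            return compute_losses(V, model, P, V_in, V_ref).total

        def jac(V):
            return loss_gradient(V, model, P, V_in, V_ref)

        oracle = minimize(fun, P.P_in.T @ V_in, jac=jac, method="L-BFGS-B",
                          options={"maxiter": 5000, "ftol": 1e-14})
        st = qp_solve(model, P, V_in, V_ref=V_ref, mode="UB", n_iter=30000)
        assert st.loss_trace[-1] == pytest.approx(oracle.fun, abs=1e-5)

    def test_monotone_nonincreasing_loss(self):
        for seed in (0, 3, 7):
            model = make_random_network(n_mets=4, seed=seed)
            P = build_projections(model)
            st = qp_solve(model, P, np.array([2.0]), V_ref=np.array([1.0]),
                          mode="UB", n_iter=500)
            trace = np.asarray(st.loss_trace[10:])
            assert np.all(np.diff(trace) <= 1e-12)

    def test_eb_clamp_bit_identical(self, chain, chain_projections):
        V_in = np.array([1.3])
        st = qp_solve(chain, chain_projections, V_in,
                      V_ref=np.array([1.3]), mode="EB", n_iter=100)
        assert st.V[0] == V_in[0]

    def test_fba_consistent_reference_reaches_tiny_loss(self):
        """With an FBA-consistent target the terminal loss is < 1e-5
        across random networks (the spec-level oracle property)."""
        count = 0
        for seed in range(20):
            model = make_random_network(n_mets=4, seed=seed)
            P = build_projections(model)
            ub = 1.5
            ref = solve_fba(model, [ub]).objective_value
            st = qp_solve(model, P, np.array([ub]), V_ref=np.array([ref]),
                          mode="UB", n_iter=150000)
            assert st.loss_trace[-1] < 1e-5, f"seed {seed}"
            count += 1
        assert count == 20
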