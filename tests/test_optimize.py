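"""Design-optimization behaviour: cost arithmetic, the method catalogue's
structural contracts, solver reproducibility, and a grid-search oracle for a
low-dimensional design."""

import dataclasses

import numpy as np
import pytest

from qmreff import SequenceSettings, TissueParams, method_catalogue, solve
from qmreff.optimize import (COST_CAP, WHITE_MATTER, canonicalize_cycle, cost,
                             fingerprint_toy_problem)


class TestCost:
    def test_arithmetic(self, wm, monkeypatch):
        """eta_T1 = eta_T2 = 0.5 for a single tissue gives cost 8."""
        import qmreff.optimize as opt

        monkeypatch.setattr(
            opt.crlb, "efficiency_batch",
            lambda *a, **k: np.array([[0.5, 0.5]]),
        )
        u = SequenceSettings("SPGR", [10.0], 20.0, 0.0)
        assert cost(u, [wm]) == pytest.approx(8.0)

    def test_zero_eta_contributes_cap(self, wm):
        u = SequenceSettings("SPGR", [10.0, 20.0], 20.0, 0.0)
        # spoiled nuisance set includes T2 which SPGR cannot see -> eta = 0
        assert cost(u, [wm]) == pytest.approx(2 * COST_CAP)

    def test_invariant_to_sigma0_and_m0(self, wm):
        u = SequenceSettings("SPGR", [5.0, 18.0], 20.0, 0.0)
        c1 = cost(u, [wm], params=("t1", "m0"), poi=("t1",))
        c2 = cost(u, [wm.replace(m0=4.0)], params=("t1", "m0"), poi=("t1",))
        assert c1 == pytest.approx(c2, rel=1e-9)

    def test_white_matter_set_matches_per_tissue_summation(self):
        """Cost over the off-resonance grid equals the brute-force sum of
        single-tissue costs (T1 = 781 ms, T2 = 65 ms white matter point)."""
        grid = np.arange(-100.0, 105.0, 5.0)
        tissues = [WHITE_MATTER.replace(omega0=w) for w in grid]
        u = SequenceSettings("bSSFP", [20, 40, 60], 6.0, 3.0,
                             rf_phases=[180, 0, 90])
        total = cost(u, tissues)
        brute = sum(cost(u, [p]) for p in tissues)
        assert total == pytest.approx(brute, rel=1e-10)


class TestCatalogue:
    def test_planet_has_two_free_variables(self):
        prob = method_catalogue("PLANET", 6)
        assert prob.n_variables == 2
        u = prob.build(np.array([35.0, 6.0]))
        assert len(u) == 1 and u[0].n_measurements == 6
        assert np.unique(u[0].flips).size == 1  # single flip forced
        assert np.unique(u[0].trs).size == 1

    def test_dess_two_signals_per_tr_shared_flip(self):
        prob = method_catalogue("DESS", 4)
        u = prob.build(prob.random_x0(np.random.default_rng(0)))
        assert all(s.method == "DESS" and s.n_measurements == 2 for s in u)
        assert all(s.flips.size == 1 for s in u)

    def test_transient_below_400_flagged_not_encodable(self):
        assert not method_catalogue("MRF_spoiled", 100).spatially_encodable
        assert not method_catalogue("MRF_balanced", 200).spatially_encodable
        assert method_catalogue("MRF_balanced", 400).spatially_encodable

    def test_unsupported_n_lists_grid(self):
        with pytest.raises(ValueError, match="transient grid"):
            method_catalogue("MRF_spoiled", 17)
        with pytest.raises(ValueError, match="echoes per TR"):
            method_catalogue("TESS", 4)

    def test_balanced_methods_score_omega0_grid(self):
        prob = method_catalogue("DESPOT_JSR", 5)
        assert len(prob.tissue_set) == 41  # -100..100 Hz in 5 Hz steps
        assert prob.nuisance == ("t1", "t2", "m0", "phi0", "omega0")
        spoiled = method_catalogue("MRF_spoiled", 10)
        assert len(spoiled.tissue_set) == 1
        assert spoiled.nuisance == ("t1", "t2", "m0")

    def test_fast_path_matches_settings_path(self, rng):
        """The vectorized design sweep and the generic settings-based cost
        agree exactly for every catalogued fast path."""
        grid = [-50.0, 0.0, 50.0]
        for meth, n, kw in [
            ("MRF_spoiled", 5, dict(driven_equilibrium=True,
                                    tr_bounds=(2.3, 3000.0))),
            ("MRF_balanced", 10, dict(omega0_grid=grid)),
            ("SPGR", 4, {}),
            ("DESPOT_JSR", 6, dict(omega0_grid=grid)),
            ("PLANET", 6, dict(omega0_grid=grid)),
        ]:
            prob = method_catalogue(meth, n, **kw)
            x = prob.random_x0(rng)
            c_batch = prob.cost_batch(x[None])[0]
            c_ref = cost(prob.build(x), prob.tissue_set,
                         params=prob.nuisance, poi=prob.poi)
            assert c_batch == pytest.approx(c_ref, rel=1e-9), meth


class TestSolve:
    def test_degenerate_bounds_return_initialization(self, wm):
        prob = method_catalogue("SPGR", 2, n_starts=3, seed=0, maxiter=20)
        x_fixed = np.array([8.0, 15.0, 12.0, 12.0])
        prob = dataclasses.replace(
            prob, bounds=np.stack([x_fixed, x_fixed], axis=1),
            tissue_set=[wm], nuisance=("t1", "m0"), poi=("t1",),
        )
        res = solve(prob)
        assert np.allclose(res.x_opt, x_fixed)
        assert res.cost == pytest.approx(
            cost(prob.build(x_fixed), [wm], params=("t1", "m0"), poi=("t1",))
        )

    def test_two_flip_toy_matches_grid_search(self, wm):
        """Two SPGR flips at fixed TR, T1-only efficiency: the SQP solution
        coincides with an exhaustive 1-degree grid search within 0.5 deg."""
        tr = 20.0

        def grid_cost(a1, a2):
            u = SequenceSettings("SPGR", [a1, a2], tr, 0.0)
            return cost(u, [wm], params=("t1", "m0"), poi=("t1",))

        grid = np.arange(1.0, 91.0, 1.0)
        costs = np.array([[grid_cost(a, b) for b in grid] for a in grid])
        i, j = np.unravel_index(np.argmin(costs), costs.shape)
        best_grid = sorted([grid[i], grid[j]])

        prob = method_catalogue("SPGR", 2, n_starts=12, seed=4, maxiter=80)
        prob = dataclasses.replace(prob, tissue_set=[wm],
                                   nuisance=("t1", "m0"), poi=("t1",))
        # fix TRs to the same value as the grid search
        b = prob.bounds.copy()
        b[2] = (tr, tr)
        b[3] = (tr, tr)
        prob = dataclasses.replace(prob, bounds=b)
        res = solve(prob)
        best_sqp = sorted(res.x_opt[:2])
        assert np.all(np.abs(np.array(best_sqp) - best_grid) < 0.5)

    def test_reproducible_and_multistart_superset(self, wm):
        """Same seed gives identical results; more starts from the same
        stream can only improve (or match) the best cost."""
        kw = dict(omega0_grid=[0.0, 50.0], seed=9, maxiter=30)
        p1 = method_catalogue("PLANET", 6, n_starts=4, **kw)
        p2 = method_catalogue("PLANET", 6, n_starts=4, **kw)
        r1, r2 = solve(p1), solve(p2)
        assert r1.cost == r2.cost
        assert np.array_equal(r1.x_opt, r2.x_opt)
        assert r1.per_start_costs == r2.per_start_costs
        p8 = method_catalogue("PLANET", 6, n_starts=8, **kw)
        r8 = solve(p8)
        assert r8.cost <= r1.cost + 1e-12
        assert r8.per_start_costs[:4] == r1.per_start_costs

    def test_solution_respects_bounds(self, wm):
        prob = fingerprint_toy_problem(n_starts=2, seed=5, maxiter=25)
        res = solve(prob)
        assert np.all(res.x_opt >= prob.bounds[:, 0] - 1e-6)
        assert np.all(res.x_opt <= prob.bounds[:, 1] + 1e-6)
        # reported cost is the independent settings-path recomputation
        ref = cost(res.u_opt, prob.tissue_set, params=prob.nuisance)
        assert res.cost == pytest.approx(ref, rel=1e-8)


def test_canonicalize_cycle_rotation():
    flips = np.array([90.0, 0.0, 60.0, 180.0, 0.0])
    trs = np.array([5.0, 2000.0, 3.0, 4.0, 100.0])
    f, t = canonicalize_cycle(flips, trs)
    # longest delay is after pulse 1, so pulse 2 (60 deg) leads
    assert f[0] == 60.0 and t[0] == 3.0
    assert list(f) == [60.0, 180.0, 0.0, 90.0, 0.0]
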