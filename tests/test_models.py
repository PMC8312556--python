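"""Forward-model correctness: closed forms vs brute-force isochromat
propagation, EPG transients, driven-equilibrium fixed points, and the
structural invariants every signal model must satisfy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles as oracles
from qmreff import (EPGState, SequenceSettings, TissueParams,
                    bloch_balanced_transient, bssfp_signal,
                    driven_equilibrium_state, epg_spoiled_transient, simulate,
                    spgr_signal, steady_state_echoes)
from qmreff.models import _epg_cycle_factory, signals_batch, tissue_arrays


class TestSPGR:
    def test_zero_flip_gives_zero_signal(self, wm):
        assert spgr_signal(wm, 0.0, 20.0) == 0

    def test_full_recovery_90_gives_m0(self):
        p = TissueParams(781, 65, m0=1.0)
        s = spgr_signal(p, 90.0, 1e9)
        assert abs(s - 1.0) < 1e-12

    def test_ernst_angle_argmax(self, wm):
        """Signal is maximized at acos(exp(-TR/T1)), and the closed form
        tracks an ideally spoiled Bloch simulation."""
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda a: -abs(spgr_signal(wm, a, 20.0)),
                              bounds=(0.5, 90.0), method="bounded")
        ernst = np.degrees(np.arccos(np.exp(-20.0 / 781.0)))
        assert abs(res.x - ernst) < 1e-3
        for flip in (5.0, ernst, 40.0):
            brute = oracles.ideally_spoiled_spgr(wm, flip, 20.0)
            assert abs(spgr_signal(wm, flip, 20.0) - brute) < 1e-6 * abs(brute)

    def test_invalid_parameters_raise(self, wm):
        with pytest.raises(ValueError):
            spgr_signal(wm, 200.0, 20.0)
        with pytest.raises(ValueError):
            spgr_signal(wm, 30.0, -1.0)
        with pytest.raises(ValueError):
            TissueParams(-5.0, 65.0)


class TestBSSFP:
    def test_zero_flip_gives_zero_signal(self, wm):
        assert abs(bssfp_signal(wm, 0.0, 5.0, 2.5)) < 1e-15

    @pytest.mark.parametrize("omega0", [0.0, 17.0, -63.0])
    def test_matches_lab_frame_isochromat(self, omega0):
        p = TissueParams(781, 65, 1.0, phi0=0.4, omega0=omega0)
        ours = bssfp_signal(p, 30.0, 5.0, 2.5)
        brute = oracles.bssfp_lab_frame(p, 30.0, 5.0, 2.5)
        assert abs(ours - brute) < 1e-8 * abs(brute)

    def test_banding_periodicity_in_omega0(self, wm):
        """|s| is periodic in omega0 with period 1/TR (the TE precession
        phase breaks complex periodicity, the magnitude is exact)."""
        tr = 5.0
        for om in (0.0, 31.0, 90.0):
            a = bssfp_signal(wm.replace(omega0=om), 35.0, tr, 2.5)
            b = bssfp_signal(wm.replace(omega0=om + 1000.0 / tr), 35.0, tr, 2.5)
            assert abs(abs(a) - abs(b)) < 1e-12


class TestSteadyStateEchoes:
    def test_zero_flip_all_echoes_zero(self, wm):
        assert np.all(np.abs(steady_state_echoes(wm, 0.0, 10.0, 3.0, 3)) < 1e-14)

    @pytest.mark.parametrize("flip,tr", [(35.0, 10.0), (70.0, 15.0), (15.0, 8.0)])
    def test_matches_isochromat_pathways(self, wm, flip, tr):
        ours = steady_state_echoes(wm, flip, tr, 3.0, 3)
        brute = oracles.sss_pathways_isochromats(wm, flip, tr, 3.0)
        assert np.max(np.abs(ours - brute)) < 1e-6 * np.max(np.abs(brute))

    def test_higher_order_echo_not_larger(self, wm):
        """For T2 < T1 and flip <= 90 the F_-1 echo never exceeds F_0."""
        for flip in np.arange(10.0, 95.0, 10.0):
            for tr in (5.0, 12.0, 25.0):
                e = steady_state_echoes(wm, flip, tr, 2.0, 2)
                assert abs(e[1]) <= abs(e[0]) + 1e-12


class TestSpoiledTransient:
    def test_zero_flips_zero_signal(self, wm):
        u = SequenceSettings("MRF_spoiled", np.zeros(6), 10.0, 2.0)
        assert np.all(epg_spoiled_transient(wm, u).signal == 0)

    def test_single_90_from_thermal(self, wm):
        u = SequenceSettings("MRF_spoiled", [90.0], [10.0], 0.0)
        rec = epg_spoiled_transient(wm, u)
        assert abs(abs(rec.signal[0]) - wm.m0) < 1e-12

    def test_matches_isochromat_ensemble(self, wm):
        flips = [40.0, 120.0, 70.0, 10.0, 90.0, 150.0]
        trs = [8.0, 12.0, 6.0, 20.0, 9.0, 15.0]
        u = SequenceSettings("MRF_spoiled", flips, trs, 2.0)
        ours = epg_spoiled_transient(wm, u).signal
        brute = oracles.spoiled_transient_isochromats(wm, flips, trs, 2.0)
        assert np.max(np.abs(ours - brute)) < 1e-6 * np.max(np.abs(brute))

    def test_record_timing(self, wm):
        u = SequenceSettings("MRF_spoiled", [30.0, 30.0], [10.0, 20.0], 2.0)
        rec = epg_spoiled_transient(wm, u)
        assert rec.t_acq == 30.0
        assert np.allclose(rec.times, [2.0, 12.0])


class TestBalancedTransient:
    def test_zero_flips_zero_signal(self, wm):
        u = SequenceSettings("MRF_balanced", np.zeros(8), 5.0, 2.5)
        assert np.all(bloch_balanced_transient(wm, u).signal == 0)

    def test_converges_to_bssfp_steady_state(self):
        """A constant-flip alternating-phase train settles onto the closed
        form after ~5 T1 of pulsing."""
        p = TissueParams(781, 65, 1.0, phi0=0.3, omega0=12.0)
        n = int(8 * p.t1 / 5.0)
        u = SequenceSettings("MRF_balanced", np.full(n, 30.0), 5.0, 2.5)
        tail = bloch_balanced_transient(p, u).signal[-1]
        cf = bssfp_signal(p, 30.0, 5.0, 2.5)
        assert abs(tail - cf) < 1e-6 * abs(cf)

    def test_band_edge_null(self, wm):
        """At omega0 = +-1/(2 TR) the alternating-phase steady state hits
        the banding null (moderate flip): the magnitude minimum of an
        omega0 sweep sits at the band edge, matching the isochromat
        oracle."""
        tr, flip = 5.0, 30.0
        edge = 1000.0 / (2 * tr)
        sweep = np.linspace(-edge, edge, 41)
        mags = np.array([
            abs(bssfp_signal(wm.replace(omega0=om), flip, tr, 2.5))
            for om in sweep
        ])
        assert sweep[np.argmin(mags)] in (-edge, edge)
        s_on = abs(bssfp_signal(wm, flip, tr, 2.5))
        s_edge = mags[0]
        assert s_edge < 0.1 * s_on
        brute = abs(oracles.bssfp_lab_frame(wm.replace(omega0=edge), flip, tr, 2.5))
        assert abs(s_edge - brute) < 1e-8
        # and the transient engine reproduces the same null
        u = SequenceSettings("MRF_balanced", np.full(2000, flip), tr, 2.5)
        tail = bloch_balanced_transient(wm.replace(omega0=edge), u).signal[-1]
        assert abs(abs(tail) - s_edge) < 1e-8


class TestDrivenEquilibrium:
    def test_zero_flips_fixed_point_is_thermal(self, wm):
        u = SequenceSettings("MRF_spoiled", np.zeros(4), 50.0, 2.0,
                             driven_equilibrium=True)
        st = driven_equilibrium_state(wm, u)
        assert abs(st.z[0] - wm.m0) < 1e-10
        assert np.all(np.abs(st.f_plus) < 1e-12)

    def test_fixed_point_matches_iterated_cycle(self, wm, rng):
        flips = rng.uniform(0, 120, 6)
        trs = rng.uniform(3, 80, 6)
        u = SequenceSettings("MRF_spoiled", flips, trs, 2.0,
                             driven_equilibrium=True)
        st = driven_equilibrium_state(wm, u)
        tissue = tissue_arrays(wm)
        cycle = _epg_cycle_factory(tissue, np.radians(flips), trs, 2.0,
                                   np.zeros(6), 0.0)
        it = EPGState.thermal(wm.m0, st.max_order, (1,))
        for _ in range(200):
            it = cycle(it)
        assert np.abs(st.to_vector() - it.to_vector()[0]).max() < 1e-9

    def test_residual_contract(self, wm, rng):
        """One full-cycle propagation of the returned state moves it by
        less than 1e-10 M0 (also for a long train)."""
        for n in (5, 60):
            flips = rng.uniform(0, 90, n)
            trs = rng.uniform(3, 30, n)
            u = SequenceSettings("MRF_spoiled", flips, trs, 2.0,
                                 driven_equilibrium=True)
            st = driven_equilibrium_state(wm, u)
            tissue = tissue_arrays(wm)
            cycle = _epg_cycle_factory(tissue, np.radians(flips), trs, 2.0,
                                       np.zeros(n), 0.0)
            before = st.to_vector()
            after = cycle(EPGState(st.f_plus[None].copy(),
                                   st.f_minus[None].copy(),
                                   st.z[None].copy())).to_vector()[0]
            assert np.abs(after - before).max() <= 1e-10 * wm.m0

    def test_balanced_fixed_point(self, wm):
        u = SequenceSettings("MRF_balanced", [40.0, 70.0, 20.0], [5.0, 7.0, 9.0],
                             2.0, driven_equilibrium=True)
        m = driven_equilibrium_state(wm, u)
        rec1 = bloch_balanced_transient(wm, u)
        rec2 = bloch_balanced_transient(wm, u, initial=m)
        assert np.allclose(rec1.signal, rec2.signal, atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    flip=st.floats(0.0, 180.0),
    tr=st.floats(3.0, 50.0),
    m0=st.floats(0.1, 5.0),
    omega0=st.floats(-200.0, 200.0),
)
def test_magnitude_bound_and_m0_linearity(flip, tr, m0, omega0):
    """|signal| <= M0 for every model, and signal is exactly linear in M0."""
    p = TissueParams(781.0, 65.0, m0=m0, omega0=omega0)
    p2 = p.replace(m0=2.5 * m0)
    checks = [
        spgr_signal(p, flip, tr),
        bssfp_signal(p, flip, tr, 2.5),
        steady_state_echoes(p, flip, tr, 2.0, 2)[0],
    ]
    doubles = [
        spgr_signal(p2, flip, tr),
        bssfp_signal(p2, flip, tr, 2.5),
        steady_state_echoes(p2, flip, tr, 2.0, 2)[0],
    ]
    for s, s2 in zip(checks, doubles):
        assert abs(s) <= m0 * (1 + 1e-9)
        assert abs(s2 - 2.5 * s) <= 1e-9 * m0


def test_t2_longer_than_t1_warns_but_evaluates():
    with pytest.warns(UserWarning, match="exceeds t1"):
        p = TissueParams(100.0, 200.0)
    assert np.isfinite(bssfp_signal(p, 30.0, 5.0, 2.5))


def test_signals_batch_stacks_sequences(wm):
    """Jointly fitted sequence lists stack measurements and sum durations."""
    spgr = SequenceSettings("SPGR", [10.0, 20.0], 8.0, 2.0)
    bssfp = SequenceSettings("bSSFP", [35.0], 6.0, 2.0)
    sig, t_acq = signals_batch(wm, [spgr, bssfp])
    assert sig.shape == (1, 3)
    assert t_acq == pytest.approx(22.0)
    assert sig[0, 0] == pytest.approx(spgr_signal(wm, 10.0, 8.0))


def test_signal_record_csv_roundtrip(wm, tmp_path):
    u = SequenceSettings("MRF_spoiled", [30.0, 60.0], [10.0, 12.0], 2.0)
    rec = simulate(wm, u)
    df = rec.to_frame()
    path = tmp_path / "sig.csv"
    df.to_csv(path, index=False)
    import pandas as pd

    back = pd.read_csv(path)
    assert list(back.columns) == ["index", "time_ms", "re", "im"]
    assert np.allclose(back["re"] + 1j * back["im"], rec.signal)
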