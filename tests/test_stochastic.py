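"""Exact SSA: oracles on reduced networks, classification, ensembles."""

import numpy as np
import pytest

import sacsim as s

from conftest import SUITE_SEED


def _zeroed(**keep):
    """Molecule-unit parameters with every rate zero except ``keep``."""
    # rates off; saturation constants keep their canonical (positive)
    # values so the rate laws stay well-defined
    base = {f: 0.0 for f in (
        "kdeg", "ksynCDC20", "kassMC", "kDMC", "kassAC", "kDAC", "kassACMC",
        "kDACMC", "kdegBG", "kact", "kinact", "ksynX", "kdegX", "kdegBGX",
        "katt", "kprime", "vinact", "konCDC20", "koffCDC20", "konX",
        "koffX")}
    base.update(keep)
    return s.ModelParameters.molecules(**base)


class TestKernel:
    def test_frozen_system_stays_constant(self):
        p = _zeroed()
        proto = s.ProtocolSpec(mode="arrest", nUK0=10, t_max=100.0, seed=1)
        traj = s.ssa_run(proto, p)
        assert np.ptp(traj.y[:, :9], axis=0).max() == 0.0

    def test_states_are_nonnegative_integers(self, params):
        proto = s.ProtocolSpec(mode="washout", nUK0=10, t_max=300.0, seed=3)
        traj = s.ssa_run(proto, params)
        assert np.all(traj.y >= 0.0)
        assert np.all(traj.y == np.round(traj.y))

    def test_moieties_integer_exact_along_path(self, params):
        proto = s.ProtocolSpec(mode="arrest", nUK0=10, t_max=400.0, seed=5)
        traj = s.ssa_run(proto, params)
        apc = traj.y[:, 1] + traj.y[:, 2] + traj.y[:, 7]
        mad = traj.y[:, 3] + traj.y[:, 4] + traj.y[:, 6] + traj.y[:, 7]
        assert np.ptp(apc) == 0.0 and np.ptp(mad) == 0.0

    def test_nuk_non_increasing_in_washout(self, params):
        proto = s.ProtocolSpec(mode="washout", nUK0=10, t_max=400.0, seed=7)
        traj = s.ssa_run(proto, params)
        assert np.all(np.diff(traj.nUK) <= 0)

    def test_nuk_frozen_in_arrest(self, params):
        proto = s.ProtocolSpec(mode="arrest", nUK0=10, t_max=300.0, seed=9)
        traj = s.ssa_run(proto, params)
        assert np.all(traj.nUK == 10)

    def test_reproducible_given_seed(self, params):
        proto = s.ProtocolSpec(mode="washout", nUK0=10, t_max=200.0, seed=11)
        a, b = s.ssa_run(proto, params), s.ssa_run(proto, params)
        assert np.array_equal(a.y, b.y)
        assert a.t_cross == b.t_cross

    def test_nm_parameters_rejected(self, params_nm):
        with pytest.raises(ValueError):
            s.ssa_run(s.ProtocolSpec(), params_nm)


class TestAttachmentOracle:
    def test_mean_time_to_full_attachment_matches_closed_form(self):
        # pure attachment from nUK0=10: sum of independent exponential
        # stages, E[T] = (1/katt) * H_10
        p = _zeroed(katt=3.0e-2)
        times = []
        for i in range(300):
            proto = s.ProtocolSpec(mode="washout", nUK0=10, t_max=2000.0,
                                   seed=100 + i)
            times.append(s.ssa_run(proto, p).t_all_attached)
        h10 = sum(1.0 / k for k in range(1, 11))
        expected = h10 / 3.0e-2
        assert np.mean(times) == pytest.approx(expected, rel=0.10)


class TestBirthDeathOracle:
    def test_stationary_mean_and_variance_without_bursting(self):
        # constitutive synthesis (promoter pinned ON) + linear decay is a
        # Poisson birth-death process: mean = variance = ksyn/kdeg
        p = _zeroed(ksynCDC20=42.0, kdegBG=0.038, konCDC20=1.0)
        proto = s.ProtocolSpec(mode="arrest", nUK0=0, t_max=20_000.0, seed=21)
        traj = s.ssa_run(proto, p)
        c = traj.y[traj.t > 500.0, 0]
        expected = 42.0 / 0.038
        assert c.mean() == pytest.approx(expected, rel=0.03)
        assert c.var() == pytest.approx(expected, rel=0.15)

    def test_stationary_mean_with_bursting_carries_duty_cycle(self):
        p = _zeroed(ksynCDC20=42.0, kdegBG=0.038, konCDC20=1.0,
                    koffCDC20=0.1)
        proto = s.ProtocolSpec(mode="arrest", nUK0=0, t_max=40_000.0, seed=22)
        traj = s.ssa_run(proto, p)
        c = traj.y[traj.t > 1000.0, 0]
        duty = 1.0 / 1.1
        assert c.mean() == pytest.approx(42.0 * duty / 0.038, rel=0.05)

    def test_promoter_duty_cycle(self):
        p = _zeroed(konCDC20=1.0, koffCDC20=0.1, konX=1.0, koffX=0.1)
        proto = s.ProtocolSpec(mode="arrest", nUK0=0, t_max=40_000.0, seed=23)
        traj = s.ssa_run(proto, p)
        assert traj.y[:, 9].mean() == pytest.approx(1.0 / 1.1, abs=0.01)


class TestClassification:
    def _traj(self, t_cross, nuk, seed=0):
        proto = s.ProtocolSpec(mode="washout", nUK0=10, t_max=700.0,
                               seed=seed)
        y = np.zeros((3, 11))
        return s.stochastic.StochasticTrajectory(
            t=np.array([0.0, 1.0, 2.0]), y=y, t_cross=t_cross,
            nUK_at_cross=nuk, t_all_attached=None, seed=seed, protocol=proto)

    def test_crossing_with_unattached_kinetochores_is_adaptation(self,
                                                                 params):
        rec = s.classify_outcome(self._traj(300.0, 3), params)
        assert rec.classification == "adapted"

    def test_crossing_after_full_attachment_is_exit(self, params):
        rec = s.classify_outcome(self._traj(300.0, 0), params)
        assert rec.classification == "exited"

    def test_no_crossing_is_arrested(self, params):
        rec = s.classify_outcome(self._traj(None, None), params)
        assert rec.classification == "arrested"

    def test_grid_fallback_matches_metadata(self, params):
        proto = s.ProtocolSpec(mode="arrest", nUK0=10, t_max=2500.0, seed=33)
        traj = s.ssa_run(proto, params)
        rec = s.classify_outcome(traj, params)
        stripped = s.stochastic.StochasticTrajectory(
            t=traj.t, y=traj.y, t_cross=None, nUK_at_cross=None,
            t_all_attached=traj.t_all_attached, seed=traj.seed,
            protocol=proto)
        rec2 = s.classify_outcome(stripped, params)
        assert rec2.classification == rec.classification
        if rec.t_cross is not None:
            # grid detection can only lag the exact event time
            assert 0.0 <= rec2.t_cross - rec.t_cross <= 2 * proto.sample_dt


class TestEnsembles:
    def test_fractions_sum_to_one(self, wt_washout):
        total = (wt_washout.adapted_fraction + wt_washout.exited_fraction
                 + wt_washout.arrested_fraction)
        assert total == pytest.approx(1.0)

    def test_ecdf_is_monotone(self, wt_washout):
        t, f = wt_washout.ecdf()
        assert np.all(np.diff(t) >= 0) and np.all(np.diff(f) > 0)

    def test_deterministic_given_seed0(self, params):
        proto = s.ProtocolSpec(mode="washout", nUK0=10)
        a = s.run_ensemble(proto, params, n=8, seed0=77)
        b = s.run_ensemble(proto, params, n=8, seed0=77)
        assert [r.to_dict() for r in a.records] == \
            [r.to_dict() for r in b.records]

    def test_spontaneous_escape_from_arrest(self, params):
        # noise alone drives ON -> OFF threshold crossings at fixed nUK=10
        escapes = s.run_ensemble(
            s.ProtocolSpec(mode="arrest", nUK0=10, t_max=3000.0), params,
            n=12, seed0=SUITE_SEED).crossing_times()
        assert len(escapes) >= 10

    def test_satisfied_checkpoint_state_is_absorbing(self, params):
        # once every kinetochore is attached there is no activating signal:
        # the high-AC state cannot re-engage the checkpoint
        for i in range(6):
            proto = s.ProtocolSpec(mode="arrest", nUK0=0, initial="off",
                                   t_max=700.0, seed=SUITE_SEED + i)
            traj = s.ssa_run(proto, params)
            assert traj.AC.min() > 0.5 * params.ac_threshold

    def test_washout_phenotypes(self, wt_washout):
        # attachment competes with escape: both outcomes occur, nobody
        # stays arrested over the 960-minute horizon
        assert wt_washout.adapted_fraction > 0.2
        assert wt_washout.exited_fraction > 0.2
        assert wt_washout.arrested_fraction < 0.1


class TestAdaptationStatistics:
    def test_exponential_rate_recovery_on_synthetic_sample(self, params):
        rng = np.random.default_rng(5)
        times = rng.exponential(100.0, size=100)
        records = [s.OutcomeRecord(seed=i, t_cross=float(t), nUK_at_cross=5,
                                   t_all_attached=None,
                                   classification="adapted")
                   for i, t in enumerate(times)]
        summary = s.EnsembleSummary(protocol=s.ProtocolSpec(),
                                    records=records, seed0=0)
        fit = s.adaptation_time_distribution(summary)
        assert fit.rate == pytest.approx(0.01, rel=0.20)
        assert fit.exponential_like

    def test_degenerate_times_flagged_non_exponential(self):
        records = [s.OutcomeRecord(seed=i, t_cross=50.0, nUK_at_cross=5,
                                   t_all_attached=None,
                                   classification="adapted")
                   for i in range(30)]
        summary = s.EnsembleSummary(protocol=s.ProtocolSpec(),
                                    records=records, seed0=0)
        fit = s.adaptation_time_distribution(summary)
        assert fit.cv == pytest.approx(0.0)
        assert not fit.exponential_like

    def test_too_few_events_raise(self):
        records = [s.OutcomeRecord(seed=0, t_cross=10.0, nUK_at_cross=1,
                                   t_all_attached=None,
                                   classification="adapted")]
        summary = s.EnsembleSummary(protocol=s.ProtocolSpec(),
                                    records=records, seed0=0)
        with pytest.raises(ValueError):
            s.adaptation_time_distribution(summary)

    def test_memoryless_escape_has_unit_cv(self, wt_arrest):
        fit = s.adaptation_time_distribution(wt_arrest)
        assert 0.7 <= fit.cv <= 1.3

    def test_adapters_escape_early_with_many_kinetochores(self, wt_washout):
        cmp = s.adapters_vs_exiters(wt_washout)
        assert cmp.complete
        # early adapters escape while many kinetochores remain unattached
        assert cmp.pearson_r < 0.0
        assert np.median(cmp.adapter_times) <= np.median(cmp.exiter_times)

    def test_partial_result_when_a_class_is_empty(self, params):
        records = [s.OutcomeRecord(seed=i, t_cross=50.0 + i, nUK_at_cross=2,
                                   t_all_attached=None,
                                   classification="adapted")
                   for i in range(5)]
        summary = s.EnsembleSummary(protocol=s.ProtocolSpec(),
                                    records=records, seed0=0)
        cmp = s.adapters_vs_exiters(summary)
        assert cmp.exiters_empty and not cmp.adapters_empty
        assert not cmp.complete
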