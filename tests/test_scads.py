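"""Statistical artifact control: stats, thresholds, flags, feasibility,
two-pass detection, repair and averaging."""

import numpy as np
import pytest

from emkit.containers import ConditionTable, EpochSet
from emkit.forward import forward_dipoles
from emkit.inverse import InterpolationOperator
from emkit.scads import (
    apply_feasibility,
    compute_trial_stats,
    flag_artifacts,
    interpolation_feasibility,
    propose_thresholds,
    read_thresholds,
    repair_and_average,
    scenario_counts,
    two_pass_detect,
    write_thresholds,
)


def _epochs(layout, data, codes=None):
    codes = codes if codes is not None else [1] * data.shape[0]
    return EpochSet(
        data=data, fs=250.0, t0=-0.1, layout=layout,
        conditions=ConditionTable.from_codes(codes),
    )


@pytest.fixture(scope="module")
def interp300(eeg_layout_64):
    return InterpolationOperator(eeg_layout_64, lam=0.05, n_sources=300)


class TestTrialStats:
    def test_hand_computed_values(self, eeg_layout_32):
        data = np.zeros((1, 32, 3))
        data[0, 0] = [1.0, -4.0, 2.0]
        stats = compute_trial_stats(_epochs(eeg_layout_32, data))
        assert stats.amp_max[0, 0] == 4.0
        assert stats.grad_max[0, 0] == 6.0
        assert stats.sd[0, 0] == pytest.approx(np.std([1, -4, 2], ddof=1))

    def test_constant_trial(self, eeg_layout_32):
        data = np.full((1, 32, 10), -2.5)
        stats = compute_trial_stats(_epochs(eeg_layout_32, data))
        assert np.all(stats.sd == 0) and np.all(stats.grad_max == 0)
        assert np.all(stats.amp_max == 2.5)

    def test_permutation_invariant_to_trial_order(self, eeg_layout_32, rng):
        data = rng.normal(size=(6, 32, 50))
        s1 = compute_trial_stats(_epochs(eeg_layout_32, data))
        perm = rng.permutation(6)
        s2 = compute_trial_stats(_epochs(eeg_layout_32, data[perm]))
        assert np.allclose(np.sort(s1.amp_max, axis=0), np.sort(s2.amp_max, axis=0))

    def test_interval_outside_epoch_rejected(self, eeg_layout_32, rng):
        data = rng.normal(size=(2, 32, 50))
        with pytest.raises(ValueError, match="interval"):
            compute_trial_stats(_epochs(eeg_layout_32, data), intervals=[(5.0, 6.0)])


class TestThresholds:
    def test_identical_trials_give_zero_iqr(self, eeg_layout_32, rng):
        """Pure IQR rule (no spread floor): identical trials collapse the
        limit onto the median, so any deviation would be flagged."""
        trial = rng.normal(size=(1, 32, 50))
        data = np.repeat(trial, 6, axis=0)
        stats = compute_trial_stats(_epochs(eeg_layout_32, data))
        thr = propose_thresholds(stats, relative_floor=0.0)
        assert np.allclose(thr.channel_limits["sd"], np.median(stats.sd, axis=0))

    def test_outlier_trial_flagged_at_default_k(self, eeg_layout_32, rng):
        data = rng.normal(size=(20, 32, 50))
        data[7, 3] *= 10  # one clearly contaminated sensor-trial
        stats = compute_trial_stats(_epochs(eeg_layout_32, data))
        thr = propose_thresholds(stats, k=3.0)
        # direct quantile computation confirms the statistic exceeds the rule
        x = stats.sd[:, 3]
        q75, q25 = np.percentile(x, [75, 25])
        assert x[7] > np.median(x) + 3.0 * (q75 - q25)
        flags = flag_artifacts(stats, thr)
        assert flags.sensor_bad[7, 3]

    def test_too_few_trials_rejected(self, eeg_layout_32, rng):
        data = rng.normal(size=(3, 32, 20))
        stats = compute_trial_stats(_epochs(eeg_layout_32, data))
        with pytest.raises(ValueError, match="4 trials"):
            propose_thresholds(stats)

    def test_threshold_file_round_trip(self, tmp_path, eeg_layout_32, rng):
        data = rng.normal(size=(8, 32, 20))
        stats = compute_trial_stats(_epochs(eeg_layout_32, data))
        thr = propose_thresholds(stats)
        path = tmp_path / "thr.txt"
        write_thresholds(thr, path, eeg_layout_32.names)
        back = read_thresholds(path, eeg_layout_32.names)
        for stat in ("amp_max", "sd", "grad_max"):
            assert np.array_equal(back.channel_limits[stat], thr.channel_limits[stat])
            assert back.global_limits[stat] == thr.global_limits[stat]
        assert back.max_bad_sensors_per_trial == thr.max_bad_sensors_per_trial


class TestFlagArtifacts:
    def test_injected_spike_flagged_alone(self, eeg_layout_32, rng):
        """A 10x amplitude spike is the only flag on otherwise clean data."""
        erp = 10.0 * np.hanning(50)
        data = erp[None, None, :] + rng.normal(size=(20, 32, 50))
        data[3, 7] += 10 * np.abs(data).max()
        stats = compute_trial_stats(_epochs(eeg_layout_32, data))
        flags = flag_artifacts(stats, propose_thresholds(stats))
        assert flags.sensor_bad[3, 7]
        others = flags.sensor_bad.copy()
        others[3, 7] = False
        assert others.sum() == 0

    def test_infinite_thresholds_flag_nothing(self, eeg_layout_32, rng):
        data = rng.normal(size=(6, 32, 50))
        stats = compute_trial_stats(_epochs(eeg_layout_32, data))
        thr = propose_thresholds(stats)
        for s in thr.channel_limits:
            thr.channel_limits[s] = np.full(32, np.inf)
            thr.global_limits[s] = np.inf
        flags = flag_artifacts(stats, thr)
        assert not flags.sensor_bad.any() and not flags.trial_rejected.any()

    def test_all_zero_data_unflagged(self, eeg_layout_32):
        data = np.zeros((6, 32, 50))
        stats = compute_trial_stats(_epochs(eeg_layout_32, data))
        flags = flag_artifacts(stats, propose_thresholds(stats))
        assert not flags.sensor_bad.any()

    def test_scale_equivariance(self, eeg_layout_32, rng):
        """Multiplying the data by c scales stats and thresholds by c and
        leaves the flags unchanged."""
        data = rng.normal(size=(12, 32, 50))
        data[2, 5] *= 8
        s1 = compute_trial_stats(_epochs(eeg_layout_32, data))
        s2 = compute_trial_stats(_epochs(eeg_layout_32, 3.7 * data))
        assert np.allclose(s2.amp_max, 3.7 * s1.amp_max)
        f1 = flag_artifacts(s1, propose_thresholds(s1))
        f2 = flag_artifacts(s2, propose_thresholds(s2))
        assert np.array_equal(f1.sensor_bad, f2.sensor_bad)
        assert np.array_equal(f1.trial_rejected, f2.trial_rejected)


class TestFeasibility:
    def test_no_bad_sensors_passes_with_zero_error(self, eeg_layout_64, interp300):
        ok, worst = interpolation_feasibility(
            np.zeros(64, dtype=bool), eeg_layout_64, interp=interp300
        )
        assert ok and worst == 0.0

    def test_isolated_bad_sensor_passes(self, eeg_layout_64, interp300):
        for s in (0, 20, 45):
            bad = np.zeros(64, dtype=bool)
            bad[s] = True
            ok, _ = interpolation_feasibility(bad, eeg_layout_64, interp=interp300)
            assert ok

    def test_contiguous_edge_patch_fails(self, eeg_layout_64, interp300):
        """A 25% patch of bad sensors at the cap edge leaves the region
        unconstrained: extrapolation error explodes."""
        z = eeg_layout_64.positions[:, 2]
        seed = int(np.argmin(z))
        d = np.linalg.norm(
            eeg_layout_64.positions - eeg_layout_64.positions[seed], axis=1
        )
        patch = np.argsort(d)[:16]
        bad = np.zeros(64, dtype=bool)
        bad[patch] = True
        ok, worst = interpolation_feasibility(bad, eeg_layout_64, interp=interp300)
        assert not ok and worst > 0.2

    def test_monotone_under_growing_bad_set(self, eeg_layout_64, interp300):
        """Once the bad set grows past feasibility it never recovers
        (checked on a seeded nested sequence)."""
        rng = np.random.default_rng(5)
        order = rng.permutation(64)
        bad = np.zeros(64, dtype=bool)
        seen_fail = False
        for s in order[:20]:
            bad[s] = True
            ok, _ = interpolation_feasibility(bad, eeg_layout_64, interp=interp300)
            if seen_fail:
                assert not ok
            seen_fail = seen_fail or not ok


class TestTwoPass:
    def _signal_epochs(self, layout, rng, n_trials=12):
        data = rng.normal(size=(n_trials, layout.n_sensors, 80))
        return _epochs(layout, data)

    def test_single_channel_artifact_found_by_both_modes(self, eeg_layout_64, rng):
        epochs = self._signal_epochs(eeg_layout_64, rng)
        epochs.data[4, 9] += 40.0
        flags1, _ = two_pass_detect(epochs, mode="single")
        flags2, _ = two_pass_detect(epochs, mode="average-ref")
        assert flags1.sensor_bad[4, 9]
        assert flags2.sensor_bad[4, 9]

    def test_common_mode_transient_caught_after_average_reference(self, eeg_layout_64, rng):
        """An all-channel transient hides in the recording reference but
        is flagged globally once the reference bias is removed."""
        epochs = self._signal_epochs(eeg_layout_64, rng, n_trials=16)
        # common-mode: identical on every channel -> vanishes under average
        # reference... so use a near-common-mode transient with slight gradient
        gradient = 1.0 + 0.5 * np.linspace(0, 1, 64)
        burst = np.zeros(80)
        burst[30:50] = 25.0 * np.sin(np.linspace(0, 6 * np.pi, 20))
        epochs.data[5] += gradient[:, None] * burst[None, :]
        flags, _ = two_pass_detect(epochs, mode="average-ref")
        assert flags.trial_rejected[5]

    def test_clean_data_produces_no_rejections(self, eeg_layout_64, rng):
        epochs = self._signal_epochs(eeg_layout_64, rng)
        flags, _ = two_pass_detect(epochs, mode="average-ref")
        assert not flags.trial_rejected.any()

    def test_meg_uses_single_pass(self, meg_layout_32, rng):
        data = rng.normal(size=(8, 32, 40))
        epochs = _epochs(meg_layout_32, data)
        flags_single, _ = two_pass_detect(epochs, mode="single")
        flags_auto, _ = two_pass_detect(epochs)  # MEG: one pass regardless
        assert np.array_equal(flags_single.sensor_bad, flags_auto.sensor_bad)


class TestRepairAndAverage:
    def test_no_flags_equals_plain_mean(self, eeg_layout_32, rng):
        data = rng.normal(size=(10, 32, 40))
        epochs = _epochs(eeg_layout_32, data, codes=[1] * 5 + [2] * 5)
        stats = compute_trial_stats(epochs)
        thr = propose_thresholds(stats)
        for s in thr.channel_limits:
            thr.channel_limits[s][:] = np.inf
            thr.global_limits[s] = np.inf
        flags = flag_artifacts(stats, thr)
        averages = repair_and_average(epochs, flags)
        assert len(averages) == 2
        assert np.allclose(averages[0].data, data[:5].mean(axis=0))

    def test_interpolation_counts_bookkeeping(self, eeg_layout_64, interp300, rng):
        data = rng.normal(size=(6, 64, 40))
        epochs = _epochs(eeg_layout_64, data)
        stats = compute_trial_stats(epochs)
        thr = propose_thresholds(stats)
        flags = flag_artifacts(stats, thr)
        flags.sensor_bad[:] = False
        flags.sensor_bad[:, 11] = True  # one sensor bad in every trial
        flags.trial_rejected[:] = False
        averages = repair_and_average(epochs, flags, interp=interp300)
        assert averages[0].interpolation_counts[11] == averages[0].n_trials_used
        assert averages[0].interpolation_counts.sum() == averages[0].n_trials_used

    def test_repaired_sensor_close_to_truth(self, eeg_layout_64, interp300, rng):
        """Forward-simulated smooth topographies with one deleted sensor
        per trial: the averaged repaired sensor recovers the noiseless
        truth within 5% RMS."""
        topo = forward_dipoles(
            eeg_layout_64, np.array([1.0, 1.0, 6.0]), np.array([3.0, 5.0, 2.0])
        )[:, 0]
        course = np.hanning(40)
        clean = np.einsum("c,t->ct", topo, course)
        n_trials = 8
        data = np.tile(clean, (n_trials, 1, 1))
        epochs = _epochs(eeg_layout_64, data.copy())
        flags_bad = np.zeros((n_trials, 64), dtype=bool)
        for t in range(n_trials):
            s = t * 7 % 64
            flags_bad[t, s] = True
            epochs.data[t, s] = 999.0  # corrupted beyond recognition
        from emkit.scads import ArtifactFlags

        flags = ArtifactFlags(
            sensor_bad=flags_bad, trial_rejected=np.zeros(n_trials, dtype=bool)
        )
        averages = repair_and_average(epochs, flags, interp=interp300)
        err = np.sqrt(((averages[0].data - clean) ** 2).mean())
        assert err < 0.05 * np.sqrt((clean**2).mean())

    def test_condition_without_survivors_skipped(self, eeg_layout_32, rng):
        data = rng.normal(size=(6, 32, 20))
        epochs = _epochs(eeg_layout_32, data, codes=[1, 1, 1, 2, 2, 2])
        from emkit.scads import ArtifactFlags

        flags = ArtifactFlags(
            sensor_bad=np.zeros((6, 32), dtype=bool),
            trial_rejected=np.array([False] * 3 + [True] * 3),
        )
        averages = repair_and_average(epochs, flags)
        assert [a.condition_code for a in averages] == [1]


class TestScenarios:
    def test_trichotomy_counts_conserved(self, eeg_layout_64, interp300, rng):
        epochs = _epochs(eeg_layout_64, rng.normal(size=(20, 64, 60)))
        epochs.data[2, 5] += 50.0  # repairable
        epochs.data[8] += 30.0 * rng.normal(size=(64, 60))  # global garbage
        flags, thr = two_pass_detect(epochs)
        flags = apply_feasibility(flags, eeg_layout_64, thr, interp=interp300)
        counts = scenario_counts(flags)
        assert counts["clean"] + counts["repaired"] + counts["rejected"] == 20
        assert flags.sensor_bad[2, 5]
        assert flags.trial_rejected[8]
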