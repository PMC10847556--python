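"""Heart-rate estimation, fusion, HSMM decoding, and block extraction."""

import numpy as np
import pytest

from pcgscreen import segmentation as seg
from pcgscreen import synth


def viterbi_reference(emission_ll, dur_means, dur_sds, d_max):
    """Plain-loop exhaustive DP over (end frame, state, duration) — the
    independent reference for the vectorized decoder."""
    T = emission_ll.shape[0]
    n_s = 4
    logdur = np.full((n_s, d_max + 1), -np.inf)
    for j in range(n_s):
        for d in range(1, d_max + 1):
            logdur[j, d] = (-0.5 * ((d - dur_means[j]) / dur_sds[j]) ** 2
                            - np.log(dur_sds[j] * np.sqrt(2 * np.pi)))
    delta = np.full((T, n_s), -np.inf)
    for t in range(T):
        for j in range(n_s):
            best = -np.inf
            for d in range(1, min(d_max, t + 1) + 1):
                start = t - d + 1
                em = emission_ll[start:t + 1, j].sum()
                prev = 0.0 if start == 0 else delta[start - 1, (j - 1) % n_s]
                best = max(best, prev + logdur[j, d] + em)
            delta[t, j] = best
    return delta[T - 1].max()


class TestHeartRate:
    def test_exact_periodic_envelope(self):
        t = np.arange(0, 10, 1 / 50.0)
        env = np.maximum(0, np.sin(2 * np.pi * t / 0.8)) ** 4  # 800 ms period
        hr, sys_ms, _ = seg.estimate_heart_rate(env)
        assert hr == pytest.approx(75, abs=1)

    def test_bounds_forced_by_lag_window(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            hr, _, _ = seg.estimate_heart_rate(rng.standard_normal(500))
            assert 30 <= hr <= 120

    def test_too_short_envelope_rejected(self):
        with pytest.raises(ValueError):
            seg.estimate_heart_rate(np.ones(60))


class TestFusion:
    def test_single_recording_reduction(self):
        wav, _, _ = synth.synthesize_pcg(72, 1.0, 0.0, 2205, 10.0, 3)
        env = seg.envelope_features(wav, 2205)[:, 0]
        hr1, sys1, ac = seg.estimate_heart_rate(env)
        hr2, sys2 = seg.fuse_heart_rate([ac], [False])
        assert hr2 == hr1 and sys2 == sys1

    def test_noisy_recording_excluded(self):
        acs, flags = [], []
        for i in range(3):
            wav, _, _ = synth.synthesize_pcg(75, 0.5, 0.0, 2205, 10.0, 10 + i)
            env = seg.envelope_features(wav, 2205)[:, 0]
            acs.append(seg.estimate_heart_rate(env)[2])
            flags.append(False)
        noise_env = np.random.default_rng(1).standard_normal(500)
        acs.append(seg._autocorr(noise_env))
        flags.append(True)
        hr, _ = seg.fuse_heart_rate(acs, flags)
        assert hr == pytest.approx(75, abs=2)

    def test_fused_estimate_within_hull(self):
        """Four clean recordings at the same true rate: the fused rate stays
        inside the per-recording estimate range."""
        acs, hrs = [], []
        for i in range(4):
            wav, _, _ = synth.synthesize_pcg(68, 0.0, 0.0, 2205, 10.0, 20 + i)
            env = seg.envelope_features(wav, 2205)[:, 0]
            hr, _, ac = seg.estimate_heart_rate(env)
            hrs.append(hr)
            acs.append(ac)
        fused, _ = seg.fuse_heart_rate(acs, [False] * 4)
        assert min(hrs) - 1e-9 <= fused <= max(hrs) + 1e-9

    def test_all_noisy_rejected(self):
        with pytest.raises(ValueError):
            seg.fuse_heart_rate([np.ones(200)], [True])

    def test_fusion_robustness_vs_corrupted_single(self):
        """Replacing one of four recordings with noise: fused heart-rate
        error stays at or below the corrupted recording's own estimate
        error (median over participants)."""
        rng = np.random.default_rng(7)
        fused_err, single_err = [], []
        for i in range(25):
            true_hr = float(rng.uniform(55, 90))
            acs = []
            for k in range(3):
                wav, _, _ = synth.synthesize_pcg(true_hr, 0.5, 0.0, 2205, 10.0, 100 * i + k)
                acs.append(seg._autocorr(seg.envelope_features(wav, 2205)[:, 0]))
            noise = rng.standard_normal(len(acs[0]))
            ac_bad = seg._autocorr(noise)
            hr_bad, _, _ = seg._pick_from_autocorr(ac_bad, 50)
            fused, _ = seg.fuse_heart_rate(acs + [ac_bad], [False] * 4)
            fused_err.append(abs(fused - true_hr))
            single_err.append(abs(hr_bad - true_hr))
        assert np.median(fused_err) <= np.median(single_err)


class TestViterbi:
    @pytest.mark.parametrize("seed,t_frames", [(0, 60), (1, 120), (2, 200)])
    def test_matches_exhaustive_dp(self, seed, t_frames):
        rng = np.random.default_rng(seed)
        ll = rng.standard_normal((t_frames, 4))
        means = np.array([6.0, 10.0, 4.5, 20.0])
        sds = np.array([1.1, 2.0, 1.1, 2.5])
        d_max = 30
        states, logp = seg.viterbi_hsmm(ll, means, sds, d_max)
        ref = viterbi_reference(ll, means, sds, d_max)
        assert logp == pytest.approx(ref, rel=1e-9)

    def test_cyclic_state_order(self):
        rng = np.random.default_rng(5)
        ll = rng.standard_normal((150, 4))
        states, _ = seg.viterbi_hsmm(ll, [6, 10, 4.5, 20], [1.1, 2, 1.1, 2.5], 30)
        changes = np.flatnonzero(np.diff(states.astype(int)))
        for c in changes:
            assert states[c + 1] == (states[c] + 1) % 4


class TestSegmentationAccuracy:
    def test_s1_onset_recovery_on_clean_recordings(self):
        """>= 90% of true S1 onsets recovered within 60 ms; median heart-rate
        error <= 2 bpm over clean synthetic recordings."""
        rng = np.random.default_rng(123)
        em = seg.default_emission_model(2205)
        matched = total = 0
        hr_errors = []
        s1_durations = []
        for i in range(15):
            true_hr = float(rng.uniform(50, 90))
            grade = float(rng.choice([0.0, 0.0, 1.0, 2.0]))
            wav, onsets, _ = synth.synthesize_pcg(true_hr, grade, 0.0, 2205, 10.0, 1000 + i)
            feats = seg.envelope_features(wav, 2205)
            hr, sys_ms, _ = seg.estimate_heart_rate(feats[:, 0])
            hr_errors.append(abs(hr - true_hr))
            res = seg.segment_hsmm(wav, 2205, hr, sys_ms, em)
            tol = int(0.060 * 2205)
            for o in onsets:
                total += 1
                if len(res.cycle_starts) and np.min(np.abs(res.cycle_starts - o)) <= tol:
                    matched += 1
            st = res.frame_states
            runs = np.split(np.arange(len(st)), np.flatnonzero(np.diff(st)) + 1)
            s1_durations += [len(r) * 20.0 for r in runs[1:-1] if st[r[0]] == 0]
        assert matched / total >= 0.90
        assert np.median(hr_errors) <= 2.0
        assert 60 <= np.mean(s1_durations) <= 200  # decoded S1 duration sane (ms)


class TestExtractBlocks:
    def _onsets(self, n_cycles):
        return np.arange(n_cycles + 1) * 1000

    def test_fourteen_cycles_give_six_blocks(self):
        blocks = seg.extract_blocks(self._onsets(14))
        assert len(blocks) == 6
        assert [b.start_sample for b in blocks] == [0, 2000, 4000, 6000, 8000, 10000]

    def test_ten_cycles_give_four_blocks(self):
        assert len(seg.extract_blocks(self._onsets(10))) == 4

    def test_four_cycles_single_block(self):
        blocks = seg.extract_blocks(self._onsets(4))
        assert len(blocks) == 1
        assert blocks[0].start_sample == 0 and blocks[0].end_sample == 4000

    def test_short_decode_single_partial_block(self):
        blocks = seg.extract_blocks(self._onsets(2))
        assert len(blocks) == 1 and blocks[0].n_cycles == 2

    def test_zero_cycles_empty(self):
        assert seg.extract_blocks([500]) == []

    def test_blocks_tile_with_stride_two(self):
        onsets = self._onsets(20)
        blocks = seg.extract_blocks(onsets)
        for i, b in enumerate(blocks):
            assert b.start_sample == onsets[2 * i]
            assert b.end_sample == onsets[2 * i + 4]
            assert b.end_sample <= onsets[-1]
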