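"""Harmonic response mapping: DFT conventions, window handling, invariances,
and responder recovery on synthetic movies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evanstim import (
    OpticalStack,
    StimulationProtocol,
    ValidationError,
    classify_responders,
    extract_window,
    harmonic_response_score,
    response_map,
    roi_average_trace,
)
from evanstim.synthetic import NoiseModel, demo_layout, generate_calcium_movie


def brute_force_score(trace, fs, f_stim, harmonics):
    """Direct-summation DFT oracle, independent of numpy's FFT."""
    n = len(trace)
    total = 0.0
    for k in harmonics:
        b = round(k * f_stim * n / fs)
        re = sum(trace[j] * np.cos(-2 * np.pi * b * j / n) for j in range(n))
        im = sum(trace[j] * np.sin(-2 * np.pi * b * j / n) for j in range(n))
        total += np.hypot(re, im)
    return total


def pulse_train_trace(n=100, fs=10.0, amplitude=1.0, tau=0.5, n_pulses=10, rate=1.0):
    t = np.arange(n) / fs
    out = np.zeros(n)
    for i in range(n_pulses):
        t_i = i / rate
        active = t > t_i
        out[active] += amplitude * np.exp(-(t[active] - t_i) / tau)
    return out


class TestExtractWindow:
    def make_movie(self, n_frames=600, dt=0.1):
        data = np.arange(n_frames, dtype=float)[:, None, None] * np.ones((1, 4, 4))
        return OpticalStack(data, frame_interval_s=dt)

    def test_default_window_has_100_frames(self):
        movie = self.make_movie()
        sub = extract_window(movie, 21.0, 31.0)
        assert sub.n_frames == 100
        assert sub.t0_s == pytest.approx(21.0)
        # half-open: frame at t=31.0 excluded, frame at 21.0 included
        assert sub.data[0, 0, 0] == 210.0
        assert sub.data[-1, 0, 0] == 309.0

    def test_full_window_is_identity(self):
        movie = self.make_movie()
        sub = extract_window(movie, 0.0, 60.0)
        np.testing.assert_array_equal(sub.data, movie.data)

    def test_window_outside_recording_rejected(self):
        with pytest.raises(ValidationError):
            extract_window(self.make_movie(), 60.0, 62.0)


class TestHarmonicResponseScore:
    def test_pure_cosine_occupies_single_bin(self):
        t = np.arange(100) / 10.0
        score = harmonic_response_score(np.cos(2 * np.pi * 1.0 * t), 10.0, 1.0, (1, 2, 3, 4, 5))
        assert score == pytest.approx(50.0, abs=1e-9)  # N/2 at the 1 Hz bin

    @given(st.floats(-1e4, 1e4))
    def test_dc_shift_invariance(self, offset):
        # exact in exact arithmetic; the FFT of the shifted trace reintroduces
        # rounding at the scale of the offset, hence the absolute term
        trace = pulse_train_trace()
        s0 = harmonic_response_score(trace, 10.0, 1.0)
        s1 = harmonic_response_score(trace + offset, 10.0, 1.0)
        assert s1 == pytest.approx(s0, rel=1e-9, abs=1e-9 * max(1.0, abs(offset)))

    def test_constant_trace_scores_zero(self):
        assert harmonic_response_score(np.full(100, 7.0), 10.0, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_dft_oracle(self):
        trace = pulse_train_trace()
        fast = harmonic_response_score(trace, 10.0, 1.0, (1, 2, 3, 4, 5))
        slow = brute_force_score(trace, 10.0, 1.0, (1, 2, 3, 4, 5))
        assert fast == pytest.approx(slow, rel=1e-9)

    def test_off_bin_harmonic_refused_with_name(self):
        with pytest.raises(ValidationError, match="harmonic 3"):
            harmonic_response_score(np.zeros(100), 10.0, 0.33, (3,))

    def test_dc_harmonic_refused(self):
        with pytest.raises(ValidationError, match="DC"):
            harmonic_response_score(np.zeros(100), 10.0, 1.0, (0, 1))

    def test_ideal_pulse_train_energy_in_harmonic_bins(self):
        # an ideal 10-pulse decaying train concentrates its non-DC spectral
        # energy at integer multiples of the 1 Hz stimulation rate
        trace = pulse_train_trace()
        spec = np.abs(np.fft.rfft(trace))
        energy = spec[1:] ** 2
        harmonic_energy = sum(spec[b] ** 2 for b in (10, 20, 30, 40, 50))
        assert harmonic_energy / energy.sum() > 0.90


class TestResponseMap:
    def test_equals_pixelwise_scores(self, waveguide_movie, default_protocol):
        movie, _ = waveguide_movie
        rm = response_map(movie, default_protocol)
        sub = extract_window(movie, 21.0, 31.0)
        i, j = 10, 97
        manual = harmonic_response_score(sub.data[:, i, j], 10.0, 1.0)
        assert rm.scores[i, j] == pytest.approx(manual / rm.raw_max_score, rel=1e-12)

    def test_scale_invariance_exact(self, waveguide_movie, default_protocol):
        movie, _ = waveguide_movie
        rm1 = response_map(movie, default_protocol)
        rm2 = response_map(movie.with_data(movie.data * 3.0), default_protocol)
        np.testing.assert_allclose(rm2.scores, rm1.scores, rtol=1e-12)

    def test_normalization_and_range(self, waveguide_movie, default_protocol):
        movie, _ = waveguide_movie
        rm = response_map(movie, default_protocol)
        assert rm.scores.max() == 1.0
        assert rm.scores.min() >= 0.0

    def test_all_zero_movie_yields_zero_map(self, default_protocol):
        movie = OpticalStack(np.zeros((600, 8, 8)), frame_interval_s=0.1)
        rm = response_map(movie, default_protocol)
        assert rm.raw_max_score == 0.0
        assert np.all(rm.scores == 0.0)

    def test_waveguide_mode_recovers_responders(self, default_protocol):
        for seed in range(3):
            movie, truth = generate_calcium_movie(
                demo_layout(seed=seed), default_protocol,
                stimulation_mode="waveguide", noise=NoiseModel(seed=seed),
            )
            rm = response_map(movie, default_protocol)
            responders = truth["responder_mask"]
            assert (rm.scores[responders] > 0.5).all()
            # the 0.5 threshold recovers the ground-truth responder set
            np.testing.assert_array_equal(classify_responders(rm, 0.5), responders)

    def test_full_field_mode_all_cells_respond(self, default_protocol):
        movie, truth = generate_calcium_movie(
            demo_layout(seed=1), default_protocol,
            stimulation_mode="full_field", noise=NoiseModel(seed=1),
        )
        rm = response_map(movie, default_protocol)
        assert (rm.scores[truth["cell_mask"]] > 0.5).all()

    def test_pure_noise_map_matches_permutation_null(self, default_protocol):
        # with zero transient amplitude the responder count at threshold 0.5
        # behaves like the null obtained by permuting the frame order
        movie, truth = generate_calcium_movie(
            demo_layout(seed=2), default_protocol,
            transient_amplitude_frac=0.0, stimulation_mode="waveguide",
            noise=NoiseModel(seed=2),
        )
        rm = response_map(movie, default_protocol)
        assert rm.scores.max() == 1.0  # by construction
        n_hits = int(classify_responders(rm, 0.5).sum())
        rng = np.random.default_rng(0)
        perm = movie.with_data(movie.data[rng.permutation(movie.n_frames)])
        rm_null = response_map(perm, default_protocol)
        n_null = int(classify_responders(rm_null, 0.5).sum())
        # both are small false-positive counts of the same null
        assert n_hits <= max(10, 5 * max(n_null, 1))


class TestRoiAverageTrace:
    def test_single_pixel_mask_returns_that_trace(self, waveguide_movie):
        movie, _ = waveguide_movie
        mask = np.zeros(movie.frame_shape, bool)
        mask[5, 7] = True
        np.testing.assert_array_equal(
            roi_average_trace(movie, mask), movie.data[:, 5, 7]
        )

    def test_responder_roi_shows_ten_pulse_peaks(self, waveguide_movie, default_protocol):
        movie, truth = waveguide_movie
        trace = roi_average_trace(movie, truth["responder_mask"])
        t = movie.times_s
        background = trace[t < 20.0]
        thresh = background.mean() + 3 * background.std()
        for t_i in default_protocol.pulse_times_s:
            window = (t > t_i) & (t <= t_i + 0.3)
            assert trace[window].max() > thresh

    def test_non_stimulated_roi_is_flat(self, waveguide_movie):
        movie, truth = waveguide_movie
        silent = truth["cell_mask"] & ~truth["responder_mask"]
        trace = roi_average_trace(movie, silent)
        t = movie.times_s
        background = trace[t < 20.0]
        thresh = background.mean() + 3 * background.std()
        assert trace[(t >= 20.0) & (t < 31.0)].max() <= thresh

    def test_empty_mask_rejected(self, waveguide_movie):
        movie, _ = waveguide_movie
        with pytest.raises(ValidationError):
            roi_average_trace(movie, np.zeros(movie.frame_shape, bool))
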