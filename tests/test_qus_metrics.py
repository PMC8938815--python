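"""Peak density, MPVD and spectral features against brute-force enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from marginqus.oracles import SynthSpectrum, SynthSpectrumSpec, synth_spectrum
from marginqus.qus_metrics import (
    find_extrema,
    mpvd,
    peak_density,
    spectral_features,
    summarize,
)


def brute_force_extrema(v):
    """Independent O(n^2)-style rescan with the same plateau rule: a run of
    equal values is one extremum at its midpoint when both run neighbours lie
    on the same side; endpoints excluded."""
    v = list(v)
    n = len(v)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if i > 0 and j < n - 1:
            if v[i - 1] < v[i] and v[j + 1] < v[i]:
                out.append(((i + j) // 2, "peak"))
            elif v[i - 1] > v[i] and v[j + 1] > v[i]:
                out.append(((i + j) // 2, "valley"))
        i = j + 1
    return out


def _spec(values):
    values = np.asarray(values, dtype=float)
    return SynthSpectrum(
        frequencies=np.arange(len(values), dtype=float) + 1.0,
        front_abs=values,
        back_abs=values,
    )


class TestFindExtrema:
    def test_worked_example(self):
        ex = find_extrema([1, 3, 1, 3, 1])
        assert ex.indices == (1, 2, 3)
        assert ex.kinds == ("peak", "valley", "peak")

    def test_monotone_sequence_has_no_extrema(self):
        assert len(find_extrema(np.linspace(0, 1, 50))) == 0
        assert len(find_extrema(np.linspace(1, 0, 50))) == 0

    def test_plateau_collapses_to_midpoint(self):
        #       0  1  2  3  4  5  6
        v = [0, 5, 5, 5, 0, 9, 0]
        ex = find_extrema(v)
        assert ex.indices == (2, 4, 5)
        assert ex.kinds == ("peak", "valley", "peak")

    def test_endpoint_runs_are_never_extrema(self):
        assert len(find_extrema([7, 7, 1, 1])) == 0

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            find_extrema([1, 2])

    def test_matches_brute_force_on_1000_seeded_spectra(self):
        rng = np.random.default_rng(20220301)
        for _ in range(1000):
            n = int(rng.integers(3, 120))
            if rng.random() < 0.3:
                v = rng.integers(0, 4, size=n).astype(float)  # many plateaus
            else:
                v = rng.standard_normal(n)
            ex = find_extrema(v)
            ref = brute_force_extrema(v)
            assert list(zip(ex.indices, ex.kinds)) == ref

    @given(st.lists(st.integers(min_value=0, max_value=5), min_size=3, max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_peaks_and_valleys_alternate(self, vals):
        ex = find_extrema(vals)
        for a, b in zip(ex.kinds, ex.kinds[1:]):
            assert a != b


class TestPeakDensity:
    def test_worked_example(self):
        assert peak_density(_spec([1, 3, 1, 3, 1]), "pulse_echo") == 3

    def test_sampled_sinusoid_count_matches_brute_force(self):
        spec = synth_spectrum(SynthSpectrumSpec(kind="sinusoid", length=190, periods=10))
        n_ref = len(brute_force_extrema(spec.back_abs))
        assert peak_density(spec, "pitch_catch") == n_ref
        # 10 full periods sampled well above Nyquist: ~2 extrema per period
        assert n_ref in (19, 20)

    def test_invariant_under_positive_rescaling(self):
        spec = synth_spectrum(SynthSpectrumSpec(kind="random_walk", seed=7))
        scaled = _spec(np.asarray(spec.front_abs) * 137.5)
        assert peak_density(spec, "pulse_echo") == peak_density(scaled, "pulse_echo")

    def test_invariant_under_monotone_transform(self):
        spec = synth_spectrum(SynthSpectrumSpec(kind="random_walk", seed=3))
        assert peak_density(_spec(np.exp(spec.front_abs)), "pulse_echo") == \
            peak_density(spec, "pulse_echo")

    def test_mode_selects_channel(self):
        s = SynthSpectrum(
            frequencies=np.arange(5.0),
            front_abs=np.array([1, 3, 1, 3, 1.0]),
            back_abs=np.array([1, 2, 3, 4, 5.0]),
        )
        assert peak_density(s, "pulse_echo") == 3
        assert peak_density(s, "pitch_catch") == 0


class TestMPVD:
    def test_worked_example(self):
        assert mpvd(_spec([1, 3, 1, 3, 1]), "pulse_echo") == pytest.approx(2.0)

    def test_scales_linearly_with_magnitude(self):
        spec = synth_spectrum(SynthSpectrumSpec(kind="random_walk", seed=11))
        a = mpvd(spec, "pitch_catch")
        b = mpvd(_spec(3.5 * np.asarray(spec.back_abs)), "pitch_catch")
        assert b == pytest.approx(3.5 * a, rel=1e-12)

    def test_undefined_with_fewer_than_two_extrema_raises(self):
        with pytest.raises(ValueError, match="MPVD undefined"):
            mpvd(_spec(np.linspace(0, 1, 20)), "pulse_echo")

    def test_matches_brute_force_adjacent_pair_average_on_seeded_spectra(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(1000):
            v = rng.standard_normal(int(rng.integers(5, 150))) ** 2
            ref = brute_force_extrema(v)
            if len(ref) < 2:
                continue
            mags = [v[i] for i, _ in ref]
            expected = np.mean(np.abs(np.diff(mags)))
            assert mpvd(_spec(v), "pulse_echo") == pytest.approx(expected, rel=1e-12)
            checked += 1
        assert checked > 900


class TestSpectralFeatures:
    def test_constant_spectrum(self):
        r = spectral_features(_spec(np.full(30, 2.5)), "pulse_echo")
        assert r.jaggedness == 0.0
        assert r.peak_frequency == 1.0  # first grid point on ties
        assert r.peak_density == 0
        assert r.mpvd is None

    def test_single_lobe_peak_at_center(self):
        f = np.linspace(-1, 1, 51)
        v = np.exp(-(f**2) / 0.1)
        s = SynthSpectrum(frequencies=np.arange(51.0), front_abs=v, back_abs=v)
        r = spectral_features(s, "pitch_catch")
        assert r.peak_frequency == 25.0
        assert r.peak_magnitude == pytest.approx(1.0)

    def test_features_equal_direct_recomputation_on_seeded_channel(self):
        spec = synth_spectrum(SynthSpectrumSpec(kind="random_walk", seed=5))
        v = np.asarray(spec.back_abs)
        r = spectral_features(spec, "pitch_catch")
        assert r.peak_magnitude == v.max()
        assert r.overall_magnitude == pytest.approx(v.mean(), rel=1e-14)
        assert r.jaggedness == pytest.approx(np.abs(np.diff(v)).mean(), rel=1e-14)
        assert r.peak_frequency == spec.frequencies[np.argmax(v)]


class TestSummarize:
    def _result(self, v):
        return spectral_features(_spec(v), "pulse_echo")

    def test_identical_inputs_give_zero_sd(self):
        r = self._result([1, 3, 1, 3, 1])
        s = summarize([r] * 5, "normal", "pulse_echo")
        assert s.n == 5
        assert all(v == 0.0 for v in s.sd.values())

    def test_known_mean_and_sample_sd(self):
        results = [self._result([0, x, 0, x, 0]) for x in (1, 2, 3, 4, 5)]
        s = summarize(results, "normal", "pulse_echo")
        assert s.mean["mpvd"] == pytest.approx(3.0)
        assert s.sd["mpvd"] == pytest.approx(1.5811, rel=1e-4)

    def test_mean_bounded_by_inputs(self):
        rng = np.random.default_rng(1)
        results = [self._result(rng.random(40) + 0.5) for _ in range(5)]
        s = summarize(results, "x", "pitch_catch")
        vals = [r.overall_magnitude for r in results]
        assert min(vals) <= s.mean["overall_magnitude"] <= max(vals)

    def test_single_result_warns_and_reports_zero_sd(self):
        with pytest.warns(UserWarning):
            s = summarize([self._result([1, 3, 1, 3, 1])], "x", "pulse_echo")
        assert s.sd["peak_density"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize([], "x", "pulse_echo")
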