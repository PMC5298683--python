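"""Synthetic wingbeat generator: presets, SNR calibration, spectral structure."""

import dataclasses

import numpy as np
import pytest

import wingtrap as wt
from wingtrap import spectral, synth


class TestPresets:
    @pytest.mark.parametrize(
        "name, f0_range",
        [
            ("B. oleae", (170.0, 230.0)),
            ("Drosophila", (260.0, 310.0)),
            ("mosquito", (350.0, 700.0)),
        ],
    )
    def test_documented_f0_ranges(self, name, f0_range):
        assert wt.make_preset(name).f0_range == f0_range

    def test_overlapping_spectra_species_share_the_target_band(self):
        target = wt.make_preset("B. oleae").f0_range
        for name in ("C. capitata", "L. aristella"):
            lo, hi = wt.make_preset(name).f0_range
            assert lo < target[1] and hi > target[0]

    def test_unknown_species_rejected_with_options(self):
        with pytest.raises(ValueError, match="B. oleae"):
            wt.make_preset("housefly")

    def test_drosophila_modulates_less_light_than_target(self):
        small = wt.make_preset("Drosophila").wing_amplitude_range
        big = wt.make_preset("B. oleae").wing_amplitude_range
        assert small[1] < big[1]

    def test_invalid_preset_parameters_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(wt.make_preset("B. oleae"), harmonic_decay=1.5)
        with pytest.raises(ValueError):
            dataclasses.replace(wt.make_preset("B. oleae"), wing_amplitude_range=(0.0, 0.5))


class TestF0AtTemperature:
    @pytest.mark.parametrize("temp, f0", [(15.0, 170.0), (25.0, 200.0), (35.0, 230.0)])
    def test_linear_map_over_activity_range(self, oleae_preset, temp, f0):
        assert wt.f0_at_temperature(oleae_preset, temp) == pytest.approx(f0)

    @pytest.mark.parametrize("temp", [10.0, 40.0])
    def test_species_inactive_outside_range(self, oleae_preset, temp):
        with pytest.raises(ValueError, match="activity range"):
            wt.f0_at_temperature(oleae_preset, temp)

    def test_jitter_reproducible_under_seeded_rng(self, oleae_preset):
        a = wt.f0_at_temperature(oleae_preset, 25, jitter_hz=3, rng=np.random.default_rng(1))
        b = wt.f0_at_temperature(oleae_preset, 25, jitter_hz=3, rng=np.random.default_rng(1))
        assert a == b != 200.0


class TestSnippet:
    def test_shape_range_and_ground_truth(self, oleae_preset):
        s = wt.synth_snippet(oleae_preset, rng=0)
        assert len(s.samples) == 1024
        assert np.all(np.abs(s.samples) <= 1.0)
        assert 170 <= s.f0_true <= 230
        assert s.clean_rms > 0 and not s.below_floor

    def test_bit_identical_under_fixed_seed(self, oleae_preset):
        a = wt.synth_snippet(oleae_preset, rng=42)
        b = wt.synth_snippet(oleae_preset, rng=42)
        assert np.array_equal(a.samples, b.samples)
        assert a.f0_true == b.f0_true

    @pytest.mark.parametrize("snr", [20.0, 50.0, 70.0])
    def test_snr_calibrated_within_one_db(self, oleae_preset, snr):
        config = wt.GenConfig(snr_db=snr)
        rng = np.random.default_rng(7)
        realised = [
            wt.synth_snippet(oleae_preset, config, rng).snr_db for _ in range(100)
        ]
        assert np.mean(realised) == pytest.approx(snr, abs=1.0)

    def test_partials_land_within_one_psd_bin(self, oleae_preset):
        # Detuning off, fundamental pinned at 200 Hz: each partial's local
        # PSD maximum must fall within one 15.625 Hz bin of k*f0.
        preset = dataclasses.replace(
            oleae_preset, f0_range=(200.0, 200.0), detune_max=0.0
        )
        psd = wt.welch_log_psd(wt.synth_snippet(preset, rng=3).samples)
        for k in range(1, 6):
            target = k * 200.0
            near = np.flatnonzero(np.abs(psd.freqs - target) <= 3 * spectral.BIN_HZ)
            peak = near[np.argmax(psd.power[near])]
            assert abs(psd.freqs[peak] - target) <= spectral.BIN_HZ

    def test_body_component_is_near_dc(self, oleae_preset):
        # Effectively no wingbeat: the remaining body pulse concentrates its
        # PSD energy below 50 Hz.
        walking = dataclasses.replace(oleae_preset, wing_amplitude_range=(1e-6, 1e-6))
        psd = wt.welch_log_psd(wt.synth_snippet(walking, rng=5).samples)
        low = psd.power[psd.freqs <= 50].sum()
        assert low / psd.power.sum() > 0.99

    def test_below_floor_flagged_not_failed(self, oleae_preset):
        s = wt.synth_snippet(
            dataclasses.replace(oleae_preset, wing_amplitude_range=(1e-5, 1e-5),
                                body_amplitude_range=(1e-5, 1e-5)),
            rng=1,
        )
        assert s.below_floor


class TestStream:
    def test_empty_event_list_is_pure_noise(self):
        stream, truth = wt.synth_stream([], 10.0, wt.GenConfig(seed=1))
        assert len(stream) == 40_000
        assert truth.empty
        assert np.sqrt(np.mean(stream**2)) == pytest.approx(10 ** (-75 / 20), rel=0.05)

    def test_onset_index_is_fs_times_time(self, oleae_preset):
        _, truth = wt.synth_stream([(1.0, oleae_preset)], 3.0, wt.GenConfig(seed=1))
        assert list(truth.onset_index) == [4000]
        assert list(truth.label) == ["B. oleae"]

    def test_overlapping_transits_rejected(self, oleae_preset):
        with pytest.raises(ValueError, match="overlap"):
            wt.synth_stream(
                [(1.0, oleae_preset), (1.01, oleae_preset)], 3.0, wt.GenConfig(seed=1)
            )

    def test_onset_outside_duration_rejected(self, oleae_preset):
        with pytest.raises(ValueError):
            wt.synth_stream([(5.0, oleae_preset)], 3.0, wt.GenConfig(seed=1))


class TestCorpus:
    def test_default_composition(self):
        spec = wt.CorpusSpec()
        assert spec.composition["B. oleae"] == 913
        assert sum(spec.composition.values()) == 2473

    def test_counts_and_binary_labels(self):
        spec = wt.CorpusSpec(composition={"B. oleae": 5, "mosquito": 3}, seed=2)
        corpus = wt.synth_corpus(spec)
        assert len(corpus) == 8
        assert corpus.labels.sum() == 5  # only the target species is tagged 1
        assert [s.label for s in corpus.snippets[:5]] == ["B. oleae"] * 5

    def test_empty_composition_gives_empty_corpus(self):
        corpus = wt.synth_corpus(wt.CorpusSpec(composition={"B. oleae": 0}))
        assert len(corpus) == 0

    def test_bit_identical_under_fixed_seed(self):
        spec = wt.CorpusSpec(composition={"B. oleae": 4, "Drosophila": 4}, seed=9)
        a, b = wt.synth_corpus(spec), wt.synth_corpus(spec)
        for sa, sb in zip(a.snippets, b.snippets):
            assert np.array_equal(sa.samples, sb.samples)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            wt.CorpusSpec(composition={"B. oleae": -1})

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            wt.CorpusSpec(composition={"unicorn": 3})
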