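"""Synthetic ECG generator: beat rendering, records, cohorts, on-disk output."""

import numpy as np
import pytest

from ecgcascade import io as ecg_io
from ecgcascade.core import CLASS_SYMBOLS
from ecgcascade.errors import CapacityError, ParameterError
from ecgcascade.synth import (
    BeatMorphology,
    CohortConfig,
    Wave,
    default_templates,
    episode_class_sequence,
    generate_cohort,
    generate_record,
    nearest_template_symbol,
    perturb_templates,
    render_beat,
    write_cohort,
)


def half_max_width(samples: np.ndarray, fs: float) -> float:
    """QRS width via threshold crossing at half the R amplitude."""
    above = samples >= samples.max() / 2
    peak = int(np.argmax(samples))
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(samples) - 1 and above[hi + 1]:
        hi += 1
    return (hi - lo + 1) / fs


class TestRenderBeat:
    def test_all_zero_amplitudes_render_to_zero(self):
        waves = {n: Wave(0.0, 0.02, off) for n, off in
                 [("P", -0.18), ("Q", -0.05), ("R", 0.0), ("S", 0.04), ("T", 0.25)]}
        beat = render_beat(BeatMorphology("N", waves), fs=360)
        assert np.all(beat.samples == 0.0)

    @pytest.mark.parametrize("symbol", CLASS_SYMBOLS)
    def test_global_max_at_r_offset(self, symbol):
        # oracle: argmax of the analytic Gaussian sum on a 10x finer grid
        morph = default_templates()[symbol]
        fs = 360
        beat = render_beat(morph, fs)
        fine = np.arange(-0.4, 0.5, 1 / (10 * fs))
        y = sum(w.amplitude * np.exp(-0.5 * ((fine - w.offset) / w.width) ** 2)
                for w in morph.waves.values())
        t_peak = fine[np.argmax(y)]
        expected_index = beat.r_index + t_peak * fs
        assert abs(int(np.argmax(beat.samples)) - expected_index) <= 2

    def test_pvc_qrs_wider_than_normal(self):
        templates = default_templates()
        w_n = half_max_width(render_beat(templates["N"], 360).samples, 360)
        w_pvc = half_max_width(render_beat(templates["PVC"], 360).samples, 360)
        assert w_pvc > w_n

    def test_nonpositive_fs_rejected(self):
        with pytest.raises(ParameterError):
            render_beat(default_templates()["N"], fs=0)


class TestGenerateRecord:
    def test_annotation_count_and_symbols(self):
        config = CohortConfig(n_subjects=1, duration_s=30, seed=0)
        _, anns = generate_record("s", config, ["N"] * 10, np.random.default_rng(0))
        assert len(anns) == 10
        assert all(a.symbol == "N" for a in anns)

    def test_zero_noise_single_beat_is_padded_template(self):
        config = CohortConfig(
            n_subjects=1, duration_s=10, seed=0,
            powerline_amp_mv=0.0, baseline_amp_mv=0.0, white_noise_mv=0.0,
        )
        record, anns = generate_record("s", config, ["N"], np.random.default_rng(3))
        beat = render_beat(default_templates()["N"], config.fs)
        r = anns[0].sample_index
        start = r - beat.r_index
        np.testing.assert_array_equal(
            record.signal[start : start + len(beat.samples)], beat.samples
        )
        rest = np.delete(record.signal, np.arange(start, start + len(beat.samples)))
        assert np.all(rest == 0.0)

    def test_fixed_seed_is_bit_identical(self):
        config = CohortConfig(n_subjects=1, duration_s=30, seed=0)
        a, _ = generate_record("s", config, ["N", "PVC"] * 5, np.random.default_rng(7))
        b, _ = generate_record("s", config, ["N", "PVC"] * 5, np.random.default_rng(7))
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_too_many_beats_raise_capacity_error(self):
        config = CohortConfig(n_subjects=1, duration_s=10, seed=0)
        with pytest.raises(CapacityError):
            generate_record("s", config, ["N"] * 50, np.random.default_rng(0))


class TestGenerateCohort:
    def test_same_seed_same_cohort(self):
        config = CohortConfig(n_subjects=2, duration_s=20, seed=5)
        a = generate_cohort(config)
        b = generate_cohort(config)
        for (ra, aa), (rb, ab) in zip(a, b):
            np.testing.assert_array_equal(ra.signal, rb.signal)
            assert aa == ab

    def test_degenerate_prevalence_yields_single_class(self):
        config = CohortConfig(
            n_subjects=5, duration_s=20, seed=1,
            prevalence={"N": 1.0, "PVC": 0.0, "LBBB": 0.0, "RBBB": 0.0},
        )
        for _, anns in generate_cohort(config):
            assert all(a.symbol == "N" for a in anns)

    def test_pooled_prevalence_close_to_configured(self):
        config = CohortConfig(n_subjects=20, duration_s=180, seed=9)
        symbols = [a.symbol for _, anns in generate_cohort(config) for a in anns]
        assert len(symbols) >= 20 * 200
        for sym in CLASS_SYMBOLS:
            realized = symbols.count(sym) / len(symbols)
            assert abs(realized - config.prevalence[sym]) < 0.05

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ParameterError):
            CohortConfig(prevalence={"N": 0.5, "PVC": 0.2, "LBBB": 0.2, "RBBB": 0.2})

    def test_episode_sequence_quota_exact(self):
        probs = np.array([0.55, 0.15, 0.15, 0.15])
        seq = episode_class_sequence(200, probs, np.random.default_rng(0))
        counts = {s: seq.count(s) for s in CLASS_SYMBOLS}
        assert sum(counts.values()) == 200
        for sym, p in zip(CLASS_SYMBOLS, probs):
            assert abs(counts[sym] - 200 * p) <= 1


class TestClassSeparability:
    def test_nearest_template_recovers_class_under_subject_jitter(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            perturbed = perturb_templates(default_templates(), rng, scale=0.10)
            for sym, morph in perturbed.items():
                beat = render_beat(morph, 360)
                assert nearest_template_symbol(beat.samples, beat.r_index, 360) == sym

    def test_annotations_sit_on_local_maxima(self, mini_cohort_config):
        config = CohortConfig(
            n_subjects=2, duration_s=30, seed=2,
            powerline_amp_mv=0.0, baseline_amp_mv=0.0, white_noise_mv=0.0,
        )
        for record, anns in generate_cohort(config):
            for a in anns:
                lo, hi = a.sample_index - 5, a.sample_index + 6
                local_peak = lo + int(np.argmax(record.signal[lo:hi]))
                assert abs(local_peak - a.sample_index) <= 2


class TestWriteCohort:
    def test_round_trip_preserves_annotations_and_signal(self, tmp_path, mini_cohort):
        write_cohort(mini_cohort, tmp_path)
        for record, anns in mini_cohort:
            back = ecg_io.read_record(tmp_path / f"{record.record_id}.csv")
            np.testing.assert_array_equal(back.signal, record.signal)
            back_anns = ecg_io.read_annotations(tmp_path / f"{record.record_id}.ann.csv")
            assert [a.sample_index for a in back_anns] == [a.sample_index for a in anns]

    def test_empty_cohort_creates_empty_directory(self, tmp_path):
        out = tmp_path / "empty"
        write_cohort([], out)
        assert out.is_dir() and not list(out.iterdir())

    def test_csv_sample_count_matches_duration(self, tmp_path):
        config = CohortConfig(n_subjects=1, duration_s=30, seed=0)
        write_cohort(generate_cohort(config), tmp_path)
        lines = (tmp_path / "S00.csv").read_text().splitlines()
        assert len(lines) - 1 == 30 * 360
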