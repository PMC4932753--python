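"""Fourier time-normalization, binning, difficulty collapse, imputation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilpath.errors import ValidationError
from pupilpath.tables import CellTable, build_cell_table, impute_condition_means
from pupilpath.tonic import (
    baseline_first_second,
    collapse_difficulty,
    fourier_resample,
    tonic_bins,
)


class TestFourierResample:
    def test_constant_signal_preserved(self):
        for n_in, n_out in [(7, 500), (500, 7), (120, 360)]:
            out = fourier_resample(np.full(n_in, 13.3), n_out)
            np.testing.assert_allclose(out, 13.3, atol=1e-12)

    def test_identity_when_lengths_match(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=137)
        np.testing.assert_allclose(fourier_resample(x, 137), x, atol=1e-9)

    def test_bandlimited_sinusoid_exact(self):
        k_in = np.arange(120)
        x = np.cos(2 * np.pi * 3 * k_in / 120)
        out = fourier_resample(x, 500)
        k_out = np.arange(500)
        expected = np.cos(2 * np.pi * 3 * k_out / 500)
        assert np.abs(out - expected).max() < 1e-6

    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 60),
           st.integers(2, 60))
    @settings(max_examples=60, deadline=None)
    def test_mean_preserved_for_any_lengths(self, seed, n_in, n_out):
        rng = np.random.default_rng(seed)
        x = rng.normal(13.0, 1.0, size=n_in)
        out = fourier_resample(x, n_out)
        assert out.mean() == pytest.approx(x.mean(), abs=1e-9)

    def test_energy_at_retained_frequencies_conserved_when_lengthening(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=121)  # odd length: no Nyquist split
        n_out = 500
        out = fourier_resample(x, n_out)
        X = np.fft.fft(x) / len(x)
        Y = np.fft.fft(out) / n_out
        h = len(x) // 2
        np.testing.assert_allclose(np.abs(Y[:h + 1]), np.abs(X[:h + 1]),
                                   atol=1e-9)

    def test_matches_scipy_resample(self):
        from scipy.signal import resample
        rng = np.random.default_rng(3)
        for n_in, n_out in [(120, 500), (3600, 500), (13, 8), (12, 9)]:
            x = rng.normal(size=n_in)
            np.testing.assert_allclose(fourier_resample(x, n_out),
                                       resample(x, n_out), atol=1e-9)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValidationError):
            fourier_resample(np.array([1.0, np.nan, 2.0]), 10)


class TestTonicBins:
    def test_constant(self):
        np.testing.assert_allclose(tonic_bins(np.full(500, 13.3)),
                                   np.full(10, 13.3))

    def test_index_ramp_block_means(self):
        bins = tonic_bins(np.arange(500, dtype=float))
        np.testing.assert_allclose(bins, 24.5 + 50.0 * np.arange(10))

    def test_monotone_input_gives_monotone_bins(self):
        bins = tonic_bins(np.linspace(13.0, 14.0, 500))
        assert np.all(np.diff(bins) > 0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            tonic_bins(np.zeros(499))


class TestCollapseDifficulty:
    @pytest.mark.parametrize("rating, condition", [
        (1, "A"), (2, "A"), (3, "B"), (4, "C"), (5, "D"), (6, "D"),
    ])
    def test_mapping(self, rating, condition):
        assert collapse_difficulty(rating) == condition

    @pytest.mark.parametrize("rating", [0, 7, 2.5, "3"])
    def test_out_of_domain_rejected(self, rating):
        with pytest.raises(ValidationError):
            collapse_difficulty(rating)


class TestImputation:
    def grid(self):
        values = np.full((3, 4, 10), np.nan)
        for i in range(3):
            for j in range(4):
                values[i, j] = 13.0 + 0.2 * j + 0.01 * i
        return values

    def test_complete_table_unchanged(self):
        t = CellTable(["P1", "P2", "P3"], list("ABCD"), self.grid(),
                      np.zeros((3, 4, 10), bool))
        out = impute_condition_means(t)
        np.testing.assert_array_equal(out.values, t.values)
        assert not out.imputed_mask.any()

    def test_missing_cell_gets_condition_mean(self):
        values = self.grid()
        values[0, 3, :] = np.nan
        values[1, 3, 0] = 13.8
        values[2, 3, 0] = 14.0
        t = CellTable(["P1", "P2", "P3"], list("ABCD"), values,
                      np.zeros((3, 4, 10), bool))
        out = impute_condition_means(t)
        assert out.values[0, 3, 0] == pytest.approx(13.9)
        assert out.imputed_mask[0, 3].all()
        assert not out.imputed_mask[1:].any()

    def test_grand_mean_preserved_per_condition_bin(self):
        values = self.grid()
        values[2, 1, :] = np.nan
        t = CellTable(["P1", "P2", "P3"], list("ABCD"), values,
                      np.zeros((3, 4, 10), bool))
        observed = np.nanmean(values[:, 1, :], axis=0)
        out = impute_condition_means(t)
        np.testing.assert_allclose(out.values[:, 1, :].mean(axis=0), observed)

    def test_empty_condition_is_unrecoverable(self):
        values = self.grid()
        values[:, 2, :] = np.nan
        t = CellTable(["P1", "P2", "P3"], list("ABCD"), values,
                      np.zeros((3, 4, 10), bool))
        with pytest.raises(ValidationError):
            impute_condition_means(t)

    def test_build_cell_table_averages_trials(self):
        records = [
            ("P1", "A", np.full(10, 13.0)),
            ("P1", "A", np.full(10, 14.0)),
            ("P2", "B", np.full(10, 12.0)),
        ]
        t = build_cell_table(records, list("ABCD"))
        np.testing.assert_allclose(t.values[0, 0], 13.5)
        np.testing.assert_allclose(t.values[1, 1], 12.0)
        assert np.isnan(t.values[0, 1]).all()


class TestBaseline:
    def test_constant_first_second(self, clean_factory):
        clean = clean_factory(np.full(100, 13.0))
        assert baseline_first_second(clean) == pytest.approx(13.0)

    def test_two_level_average(self, clean_factory):
        d = np.concatenate([np.full(30, 12.0), np.full(70, 14.0)])
        assert baseline_first_second(clean_factory(d)) == pytest.approx(13.0)

    def test_short_recording_rejected(self, clean_factory):
        with pytest.raises(ValidationError):
            baseline_first_second(clean_factory(np.full(59, 13.0)))
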