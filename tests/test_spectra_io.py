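"""Data model validation, file round trips, replicate averaging, extraction."""

import numpy as np
import pandas as pd
import pytest

from fluorobind import (
    EmissionSpectrum,
    TitrationSeries,
    average_replicates,
    extract_intensities,
    read_titration,
    write_titration,
)

GRID = np.arange(320.0, 461.0)


def _spectrum(conc, rep=1, amp=100.0, grid=GRID, center=348.0, exc=280.0, temp=298.0):
    return EmissionSpectrum(
        excitation_wavelength=exc,
        temperature=temp,
        quencher_concentration=conc,
        replicate_id=rep,
        wavelengths=grid,
        intensities=amp * np.exp(-((grid - center) ** 2) / (2 * 25.0**2)),
    )


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"wavelengths": [340, 330, 350], "intensities": [1, 2, 3]},  # non-monotone
            {"wavelengths": [330, 340], "intensities": [1, -2]},  # negative intensity
            {"wavelengths": [330, 340], "intensities": [1, np.inf]},  # non-finite
            {"wavelengths": [330, 340], "intensities": [1, 2, 3]},  # length mismatch
            {"temperature": 0.0},  # nonpositive temperature
            {"quencher_concentration": -1e-6},  # negative concentration
        ],
    )
    def test_bad_spectrum_rejected(self, kwargs):
        base = dict(
            excitation_wavelength=280.0,
            temperature=298.0,
            quencher_concentration=0.0,
            replicate_id=1,
            wavelengths=[330.0, 340.0],
            intensities=[1.0, 2.0],
        )
        with pytest.raises(ValueError):
            EmissionSpectrum(**{**base, **kwargs})

    def test_series_needs_zero_reference_and_two_nonzero(self):
        with pytest.raises(ValueError, match="zero-quencher"):
            TitrationSeries(20e-6, 280.0, 298.0, [_spectrum(c) for c in (1e-6, 2e-6)])
        with pytest.raises(ValueError, match="nonzero"):
            TitrationSeries(20e-6, 280.0, 298.0, [_spectrum(0.0), _spectrum(1e-6)])

    def test_series_rejects_mixed_grids_and_empty(self):
        off_grid = _spectrum(2e-6)
        off_grid = EmissionSpectrum(
            280.0, 298.0, 2e-6, 1, GRID + 0.5, off_grid.intensities
        )
        with pytest.raises(ValueError, match="grid"):
            TitrationSeries(
                20e-6, 280.0, 298.0, [_spectrum(0.0), _spectrum(1e-6), off_grid]
            )
        with pytest.raises(ValueError):
            TitrationSeries(20e-6, 280.0, 298.0, [])


class TestFileRoundTrip:
    def test_round_trip_is_lossless(self, tmp_path, noiseless_dynamic_series):
        path = tmp_path / "titration.csv"
        write_titration(noiseless_dynamic_series, path)
        assert read_titration(path) == noiseless_dynamic_series

    def test_replicate_ids_survive_round_trip(self, tmp_path, noisy_series):
        path = tmp_path / "titration.csv"
        write_titration(noisy_series, path)
        back = read_titration(path)
        assert sorted(sp.replicate_id for sp in back.spectra) == sorted(
            sp.replicate_id for sp in noisy_series.spectra
        )
        assert back == noisy_series

    def test_paper_design_file_has_eight_concentration_groups(
        self, tmp_path, noiseless_dynamic_series
    ):
        path = tmp_path / "titration.csv"
        write_titration(noiseless_dynamic_series, path)
        series = read_titration(path)
        assert series.concentrations.size == 8
        np.testing.assert_allclose(
            series.concentrations,
            np.array([0, 20, 40, 80, 120, 160, 240, 320]) * 1e-6,
        )

    def test_micromolar_unit_column_converted(self, tmp_path):
        rows = []
        for conc_um in (0.0, 20.0, 40.0):
            for nm in (330.0, 340.0, 350.0):
                rows.append((280.0, 298.0, conc_um, "uM", 1, nm, 100.0))
        df = pd.DataFrame(
            rows,
            columns=[
                "excitation_nm",
                "temperature_K",
                "quencher_conc",
                "conc_unit",
                "replicate",
                "emission_nm",
                "intensity",
            ],
        )
        path = tmp_path / "um.csv"
        df.to_csv(path, index=False)
        series = read_titration(path)
        np.testing.assert_allclose(series.concentrations, [0.0, 20e-6, 40e-6])

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"emission_nm": [330.0], "intensity": [1.0]}).to_csv(
            path, index=False
        )
        with pytest.raises(KeyError, match="quencher_conc"):
            read_titration(path)

    def test_zero_only_file_fails_validation(self, tmp_path):
        rows = [(280.0, 298.0, 0.0, "M", 1, nm, 50.0) for nm in (330.0, 340.0)]
        path = tmp_path / "zero_only.csv"
        pd.DataFrame(
            rows,
            columns=[
                "excitation_nm",
                "temperature_K",
                "quencher_conc",
                "conc_unit",
                "replicate",
                "emission_nm",
                "intensity",
            ],
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="nonzero"):
            read_titration(path)


class TestAverageReplicates:
    def test_mean_of_identical_replicates_is_unchanged(self):
        reps = [_spectrum(c, rep=r) for c in (0.0, 1e-6, 2e-6) for r in (1, 2, 3)]
        series = TitrationSeries(20e-6, 280.0, 298.0, reps)
        avg = average_replicates(series)
        assert len(avg.spectra) == 3
        for sp in avg.spectra:
            np.testing.assert_allclose(
                sp.intensities,
                series.spectra_at(sp.quencher_concentration)[0].intensities,
                rtol=1e-15,
            )

    def test_pointwise_arithmetic_mean(self):
        grid = np.array([330.0, 340.0])
        spectra = [_spectrum(0.0)]
        for c in (1e-6, 2e-6):
            for r, val in ((1, 90.0), (2, 100.0), (3, 110.0)):
                spectra.append(
                    EmissionSpectrum(280.0, 298.0, c, r, grid, [val, val])
                )
        spectra[0] = EmissionSpectrum(280.0, 298.0, 0.0, 1, grid, [100.0, 100.0])
        series = TitrationSeries(20e-6, 280.0, 298.0, spectra)
        avg = average_replicates(series)
        for c in (1e-6, 2e-6):
            np.testing.assert_array_equal(
                avg.spectra_at(c)[0].intensities, [100.0, 100.0]
            )

    def test_matches_bruteforce_sum_over_n(self, noisy_series):
        avg = average_replicates(noisy_series)
        for conc in noisy_series.concentrations:
            reps = noisy_series.spectra_at(conc)
            brute = sum(sp.intensities for sp in reps) / len(reps)
            np.testing.assert_allclose(avg.spectra_at(conc)[0].intensities, brute)

    def test_idempotent(self, noisy_series):
        once = average_replicates(noisy_series)
        assert average_replicates(once) == once

    def test_mismatched_replicate_grids_rejected(self):
        a = _spectrum(1e-6, rep=1)
        b = EmissionSpectrum(280.0, 298.0, 1e-6, 2, GRID, a.intensities)
        series = TitrationSeries(
            20e-6, 280.0, 298.0, [_spectrum(0.0), a, b, _spectrum(2e-6)]
        )
        # corrupt one replicate's grid after construction
        b.wavelengths = GRID.copy()
        b.wavelengths[0] -= 0.5
        with pytest.raises(ValueError, match="mismatched grids"):
            average_replicates(series)


class TestExtractIntensities:
    def test_peak_max_recovers_band_amplitude(self):
        amps = {0.0: 200.0, 1e-6: 150.0, 2e-6: 100.0}
        series = TitrationSeries(
            20e-6, 280.0, 298.0, [_spectrum(c, amp=a) for c, a in amps.items()]
        )
        table = extract_intensities(series)
        assert table.f0 == 200.0
        np.testing.assert_array_equal(table.f_values, [150.0, 100.0])
        assert table.extraction_method == "peak-max"

    def test_fixed_wavelength_at_band_center_equals_peak_max(self):
        series = TitrationSeries(
            20e-6,
            280.0,
            298.0,
            [_spectrum(c, amp=a) for c, a in ((0.0, 90.0), (1e-6, 60.0), (2e-6, 30.0))],
        )
        peak = extract_intensities(series, method="peak-max")
        fixed = extract_intensities(
            series, method="fixed-wavelength", fixed_wavelength=348.0
        )
        np.testing.assert_allclose(fixed.f_values, peak.f_values)
        assert fixed.f0 == peak.f0

    def test_pure_quenching_gives_strictly_decreasing_intensities(
        self, noiseless_dynamic_series
    ):
        table = extract_intensities(average_replicates(noiseless_dynamic_series))
        assert np.all(np.diff(table.f_values) < 0)

    def test_invariant_to_wavelengths_outside_window(self):
        wide = np.arange(300.0, 481.0)
        spectra_wide = [
            _spectrum(c, amp=a, grid=wide)
            for c, a in ((0.0, 80.0), (1e-6, 50.0), (2e-6, 20.0))
        ]
        spectra_narrow = [
            _spectrum(c, amp=a)
            for c, a in ((0.0, 80.0), (1e-6, 50.0), (2e-6, 20.0))
        ]
        wide_tab = extract_intensities(
            TitrationSeries(20e-6, 280.0, 298.0, spectra_wide), window=(320, 460)
        )
        narrow_tab = extract_intensities(
            TitrationSeries(20e-6, 280.0, 298.0, spectra_narrow), window=(320, 460)
        )
        np.testing.assert_allclose(wide_tab.f_values, narrow_tab.f_values)
        np.testing.assert_allclose(wide_tab.f0, narrow_tab.f0)

    def test_unaveraged_series_rejected(self, noisy_series):
        with pytest.raises(ValueError, match="average_replicates"):
            extract_intensities(noisy_series)

    def test_off_grid_fixed_wavelength_rejected(self, noiseless_dynamic_series):
        avg = average_replicates(noiseless_dynamic_series)
        with pytest.raises(ValueError, match="not on the grid"):
            extract_intensities(avg, method="fixed-wavelength", fixed_wavelength=348.5)
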