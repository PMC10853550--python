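"""Feature extraction: Legendre/local decompositions, preconditions,
pooled biomarkers."""

import numpy as np
import pandas as pd
import pytest

from biodyn.features import (
    BIOMARKER_NAMES,
    FEATURE_NAMES,
    PoolingMap,
    assemble_feature_vector,
    baseline_features,
    data_quality,
    default_pooling_map,
    extract_features,
    fit_zscores,
    global_legendre_features,
    local_band_features,
    pool_features,
    precondition_deltas,
    precondition_features,
)
from biodyn.speckle import synthesize_intensity_stack
from biodyn.spectral import SpectralModel
from biodyn.spectroscopy import PowerSpectrum, Spectrogram, WellSpectrumSeries
from biodyn.trial import ResponseArchetype, simulate_well


def _sg(D, n_pre=4):
    nf, nl = D.shape
    freqs = np.geomspace(0.0125, 12.5, nf)
    times = (np.arange(nl) - n_pre) * 2 / 3
    return Spectrogram(
        freqs=freqs, loop_times=times, D=D, baseline=np.ones(nf), treatment_loop=n_pre
    )


def _xy(sg):
    lf = sg.log_freqs
    x = 2 * (lf - lf[0]) / (lf[-1] - lf[0]) - 1
    t = sg.loop_times[sg.treatment_loop :]
    y = 2 * (t - t[0]) / (t[-1] - t[0]) - 1
    return x, y


def _trapz_mean(values, x):
    # independent weighted-mean oracle on a non-uniform grid
    return np.trapezoid(values, x) / (x[-1] - x[0])


class TestGlobalFeatures:
    def test_constant_field_isolates_g00(self):
        D = np.full((30, 16), 0.37)
        g = global_legendre_features(_sg(D))
        assert g["g00"] == pytest.approx(0.37, abs=1e-12)
        off = g.drop("g00")
        assert np.abs(off.to_numpy()).max() < 1e-10

    def test_pure_frequency_ramp_gives_x_variance(self):
        sg = _sg(np.zeros((30, 16)))
        x, _ = _xy(sg)
        sg.D[:, sg.treatment_loop :] = x[:, None]
        g = global_legendre_features(sg)
        assert g["g10"] == pytest.approx(_trapz_mean(x * x, x), rel=1e-9)
        assert abs(g["g00"]) < 1e-12

    def test_time_ramp_gives_y_variance(self):
        sg = _sg(np.zeros((30, 16)))
        _, y = _xy(sg)
        a = 0.21
        sg.D[:, sg.treatment_loop :] = a * y[None, :]
        g = global_legendre_features(sg)
        assert g["g01"] == pytest.approx(a * _trapz_mean(y * y, y), rel=1e-9)
        assert abs(g["g00"]) < 1e-12

    def test_separable_product_isolates_g11(self):
        sg = _sg(np.zeros((30, 16)))
        x, y = _xy(sg)
        sg.D[:, sg.treatment_loop :] = np.outer(x, y)
        g = global_legendre_features(sg)
        expected = _trapz_mean(x * x, x) * _trapz_mean(y * y, y)
        assert g["g11"] == pytest.approx(expected, rel=1e-9)
        off = g.drop("g11")
        assert np.abs(off.to_numpy()).max() < 1e-10

    def test_too_few_loops_rejected(self):
        with pytest.raises(ValueError):
            global_legendre_features(_sg(np.zeros((30, 6)), n_pre=4))


class TestLocalFeatures:
    def test_constant_field_fills_all_cells(self):
        loc = local_band_features(_sg(np.full((30, 16), -0.2)))
        assert np.allclose(loc.to_numpy(), -0.2)

    def test_single_cell_impulse(self):
        sg = _sg(np.zeros((30, 16)))
        # mid-frequency band (rows 10..19), late epoch (last third of post loops)
        sg.D[10:20, sg.treatment_loop + 8 :] = 1.0
        loc = local_band_features(sg)
        assert loc["loc_f1_t2"] == pytest.approx(1.0)
        assert np.abs(loc.drop("loc_f1_t2").to_numpy()).max() == 0.0

    def test_mid_enhanced_archetype_peaks_in_mid_band(self, knee_model):
        series = simulate_well(ResponseArchetype("mid_enhanced", 0.3), knee_model, noise_sd=0.0, seed=0)
        from biodyn.spectroscopy import drug_response_spectrogram

        loc = local_band_features(drug_response_spectrogram(series))
        for t in range(3):
            assert loc[f"loc_f1_t{t}"] > loc[f"loc_f0_t{t}"]
            assert loc[f"loc_f1_t{t}"] > loc[f"loc_f2_t{t}"]


class TestPreconditions:
    def test_flat_spectrum_metrics(self):
        f = np.geomspace(0.0125, 12.5, 60)
        flat = np.column_stack([np.ones_like(f)] * 3)
        loops = [PowerSpectrum(f, flat[:, i], loop_time=float(i - 3) * 2 / 3) for i in range(3)]
        series = WellSpectrumSeries("w", "p", "d", loops, treatment_loop=3)
        pre = precondition_features(series)
        assert pre["dr"] == pytest.approx(0.0, abs=1e-12)
        assert pre["se"] == pytest.approx(1.0, abs=1e-12)
        assert pre["sf"] == pytest.approx(0.0, abs=1e-9)

    def test_knee_recovery_from_pre_treatment(self, knee_model):
        series = simulate_well(ResponseArchetype("null", 0.0), knee_model, noise_sd=0.0, seed=0)
        pre = precondition_features(series)
        assert pre["kn"] == pytest.approx(knee_model.knee_freq, rel=0.10)
        assert pre["s0"] == pytest.approx(knee_model.s0 + knee_model.floor, rel=0.05)

    def test_speckle_contrast_of_fully_developed_speckle(self):
        flat = SpectralModel(s0=1e-9, knee_freq=1.0, slope=2.0, floor=1.0)
        stack = synthesize_intensity_stack(flat, 256, 25.0, 512, seed=1)
        I = stack.frames.ravel()
        stats = {"mean_intensity": I.mean(), "std_intensity": I.std()}
        f = np.geomspace(0.0125, 12.5, 40)
        loops = [PowerSpectrum(f, np.ones_like(f), loop_time=-1.0), PowerSpectrum(f, np.ones_like(f), loop_time=0.0)]
        series = WellSpectrumSeries("w", "p", "d", loops, treatment_loop=2)
        pre = precondition_features(series, stack_stats=stats)
        assert pre["nsd"] == pytest.approx(1.0, abs=0.05)  # exponential intensity

    def test_null_deltas_vanish_noise_free(self, knee_model):
        series = simulate_well(ResponseArchetype("null", 0.0), knee_model, noise_sd=0.0, seed=0)
        d = precondition_deltas(series)
        assert np.abs(d.to_numpy()).max() < 1e-9

    def test_shift_deltas_have_matching_signs(self, knee_model):
        red = simulate_well(ResponseArchetype("redshift", 0.3), knee_model, noise_sd=0.0, seed=0)
        blue = simulate_well(ResponseArchetype("blueshift", 0.3), knee_model, noise_sd=0.0, seed=0)
        assert precondition_deltas(red)["d_hw"] < 0
        assert precondition_deltas(blue)["d_hw"] > 0


class TestBaselineAndQuality:
    def test_zero_pre_treatment_baseline(self):
        b = baseline_features(_sg(np.zeros((30, 16))))
        assert tuple(b) == (0.0, 0.0, 0.0)

    def test_planted_linear_drift_slope(self):
        sg = _sg(np.zeros((30, 16)), n_pre=5)
        t = sg.loop_times[:5]
        sg.D[:, :5] = 0.04 * t[None, :]
        b = baseline_features(sg)
        assert b["b_slope"] == pytest.approx(0.04, rel=1e-9)
        assert b["b_resid"] == pytest.approx(0.0, abs=1e-12)

    def test_noise_residual_matches_sigma(self, rng):
        sg = _sg(np.zeros((300, 16)), n_pre=6)
        sg.D[:, :6] = rng.normal(0, 0.1, size=(300, 6))
        b = baseline_features(sg)
        # freq-averaged noise has sd 0.1/sqrt(300); residual after detrend
        assert b["b_resid"] < 3 * 0.1 / np.sqrt(300) * 2
        assert b["b_drift"] == pytest.approx(0.1 * np.sqrt(2 / np.pi), rel=0.05)

    def test_clean_well_has_unit_quality(self, knee_model):
        series = simulate_well(ResponseArchetype("blueshift", 0.3), knee_model, noise_sd=0.05, seed=0)
        assert data_quality(series) == 1.0

    def test_half_zeroed_loops_give_half_quality(self, knee_model):
        series = simulate_well(ResponseArchetype("null", 0.0), knee_model, loops_pre=4, loops_post=4, noise_sd=0.0, seed=0)
        for ps in series.loops[4:]:
            ps.density = np.zeros_like(ps.density)
        assert data_quality(series) == 0.5

    def test_floor_dominated_well_fails_quality(self):
        flat = SpectralModel(s0=1e-9, knee_freq=1.0, slope=2.0, floor=1.0)
        series = simulate_well(ResponseArchetype("null", 0.0), flat, noise_sd=0.01, seed=0)
        assert data_quality(series) < 0.5


class TestAssemblyAndPooling:
    def test_forty_features_partitioned_9_9_9_9_3_1(self, knee_model):
        fv = extract_features(simulate_well(ResponseArchetype("blueshift", 0.3), knee_model, seed=1))
        assert len(fv) == 40
        assert list(fv.index) == FEATURE_NAMES
        groups = [
            [n for n in FEATURE_NAMES if n.startswith("g")],
            [n for n in FEATURE_NAMES if n.startswith("loc_")],
            [n for n in FEATURE_NAMES if not n.startswith(("g", "loc_", "d_", "b_", "dq"))],
            [n for n in FEATURE_NAMES if n.startswith("d_")],
            [n for n in FEATURE_NAMES if n.startswith("b_")],
            ["dq"],
        ]
        assert [len(g) for g in groups] == [9, 9, 9, 9, 3, 1]

    def test_missing_part_rejected(self):
        with pytest.raises(ValueError):
            assemble_feature_vector(
                pd.Series({"g00": 1.0}),
                pd.Series(dtype=float),
                pd.Series(dtype=float),
                pd.Series(dtype=float),
                pd.Series(dtype=float),
                1.0,
            )

    def test_default_map_emits_canonical_biomarkers(self, knee_model):
        fv = extract_features(simulate_well(ResponseArchetype("redshift", 0.2), knee_model, seed=2))
        table = pd.DataFrame([fv, fv * 1.1, fv * 0.7])
        bm = pool_features(table)
        assert list(bm.columns) == BIOMARKER_NAMES
        assert bm.shape == (3, 12)

    def test_singleton_pool_equals_zscored_feature(self, knee_model):
        wells = [
            extract_features(simulate_well(ResponseArchetype("blueshift", a), knee_model, noise_sd=0.02, seed=i))
            for i, a in enumerate((0.1, 0.2, 0.3, 0.4))
        ]
        table = pd.DataFrame(wells)
        z = fit_zscores(table)
        bm = pool_features(table, zstats=z)
        assert np.allclose(bm["DNSD"], z.transform(table)["d_nsd"])

    def test_pooling_is_deterministic(self, knee_model):
        fv = extract_features(simulate_well(ResponseArchetype("blueshift", 0.3), knee_model, seed=3))
        table = pd.DataFrame([fv, fv * 2])
        z = fit_zscores(table)
        assert pool_features(table, zstats=z).equals(pool_features(table, zstats=z))

    def test_planted_broad_time_ramp_tracked_by_ALLFT(self):
        """A frequency-flat response growing linearly in time is the
        ALLFT pattern: among all 12 biomarkers, ALLFT correlates best
        with the planted time-ramp coefficient."""
        rows, coeffs = [], []
        rng = np.random.default_rng(0)
        for a in rng.uniform(-0.3, 0.3, size=16):
            sg = _sg(np.zeros((30, 16)))
            _, y = _xy(sg)
            sg.D[:, sg.treatment_loop :] = a * y[None, :] + rng.normal(0, 0.05, (30, 12))
            coeffs.append(a)
            rows.append(
                assemble_feature_vector(
                    global_legendre_features(sg),
                    local_band_features(sg),
                    pd.Series(0.0, index=[n for n in FEATURE_NAMES if n in ("nsd", "dr", "hw", "kn", "bb", "sf", "se", "s0", "ht")]),
                    pd.Series(0.0, index=[f"d_{n}" for n in ("nsd", "dr", "hw", "kn", "bb", "sf", "se", "s0", "ht")]),
                    baseline_features(sg),
                    1.0,
                )
            )
        table = pd.DataFrame(rows)
        bm = pool_features(table, zstats=fit_zscores(table))
        tracking = bm.corrwith(pd.Series(coeffs, index=bm.index)).abs()
        assert tracking.idxmax() == "ALLFT"
        assert tracking["ALLFT"] > 0.85

    def test_map_validation(self):
        with pytest.raises(ValueError):
            PoolingMap.from_dict({"ALLF": {"not_a_feature": 1.0}})
        with pytest.raises(ValueError):
            PoolingMap.from_dict({})
        pm = default_pooling_map()
        for name, pool in pm.items():
            assert sum(w for _, w in pool) == pytest.approx(1.0)
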