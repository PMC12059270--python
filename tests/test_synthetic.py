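"""Synthetic phantom / signal / noise / cohort generator behavior."""

import numpy as np
import pytest
from scipy import stats

from radstab.synthetic import (
    AfProfile,
    BValueScheme,
    DwiSeries,
    HeterogeneityModel,
    add_rician_noise,
    default_af_profiles,
    default_scheme,
    emulate_af,
    make_cohort,
    make_phantom,
    simulate_signal,
)

from conftest import UNIFORM_PARAMS, small_spec


class TestBValueScheme:
    def test_default_protocol(self):
        s = default_scheme()
        assert len(s) == 11
        assert s.b_values[0] == 0 and s.b_values[-1] == 2000
        assert s.n_averages.tolist() == [1, 1, 1, 1, 1, 1, 2, 2, 2, 4, 6]

    @pytest.mark.parametrize(
        "entries",
        [((10, 1),), ((0, 1), (0, 1)), ((0, 1), (100, 0)), ((0, 1), (50, 1), (20, 1))],
    )
    def test_invalid_schemes_rejected(self, entries):
        with pytest.raises(ValueError):
            BValueScheme(entries)


class TestMakePhantom:
    def test_zero_amplitude_gives_exact_lesion_values(self):
        spec = small_spec(
            heterogeneity=HeterogeneityModel(amplitude=0.0),
            lesion_params=dict(UNIFORM_PARAMS),
        )
        truth = make_phantom(spec)
        for name, val in UNIFORM_PARAMS.items():
            assert np.all(truth.param_fields[name][truth.lesion_mask] == val)

    def test_determinism_bit_identical(self):
        spec = small_spec(seed=42)
        t1, t2 = make_phantom(spec), make_phantom(spec)
        assert np.array_equal(t1.lesion_mask, t2.lesion_mask)
        for name in t1.param_fields:
            assert np.array_equal(t1.param_fields[name], t2.param_fields[name])

    def test_texture_amplitude_bounds_and_mean(self):
        # amplitude 0.1 around D = 1.0e-3: all lesion voxels within +/-10%,
        # mean within 2% of the nominal value over >= 500 voxels
        spec = small_spec(
            grid_shape=(48, 48, 16), lesion_center=(24.0, 24.0, 8.0),
            lesion_radii=(8.0, 8.0, 4.0),
            heterogeneity=HeterogeneityModel(amplitude=0.1),
            lesion_params={**UNIFORM_PARAMS, "D": 1.0e-3},
            seed=3,
        )
        truth = make_phantom(spec)
        d = truth.param_fields["D"][truth.lesion_mask]
        assert d.size >= 500
        assert np.all((d >= 0.9e-3 - 1e-15) & (d <= 1.1e-3 + 1e-15))
        assert abs(d.mean() - 1.0e-3) / 1.0e-3 < 0.02

    def test_lesion_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside grid"):
            small_spec(lesion_center=(22.0, 12.0, 6.0))

    def test_voxelwise_invariants(self):
        truth = make_phantom(small_spec(stage_label="high", seed=11))
        p = truth.param_fields
        assert np.all((p["f"] >= 0) & (p["f"] <= 1))
        assert np.all(p["Dstar"] > p["D"])
        assert np.all(p["D"] > 0) and np.all(p["MD"] > 0)
        assert np.all(p["MK"] >= 0)


class TestSimulateSignal:
    def test_ivim_closed_form_f0(self):
        # pure mono-exponential: S(800)/S0 = exp(-0.8) at D = 1e-3
        spec = small_spec(
            signal_model="ivim",
            heterogeneity=HeterogeneityModel(amplitude=0.0),
            lesion_params={**UNIFORM_PARAMS, "f": 0.0, "D": 1.0e-3},
        )
        ser = simulate_signal(make_phantom(spec))
        vox = tuple(np.argwhere(make_phantom(spec).lesion_mask)[0])
        s = ser.volumes[vox]
        i800 = list(ser.scheme.b_values).index(800)
        assert s[i800] / s[0] == pytest.approx(np.exp(-0.8), rel=1e-12)

    def test_b0_equals_s0_all_models(self):
        for model in ("ivim", "dki", "combined"):
            spec = small_spec(signal_model=model, seed=5)
            truth = make_phantom(spec)
            ser = simulate_signal(truth)
            assert np.array_equal(ser.volumes[..., 0], truth.param_fields["S0"])

    def test_dki_closed_form(self):
        # MD = 1e-3, MK = 1, b = 2000: S/S0 = exp(-2 + 4/6)
        spec = small_spec(
            signal_model="dki",
            heterogeneity=HeterogeneityModel(amplitude=0.0),
            lesion_params={**UNIFORM_PARAMS, "MD": 1.0e-3, "MK": 1.0},
        )
        truth = make_phantom(spec)
        ser = simulate_signal(truth)
        vox = tuple(np.argwhere(truth.lesion_mask)[0])
        ratio = ser.volumes[vox][-1] / ser.volumes[vox][0]
        assert ratio == pytest.approx(np.exp(-2 + 4 / 6), rel=1e-12)

    def test_excessive_kurtosis_clipped_with_flag(self):
        spec = small_spec(
            signal_model="dki",
            heterogeneity=HeterogeneityModel(amplitude=0.0),
            lesion_params={**UNIFORM_PARAMS, "MD": 3.0e-3, "MK": 2.5},
        )
        truth = make_phantom(spec)
        with pytest.warns(UserWarning, match="clipped"):
            ser = simulate_signal(truth)
        assert ser.flags.get("signal_clipped") is True
        s0 = truth.param_fields["S0"]
        assert np.all(ser.volumes <= s0[..., None] + 1e-9)


class TestEmulateAf:
    @pytest.mark.parametrize(
        "tr,t1,expected",
        [(4700.0, 1500.0, 1 - np.exp(-4700 / 1500)),
         (2000.0, 1500.0, 1 - np.exp(-2000 / 1500))],
    )
    def test_saturation_factor(self, tr, t1, expected):
        prof = AfProfile(af=2, tr_ms=tr, t1_ms=t1, sigma_scale=1.1)
        assert prof.saturation_factor == pytest.approx(expected, rel=1e-12)
        assert prof.saturation_factor == pytest.approx(
            {4700.0: 0.9565, 2000.0: 0.7364}[tr], abs=1e-4
        )

    def test_t1_to_zero_limit_leaves_signal(self, uniform_ivim_series):
        prof = AfProfile(af=3, tr_ms=2000.0, t1_ms=1e-9, sigma_scale=1.3)
        out = emulate_af(uniform_ivim_series, prof)
        assert np.allclose(out.volumes, uniform_ivim_series.volumes, rtol=1e-12)

    def test_scaling_and_profile_attachment(self, uniform_ivim_series):
        prof = default_af_profiles()["S3"]
        out = emulate_af(uniform_ivim_series, prof)
        assert out.af_profile is prof
        assert out.sequence_label == "S3"
        np.testing.assert_allclose(
            out.volumes, uniform_ivim_series.volumes * prof.saturation_factor
        )


class TestRicianNoise:
    def test_sigma_zero_is_identity(self, uniform_ivim_series):
        assert add_rician_noise(uniform_ivim_series, 0.0, seed=1) is uniform_ivim_series

    def test_negative_sigma_rejected(self, uniform_ivim_series):
        with pytest.raises(ValueError):
            add_rician_noise(uniform_ivim_series, -1.0)

    def test_rician_mean_at_zero_signal(self):
        # nu = 0, sigma = 1: E|noise| = sqrt(pi/2), checked over >= 1e5 voxels
        vols = np.zeros((64, 64, 32, 1))
        ser = DwiSeries(volumes=vols, scheme=BValueScheme(((0, 1),)))
        noisy = add_rician_noise(ser, 1.0, seed=9)
        assert noisy.volumes.size >= 1e5
        assert noisy.volumes.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=0.01)

    def test_averaging_variance_law(self):
        # 4 averages vs 1 at equal sigma: sd ratio ~ 1/2 at high SNR
        scheme1 = BValueScheme(((0, 1), (10, 1)))
        scheme4 = BValueScheme(((0, 1), (10, 4)))
        vols = np.full((48, 48, 24, 2), 100.0)
        sd = {}
        for key, scheme in (("n1", scheme1), ("n4", scheme4)):
            ser = DwiSeries(volumes=vols, scheme=scheme)
            noisy = add_rician_noise(ser, 1.0, seed=13)
            sd[key] = noisy.volumes[..., 1].std()
        assert sd["n4"] / sd["n1"] == pytest.approx(0.5, rel=0.10)

    def test_masks_and_grid_conserved(self, uniform_ivim_truth, uniform_ivim_series):
        noisy = add_rician_noise(uniform_ivim_series, 3.0, seed=2)
        assert noisy.volumes.shape == uniform_ivim_series.volumes.shape
        assert noisy.scheme is uniform_ivim_series.scheme


class TestMakeCohort:
    def test_cohort_shape_contract(self):
        cohort = make_cohort(2, 3, base_spec=small_spec(), seed=4, sigma=1.0)
        assert len(cohort) == 5
        assert len(cohort.metadata) == 15  # 5 subjects x 3 sequences
        sid, stage, truth, series = cohort.subjects[0]
        assert set(series) == {"S1", "S2", "S3"}
        for label, ser in series.items():
            assert ser.sequence_label == label
            assert ser.volumes.shape[3] == 11

    def test_paper_cohort_counts(self):
        # 12 low + 28 high -> 40 subjects, 120 series (metadata only; tiny grid)
        cohort = make_cohort(12, 28, base_spec=small_spec(), seed=1, sigma=0.0)
        assert len(cohort) == 40
        assert len(cohort.metadata) == 120
        assert (cohort.metadata["stage"] == "low").sum() == 36  # 12 subjects x 3 rows

    def test_determinism(self):
        a = make_cohort(2, 2, base_spec=small_spec(), seed=8, sigma=2.0)
        b = make_cohort(2, 2, base_spec=small_spec(), seed=8, sigma=2.0)
        assert a.metadata.equals(b.metadata)
        va = a.subjects[1][3]["S2"].volumes
        vb = b.subjects[1][3]["S2"].volumes
        assert np.array_equal(va, vb)

    def test_shared_truth_across_sequences(self):
        cohort = make_cohort(1, 1, base_spec=small_spec(), seed=3, sigma=1.0)
        _, _, truth, series = cohort.subjects[0]
        for ser in series.values():
            assert ser.volumes.shape[:3] == truth.lesion_mask.shape

    def test_null_stage_effect_indistinguishable(self):
        # multiplier 1.0: low/high lesion parameter distributions should be
        # statistically indistinguishable (p > 0.05 in >= 90% of 20 replicates)
        spec = small_spec(stage_amp_multiplier=1.0)
        ok = 0
        for rep in range(20):
            cohort = make_cohort(
                10, 10, base_spec=spec, seed=100 + rep, sigma=0.0,
                stage_radius_multiplier=1.0,
            )
            means = {"low": [], "high": []}
            for _, stage, truth, _ in cohort:
                means[stage].append(truth.param_fields["D"][truth.lesion_mask].mean())
            p = stats.ttest_ind(means["low"], means["high"]).pvalue
            ok += p > 0.05
        assert ok >= 18
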