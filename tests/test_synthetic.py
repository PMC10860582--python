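"""Generator contracts: bolus curves, phantoms, maps and cohorts."""

import numpy as np
import pytest

from ctaphase.synthetic import (
    BolusModel,
    BolusParams,
    CohortParams,
    PhantomGeometry,
    gamma_variate,
    simulate_cohort,
    simulate_cta_snapshot,
    simulate_ctp_series,
    simulate_perfusion_maps,
    simulate_probability_map,
)
from ctaphase.tac import cta_roi_values, extract_roi_curve
from ctaphase.volumetry import (
    CEREBELLUM,
    IPSILATERAL,
    compute_hir,
    thresholded_volume,
)


class TestGammaVariate:
    def test_zero_at_and_before_onset(self):
        p = BolusParams(t0=10.0)
        assert gamma_variate(10.0, p) == 0.0
        assert gamma_variate(3.0, p) == 0.0

    def test_peak_equals_amplitude(self):
        p = BolusParams(t0=10.0, alpha=3.0, beta=1.5, amplitude=200.0)
        peak_t = p.t0 + p.alpha * p.beta
        assert gamma_variate(peak_t, p) == pytest.approx(200.0, abs=1e-12)
        # and it really is the maximum
        t = np.linspace(0, 80, 2000)
        assert gamma_variate(t, p).max() <= 200.0 + 1e-9

    def test_closed_form_value(self):
        # frozen from an independent evaluation of the closed form:
        # alpha=3, beta=1.5, t0=10, amplitude=200 at t=12
        p = BolusParams(t0=10.0, alpha=3.0, beta=1.5, amplitude=200.0)
        assert gamma_variate(12.0, p) == pytest.approx(92.96223956929543, rel=1e-12)

    def test_non_finite_time_rejected(self):
        with pytest.raises(ValueError):
            gamma_variate(np.nan, BolusParams())

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"beta": -1.0},
            {"amplitude": 0.0},
            {"venous_delay": -1.0},
            {"venous_dispersion": 0.9},
            {"n_frames": 1},
            {"t0": float("inf")},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BolusParams(**kwargs)


class TestBolusModel:
    def test_vof_equals_aif_without_delay_or_dispersion(self):
        m = BolusModel(BolusParams(venous_delay=0.0, venous_dispersion=1.0))
        t = np.linspace(0, 78, 500)
        np.testing.assert_allclose(m.vof(t), m.aif(t), atol=1e-9)

    def test_vof_area_preserved_under_dispersion(self):
        m = BolusModel(BolusParams(noise_sd=0.0))
        t = np.linspace(0.0, 150.0, 30000)
        area_a = np.trapezoid(m.aif(t), t)
        area_v = np.trapezoid(m.vof(t), t)
        assert area_v == pytest.approx(area_a, rel=1e-3)

    def test_vof_peak_after_aif_peak(self):
        m = BolusModel(BolusParams())
        assert m.vof_peak_time > m.aif_peak_time


class TestCtpSeries:
    def test_noiseless_extraction_matches_truth_exactly(self, noiseless_phantom, geometry):
        series, truth = noiseless_phantom
        aif = extract_roi_curve(series, geometry.arterial_roi())
        vof = extract_roi_curve(series, geometry.venous_roi())
        # identical voxels, so the ROI mean reproduces the truth to the ULP
        np.testing.assert_allclose(aif.values, truth.aif.values, rtol=1e-14)
        np.testing.assert_allclose(vof.values, truth.vof.values, rtol=1e-14)

    def test_fixed_seed_is_bit_identical(self, geometry):
        p = BolusParams(noise_sd=5.0, seed=17)
        s1, _ = simulate_ctp_series(p, geometry)
        s2, _ = simulate_ctp_series(p, geometry)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)

    def test_overlapping_rois_rejected(self):
        geom = PhantomGeometry(arterial_center=(6.0, 6.0, 6.0), venous_center=(7.0, 6.0, 6.0))
        with pytest.raises(ValueError, match="overlap"):
            simulate_ctp_series(BolusParams(), geom)


class TestCtaSnapshot:
    def test_noiseless_snapshot_traces_the_dynamic_curves(self, noiseless_params, geometry):
        """Sweeping the acquisition time, ROI means must follow the
        continuous AIF/VOF exactly (snapshot-consistency invariant)."""
        m = BolusModel(noiseless_params)
        for t_acq in np.linspace(1.0, 70.0, 15):
            snap = simulate_cta_snapshot(noiseless_params, geometry, float(t_acq))
            a, v = cta_roi_values(snap, geometry.arterial_roi(), geometry.venous_roi())
            assert a == pytest.approx(noiseless_params.baseline + m.aif(t_acq), abs=1e-9)
            assert v == pytest.approx(noiseless_params.baseline + m.vof(t_acq), abs=1e-9)

    def test_snapshot_at_peak_equals_baseline_plus_amplitude(self, noiseless_params, geometry):
        p = noiseless_params
        snap = simulate_cta_snapshot(p, geometry, p.t0 + p.alpha * p.beta)
        a, _ = cta_roi_values(snap, geometry.arterial_roi(), geometry.venous_roi())
        assert a == pytest.approx(p.baseline + p.amplitude, abs=1e-9)

    def test_same_seed_same_snapshot(self, geometry):
        p = BolusParams(noise_sd=5.0, seed=3)
        s1 = simulate_cta_snapshot(p, geometry, 18.0)
        s2 = simulate_cta_snapshot(p, geometry, 18.0)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)

    def test_out_of_window_rejected(self, noiseless_params, geometry):
        with pytest.raises(ValueError, match="outside"):
            simulate_cta_snapshot(noiseless_params, geometry, noiseless_params.duration + 1.0)


class TestPerfusionMaps:
    def test_zero_request_gives_zero_volumes(self):
        maps = simulate_perfusion_maps(0.0, 0.0, 0.0)
        assert maps.core_volume_mL() == 0.0
        assert maps.penumbra_volume_mL() == 0.0

    def test_requested_volume_is_exact_voxel_count(self):
        geom = PhantomGeometry(shape=(40, 40, 20), spacing=(1.0, 1.0, 1.0))
        maps = simulate_perfusion_maps(20.0, 25.0, 0.0, geom)
        n_core = int(np.sum(maps.rcbf_ratio < 0.3))
        assert abs(n_core - 20000) <= 1

    def test_hir_round_trip(self):
        geom = PhantomGeometry(shape=(40, 40, 20), spacing=(1.0, 1.0, 1.0))
        maps = simulate_perfusion_maps(5.0, 20.0, 0.4, geom, seed=2)
        vv = 1.0 / 1000.0
        tol = vv / 20.0  # one voxel's worth of ratio
        assert compute_hir(maps) == pytest.approx(0.4, abs=tol + 1e-12)

    def test_volume_conservation(self):
        """Thresholded volume equals suprathreshold count x voxel volume."""
        geom = PhantomGeometry(shape=(20, 20, 10), spacing=(1.5, 1.5, 3.0))
        maps = simulate_perfusion_maps(8.0, 20.0, 0.5, geom, seed=3)
        vol = thresholded_volume(maps.tmax, lambda m: m > 6.0, maps.spacing)
        count = int(np.sum(maps.tmax > 6.0))
        assert vol == count * (1.5 * 1.5 * 3.0) / 1000.0

    def test_invalid_requests_rejected(self):
        with pytest.raises(ValueError, match="core"):
            simulate_perfusion_maps(30.0, 20.0, 0.5)
        with pytest.raises(ValueError, match="capacity"):
            simulate_perfusion_maps(10.0, 1e6, 0.5)
        with pytest.raises(ValueError, match="hir"):
            simulate_perfusion_maps(1.0, 2.0, 1.5)


class TestProbabilityMap:
    def test_lesion_painting_and_labels(self):
        geom = PhantomGeometry(shape=(24, 24, 12), spacing=(1.0, 1.0, 1.0))
        pmap = simulate_probability_map(
            [{"center": (6.0, 12.0, 7.0), "radius": 3.0, "p": 0.9}], geom
        )
        assert pmap.values.max() == 0.9
        assert (pmap.hemisphere_mask[:12, :, 2:] == IPSILATERAL).all()
        assert (pmap.hemisphere_mask[:, :, :2] == CEREBELLUM).all()


class TestCohort:
    def test_lambda_zero_estimate_equals_core(self):
        records = simulate_cohort(
            CohortParams(n_patients=50, lambda_penumbra=0.0, estimate_noise_sd=0.0, seed=1)
        )
        for r in records:
            assert r.cnn_volume_mL == pytest.approx(r.core_mL, abs=1e-12)

    def test_lambda_one_estimate_equals_penumbra(self):
        records = simulate_cohort(
            CohortParams(n_patients=50, lambda_penumbra=1.0, estimate_noise_sd=0.0, seed=1)
        )
        for r in records:
            assert r.cnn_volume_mL == pytest.approx(r.penumbra_mL, abs=1e-12)

    def test_noiseless_estimate_ordered_between_core_and_penumbra(self):
        records = simulate_cohort(
            CohortParams(n_patients=100, lambda_penumbra=0.4, estimate_noise_sd=0.0, seed=2)
        )
        for r in records:
            assert r.core_mL <= r.cnn_volume_mL <= r.penumbra_mL

    def test_poor_collaterals_have_larger_final_infarcts(self):
        """With collateral_effect > 1 the Miteff-1 (poor) median FIV must
        exceed the Miteff-3 (good) median in a 500-patient cohort."""
        records = simulate_cohort(CohortParams(n_patients=500, collateral_effect=2.0, seed=3))
        fiv_poor = np.median([r.fiv_mL for r in records if r.miteff == 1])
        fiv_good = np.median([r.fiv_mL for r in records if r.miteff == 3])
        assert fiv_poor > fiv_good

    def test_determinism_and_validity(self):
        a = simulate_cohort(CohortParams(n_patients=30, seed=9))
        b = simulate_cohort(CohortParams(n_patients=30, seed=9))
        assert [r.__dict__ for r in a] == [r.__dict__ for r in b]
        for r in a:
            assert 0.0 <= r.hir <= 1.0
            assert r.core_mL <= r.penumbra_mL
            assert (r.sleep_time is not None) == r.wake_up

    @pytest.mark.parametrize(
        "kwargs",
        [{"n_patients": 0}, {"lambda_penumbra": 1.2}, {"reperfusion_rate": -0.1}],
    )
    def test_invalid_cohort_params(self, kwargs):
        with pytest.raises(ValueError):
            CohortParams(**kwargs)
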