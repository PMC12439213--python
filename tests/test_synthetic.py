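import numpy as np
import pytest

from contourqa.errors import ContourQAError
from contourqa.geometry import volume_cc
from contourqa.io import ImageGrid
from contourqa.synthetic import (
    Ellipsoid,
    HalfTorus,
    ObserverModel,
    PhantomSpec,
    TimingModel,
    ZCylinder,
    default_observer_models,
    default_phantom,
    load_study,
    make_cohort,
    make_dose,
    make_phantom,
    make_timing,
    perturb_mask,
)


def sphere_spec(radius=10.0):
    return PhantomSpec(organs={"s": Ellipsoid((96.0, 96.0, 64.0), (radius,) * 3)})


class TestPhantom:
    def test_sphere_volume_matches_analytic(self):
        mask = make_phantom(sphere_spec())["s"]
        analytic = 4.0 / 3.0 * np.pi * 10.0**3 / 1000.0  # 4.19 cc
        assert volume_cc(mask) == pytest.approx(analytic, rel=0.10)

    def test_cylinder_volume_matches_analytic(self):
        spec = PhantomSpec(organs={"c": ZCylinder((96.0, 96.0), (5.0, 5.0), (40.0, 80.0))})
        mask = make_phantom(spec)["c"]
        analytic = np.pi * 25.0 * 40.0 / 1000.0
        assert volume_cc(mask) == pytest.approx(analytic, rel=0.10)

    def test_deterministic(self):
        a = make_phantom(default_phantom())
        b = make_phantom(default_phantom())
        for name in a:
            np.testing.assert_array_equal(a[name].voxels, b[name].voxels)

    def test_out_of_bounds_organ_rejected(self):
        spec = PhantomSpec(organs={"big": Ellipsoid((96.0, 96.0, 64.0), (200.0, 50.0, 50.0))})
        with pytest.raises(ContourQAError, match="big"):
            make_phantom(spec)

    def test_default_phantom_anatomy(self):
        spec = default_phantom()
        masks = make_phantom(spec)
        assert len(masks) == 12
        sc = masks["spinal_cord"]
        occupied_slices = np.nonzero(sc.voxels.any(axis=(0, 1)))[0]
        assert occupied_slices.size >= 10
        # half-torus mandible is a curved bar, not a full ring
        assert isinstance(spec.organs["mandible"], HalfTorus)
        assert all(not m.is_empty for m in masks.values())


class TestPerturbMask:
    def test_zero_noise_zero_margin_is_identity(self):
        gt = make_phantom(sphere_spec())["s"]
        out = perturb_mask(gt, ObserverModel("manual", 0.0, 0.0, seed=9), "o1", "P1")
        np.testing.assert_array_equal(out.voxels, gt.voxels)

    def test_margin_dilates_sphere_volume(self):
        gt = make_phantom(sphere_spec())["s"]
        out = perturb_mask(gt, ObserverModel("ai_only", 0.0, 2.0, seed=9), "ai", "P1")
        ratio = out.voxels.sum() / gt.voxels.sum()
        assert ratio == pytest.approx((12.0 / 10.0) ** 3, rel=0.10)

    def test_reproducible_and_observer_dependent(self):
        gt = make_phantom(sphere_spec())["s"]
        model = ObserverModel("manual", 2.0, seed=9)
        a = perturb_mask(gt, model, "o1", "P1")
        b = perturb_mask(gt, model, "o1", "P1")
        c = perturb_mask(gt, model, "o2", "P1")
        np.testing.assert_array_equal(a.voxels, b.voxels)
        assert (a.voxels != c.voxels).any()

    def test_noise_perturbs_but_preserves_scale(self):
        gt = make_phantom(sphere_spec())["s"]
        out = perturb_mask(gt, ObserverModel("manual", 2.0, seed=2), "o1", "P1")
        assert (out.voxels != gt.voxels).any()
        assert 0.5 < out.voxels.sum() / gt.voxels.sum() < 2.0

    def test_caudal_jitter_moves_inferior_end_only(self):
        spec = PhantomSpec(
            organs={"spinal_cord": ZCylinder((96.0, 96.0), (5.0, 5.0), (20.0, 100.0))}
        )
        gt = make_phantom(spec)["spinal_cord"]
        model = ObserverModel("manual", 0.0, 0.0, caudal_jitter_slices=2, seed=4)
        shifts = set()
        for obs in ("o1", "o2", "o3", "o4", "o5", "o6"):
            out = perturb_mask(gt, model, obs, "P1", is_tubular=True)
            gt_lo = np.nonzero(gt.voxels.any(axis=(0, 1)))[0]
            out_lo = np.nonzero(out.voxels.any(axis=(0, 1)))[0]
            assert out_lo[-1] == gt_lo[-1]  # cranial end untouched
            shifts.add(int(out_lo[0]) - int(gt_lo[0]))
        assert shifts <= {-2, -1, 0, 1, 2}
        assert len(shifts) > 1


class TestMakeDose:
    def test_prescription_at_target_center(self):
        grid = ImageGrid((20, 20, 20), (2.0, 2.0, 2.0))
        dose = make_dose(grid, (20.0, 20.0, 20.0), prescription_gy=68.0, falloff_mm=25.0)
        assert dose.dose[10, 10, 10] == pytest.approx(68.0)

    def test_falloff_closed_form(self):
        grid = ImageGrid((40, 20, 20), (1.0, 2.0, 2.0))
        dose = make_dose(grid, (10.0, 20.0, 20.0), prescription_gy=68.0, falloff_mm=15.0)
        # voxel 15 mm from the center along x
        assert dose.dose[25, 10, 10] == pytest.approx(68.0 * np.exp(-0.5), abs=1e-9)

    def test_monotone_decay_with_distance(self):
        grid = ImageGrid((30, 10, 10), (2.0, 2.0, 2.0))
        dose = make_dose(grid, (0.0, 0.0, 0.0), falloff_mm=20.0)
        profile = dose.dose[:, 0, 0]
        assert (np.diff(profile) < 0).all()


class TestMakeTiming:
    def test_zero_dispersion_reproduces_medians(self):
        model = TimingModel(manual_dispersion=0.0, adjusted_dispersion=0.0, processing_dispersion=0.0)
        recs = make_timing(model, 3)
        by_group = {g: [r.minutes for r in recs if r.group == g] for g in ("manual", "adjusted", "processing")}
        assert by_group["manual"] == [55.0] * 3
        assert by_group["adjusted"] == [17.0] * 3
        assert by_group["processing"] == [10.0] * 3

    def test_sample_median_near_configured_median(self):
        recs = make_timing(TimingModel(seed=0), 200)
        manual = [r.minutes for r in recs if r.group == "manual"]
        assert abs(np.median(manual) - 55.0) <= 5.0

    def test_same_seed_identical(self):
        assert make_timing(TimingModel(seed=3), 5) == make_timing(TimingModel(seed=3), 5)

    def test_half_minute_resolution(self):
        recs = make_timing(TimingModel(seed=1), 20)
        assert all((r.minutes * 2) == int(r.minutes * 2) for r in recs)


class TestMakeCohort:
    def small_observers(self, seed):
        return {
            "manual": [ObserverModel("manual", 2.0, seed=seed) for _ in range(3)],
            "adjusted": [ObserverModel("adjusted", 0.8, 0.5, seed=seed)],
        }

    def test_mask_counts(self):
        study = make_cohort(
            observers=self.small_observers(1), n_patients=2, seed=1, with_dose=False
        )
        manual_masks = sum(
            len(organs) for key, organs in study.masks.items() if key[1] == "manual"
        )
        assert manual_masks == 2 * 3 * 12  # patients x observers x organs

    def test_same_seed_reproduces_study(self):
        a = make_cohort(observers=self.small_observers(2), n_patients=1, seed=2, with_dose=False)
        b = make_cohort(observers=self.small_observers(2), n_patients=1, seed=2, with_dose=False)
        assert a.manifest == b.manifest
        for key in a.masks:
            for organ in a.masks[key]:
                np.testing.assert_array_equal(a.masks[key][organ].voxels, b.masks[key][organ].voxels)
        assert a.timing == b.timing

    def test_omitted_contour_recorded(self):
        omit = [("P01", "manual", "manual01", "thyroid")]
        study = make_cohort(
            observers=self.small_observers(3), n_patients=1, seed=3, with_dose=False, omit=omit
        )
        assert "thyroid" not in study.masks[("P01", "manual", "manual01")]
        assert study.manifest["omitted"] == [list(omit[0])]

    def test_write_load_round_trip(self, tmp_path):
        spec = PhantomSpec(
            grid=ImageGrid((32, 32, 24), (2.0, 2.0, 2.0)),
            organs={
                "larynx": Ellipsoid((32.0, 32.0, 24.0), (8.0, 8.0, 8.0)),
                "spinal_cord": ZCylinder((32.0, 44.0), (4.0, 4.0), (10.0, 38.0)),
            },
        )
        obs = {"manual": [ObserverModel("manual", 1.0, seed=4)]}
        study = make_cohort(phantom=spec, observers=obs, n_patients=2, seed=4, out_dir=tmp_path / "study")
        back = load_study(tmp_path / "study")
        assert back.patients == study.patients
        assert back.organs == study.organs
        for pid in study.patients:
            for organ, mask in study.gt[pid].items():
                np.testing.assert_array_equal(back.gt[pid][organ].voxels, mask.voxels)
                assert back.gt[pid][organ].grid.compatible(mask.grid)
        key = ("P01", "manual", "manual01")
        for organ in study.masks[key]:
            np.testing.assert_array_equal(back.masks[key][organ].voxels, study.masks[key][organ].voxels)
        assert back.timing == study.timing
        np.testing.assert_allclose(back.dose["P01"].dose, study.dose["P01"].dose, rtol=1e-6)

    def test_default_observer_groups(self):
        models = default_observer_models(seed=0)
        assert [len(models[g]) for g in ("manual", "adjusted", "ai_only")] == [5, 3, 1]
        assert models["manual"][0].radial_sd_mm > models["adjusted"][0].radial_sd_mm
        assert models["adjusted"][0].radial_sd_mm >= models["ai_only"][0].radial_sd_mm
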