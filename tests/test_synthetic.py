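import numpy as np
import pandas as pd
import pytest

from magfiber import synthetic as syn
from magfiber.circstats import axial_vonmises_band_fraction
from magfiber.ellipse import Ellipse


# ------------------------------------------------------------- length models
def test_unmasked_model_calibrated_mean_and_support(rng):
    model = syn.unmasked_length_model()
    assert model.truncated_mean() == pytest.approx(225.0, abs=1e-6)
    x = model.sample(rng, 5000)
    assert x.min() >= 100.0 and x.max() <= 550.0
    assert x.mean() == pytest.approx(225.0, rel=0.05)


def test_masked_model_moments(rng):
    model = syn.MaskedLengthModel(90.0, 13.5)
    x = model.sample(rng, 5000)
    lo, hi = model.support
    assert x.min() >= lo and x.max() <= hi
    assert x.mean() == pytest.approx(90.0, rel=0.02)


# -------------------------------------------------------------- fiber scenes
def test_fiber_truth_angles_uniform_at_kappa_zero():
    spec = syn.FiberFieldSpec(n_fibers=300,
                              length_model=syn.MaskedLengthModel(60, 9),
                              orientation_kappa=0.0, seed=4)
    scene = syn.generate_fiber_image(spec)
    doubled = np.deg2rad(2 * scene.truth.angle_deg.to_numpy())
    r = np.hypot(np.cos(doubled).mean(), np.sin(doubled).mean())
    assert np.exp(-doubled.size * r * r) > 0.01   # Rayleigh test


def test_fiber_truth_angles_degenerate_at_large_kappa():
    spec = syn.FiberFieldSpec(n_fibers=100,
                              length_model=syn.MaskedLengthModel(60, 9),
                              orientation_kappa=1e6, seed=4)
    scene = syn.generate_fiber_image(spec)
    assert np.all(np.abs(scene.truth.angle_deg) <= 0.1)


def test_unmasked_scene_mean_length_near_225(rng):
    model = syn.unmasked_length_model()
    spec = syn.FiberFieldSpec(n_fibers=500, length_model=model,
                              orientation_kappa=4.0,
                              image_shape=(2400, 2400), seed=10)
    scene = syn.generate_fiber_image(spec)
    assert scene.truth.length_um.mean() == pytest.approx(225.0, rel=0.05)


def test_fiber_scene_seed_determinism(masked_model):
    spec = syn.FiberFieldSpec(n_fibers=40, length_model=masked_model,
                              orientation_kappa=2.0, seed=77)
    a = syn.generate_fiber_image(spec)
    b = syn.generate_fiber_image(spec)
    assert np.array_equal(a.image, b.image)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_fiber_truth_rasterizes_to_support(masked_model):
    """The truth table fully determines the noise-free support mask."""
    spec = syn.FiberFieldSpec(n_fibers=30, length_model=masked_model,
                              orientation_kappa=3.0, seed=5)
    scene = syn.generate_fiber_image(spec)
    redrawn = syn.rasterize_fiber_support(scene.truth, spec.image_shape,
                                          spec.pixel_size_um)
    assert np.array_equal(redrawn, scene.support)


def test_fiber_image_too_small_raises():
    with pytest.raises(ValueError, match="too small"):
        syn.FiberFieldSpec(n_fibers=10,
                           length_model=syn.unmasked_length_model(),
                           image_shape=(256, 256), seed=0)


# ----------------------------------------------------------- tenocyte scenes
def test_tenocyte_round_cells_flagged_isotropic():
    scene = syn.generate_tenocyte_image(20, 4.0, aspect_ratio=1.0, seed=1,
                                        image_shape=(800, 800))
    assert scene.truth.isotropic.all()
    assert scene.truth.angle_deg.isna().all()


def test_tenocyte_band_occupancy_matches_integral():
    """kappa=8 about 0 deg: at least 70% of axes within +/-30 deg (the
    analytic integral is ~0.99)."""
    scene = syn.generate_tenocyte_image(100, 8.0, aspect_ratio=4.0, seed=2)
    frac = np.mean(np.abs(scene.truth.angle_deg) <= 30.0)
    assert frac >= 0.70
    p = axial_vonmises_band_fraction(8.0, 30.0)
    assert frac == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / 100))


def test_tenocyte_determinism():
    a = syn.generate_tenocyte_image(30, 4.0, 4.0, seed=3,
                                    image_shape=(900, 900))
    b = syn.generate_tenocyte_image(30, 4.0, 4.0, seed=3,
                                    image_shape=(900, 900))
    assert np.array_equal(a.image, b.image)


def test_tenocyte_packing_failure_names_density():
    with pytest.raises(RuntimeError, match="packing"):
        syn.generate_tenocyte_image(500, 0.0, 6.0, seed=0,
                                    image_shape=(400, 400))


# ---------------------------------------------------------- viability scenes
@pytest.mark.parametrize("f,expected_dead", [(0.0, 0), (1.0, 400),
                                             (0.5, 200)])
def test_viability_truth_dead_counts_exact(f, expected_dead):
    scene = syn.generate_viability_image(400, f, seed=6)
    assert int(scene.truth.dead.sum()) == expected_dead


def test_viability_pi_channel_blank_when_all_alive():
    scene = syn.generate_viability_image(50, 0.0, seed=6,
                                        image_shape=(512, 512))
    # only background noise: nothing near full object intensity
    assert scene.pi.max() < 0.5


def test_viability_rejects_bad_fraction():
    with pytest.raises(ValueError, match="dead_fraction"):
        syn.generate_viability_image(10, 1.5, seed=0)


# ----------------------------------------------------------- spheroid scenes
def test_spheroid_spec_invariants_enforced():
    with pytest.raises(ValueError, match="single"):
        syn.OutgrowthSpec(syn.SINGLE, 0.0, 30.0, 3, gap_to_body_um=10.0)
    with pytest.raises(ValueError, match="single"):
        syn.OutgrowthSpec(syn.CLUSTER, 0.0, 50.0, 1, gap_to_body_um=10.0)
    with pytest.raises(ValueError, match="gap_to_body"):
        syn.OutgrowthSpec(syn.STRAND, 0.0, 50.0, 3, gap_to_body_um=10.0)
    with pytest.raises(ValueError, match="gap_to_body"):
        syn.OutgrowthSpec(syn.CLUSTER, 0.0, 50.0, 3, gap_to_body_um=0.0)


def test_spheroid_no_outgrowths_truth_zero():
    body = syn.BodySpec(256, 256, 70, 60, n_nuclei=30)
    scene = syn.generate_spheroid_scene(
        syn.SpheroidSceneSpec(body=body, image_shape=(512, 512), seed=2))
    assert scene.truth.totals["n_migratory_cells"] == 0
    assert scene.truth.totals["total_migration_distance_um"] == 0.0
    # actin support is exactly the body ellipse raster
    # support within the 1-px anti-aliased rim of the exact interior
    inflated = scene.truth.body.scaled(1.03).interior_mask((512, 512))
    assert not (scene.support_actin & ~inflated).any()
    assert scene.support_actin.sum() == pytest.approx(
        np.pi * 70 * 60, rel=0.02)


def test_spheroid_truth_composition(spheroid_scene):
    """2 strands + 1 cluster(3) + 1 single: truth bookkeeping is exact."""
    t = spheroid_scene.truth
    assert len(t.outgrowths) == 4
    assert t.totals["n_migratory_cells"] == 5 + 4 + 3 + 1
    strata = t.totals["by_contiguity"]
    assert strata["contiguous"]["n_migratory_cells"] == 9
    assert strata["disconnected"]["n_migratory_cells"] == 4
    # totals equal column sums; every nucleus appears exactly once
    mig = t.nuclei[t.nuclei.outgrowth >= 0]
    assert len(mig) == t.totals["n_migratory_cells"]
    assert mig.distance_um.sum() == pytest.approx(
        t.totals["total_migration_distance_um"])


def test_spheroid_disconnected_gap_respected(spheroid_scene):
    t = spheroid_scene.truth
    body = t.body
    for row in t.outgrowths.itertuples():
        mask = t.outgrowth_masks[row.outgrowth]
        ys, xs = np.nonzero(mask)
        d = body.distance(np.column_stack([xs, ys]))
        if row.contiguous:
            assert d.min() < 2.0
        else:
            assert d.min() >= 0.8 * row.gap_to_body_um


def test_spheroid_determinism(spheroid_scene):
    again = syn.generate_spheroid_scene(spheroid_scene.spec)
    assert np.array_equal(again.nuclei, spheroid_scene.nuclei)
    assert np.array_equal(again.actin, spheroid_scene.actin)
    pd.testing.assert_frame_equal(again.truth.nuclei,
                                  spheroid_scene.truth.nuclei)


def test_spheroid_out_of_bounds_raises():
    body = syn.BodySpec(128, 128, 70, 60, n_nuclei=10)
    og = syn.OutgrowthSpec(syn.STRAND, 0.0, 300.0, 3)
    with pytest.raises(ValueError, match="larger canvas"):
        syn.generate_spheroid_scene(
            syn.SpheroidSceneSpec(body=body, outgrowths=(og,),
                                  image_shape=(256, 256), seed=0))


def test_random_spec_directions_follow_requested_law():
    """Unconstrained direction sampling matches the axial integral."""
    dirs = []
    for i in range(80):
        spec = syn.random_spheroid_spec(seed=900 + i, direction_kappa=6.0,
                                        min_separation_deg=0.0)
        dirs += [o.direction_deg for o in spec.outgrowths]
    d = np.abs((np.array(dirs) + 180.0) % 360.0 - 180.0)
    axial = np.minimum(d, 180.0 - d)
    frac = np.mean(axial <= 30.0)
    p = axial_vonmises_band_fraction(6.0, 30.0)
    assert frac >= 0.60
    assert frac == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / len(dirs)))
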