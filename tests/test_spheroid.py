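import numpy as np
import pytest

from magfiber import spheroid as sph
from magfiber import synthetic as syn
from magfiber.ellipse import Ellipse
from magfiber.evaluation import PopulationScore, score_scene


@pytest.fixture(scope="module")
def analyzed(spheroid_scene):
    scene = spheroid_scene
    return sph.analyze_scene(scene.nuclei, scene.actin,
                             scene.spec.pixel_size_um)


# fixture defined at session level in conftest; re-export for module scope
@pytest.fixture(scope="module")
def spheroid_scene():
    body = syn.BodySpec(cx_px=384, cy_px=384, a_px=80, b_px=64, n_nuclei=50)
    outgrowths = (
        syn.OutgrowthSpec(syn.STRAND, 20.0, 120.0, 5),
        syn.OutgrowthSpec(syn.STRAND, 200.0, 90.0, 4),
        syn.OutgrowthSpec(syn.CLUSTER, 110.0, 60.0, 3, gap_to_body_um=25.0),
        syn.OutgrowthSpec(syn.SINGLE, 300.0, 22.0, 1, gap_to_body_um=40.0),
    )
    spec = syn.SpheroidSceneSpec(body=body, outgrowths=outgrowths, seed=9)
    return syn.generate_spheroid_scene(spec)


# -------------------------------------------------------------- projection
def test_project_single_plane_identity(rng):
    stack = rng.random((2, 1, 32, 32))
    out = sph.project_stack(stack)
    assert np.array_equal(out, stack[:, 0])


def test_project_union_of_disjoint_planes():
    stack = np.zeros((1, 2, 16, 16))
    stack[0, 0, 2, 2] = 1.0
    stack[0, 1, 10, 10] = 2.0
    out = sph.project_stack(stack)
    assert out[0, 2, 2] == 1.0 and out[0, 10, 10] == 2.0


def test_project_rejects_bad_shape():
    with pytest.raises(ValueError):
        sph.project_stack(np.zeros((2, 2, 2, 2, 2)))


# ------------------------------------------------------------ preprocessing
def test_preprocess_blank_image_empty_mask():
    assert not sph.preprocess_channel(np.zeros((64, 64)), 1.0).any()


def test_preprocess_size_filter():
    img = np.zeros((128, 128))
    img[10:13, 10:13] = 1.0            # ~9 um^2 speck at 1 um/px
    img[40:60, 40:60] = 1.0            # 400 um^2 object
    mask = sph.preprocess_channel(img, 1.0, min_object_area_um2=20.0)
    assert not mask[11, 11]
    assert mask[50, 50]


def test_preprocess_mask_overlaps_truth(spheroid_scene):
    scene = spheroid_scene
    mask = sph.preprocess_channel(scene.actin, 1.0)
    inter = (mask & scene.support_actin).sum()
    union = (mask | scene.support_actin).sum()
    assert inter / union >= 0.8


# ------------------------------------------------------------ body and ROI
def test_body_fit_close_to_truth(spheroid_scene):
    scene = spheroid_scene
    mask = sph.preprocess_channel(scene.actin, 1.0)
    body = sph.segment_body(mask, 1.0)
    truth = scene.truth.body
    assert np.hypot(body.cx - truth.cx, body.cy - truth.cy) < 5.0
    assert body.a == pytest.approx(truth.a, rel=0.10)
    assert body.b == pytest.approx(truth.b, rel=0.10)


def test_user_roi_returned_verbatim():
    roi = Ellipse(100, 100, 50, 40, 10.0)
    out = sph.segment_body(np.zeros((8, 8), bool), 1.0, user_roi=roi)
    assert out is roi


def test_no_body_raises():
    with pytest.raises(ValueError, match="no spheroid"):
        sph.segment_body(np.zeros((64, 64), bool), 1.0)


def test_two_bodies_largest_wins(caplog):
    mask = np.zeros((256, 256), bool)
    yy, xx = np.mgrid[0:256, 0:256]
    mask[(xx - 64) ** 2 + (yy - 64) ** 2 < 55 ** 2] = True
    mask[(xx - 190) ** 2 + (yy - 190) ** 2 < 45 ** 2] = True
    import logging
    with caplog.at_level(logging.WARNING, logger="magfiber.spheroid"):
        body = sph.segment_body(mask, 1.0)
    assert np.hypot(body.cx - 64, body.cy - 64) < 3.0
    assert any("largest" in r.message for r in caplog.records)


# -------------------------------------------------------------- outgrowths
def test_outgrowth_labels_and_contiguity(spheroid_scene, analyzed):
    truth = spheroid_scene.truth.outgrowths
    assert len(analyzed.outgrowths) == len(truth)
    assert sum(o.contiguous for o in analyzed.outgrowths) == \
        int(truth.contiguous.sum())


def test_touching_object_is_contiguous():
    body = Ellipse(64, 64, 30, 30)
    mask = body.interior_mask((128, 128))
    mask[64, 64:110] = True            # ray touching the ellipse
    labels, contig = sph.segment_outgrowths(mask, body)
    assert list(contig.values()) == [True]


def test_distant_object_is_not_contiguous():
    body = Ellipse(64, 64, 30, 30)
    mask = body.interior_mask((128, 128))
    mask[64, 108:120] = True           # 10+ px beyond the inflated ellipse
    labels, contig = sph.segment_outgrowths(mask, body)
    assert list(contig.values()) == [False]


# ------------------------------------------------------------------- nuclei
def test_overlapping_nuclei_are_split():
    img = np.zeros((64, 64))
    from magfiber import render
    render.draw_disk(img, (26, 32), 8.0)
    render.draw_disk(img, (38, 32), 8.0)    # ~30% area overlap
    centroids = sph.segment_nuclei(img > 0.5, nucleus_radius_px=8.0)
    assert centroids.shape[0] == 2


def test_isolated_nucleus_centroid_accurate():
    img = np.zeros((64, 64))
    from magfiber import render
    render.draw_disk(img, (40, 22), 6.0)
    centroids = sph.segment_nuclei(img > 0.5, nucleus_radius_px=6.0)
    assert centroids.shape[0] == 1
    assert np.hypot(centroids[0, 0] - 40, centroids[0, 1] - 22) < 2.0


def test_blank_mask_no_nuclei():
    assert sph.segment_nuclei(np.zeros((32, 32), bool), 5.0).shape == (0, 2)


# -------------------------------------------------------- classification
def test_phenotype_rules(analyzed, spheroid_scene):
    phenos = sorted(o.phenotype for o in analyzed.outgrowths)
    assert phenos == ["cluster", "single", "strand", "strand"]
    for o in analyzed.outgrowths:
        if o.contiguous:
            assert o.phenotype == "strand"
        elif o.n_nuclei == 1:
            assert o.phenotype == "single"
        else:
            assert o.phenotype == "cluster"


def test_nucleus_conservation(analyzed):
    assert analyzed.n_detected_nuclei == analyzed.n_body_nuclei + \
        analyzed.n_migratory_cells


# ------------------------------------------------------------------ metrics
def test_boundary_nucleus_distance_zero():
    body = Ellipse(64, 64, 30, 20)
    d = body.distance(np.array([[94.0, 64.0]]))
    assert d[0] == pytest.approx(0.0, abs=1e-3)


def test_migration_metrics_match_truth(analyzed, spheroid_scene):
    truth = spheroid_scene.truth
    mt = analyzed.totals()
    assert mt["n_migratory_cells"] == truth.totals["n_migratory_cells"]
    assert mt["total_migration_distance_um"] == pytest.approx(
        truth.totals["total_migration_distance_um"], rel=0.05)
    assert mt["max_invasion_depth_um"] == pytest.approx(
        truth.totals["max_invasion_depth_um"], rel=0.05)
    # stratified totals sum to overall totals
    c = analyzed.totals(contiguous=True)
    d = analyzed.totals(contiguous=False)
    assert c["n_migratory_cells"] + d["n_migratory_cells"] == \
        mt["n_migratory_cells"]
    assert c["total_migration_distance_um"] + \
        d["total_migration_distance_um"] == \
        pytest.approx(mt["total_migration_distance_um"])


def test_three_singles_distance_sum():
    """Disconnected singles at known depths: summed distance and max depth
    recovered within 5%."""
    body = syn.BodySpec(cx_px=300, cy_px=300, a_px=70, b_px=60, n_nuclei=40)
    outs = tuple(
        syn.OutgrowthSpec(syn.SINGLE, ang, 20.0, 1, gap_to_body_um=g)
        for ang, g in [(0.0, 40.0), (120.0, 70.0), (240.0, 110.0)])
    scene = syn.generate_spheroid_scene(
        syn.SpheroidSceneSpec(body=body, outgrowths=outs,
                              image_shape=(600, 600), seed=14))
    res = sph.analyze_scene(scene.nuclei, scene.actin, 1.0)
    d = res.totals(contiguous=False)
    t = scene.truth.totals["by_contiguity"]["disconnected"]
    assert d["total_migration_distance_um"] == pytest.approx(
        t["total_migration_distance_um"], rel=0.05)
    assert d["max_invasion_depth_um"] == pytest.approx(
        t["max_invasion_depth_um"], rel=0.05)


def test_metrics_pixel_size_consistency(spheroid_scene):
    """For fixed pixel geometry, all micron metrics scale linearly with
    the declared pixel size (areas quadratically)."""
    scene = spheroid_scene
    px = scene.spec.pixel_size_um
    nmask = sph.preprocess_channel(scene.nuclei, px, 20.0)
    amask = sph.preprocess_channel(scene.actin, px, 50.0)
    body = sph.segment_body(amask, px)
    labels, contiguous = sph.segment_outgrowths(amask, body)
    centroids = sph.segment_nuclei(nmask, 5.0 / px)
    records, _ = sph.classify_outgrowths(labels, contiguous, centroids, body)
    r1 = sph.migration_metrics(records, body, labels, px)
    records2, _ = sph.classify_outgrowths(labels, contiguous, centroids,
                                          body)
    r2 = sph.migration_metrics(records2, body, labels, 2.0 * px)
    assert r2.totals()["total_migration_distance_um"] == pytest.approx(
        2.0 * r1.totals()["total_migration_distance_um"])
    assert r2.totals()["max_invasion_depth_um"] == pytest.approx(
        2.0 * r1.totals()["max_invasion_depth_um"])
    assert sum(o.area_um2 for o in r2.outgrowths) == pytest.approx(
        4.0 * sum(o.area_um2 for o in r1.outgrowths))


# -------------------------------------------------------------- aggregation
def test_single_spheroid_heatmap_is_own_mask(analyzed):
    agg = sph.aggregate_population([analyzed])
    assert agg.heatmap.max() == 1
    assert agg.heatmap.sum() == analyzed.actin_mask.sum()
    assert agg.rose_counts.sum() == analyzed.n_migratory_cells


def test_heatmap_bounded_by_population_size(analyzed):
    agg = sph.aggregate_population([analyzed, analyzed, analyzed])
    assert agg.heatmap.max() == 3


# ------------------------------------------------------------------- export
def test_export_round_trip(tmp_path, analyzed):
    path = tmp_path / "out.csv"
    table = sph.export_results([analyzed], path, ["seed: 9"])
    back = sph.read_results(path)
    assert len(back) == len(table)
    body_rows = back[back.phenotype != "TOTAL"]
    total_rows = back[back.phenotype == "TOTAL"]
    assert total_rows.n_migratory_cells.iloc[0] == \
        body_rows.n_migratory_cells.sum()
    assert total_rows.total_migration_distance_um.iloc[0] == pytest.approx(
        body_rows.total_migration_distance_um.sum())


def test_export_zero_outgrowths(tmp_path):
    body = syn.BodySpec(256, 256, 70, 60, n_nuclei=30)
    scene = syn.generate_spheroid_scene(
        syn.SpheroidSceneSpec(body=body, image_shape=(512, 512), seed=2))
    res = sph.analyze_scene(scene.nuclei, scene.actin, 1.0)
    table = sph.export_results([res], tmp_path / "empty.csv")
    assert list(table.phenotype) == ["TOTAL"]


# ------------------------------------------------------------ discrimination
def test_disconnected_regime_discrimination():
    """Scenes rich in disconnected objects vs strand-only scenes: the
    pipeline's disconnected-stratum counts separate the regimes in every
    seeded replicate pair."""
    wins = 0
    reps = 8
    for i in range(reps):
        many = syn.random_spheroid_spec(seed=500 + i, n_strands=(1, 2),
                                        n_clusters=(2, 3), n_singles=(2, 3))
        none = syn.random_spheroid_spec(seed=700 + i, n_strands=(2, 4),
                                        n_clusters=(0, 0), n_singles=(0, 0))
        counts = []
        for spec in (many, none):
            scene = syn.generate_spheroid_scene(spec)
            res = sph.analyze_scene(scene.nuclei, scene.actin, 1.0)
            counts.append(res.totals(contiguous=False)["n_migratory_cells"])
        wins += counts[0] > counts[1]
    assert wins / reps >= 0.95
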