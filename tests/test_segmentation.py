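"""Cell/vacuole/particle segmentation against ground truth and oracles."""

import math

import numpy as np
import pytest
from skimage import measure

from hemoquant import synthetic as syn
from hemoquant.errors import ConfigError, EmptySceneError
from hemoquant.segmentation import (
    ParticleFilter,
    detect_particles,
    detect_vacuoles,
    max_project,
    mid_plane,
    segment_cell_body,
)
from hemoquant.stack import Calibration, ImageStack

from conftest import NOISE_FREE


# --------------------------------------------------------------------------
# cell body


def test_cell_recovery_noise_free():
    spec = syn.SceneSpec(a_radius_um=5.0, b_height_um=3.0, seed=0, **NOISE_FREE)
    stack, truth = syn.make_cell_scene(spec)
    cell = segment_cell_body(stack, 0)
    assert cell.a_um == pytest.approx(truth.cell_a_um, rel=0.02)
    assert abs(cell.b_um - truth.cell_b_um) <= spec.z_step_um
    assert cell.n_candidates == 1
    # area equals mask pixel count × pixel area by construction
    assert cell.area_um2 == pytest.approx(
        cell.mask2d.sum() * spec.pixel_size_um**2
    )


def test_blank_image_raises_empty_scene(calib):
    stack = ImageStack(np.zeros((2, 4, 16, 16), np.float32), calib)
    with pytest.raises(EmptySceneError):
        segment_cell_body(stack, 0)


def test_two_cells_returns_larger_and_reports_candidates(calib):
    vol = np.zeros((2, 6, 64, 64), np.float32)
    vol[0, 2:5, 10:30, 10:30] = 100.0  # big cell
    vol[0, 2:4, 40:50, 40:50] = 100.0  # small cell
    stack = ImageStack(vol, calib)
    cell = segment_cell_body(stack, 0)
    assert cell.n_candidates == 2
    assert cell.mask2d[20, 20] and not cell.mask2d[45, 45]


# --------------------------------------------------------------------------
# vacuoles


def _scene_with_vacuole(r, seed=0, min_radius=1.5):
    spec = syn.SceneSpec(
        a_radius_um=5.0,
        b_height_um=3.0,
        vacuoles=[((0.0, 0.3, -0.2), r)],
        seed=seed,
        **NOISE_FREE,
    )
    stack, truth = syn.make_cell_scene(spec)
    cell = segment_cell_body(stack, 0)
    return detect_vacuoles(stack, cell, min_radius_um=min_radius), truth


def test_vacuole_radius_recovered_within_half_voxel():
    vacs, truth = _scene_with_vacuole(2.0)
    assert len(vacs) == 1
    assert abs(vacs.vacuoles[0].radius_um - 2.0) <= 0.05  # half an x-y voxel


def test_small_vacuole_excluded_by_radius_threshold():
    vacs, _ = _scene_with_vacuole(1.0, min_radius=1.5)
    assert len(vacs) == 0


def test_vacuole_free_cell_gives_empty_set():
    spec = syn.SceneSpec(seed=3, **NOISE_FREE)
    stack, _ = syn.make_cell_scene(spec)
    cell = segment_cell_body(stack, 0)
    assert len(detect_vacuoles(stack, cell)) == 0


def test_vacuole_detection_perfect_precision_recall_over_seeds():
    # noise-free scenes: every truth vacuole above threshold found, nothing else
    for seed in range(5):
        rng = np.random.default_rng(seed)
        vac = [
            ((0.0, 1.6, 1.6), float(rng.uniform(1.7, 2.2))),
            ((0.0, -1.6, -1.6), float(rng.uniform(1.7, 2.2))),
        ]
        spec = syn.SceneSpec(
            a_radius_um=5.0, b_height_um=3.0, vacuoles=vac, seed=seed, **NOISE_FREE
        )
        stack, truth = syn.make_cell_scene(spec)
        cell = segment_cell_body(stack, 0)
        vacs = detect_vacuoles(stack, cell)
        assert sorted(vacs.radii_um) == pytest.approx(
            sorted(truth.vacuole_radii_um), abs=0.06
        )


# --------------------------------------------------------------------------
# particles


def test_particle_area_filter_counts_blobs(calib):
    img = np.zeros((40, 40))
    img[5:7, 5:10] = 1.0  # 10 px²
    img[20:26, 20:25] = 1.0  # 30 px²
    ps = detect_particles(img, ParticleFilter(min_area=20, unit="px2"), calib)
    assert len(ps) == 1
    assert ps.particles[0].area_px == 30


def test_blank_image_gives_no_particles(calib):
    assert len(detect_particles(np.zeros((20, 20)), ParticleFilter(), calib)) == 0


def test_line_blob_fails_circularity_filter(calib):
    img = np.zeros((10, 40))
    img[5, 5:35] = 1.0  # 1×30 line: 4πA/P² far below 0.3
    filt = ParticleFilter(min_area=1, circularity_lo=0.3)
    assert len(detect_particles(img, filt, calib)) == 0
    # same blob passes with the full circularity range
    assert len(detect_particles(img, ParticleFilter(min_area=1), calib)) == 1


def test_particle_measures_invariant_to_positive_gain(calib):
    rng = np.random.default_rng(0)
    img = np.zeros((64, 64))
    for y, x in rng.integers(8, 56, size=(5, 2)):
        img[y - 3 : y + 3, x - 3 : x + 3] = rng.uniform(50, 150)
    ps1 = detect_particles(img, ParticleFilter(min_area=4), calib)
    ps2 = detect_particles(img * 7.3, ParticleFilter(min_area=4), calib)
    assert [p.area_px for p in ps1.particles] == [p.area_px for p in ps2.particles]


def test_particle_sanity_bounds(calib):
    rng = np.random.default_rng(1)
    img = rng.normal(size=(48, 48)) + 5.0 * (rng.uniform(size=(48, 48)) > 0.9)
    ps = detect_particles(img, ParticleFilter(min_area=1), calib)
    assert ps.total_area_um2 <= 48 * 48 * calib.pixel_area_um2
    for p in ps.particles:
        assert 0 <= p.centroid_px[0] < 48 and 0 <= p.centroid_px[1] < 48
        assert 0 <= p.circularity <= 1


def _flood_fill_labels(binary: np.ndarray) -> int:
    """Brute-force 8-connectivity component count (independent oracle)."""
    todo = {(y, x) for y, x in zip(*np.nonzero(binary))}
    n = 0
    while todo:
        n += 1
        stack = [todo.pop()]
        while stack:
            y, x = stack.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    nb = (y + dy, x + dx)
                    if nb in todo:
                        todo.remove(nb)
                        stack.append(nb)
    return n


@pytest.mark.parametrize("seed", range(8))
def test_component_labelling_matches_flood_fill_oracle(seed):
    rng = np.random.default_rng(seed)
    binary = rng.uniform(size=(24, 24)) > 0.7
    assert measure.label(binary, connectivity=2).max() == _flood_fill_labels(binary)


# --------------------------------------------------------------------------
# projections


def test_projection_and_mid_plane(calib):
    rng = np.random.default_rng(0)
    vol = rng.uniform(size=(1, 5, 12, 12)).astype(np.float32)
    stack = ImageStack(vol, calib)
    proj = max_project(stack, 0)
    # projection dominates every plane pixelwise
    for z in range(5):
        assert (proj >= vol[0, z]).all()
        np.testing.assert_array_equal(mid_plane(stack, 0, z), vol[0, z])
    with pytest.raises(IndexError):
        mid_plane(stack, 0, 5)

    const = ImageStack(np.full((1, 3, 4, 4), 7.0, np.float32), calib)
    assert (max_project(const, 0) == 7.0).all()

    onebright = np.zeros((1, 3, 8, 8), np.float32)
    onebright[0, 1, 2, 6] = 9.0
    st = ImageStack(onebright, calib)
    assert max_project(st, 0)[2, 6] == 9.0
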