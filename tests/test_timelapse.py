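"""Time-lapse phagosome scoring: docking, intensity, prevalence, spot counts."""

import numpy as np
import pytest

from hemoquant import synthetic as syn
from hemoquant.errors import ConfigError
from hemoquant.segmentation import segment_cell_body
from hemoquant.stack import Calibration, ImageStack
from hemoquant.timelapse import (
    RoiSpec,
    annulus_coverage,
    build_track,
    count_spots_in_cell,
    detect_docking,
    fyve_prevalence,
    intensity_series,
)

from conftest import NOISE_FREE


@pytest.fixture(scope="module")
def clean_movie():
    spec = syn.TimelapseSpec(
        seed=5, dwell_mean_min=20.0, dwell_sd_min=0.0, docking_frame=5, **NOISE_FREE
    )
    movie, truth = syn.make_timelapse(spec)
    cell = segment_cell_body(movie, 0, t=0)
    return spec, movie, truth, cell


def test_docking_frame_matches_truth(clean_movie):
    spec, movie, truth, cell = clean_movie
    assert detect_docking(movie, 1, cell) == truth.docking_frame == 5


def test_docking_from_frame_zero():
    spec = syn.TimelapseSpec(seed=1, docking_frame=0, n_frames=6, dwell_mean_min=4,
                             dwell_sd_min=0, **NOISE_FREE)
    movie, _ = syn.make_timelapse(spec)
    cell = segment_cell_body(movie, 0, t=0)
    assert detect_docking(movie, 1, cell) == 0


def test_never_docking_flagged_not_raised(calib):
    # particle far from the cell in every frame
    vol = np.zeros((2, 4, 3, 48, 48), np.float32)
    vol[0, :, 1, 8:20, 8:20] = 50.0  # static cell
    vol[1, :, 1, 38:42, 38:42] = 80.0  # particle never touching
    movie = ImageStack(vol, Calibration(0.1, 0.5, frame_interval_s=120))
    cell = segment_cell_body(movie, 0, t=0)
    track = build_track(movie, 1, cell)
    assert track.t0 is None and not track.docked
    with pytest.raises(ConfigError):
        intensity_series(movie, track)


def test_intensity_series_tracks_generator_ramp(clean_movie):
    spec, movie, truth, cell = clean_movie
    track = build_track(movie, 1, cell)
    series = intensity_series(movie, track)
    ramp = spec.ramp(series.times_min)
    np.testing.assert_allclose(series.values, ramp, rtol=0.01)
    # non-decreasing after t0 on a noise-free ramp
    assert (np.diff(series.values) >= -1e-6).all()
    assert not series.clipped.any()


def test_roi_per_pixel_value_independent_of_roi_size(calib):
    vol = np.full((2, 3, 4, 32, 32), 13.0, np.float32)
    movie = ImageStack(vol, Calibration(0.1, 0.5, frame_interval_s=120))
    from hemoquant.timelapse import Track

    track = Track("p", t0=0, centroids_px=np.tile([2.0, 16.0, 16.0], (3, 1)),
                  frame_interval_s=120)
    small = intensity_series(movie, track, RoiSpec(area_um2=0.9))
    large = intensity_series(movie, track, RoiSpec(area_um2=3.6))
    np.testing.assert_allclose(small.values, 13.0)
    np.testing.assert_allclose(small.values, large.values)


def test_prevalence_exact_bookkeeping(clean_movie):
    spec, movie, truth, cell = clean_movie
    track = build_track(movie, 1, cell)
    prev = fyve_prevalence(movie, track, cell=cell)
    assert prev.positive_frames == truth.dwell_frames == 10
    assert prev.prevalence_min == pytest.approx(20.0)
    # prevalence_minutes × 60 / interval is exactly the positive-frame count
    assert prev.prevalence_min * 60 / prev.frame_interval_s == prev.positive_frames


def test_prevalence_zero_on_blank_fyve_channel(clean_movie):
    spec, movie, truth, cell = clean_movie
    blank = ImageStack(
        np.stack([np.zeros_like(movie.data[0]), movie.data[1]]),
        movie.calibration,
    )
    track = build_track(blank, 1, cell)
    prev = fyve_prevalence(blank, track, cell=cell)
    assert prev.positive_frames == 0 and prev.prevalence_min == 0.0


def test_annulus_coverage_criterion_threshold():
    # half-coated particle: coverage 0.6 → positive at 0.5, negative at 0.9
    pmask = np.zeros((21, 21), bool)
    yy, xx = np.mgrid[:21, :21]
    pmask[(yy - 10) ** 2 + (xx - 10) ** 2 <= 36] = True
    annulus_px = np.argwhere(
        ~pmask & ((yy - 10) ** 2 + (xx - 10) ** 2 <= 64)
    )
    fyve = np.zeros((21, 21), bool)
    # coat the top 60% of the surroundings
    order = np.argsort(annulus_px[:, 0])
    take = annulus_px[order][: int(0.65 * len(annulus_px))]
    fyve[take[:, 0], take[:, 1]] = True
    cov = annulus_coverage(pmask, fyve)
    assert 0.5 <= cov < 0.9


def test_prevalence_parameter_recovery_small_sweep():
    # dwell recovered exactly per movie on clean data
    for seed in range(3):
        spec = syn.TimelapseSpec(seed=seed, dwell_mean_min=16.0, dwell_sd_min=4.0,
                                 **NOISE_FREE)
        movie, truth = syn.make_timelapse(spec)
        cell = segment_cell_body(movie, 0, t=0)
        track = build_track(movie, 1, cell)
        prev = fyve_prevalence(movie, track, cell=cell)
        assert prev.positive_frames == truth.dwell_frames


def test_group_contrast_long_vs_short_dwell():
    from scipy import stats as ss

    def prevalences(mean, seeds):
        out = []
        for s in seeds:
            spec = syn.TimelapseSpec(seed=s, dwell_mean_min=mean, dwell_sd_min=4.0,
                                     n_frames=30)
            movie, _ = syn.make_timelapse(spec)
            cell = segment_cell_body(movie, 0, t=0)
            track = build_track(movie, 1, cell)
            out.append(fyve_prevalence(movie, track, cell=cell).prevalence_min)
        return out

    short = prevalences(8.0, range(8))
    long = prevalences(24.0, range(100, 108))
    t, p = ss.ttest_ind(long, short, alternative="greater")
    assert p < 0.05


# --------------------------------------------------------------------------
# spot counting


def test_count_spots_inside_cell_only():
    inside = [(0.0, 1.5, 1.5), (0.5, -1.5, 0.0), (-0.5, 0.0, -2.0),
              (0.0, 2.0, -1.0), (0.3, -1.0, 2.0)]
    outside = [(0.0, 5.8, 0.0), (0.0, -5.8, 1.0), (0.0, 0.0, 5.8)]
    ves = [syn.VesicleSpec(center_um=c, diameter_um=0.8, intensity=200)
           for c in inside + outside]
    spec = syn.SceneSpec(a_radius_um=5.0, b_height_um=2.5, vesicles=ves, seed=3)
    stack, _ = syn.make_cell_scene(spec)
    cell = segment_cell_body(stack, 0)
    res = count_spots_in_cell(stack, 1, cell)
    assert res.count == 5
    assert res.n_components >= 8


def test_count_spots_blank_channel(noise_free_scene):
    stack, _ = noise_free_scene
    blank = ImageStack(
        np.stack([stack.data[0], np.zeros_like(stack.data[1])]), stack.calibration
    )
    cell = segment_cell_body(blank, 0)
    assert count_spots_in_cell(blank, 1, cell).count == 0


def test_merged_spots_undercount_and_flag():
    # two spots closer than the blur scale merge into one oversized component
    near = [(0.0, 0.0, -0.45), (0.0, 0.0, 0.45)]
    far = [(0.0, 2.0, 0.0), (0.0, -2.0, 0.0), (0.0, 0.0, 2.5)]
    ves = [syn.VesicleSpec(center_um=c, diameter_um=0.9, intensity=200)
           for c in near + far]
    spec = syn.SceneSpec(a_radius_um=5.0, b_height_um=2.5, vesicles=ves, seed=4,
                         blur_sigma_um=0.15)
    stack, _ = syn.make_cell_scene(spec)
    cell = segment_cell_body(stack, 0)
    res = count_spots_in_cell(stack, 1, cell)
    assert res.count <= 5
    assert res.count == 4 and res.n_oversized == 1
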