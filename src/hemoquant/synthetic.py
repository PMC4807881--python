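"""Ground-truthed synthetic data for every assay in the package.

No raw micrographs accompany the study design this package automates, so
each quantification stage is exercised on simulated inputs whose ground
truth is known analytically. The generators here emulate:

* 2-channel hemocyte z-stacks — a cytoskeleton channel rendered as an
  oblate-ellipsoid cell (equatorial semi-axis ``a``, axial semi-axis
  ``b``) with zero-intensity spherical voids at vacuole sites, and a
  vesicle channel with filled or ring-shaped puncta;
* 2-channel colocalization scenes with a controlled Pearson correlation,
  achieved by mixing puncta shared between channels with channel-private
  puncta;
* phagocytosis time-lapses — a pHrodo-style particle whose intensity
  follows a logistic ramp after docking into the cell, with a FYVE-coat
  ring present for a sampled dwell time;
* per-fly death-day tables (discretized Weibull lifespans) and Poisson
  colony counts across serial dilutions.

The forward imaging model is deliberately simple: ideal geometry →
Gaussian blur → signal-dependent Poisson (shot) noise → additive Gaussian
read noise. All parameters live on the spec dataclasses so tests can turn
noise off. Identical spec + seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special, stats

from .errors import ConfigError, GeometryError
from .stack import Calibration, ImageStack

__all__ = [
    "VesicleSpec",
    "SceneSpec",
    "TimelapseSpec",
    "LifespanModel",
    "ColonyModel",
    "CohortGroup",
    "CohortSpec",
    "SceneTruth",
    "make_cell_scene",
    "make_coloc_scene",
    "make_timelapse",
    "make_survival_cohort",
    "make_dilution_counts",
    "save_truth",
]


# --------------------------------------------------------------------------
# Specs


@dataclass
class VesicleSpec:
    """One rendered vesicle in the vesicle channel.

    ``center_um`` is a (z, y, x) offset from the cell centre in µm.
    ``ring=True`` renders a spherical shell of ``thickness_um`` (the
    membrane-reporter look); otherwise the sphere is filled.
    """

    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    diameter_um: float = 1.0
    ring: bool = False
    thickness_um: float = 0.3
    intensity: float = 150.0
    channel: int = 1


@dataclass
class SceneSpec:
    """Geometry, optics and noise for one 2-channel hemocyte z-stack.

    The cell is an oblate ellipsoid with equatorial semi-axis
    ``a_radius_um`` and axial semi-axis ``b_height_um`` (the "radius" and
    "height" of the ellipsoid volume formulas in :mod:`hemoquant.morphometry`),
    centred in the image. Vacuoles are spheres of zero intensity punched
    into the cytoskeleton channel (channel 0); vesicles render into
    channel 1. Lateral sampling defaults to 0.1 µm/px and the z step to
    0.5 µm, the lower end of typical live-cell confocal sectioning.
    """

    shape: tuple[int, int, int] = (16, 128, 128)  # (z, y, x)
    pixel_size_um: float = 0.1
    z_step_um: float = 0.5
    a_radius_um: float = 5.0
    b_height_um: float = 3.0
    # list of ((z, y, x) offset from cell centre in µm, radius µm)
    vacuoles: list[tuple[tuple[float, float, float], float]] = field(
        default_factory=list
    )
    vesicles: list[VesicleSpec] = field(default_factory=list)
    background: float = 2.0
    cyto_intensity: float = 100.0
    shot_noise_scale: float = 1.0  # detected counts per intensity unit; 0 = off
    read_noise_sd: float = 1.0  # additive Gaussian sd; 0 = off
    blur_sigma_um: float = 0.1  # Gaussian blur sd; 0 = off
    seed: int = 0

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size_um, self.z_step_um)

    def validate(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ConfigError(f"shape must be positive, got {self.shape}")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ConfigError("voxel sizes must be > 0")
        if self.a_radius_um <= 0 or self.b_height_um <= 0:
            raise ConfigError("cell semi-axes must be > 0")
        for center, r in self.vacuoles:
            if r <= 0:
                raise GeometryError(f"vacuole radius must be > 0, got {r}")
            az = self.b_height_um - r
            axy = self.a_radius_um - r
            if az <= 0 or axy <= 0:
                raise GeometryError(
                    f"vacuole r={r} µm cannot fit inside cell "
                    f"(a={self.a_radius_um}, b={self.b_height_um})"
                )
            cz, cy, cx = center
            # sufficient (conservative) condition for full containment
            if (cy**2 + cx**2) / axy**2 + cz**2 / az**2 > 1.0:
                raise GeometryError(
                    f"vacuole at {center} r={r} extends outside the cell ellipsoid"
                )
        for v in self.vesicles:
            if v.diameter_um <= 0:
                raise GeometryError("vesicle diameter must be > 0")


@dataclass
class TimelapseSpec:
    """One simulated phagocytosis movie (2 channels: FYVE, pHrodo particle).

    The particle sits outside the cell until ``docking_frame`` (the ground
    truth t0), then inside it; its intensity follows a logistic ramp from
    ``ramp_baseline`` to ``ramp_plateau`` in time since docking, emulating
    pH-sensitive dye brightening as the phagosome acidifies. A FYVE ring
    (spherical shell) coats the particle from docking for a dwell time
    drawn from a truncated normal (minutes). Frames default to one every
    120 s over 90 minutes, within the 90–120 s acquisition range the
    assay uses.
    """

    shape: tuple[int, int, int] = (12, 96, 144)
    pixel_size_um: float = 0.1
    z_step_um: float = 0.5
    frame_interval_s: float = 120.0
    n_frames: int = 45
    a_radius_um: float = 4.0
    b_height_um: float = 2.5
    particle_diameter_um: float = 2.0
    docking_frame: int = 5
    dwell_family: str = "truncnorm"  # or "fixed"
    dwell_mean_min: float = 20.0
    dwell_sd_min: float = 5.0
    ramp_baseline: float = 10.0
    ramp_plateau: float = 100.0
    ramp_half_rise_min: float = 10.0
    ramp_slope_min: float = 2.5  # logistic time constant tau (min)
    ring_thickness_um: float = 0.3
    fyve_ring_intensity: float = 150.0
    cyto_intensity: float = 20.0  # diffuse cytosolic FYVE reporter signal
    background: float = 0.0
    shot_noise_scale: float = 1.0
    read_noise_sd: float = 1.0
    blur_sigma_um: float = 0.1
    seed: int = 0

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size_um, self.z_step_um, self.frame_interval_s)

    def validate(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ConfigError(f"shape must be positive, got {self.shape}")
        if self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be > 0")
        if not 0 <= self.docking_frame < self.n_frames:
            raise ConfigError(
                f"docking_frame {self.docking_frame} must lie in [0, {self.n_frames})"
            )
        if self.dwell_mean_min <= 0:
            raise ConfigError("dwell_mean_min must be > 0")
        if self.particle_diameter_um <= 0:
            raise ConfigError("particle_diameter_um must be > 0")

    def ramp(self, minutes_since_docking: np.ndarray | float) -> np.ndarray | float:
        """Logistic pHrodo intensity ramp, evaluated at minutes after t0."""
        t = np.asarray(minutes_since_docking, dtype=float)
        lo, hi = self.ramp_baseline, self.ramp_plateau
        out = lo + (hi - lo) * special.expit(
            (t - self.ramp_half_rise_min) / self.ramp_slope_min
        )
        return float(out) if np.isscalar(minutes_since_docking) else out


@dataclass
class LifespanModel:
    """Death-day distribution for one cohort group.

    ``weibull`` draws continuous Weibull lifetimes parameterized by their
    median and target standard deviation (``dispersion_days``), then
    rounds up to whole days — flies are scored daily, so death days are
    integers. ``dispersion_days=0`` (or family ``fixed``) is a point mass
    at the median.
    """

    median_days: float = 23.0
    dispersion_days: float = 6.0
    family: str = "weibull"  # or "fixed"

    def validate(self) -> None:
        if self.median_days <= 0:
            raise ConfigError("median_days must be > 0")
        if self.dispersion_days < 0:
            raise ConfigError("dispersion_days must be >= 0")
        if self.family not in ("weibull", "fixed"):
            raise ConfigError(f"unknown lifespan family {self.family!r}")


@dataclass
class ColonyModel:
    """Colony-count model for the endogenous bacterial content assay.

    Each individual carries ``true_cfu`` viable bacteria; a homogenate
    aliquot of ``sampling_fraction`` is plated at each dilution and the
    spot count is Poisson with mean ``true_cfu × fraction / dilution``.
    """

    true_cfu: float = 1000.0
    dilution_factors: tuple[float, ...] = (1.0, 10.0)
    sampling_fraction: float = 0.1

    def validate(self) -> None:
        if self.true_cfu < 0:
            raise ConfigError("true_cfu must be >= 0")
        if any(d < 1 for d in self.dilution_factors):
            raise ConfigError("dilution factors must be >= 1")
        if not 0 < self.sampling_fraction <= 1:
            raise ConfigError("sampling_fraction must be in (0, 1]")


@dataclass
class CohortGroup:
    name: str
    n_individuals: int = 50
    n_replicates: int = 5
    lifespan: LifespanModel | None = None
    colony: ColonyModel | None = None

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigError(f"group {self.name!r}: n_individuals must be > 0")
        if self.n_replicates <= 0:
            raise ConfigError(f"group {self.name!r}: n_replicates must be > 0")
        if self.lifespan is not None:
            self.lifespan.validate()
        if self.colony is not None:
            self.colony.validate()


@dataclass
class CohortSpec:
    groups: list[CohortGroup] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("cohort needs at least one group")
        for g in self.groups:
            g.validate()


@dataclass
class SceneTruth:
    """Ground truth emitted alongside each simulated stack."""

    cytoplasm_volume_um3: float | None = None  # 4/3·π·a²·b of the rendered solid
    cytoplasm_volume_as_printed_um3: float | None = None  # 4/3·π·a·b²
    cell_a_um: float | None = None
    cell_b_um: float | None = None
    vacuole_radii_um: list[float] = field(default_factory=list)
    vacuole_volumes_um3: list[float] = field(default_factory=list)
    vesicle_diameters_um: list[float] = field(default_factory=list)
    realized_correlation: float | None = None
    docking_frame: int | None = None
    dwell_min: float | None = None
    dwell_frames: int | None = None
    dwell_truncated: bool = False
    particle_diameter_um: float | None = None
    frame_interval_s: float | None = None
    seed: int | None = None


def save_truth(truth: SceneTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=1, default=float))


# --------------------------------------------------------------------------
# Rendering helpers


def _grids_um(
    shape: tuple[int, int, int], pixel: float, zstep: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinate grids in µm relative to the image centre."""
    nz, ny, nx = shape
    zz = (np.arange(nz) - (nz - 1) / 2.0) * zstep
    yy = (np.arange(ny) - (ny - 1) / 2.0) * pixel
    xx = (np.arange(nx) - (nx - 1) / 2.0) * pixel
    return (
        zz[:, None, None],
        yy[None, :, None],
        xx[None, None, :],
    )


def _sphere_dist2(zz, yy, xx, center_um):
    cz, cy, cx = center_um
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2


def _finalize(
    img: np.ndarray,
    pixel: float,
    zstep: float,
    blur_sigma_um: float,
    shot_scale: float,
    read_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blur → shot noise → read noise, in place of full PSF physics."""
    out = img.astype(np.float64, copy=True)
    if blur_sigma_um > 0:
        out = ndimage.gaussian_filter(
            out, sigma=(blur_sigma_um / zstep, blur_sigma_um / pixel, blur_sigma_um / pixel)
        )
    if shot_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * shot_scale) / shot_scale
    if read_sd > 0:
        out = out + rng.normal(0.0, read_sd, size=out.shape)
    return out.astype(np.float32)


def _render_ellipsoid(zz, yy, xx, a: float, b: float) -> np.ndarray:
    return (yy**2 + xx**2) / a**2 + zz**2 / b**2 <= 1.0


# --------------------------------------------------------------------------
# Generators


def make_cell_scene(spec: SceneSpec) -> tuple[ImageStack, SceneTruth]:
    """Render a 2-channel hemocyte z-stack with its analytic ground truth.

    Channel 0 is the cytoskeleton: uniform ``cyto_intensity`` inside the
    cell ellipsoid, ``background`` outside, and exactly zero inside each
    vacuole sphere (vacuoles are voids that disrupt the cytoskeleton).
    Channel 1 carries the vesicles. In the noise-free, blur-free limit a
    truth vacuole of radius r spans 2r/pixel ± 1 pixels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    zz, yy, xx = _grids_um(spec.shape, spec.pixel_size_um, spec.z_step_um)

    cell = _render_ellipsoid(zz, yy, xx, spec.a_radius_um, spec.b_height_um)
    ch0 = np.where(cell, spec.cyto_intensity, spec.background)
    for center, r in spec.vacuoles:
        ch0[_sphere_dist2(zz, yy, xx, center) <= r**2] = 0.0

    ch1 = np.full(spec.shape, spec.background, dtype=np.float64)
    for v in spec.vesicles:
        d2 = _sphere_dist2(zz, yy, xx, v.center_um)
        r_out = v.diameter_um / 2.0
        if v.ring:
            r_in = max(r_out - v.thickness_um, 0.0)
            sel = (d2 <= r_out**2) & (d2 > r_in**2)
        else:
            sel = d2 <= r_out**2
        ch1[sel] = v.intensity

    args = (
        spec.pixel_size_um,
        spec.z_step_um,
        spec.blur_sigma_um,
        spec.shot_noise_scale,
        spec.read_noise_sd,
        rng,
    )
    data = np.stack([_finalize(ch0, *args), _finalize(ch1, *args)])
    stack = ImageStack(data=data, calibration=spec.calibration, axes="CZYX")

    a, b = spec.a_radius_um, spec.b_height_um
    truth = SceneTruth(
        cytoplasm_volume_um3=4.0 / 3.0 * math.pi * a**2 * b,
        cytoplasm_volume_as_printed_um3=4.0 / 3.0 * math.pi * a * b**2,
        cell_a_um=a,
        cell_b_um=b,
        vacuole_radii_um=[r for _, r in spec.vacuoles],
        vacuole_volumes_um3=[4.0 / 3.0 * math.pi * r**3 for _, r in spec.vacuoles],
        vesicle_diameters_um=[v.diameter_um for v in spec.vesicles],
        seed=spec.seed,
    )
    return stack, truth


def make_coloc_scene(
    n_puncta: int,
    rho_target: float,
    spec: SceneSpec,
    puncta_diameter_um: float = 0.4,
    cell_fill_intensity: float = 30.0,
) -> tuple[ImageStack, SceneTruth]:
    """Render a 2-channel scene whose within-cell Pearson r tracks a target.

    Correlation is controlled by composition: ``round(|rho|·n)`` puncta are
    shared between channels (identical position and intensity) and the
    remainder are drawn independently per channel, so the expected
    within-mask correlation is approximately ``|rho|``; negative targets
    invert channel 1 inside the cell mask. Both channels carry a constant
    dim cytoplasmic fill inside the cell so the scene is segmentable — a
    constant offset within the mask leaves the correlation unchanged.
    The truth records the realized correlation of the final voxel data.
    ``|error|`` shrinks as ``n_puncta`` grows.
    """
    spec.validate()
    if not -1.0 <= rho_target <= 1.0:
        raise ConfigError(f"rho_target must be in [-1, 1], got {rho_target}")
    if n_puncta < 1:
        raise ConfigError(
            f"rho {rho_target} is unreachable with n_puncta={n_puncta}; need >= 1"
        )
    rng = np.random.default_rng(spec.seed)
    zz, yy, xx = _grids_um(spec.shape, spec.pixel_size_um, spec.z_step_um)
    cell = _render_ellipsoid(zz, yy, xx, spec.a_radius_um, spec.b_height_um)

    def sample_centers(k: int) -> np.ndarray:
        """Uniform positions inside the (slightly shrunken) cell ellipsoid."""
        out = np.empty((k, 3))
        a = 0.85 * spec.a_radius_um
        b = 0.85 * spec.b_height_um
        got = 0
        while got < k:
            cand = rng.uniform(-1, 1, size=(2 * (k - got) + 8, 3))
            keep = (cand**2).sum(axis=1) <= 1.0
            cand = cand[keep][: k - got]
            out[got : got + len(cand)] = cand * [b, a, a]
            got += len(cand)
        return out

    def paint(img: np.ndarray, centers: np.ndarray, intensities: np.ndarray) -> None:
        r2 = (puncta_diameter_um / 2.0) ** 2
        for c, inten in zip(centers, intensities):
            img[_sphere_dist2(zz, yy, xx, c) <= r2] += inten

    n_shared = int(round(abs(rho_target) * n_puncta))
    n_priv = n_puncta - n_shared
    ch_a = np.zeros(spec.shape, dtype=np.float64)
    ch_b = np.zeros(spec.shape, dtype=np.float64)

    shared_c = sample_centers(n_shared)
    shared_i = rng.uniform(80.0, 160.0, size=n_shared)
    paint(ch_a, shared_c, shared_i)
    paint(ch_b, shared_c, shared_i)
    paint(ch_a, sample_centers(n_priv), rng.uniform(80.0, 160.0, size=n_priv))
    paint(ch_b, sample_centers(n_priv), rng.uniform(80.0, 160.0, size=n_priv))

    if rho_target < 0:
        # invert channel 1 inside the mask; outside stays background
        top = ch_b[cell].max() if cell.any() else 0.0
        ch_b = np.where(cell, top - ch_b, 0.0)

    # constant cytoplasmic fill: makes the cell segmentable without
    # changing the within-mask correlation
    ch_a[cell] += cell_fill_intensity
    ch_b[cell] += cell_fill_intensity
    ch_a += spec.background
    ch_b += spec.background

    args = (
        spec.pixel_size_um,
        spec.z_step_um,
        spec.blur_sigma_um,
        spec.shot_noise_scale,
        spec.read_noise_sd,
        rng,
    )
    data = np.stack([_finalize(ch_a, *args), _finalize(ch_b, *args)])
    stack = ImageStack(data=data, calibration=spec.calibration, axes="CZYX")

    va = data[0][cell].astype(np.float64)
    vb = data[1][cell].astype(np.float64)
    if va.std() == 0 or vb.std() == 0:
        realized = float("nan")
    else:
        realized = float(np.corrcoef(va, vb)[0, 1])

    a, b = spec.a_radius_um, spec.b_height_um
    truth = SceneTruth(
        cytoplasm_volume_um3=4.0 / 3.0 * math.pi * a**2 * b,
        cytoplasm_volume_as_printed_um3=4.0 / 3.0 * math.pi * a * b**2,
        cell_a_um=a,
        cell_b_um=b,
        realized_correlation=realized,
        seed=spec.seed,
    )
    return stack, truth


def _sample_dwell_min(spec: TimelapseSpec, rng: np.random.Generator) -> float:
    if spec.dwell_family == "fixed" or spec.dwell_sd_min == 0:
        return spec.dwell_mean_min
    if spec.dwell_family == "truncnorm":
        lo = (0.0 - spec.dwell_mean_min) / spec.dwell_sd_min
        return float(
            stats.truncnorm.rvs(
                lo, np.inf, loc=spec.dwell_mean_min, scale=spec.dwell_sd_min,
                random_state=rng,
            )
        )
    raise ConfigError(f"unknown dwell family {spec.dwell_family!r}")


def make_timelapse(spec: TimelapseSpec) -> tuple[ImageStack, SceneTruth]:
    """Render a phagocytosis movie (channel 0 FYVE, channel 1 particle).

    Before the docking frame the particle sits just outside the cell at
    baseline intensity; from docking onward it sits inside the cell and
    follows the logistic pHrodo ramp, while a FYVE ring coats it for the
    sampled dwell duration. A dwell outlasting the movie is truncated and
    flagged in the truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    zz, yy, xx = _grids_um(spec.shape, spec.pixel_size_um, spec.z_step_um)
    cell = _render_ellipsoid(zz, yy, xx, spec.a_radius_um, spec.b_height_um)

    r_p = spec.particle_diameter_um / 2.0
    outside = (0.0, 0.0, spec.a_radius_um + r_p + 0.5)
    inside = (0.0, 0.0, 0.45 * spec.a_radius_um)

    dwell_min = _sample_dwell_min(spec, rng)
    interval_min = spec.frame_interval_s / 60.0
    dwell_frames = int(round(dwell_min / interval_min))
    truncated = spec.docking_frame + dwell_frames > spec.n_frames
    rendered_dwell = (
        spec.n_frames - spec.docking_frame if truncated else dwell_frames
    )

    args = (
        spec.pixel_size_um,
        spec.z_step_um,
        spec.blur_sigma_um,
        spec.shot_noise_scale,
        spec.read_noise_sd,
        rng,
    )
    frames_fyve = []
    frames_part = []
    for t in range(spec.n_frames):
        docked = t >= spec.docking_frame
        center = inside if docked else outside
        d2 = _sphere_dist2(zz, yy, xx, center)
        part_mask = d2 <= r_p**2

        if docked:
            dt_min = (t - spec.docking_frame) * interval_min
            part_int = spec.ramp(dt_min)
        else:
            part_int = spec.ramp_baseline
        ch_part = np.full(spec.shape, spec.background, dtype=np.float64)
        ch_part[part_mask] = part_int

        ch_fyve = np.where(cell, spec.cyto_intensity, spec.background)
        if docked and (t - spec.docking_frame) < rendered_dwell:
            shell = (d2 <= (r_p + spec.ring_thickness_um) ** 2) & ~part_mask
            ch_fyve[shell] = spec.fyve_ring_intensity

        frames_fyve.append(_finalize(ch_fyve, *args))
        frames_part.append(_finalize(ch_part, *args))

    data = np.stack([np.stack(frames_fyve), np.stack(frames_part)])
    stack = ImageStack(data=data, calibration=spec.calibration, axes="CTZYX")

    truth = SceneTruth(
        cell_a_um=spec.a_radius_um,
        cell_b_um=spec.b_height_um,
        docking_frame=spec.docking_frame,
        dwell_min=dwell_min,
        dwell_frames=rendered_dwell,
        dwell_truncated=truncated,
        particle_diameter_um=spec.particle_diameter_um,
        frame_interval_s=spec.frame_interval_s,
        seed=spec.seed,
    )
    return stack, truth


# --------------------------------------------------------------------------
# Cohorts


def _weibull_shape_for(median: float, sd: float) -> float:
    """Weibull shape k whose (median-anchored) sd equals the target."""

    def sd_of(k: float) -> float:
        lam = median / math.log(2.0) ** (1.0 / k)
        g1 = math.gamma(1.0 + 1.0 / k)
        g2 = math.gamma(1.0 + 2.0 / k)
        return lam * math.sqrt(max(g2 - g1**2, 0.0))

    lo, hi = 0.3, 100.0
    if sd >= sd_of(lo):
        return lo
    if sd <= sd_of(hi):
        return hi
    return float(optimize.brentq(lambda k: sd_of(k) - sd, lo, hi))


def make_survival_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-individual death days for every group and replicate.

    Returns a tidy table with columns ``group, replicate, individual_id,
    death_day`` — one row per fly. Death days are whole days ≥ 1
    (daily scoring); all flies are followed to death, so there is no
    censoring.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g in spec.groups:
        model = g.lifespan
        if model is None:
            raise ConfigError(f"group {g.name!r} has no lifespan model")
        base = g.n_individuals // g.n_replicates
        extra = g.n_individuals % g.n_replicates
        idx = 0
        for rep in range(g.n_replicates):
            n_rep = base + (1 if rep < extra else 0)
            if model.family == "fixed" or model.dispersion_days == 0:
                days = np.full(n_rep, max(1, math.ceil(model.median_days)))
            else:
                k = _weibull_shape_for(model.median_days, model.dispersion_days)
                lam = model.median_days / math.log(2.0) ** (1.0 / k)
                days = np.maximum(1, np.ceil(lam * rng.weibull(k, size=n_rep))).astype(
                    int
                )
            for d in days:
                rows.append(
                    {
                        "group": g.name,
                        "replicate": rep,
                        "individual_id": f"{g.name}-{idx}",
                        "death_day": int(d),
                    }
                )
                idx += 1
    return pd.DataFrame(rows, columns=["group", "replicate", "individual_id", "death_day"])


def make_dilution_counts(spec: CohortSpec) -> pd.DataFrame:
    """Draw Poisson colony counts across a serial-dilution series.

    One row per individual per dilution, columns ``group, replicate,
    individual_id, dilution, count, true_cfu``. The spot count is Poisson
    with mean ``true_cfu × sampling_fraction / dilution``; counts are
    always non-negative integers.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g in spec.groups:
        model = g.colony
        if model is None:
            raise ConfigError(f"group {g.name!r} has no colony model")
        base = g.n_individuals // g.n_replicates
        extra = g.n_individuals % g.n_replicates
        idx = 0
        for rep in range(g.n_replicates):
            n_rep = base + (1 if rep < extra else 0)
            for _ in range(n_rep):
                for dil in model.dilution_factors:
                    mean = model.true_cfu * model.sampling_fraction / dil
                    rows.append(
                        {
                            "group": g.name,
                            "replicate": rep,
                            "individual_id": f"{g.name}-{idx}",
                            "dilution": float(dil),
                            "count": int(rng.poisson(mean)),
                            "true_cfu": model.true_cfu,
                        }
                    )
                idx += 1
    return pd.DataFrame(
        rows,
        columns=["group", "replicate", "individual_id", "dilution", "count", "true_cfu"],
    )
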