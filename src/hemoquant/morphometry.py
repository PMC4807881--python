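"""Morphometric indices for hemocyte vacuolation and vesicle phenotypes.

The indices quantified here:

* **OVI** (occupied volume index): Σ sphere volumes of intracellular
  vacuoles with radius ≥ 1.5 µm, divided by a cytoplasmic reference
  volume. By default the denominator is the fixed wild-type average
  cytoplasmic volume of 311.06 µm³ — the study design uses one reference
  volume for all genotypes — with a per-cell ellipsoid denominator
  available for comparison. Cells whose vacuoles are all below 1.5 µm
  score an OVI of 0.
* **OAI** (occupied area index): Σ particle areas / cytoplasmic area on
  a 2D plane or projection.
* **Lysosomal aggregation**: total lysosomal particle area divided by
  the particle count (mean particle area, µm²).
* **FYVE diameter ratio**: per cell, the mean of three representative
  vesicle diameters divided by a reference genotype's mean diameter.

Cytoplasmic volume uses the oblate-ellipsoid formula with equatorial
radius ``a`` and axial semi-height ``b``. Two arrangements are provided:
``as-printed`` computes 4/3·π·a·b² and ``standard-oblate`` computes
4/3·π·a²·b (the volume of an oblate spheroid with those semi-axes); both
reduce to the sphere when a = b. ``as-printed`` is the default so the
original arithmetic is replicated literally; see docs/methods.md for the
discussion of this choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError, UndefinedIndexError
from .segmentation import CellRegion, ParticleSet, VacuoleSet

__all__ = [
    "WILD_TYPE_CYTOPLASM_UM3",
    "VACUOLE_MIN_RADIUS_UM",
    "OviConfig",
    "MorphResult",
    "ellipsoid_volume",
    "sphere_volume",
    "ovi",
    "oai",
    "aggregation_index",
    "diameter_ratio",
]

#: Average wild-type cytoplasmic volume (µm³) used as the fixed OVI denominator.
WILD_TYPE_CYTOPLASM_UM3 = 311.06

#: Minimum vacuole radius (µm) entering the OVI sum.
VACUOLE_MIN_RADIUS_UM = 1.5


@dataclass(frozen=True)
class OviConfig:
    """Configuration of the occupied volume index.

    ``denominator`` is ``fixed-reference`` (divide by
    ``reference_volume_um3`` for every cell) or ``per-cell`` (divide by
    the cell's own ellipsoid volume, which requires 3D measurements).
    """

    denominator: str = "fixed-reference"
    reference_volume_um3: float = WILD_TYPE_CYTOPLASM_UM3
    min_radius_um: float = VACUOLE_MIN_RADIUS_UM
    ellipsoid_variant: str = "as-printed"

    def __post_init__(self) -> None:
        if self.denominator not in ("fixed-reference", "per-cell"):
            raise ConfigError(f"unknown denominator mode {self.denominator!r}")
        if self.reference_volume_um3 <= 0:
            raise ConfigError("reference_volume_um3 must be > 0")
        if self.min_radius_um < 0:
            raise ConfigError("min_radius_um must be >= 0")
        if self.ellipsoid_variant not in ("as-printed", "standard-oblate"):
            raise ConfigError(f"unknown ellipsoid variant {self.ellipsoid_variant!r}")


@dataclass
class MorphResult:
    value: float
    kind: str  # "OVI" | "OAI" | "aggregation" | "diameter-ratio"
    cell_id: str = "cell-0"
    group: str = ""
    flagged: bool = False
    note: str = ""


def ellipsoid_volume(a_um: float, b_um: float, variant: str = "as-printed") -> float:
    """Oblate-ellipsoid cytoplasm volume from radius ``a`` and height ``b``.

    ``as-printed`` returns 4/3·π·a·b²; ``standard-oblate`` returns
    4/3·π·a²·b. Both give the sphere volume when a = b.
    """
    if a_um <= 0 or b_um <= 0:
        raise ConfigError(f"semi-axes must be > 0, got a={a_um}, b={b_um}")
    if variant == "as-printed":
        return 4.0 / 3.0 * math.pi * a_um * b_um**2
    if variant == "standard-oblate":
        return 4.0 / 3.0 * math.pi * a_um**2 * b_um
    raise ConfigError(f"unknown ellipsoid variant {variant!r}")


def sphere_volume(r_um: float) -> float:
    """Sphere volume 4/3·π·r³ (the vacuole volume model)."""
    if r_um < 0:
        raise ConfigError(f"radius must be >= 0, got {r_um}")
    return 4.0 / 3.0 * math.pi * r_um**3


def ovi(
    vacuoles: VacuoleSet,
    cell: CellRegion | None = None,
    cfg: OviConfig = OviConfig(),
) -> MorphResult:
    """Occupied volume index of one cell.

    Sums the sphere volumes of vacuoles with radius ≥ ``cfg.min_radius_um``
    and divides by the configured cytoplasmic denominator. A cell with no
    vacuole at or above the threshold scores 0.
    """
    if cfg.denominator == "per-cell":
        if cell is None or cell.a_um is None or cell.b_um is None:
            raise ConfigError(
                "per-cell OVI needs a CellRegion with 3D measurements (a and b)"
            )
        denom = ellipsoid_volume(cell.a_um, cell.b_um, cfg.ellipsoid_variant)
    else:
        denom = cfg.reference_volume_um3
    total = sum(
        sphere_volume(v.radius_um)
        for v in vacuoles.vacuoles
        if v.radius_um >= cfg.min_radius_um
    )
    return MorphResult(value=total / denom, kind="OVI", cell_id=vacuoles.cell_id)


def oai(particles: ParticleSet, cell_area_um2: float) -> MorphResult:
    """Occupied area index: Σ particle areas / cytoplasmic area."""
    if cell_area_um2 <= 0:
        raise ConfigError(f"cell area must be > 0, got {cell_area_um2}")
    return MorphResult(
        value=particles.total_area_um2 / cell_area_um2,
        kind="OAI",
        cell_id=particles.cell_id,
    )


def aggregation_index(particles: ParticleSet) -> MorphResult:
    """Lysosomal aggregation: total particle area / particle count (µm²)."""
    if len(particles) == 0:
        raise UndefinedIndexError("aggregation index undefined with no particles")
    return MorphResult(
        value=particles.total_area_um2 / len(particles),
        kind="aggregation",
        cell_id=particles.cell_id,
    )


def _representative_diameters(
    particles: ParticleSet, k: int, mode: str, seed: int | None
) -> list[float]:
    diams = sorted(particles.equivalent_diameters_um, reverse=True)
    if mode == "largest":
        return diams[:k]
    if mode == "random":
        import numpy as np

        rng = np.random.default_rng(seed)
        take = min(k, len(diams))
        return list(rng.choice(diams, size=take, replace=False))
    raise ConfigError(f"unknown selection mode {mode!r}")


def diameter_ratio(
    cells: list[ParticleSet],
    reference_mean_um: float,
    k: int = 3,
    selection: str = "largest",
    seed: int | None = None,
) -> list[MorphResult]:
    """Per-cell vesicle diameter ratio against a reference genotype mean.

    For each cell, the mean of ``k`` representative vesicle equivalent
    diameters (the ``k`` largest by default; ``selection="random"`` for a
    seeded random draw) divided by ``reference_mean_um``. Cells with
    fewer than ``k`` vesicles are computed from what is there and
    flagged.
    """
    if reference_mean_um <= 0:
        raise ConfigError(f"reference mean must be > 0, got {reference_mean_um}")
    out: list[MorphResult] = []
    for ps in cells:
        if len(ps) == 0:
            out.append(
                MorphResult(
                    value=math.nan,
                    kind="diameter-ratio",
                    cell_id=ps.cell_id,
                    flagged=True,
                    note="no vesicles",
                )
            )
            continue
        diams = _representative_diameters(ps, k, selection, seed)
        ratio = (sum(diams) / len(diams)) / reference_mean_um
        out.append(
            MorphResult(
                value=ratio,
                kind="diameter-ratio",
                cell_id=ps.cell_id,
                flagged=len(ps) < k,
                note="" if len(ps) >= k else f"only {len(ps)} vesicles (k={k})",
            )
        )
    return out


def reference_mean_diameter(
    cells: list[ParticleSet], k: int = 3, selection: str = "largest",
    seed: int | None = None,
) -> float:
    """Pooled mean of per-cell representative diameters for a reference group."""
    means = []
    for ps in cells:
        if len(ps) == 0:
            continue
        diams = _representative_diameters(ps, k, selection, seed)
        means.append(sum(diams) / len(diams))
    if not means:
        raise UndefinedIndexError("reference group has no vesicles")
    return sum(means) / len(means)
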