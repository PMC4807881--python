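"""End-to-end experiments: simulate → segment → score → test.

An experiment is described by a YAML-friendly configuration (kind,
seed, groups, stats plan). Each group names the generator parameters of
its condition — vacuole and vesicle size ranges for morphometric kinds,
a correlation target for colocalization, dwell-time parameters for
phagocytosis, lifespan/colony models for cohorts. ``run_experiment``
generates every scene with seeds derived deterministically from the
experiment seed, runs the measurement pipeline, applies the configured
statistics, and writes a tidy per-cell (or per-individual) CSV, a stats
JSON, a diagnostic plot, and a resolved copy of the configuration.
Reruns with the same config produce byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometry as morpho
from . import synthetic as syn
from .cohort_stats import (
    bonferroni_posthoc,
    cfu_per_individual,
    mann_whitney,
    median_lifespan,
    one_way_anova,
    relative_lifespan,
)
from .colocalization import coloc_by_group
from .errors import ConfigError, GeometryError, HemoquantError
from .segmentation import ParticleFilter, detect_particles, detect_vacuoles, max_project, segment_cell_body
from .timelapse import RoiSpec, build_track, fyve_prevalence, intensity_series

log = logging.getLogger("hemoquant")

__all__ = ["ExperimentConfig", "validate_config", "run_experiment"]

KINDS = ("ovi", "oai", "aggregation", "ratio", "coloc", "phagocytosis", "survival", "cfu")


@dataclass
class ExperimentConfig:
    """Parsed experiment configuration."""

    kind: str
    seed: int
    groups: dict[str, dict] = field(default_factory=dict)
    n_per_group: int = 25
    reference_group: str | None = None
    stats: dict = field(default_factory=dict)  # {"alpha": 0.05, "comparisons": [...]}

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {"kind", "seed", "groups", "n_per_group", "reference_group", "stats"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            kind=d.get("kind", ""),
            seed=d.get("seed", None) if d.get("seed", None) is not None else -1,
            groups=d.get("groups", {}) or {},
            n_per_group=int(d.get("n_per_group", 25)),
            reference_group=d.get("reference_group"),
            stats=d.get("stats", {}) or {},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "groups": self.groups,
            "n_per_group": self.n_per_group,
            "reference_group": self.reference_group,
            "stats": self.stats,
        }


def validate_config(cfg: ExperimentConfig) -> list[str]:
    """Collect all configuration violations without side effects."""
    findings: list[str] = []
    if cfg.kind not in KINDS:
        findings.append(f"unknown experiment kind {cfg.kind!r}; expected one of {KINDS}")
    if cfg.seed is None or cfg.seed < 0:
        findings.append("seed missing (reproducibility requires an explicit seed)")
    if not cfg.groups:
        findings.append("at least one group is required")
    for name, params in cfg.groups.items():
        if not isinstance(params, dict):
            findings.append(f"group {name!r}: parameters must be a mapping")
            continue
        if cfg.kind in ("ovi", "oai", "aggregation", "ratio", "coloc"):
            try:
                rng = np.random.default_rng(0)
                _sample_scene_spec(rng, params, seed=0).validate()
            except (GeometryError, ConfigError) as exc:
                findings.append(f"group {name!r}: {exc}")
        elif cfg.kind == "phagocytosis":
            try:
                _timelapse_spec(params, seed=0).validate()
            except ConfigError as exc:
                findings.append(f"group {name!r}: {exc}")
        elif cfg.kind in ("survival", "cfu"):
            try:
                _cohort_group(name, params).validate()
            except ConfigError as exc:
                findings.append(f"group {name!r}: {exc}")
    for pair in cfg.stats.get("comparisons", []) or []:
        for g in pair:
            if g not in cfg.groups:
                findings.append(f"comparison references unknown group {g!r}")
    if cfg.kind == "ratio" and cfg.reference_group not in cfg.groups:
        findings.append("ratio experiments need a reference_group among the groups")
    return findings


# --------------------------------------------------------------------------
# Group parameter sampling


def _rng_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def _pair(v, default):
    if v is None:
        return tuple(default)
    if np.isscalar(v):
        return (float(v), float(v))
    return (float(v[0]), float(v[1]))


def _sample_scene_spec(rng: np.random.Generator, params: dict, seed: int) -> syn.SceneSpec:
    """Draw one cell's SceneSpec from a group's parameter ranges."""
    a = float(params.get("a_radius_um", 5.0))
    b = float(params.get("b_height_um", 3.0))
    shape = tuple(params.get("shape", (14, 128, 128)))
    n_vac_lo, n_vac_hi = _pair(params.get("n_vacuoles", 1), (1, 1))
    r_lo, r_hi = _pair(params.get("vacuole_radius_um", (2.0, 2.5)), (2.0, 2.5))
    vacuoles = []
    n_vac = int(rng.integers(int(n_vac_lo), int(n_vac_hi) + 1))
    for _ in range(n_vac):
        r = float(rng.uniform(r_lo, r_hi))
        margin_xy, margin_z = a - r, b - r
        if margin_xy <= 0 or margin_z <= 0:
            raise GeometryError(
                f"vacuole radius {r:.2f} µm cannot fit in cell (a={a}, b={b})"
            )
        for _try in range(50):
            u = rng.uniform(-1, 1, size=3)
            if (u**2).sum() > 1:
                continue
            center = (0.7 * margin_z * u[0], 0.7 * margin_xy * u[1], 0.7 * margin_xy * u[2])
            if all(
                sum((np.array(center) - np.array(c)) ** 2) ** 0.5 > r + rr
                for c, rr in vacuoles
            ):
                vacuoles.append((center, r))
                break
    n_ves_lo, n_ves_hi = _pair(params.get("n_vesicles", 0), (0, 0))
    d_lo, d_hi = _pair(params.get("vesicle_diameter_um", (0.8, 1.2)), (0.8, 1.2))
    vesicles = []
    n_ves = int(rng.integers(int(n_ves_lo), int(n_ves_hi) + 1))
    for _ in range(n_ves):
        d = float(rng.uniform(d_lo, d_hi))
        while True:
            u = rng.uniform(-1, 1, size=3)
            if (u**2).sum() <= 1:
                break
        center = (0.6 * b * u[0], 0.6 * a * u[1], 0.6 * a * u[2])
        vesicles.append(
            syn.VesicleSpec(
                center_um=center,
                diameter_um=d,
                ring=bool(params.get("vesicle_ring", False)),
            )
        )
    return syn.SceneSpec(
        shape=shape,
        pixel_size_um=float(params.get("pixel_size_um", 0.1)),
        z_step_um=float(params.get("z_step_um", 0.5)),
        a_radius_um=a,
        b_height_um=b,
        vacuoles=vacuoles,
        vesicles=vesicles,
        shot_noise_scale=float(params.get("shot_noise_scale", 1.0)),
        read_noise_sd=float(params.get("read_noise_sd", 1.0)),
        blur_sigma_um=float(params.get("blur_sigma_um", 0.1)),
        seed=seed,
    )


def _timelapse_spec(params: dict, seed: int) -> syn.TimelapseSpec:
    spec = syn.TimelapseSpec(seed=seed)
    for key in (
        "shape", "pixel_size_um", "z_step_um", "frame_interval_s", "n_frames",
        "a_radius_um", "b_height_um", "particle_diameter_um", "docking_frame",
        "dwell_family", "dwell_mean_min", "dwell_sd_min", "ramp_baseline",
        "ramp_plateau", "ramp_half_rise_min", "ramp_slope_min",
        "ring_thickness_um", "shot_noise_scale", "read_noise_sd", "blur_sigma_um",
    ):
        if key in params:
            setattr(spec, key, tuple(params[key]) if key == "shape" else params[key])
    return spec


def _cohort_group(name: str, params: dict) -> syn.CohortGroup:
    lifespan = None
    if "lifespan" in params:
        lifespan = syn.LifespanModel(**params["lifespan"])
    colony = None
    if "colony" in params:
        c = dict(params["colony"])
        if "dilution_factors" in c:
            c["dilution_factors"] = tuple(c["dilution_factors"])
        colony = syn.ColonyModel(**c)
    return syn.CohortGroup(
        name=name,
        n_individuals=int(params.get("n_individuals", 50)),
        n_replicates=int(params.get("n_replicates", 5)),
        lifespan=lifespan,
        colony=colony,
    )


# --------------------------------------------------------------------------
# Experiment runners


def _morph_values(cfg: ExperimentConfig) -> pd.DataFrame:
    """Simulate and measure per-cell morphometric indices for every group."""
    rows = []
    particle_sets: dict[str, list] = {}
    rng = np.random.default_rng(cfg.seed)
    for gname, params in cfg.groups.items():
        n = int(params.get("n_cells", cfg.n_per_group))
        psets = []
        for i in range(n):
            spec = _sample_scene_spec(rng, params, seed=_rng_seed(rng))
            stack, _truth = syn.make_cell_scene(spec)
            cell_id = f"{gname}-{i}"
            cell = segment_cell_body(stack, channel=0, cell_id=cell_id)
            if cfg.kind == "ovi":
                vacs = detect_vacuoles(stack, cell)
                value = morpho.ovi(vacs, cell).value
            else:
                proj = max_project(stack, channel=1)
                pset = detect_particles(
                    proj, ParticleFilter(), stack.calibration, cell_id=cell_id
                )
                pset.particles = [  # clip to the cell: drop out-of-mask centroids
                    p
                    for p in pset.particles
                    if cell.mask2d[
                        min(int(round(p.centroid_px[0])), cell.mask2d.shape[0] - 1),
                        min(int(round(p.centroid_px[1])), cell.mask2d.shape[1] - 1),
                    ]
                ]
                psets.append(pset)
                if cfg.kind == "oai":
                    value = morpho.oai(pset, cell.area_um2).value
                elif cfg.kind == "aggregation":
                    value = (
                        morpho.aggregation_index(pset).value if len(pset) else np.nan
                    )
                else:  # ratio: values filled in a second pass
                    value = np.nan
            rows.append(
                {"cell_id": cell_id, "group": gname, "kind": cfg.kind.upper(), "value": value}
            )
        particle_sets[gname] = psets
    df = pd.DataFrame(rows, columns=["cell_id", "group", "kind", "value"])
    if cfg.kind == "ratio":
        ref = morpho.reference_mean_diameter(particle_sets[cfg.reference_group])
        values = {}
        for gname, psets in particle_sets.items():
            for res in morpho.diameter_ratio(psets, ref):
                values[res.cell_id] = res.value
        df["value"] = df["cell_id"].map(values)
    return df.dropna(subset=["value"]).reset_index(drop=True)


def _coloc_values(cfg: ExperimentConfig) -> pd.DataFrame:
    rng = np.random.default_rng(cfg.seed)
    scenes = []
    for gname, params in cfg.groups.items():
        n = int(params.get("n_cells", cfg.n_per_group))
        rho = float(params.get("rho_target", 0.5))
        n_puncta = int(params.get("n_puncta", 40))
        for _ in range(n):
            spec = _sample_scene_spec(rng, params, seed=_rng_seed(rng))
            stack, _ = syn.make_coloc_scene(n_puncta, rho, spec)
            scenes.append((stack, gname))
    df = coloc_by_group(scenes, mask_channel=0)
    df = df[df["error"] == ""].copy()
    df["kind"] = "pearson_r"
    df["value"] = df["r"]
    return df[["cell_id", "group", "kind", "value"]]


def _phagocytosis_values(cfg: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-particle FYVE prevalence plus long-format intensity curves."""
    rng = np.random.default_rng(cfg.seed)
    prev_rows = []
    curve_rows = []
    for gname, params in cfg.groups.items():
        n = int(params.get("n_movies", cfg.n_per_group))
        for i in range(n):
            spec = _timelapse_spec(params, seed=_rng_seed(rng))
            movie, truth = syn.make_timelapse(spec)
            cell = segment_cell_body(movie, channel=0, t=0, cell_id=f"{gname}-{i}")
            track = build_track(movie, particle_channel=1, cell=cell,
                                particle_id=f"{gname}-{i}")
            if not track.docked:
                continue
            prev = fyve_prevalence(movie, track, cell=cell)
            prev_rows.append(
                {
                    "particle_id": track.particle_id,
                    "group": gname,
                    "t0": track.t0,
                    "prevalence_min": prev.prevalence_min,
                    "true_dwell_min": truth.dwell_frames * spec.frame_interval_s / 60.0,
                }
            )
            series = intensity_series(movie, track, RoiSpec())
            for t_min, v in zip(series.times_min, series.values):
                curve_rows.append(
                    {"group": gname, "subject": track.particle_id,
                     "time": float(t_min), "value": float(v)}
                )
    return (
        pd.DataFrame(prev_rows, columns=["particle_id", "group", "t0",
                                         "prevalence_min", "true_dwell_min"]),
        pd.DataFrame(curve_rows, columns=["group", "subject", "time", "value"]),
    )


def _group_stats(df: pd.DataFrame, cfg: ExperimentConfig, value_col: str = "value") -> dict:
    """Apply the configured stats plan to a tidy per-cell table."""
    alpha = float(cfg.stats.get("alpha", 0.05))
    test = cfg.stats.get("test", "anova")
    groups = {g: sub[value_col].to_numpy() for g, sub in df.groupby("group")}
    out: dict = {"alpha": alpha, "test": test}
    if len(groups) < 2:
        out["note"] = "fewer than 2 groups; no test run"
        return out
    comparisons = cfg.stats.get("comparisons")
    comparisons = [tuple(c) for c in comparisons] if comparisons else None
    if test == "mann-whitney":
        names = list(groups)
        res = mann_whitney(groups[names[0]], groups[names[1]])
        out.update(U=res.statistic, p_value=res.p_value, groups=names[:2],
                   method=res.extra["method"])
    else:
        res = one_way_anova(list(groups.values()))
        post = bonferroni_posthoc(groups, comparisons=comparisons, alpha=alpha)
        out.update(
            F=res.statistic, df=list(res.df), p_value=res.p_value,
            posthoc=post.to_dict(orient="records"),
        )
    return out


def _plot_groups(df: pd.DataFrame, path: Path, value_col: str = "value") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    names = sorted(df["group"].unique())
    data = [df[df["group"] == g][value_col].to_numpy() for g in names]
    ax.boxplot(data, tick_labels=names)
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for i, vals in enumerate(data, start=1):
        ax.plot(i + rng.uniform(-0.12, 0.12, len(vals)), vals, ".", alpha=0.5, ms=4)
    ax.set_ylabel(value_col)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run one configured experiment end to end; returns the stats summary.

    Writes ``values.csv`` (tidy per-cell/individual results),
    ``stats.json``, ``plot.png`` and ``resolved_config.yaml`` into
    ``out_dir``. Deterministic given config + seed.
    """
    findings = validate_config(cfg)
    if findings:
        raise ConfigError("invalid config: " + "; ".join(findings))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("running %s experiment (seed=%d) -> %s", cfg.kind, cfg.seed, out)

    curves = None
    if cfg.kind in ("ovi", "oai", "aggregation", "ratio"):
        df = _morph_values(cfg)
        stats_summary = _group_stats(df, cfg)
    elif cfg.kind == "coloc":
        df = _coloc_values(cfg)
        cfg.stats.setdefault("test", "mann-whitney")
        stats_summary = _group_stats(df, cfg)
    elif cfg.kind == "phagocytosis":
        prev, curves = _phagocytosis_values(cfg)
        df = prev.rename(columns={"prevalence_min": "value"})
        df["kind"] = "fyve_prevalence_min"
        stats_summary = _group_stats(df, cfg)
    elif cfg.kind == "survival":
        spec = syn.CohortSpec(
            groups=[_cohort_group(g, p) for g, p in cfg.groups.items()], seed=cfg.seed
        )
        table = syn.make_survival_cohort(spec)
        summaries = {g: median_lifespan(table, g) for g in cfg.groups}
        ref = cfg.reference_group or next(iter(cfg.groups))
        ref_median = summaries[ref].median_days
        stats_summary = {"reference_group": ref, "groups": {}}
        for g, s in summaries.items():
            s.relative_lifespan_pct = relative_lifespan(s.median_days, ref_median)
            stats_summary["groups"][g] = {
                "median_days": s.median_days,
                "sem_days": s.sem_days,
                "replicate_medians": s.replicate_medians,
                "relative_lifespan_pct": s.relative_lifespan_pct,
                "n": s.n_individuals,
            }
        df = table.rename(columns={"death_day": "value"})
        df["kind"] = "death_day"
        df["cell_id"] = df["individual_id"]
    elif cfg.kind == "cfu":
        spec = syn.CohortSpec(
            groups=[_cohort_group(g, p) for g, p in cfg.groups.items()], seed=cfg.seed
        )
        counts = syn.make_dilution_counts(spec)
        est = cfu_per_individual(counts)
        df = est.rename(columns={"estimated_cfu": "value"})
        df = df.dropna(subset=["value"])
        df["kind"] = "cfu"
        df["cell_id"] = df["individual_id"]
        cfg.stats.setdefault("test", "mann-whitney")
        stats_summary = _group_stats(df, cfg)
    else:  # pragma: no cover - validated above
        raise ConfigError(f"unknown kind {cfg.kind!r}")

    cols = [c for c in ("cell_id", "particle_id", "individual_id", "group", "kind",
                        "value") if c in df.columns]
    df[cols].to_csv(out / "values.csv", index=False, lineterminator="\n")
    if curves is not None and not curves.empty:
        curves.to_csv(out / "timecourse.csv", index=False, lineterminator="\n")
    (out / "stats.json").write_text(json.dumps(stats_summary, indent=1, default=str))
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    try:
        _plot_groups(df, out / "plot.png")
    except Exception as exc:  # diagnostic only; never fails a run
        log.warning("plotting failed: %s", exc)
    return stats_summary
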