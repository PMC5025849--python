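"""End-to-end orchestration of the shortstopping analysis.

``run_pipeline`` drives the full chain -- event detection, southernmost
selection, site clustering, covariate construction, collinearity screen,
the three mixed models, Moran diagnostics, the bootstrap band and both
randomization tests -- writing every intermediate table as CSV plus a
JSON results summary.  ``PipelineConfig`` is the single auditable home
of every numeric constant of the analysis; a YAML file with the same
keys can override any of them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import models, randomization, site_detection, spatial_diag
from .geo import GeoPoint, centroid

logger = logging.getLogger(__name__)

__all__ = [
    "PEN_SITES",
    "PipelineConfig",
    "PipelineStageError",
    "PipelineResult",
    "run_pipeline",
    "validate_inputs",
    "build_site_model_rows",
]

#: The three summer pen locations whose centroid defines the breeding
#: grounds reference point (43.87 N, -89.23 E).
PEN_SITES = (
    GeoPoint(44.13, -89.95),   # Necedah NWR
    GeoPoint(43.93, -89.10),   # White River Marsh SWA
    GeoPoint(43.55, -88.64),   # Horicon NWR
)


@dataclass
class PipelineConfig:
    """All thresholds, windows and seeds of the analysis in one place."""

    relocations_path: str | None = None
    metadata_path: str | None = None
    covariates_path: str | None = None

    winter_start: tuple[int, int] = (11, 1)
    winter_end: tuple[int, int] = (4, 30)
    event_km: float = 10.0
    min_span_days: int = 15
    linkage_method: str = "pairwise_10km"
    pairwise_km: float = 10.0
    shortstop_km: float = 1200.0
    neighbour_radius_km: float = 100.0
    autocov_normalised: bool = False
    experience_floor_km: float = 10.0
    collinearity_threshold: float = 0.70

    breeding_centroid: tuple[float, float] | None = None   # default: pen centroid
    projection_centre: tuple[float, float] = (36.0, -86.0)

    n_randomization_reps: int = 1000
    n_bootstrap_reps: int = 1000
    moran_classes_km: tuple[float, ...] = (50.0, 200.0, 1650.0)
    n_moran_perm: int = 999
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("event_km", "pairwise_km", "shortstop_km",
                     "neighbour_radius_km", "experience_floor_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.winter_start[0] <= self.winter_end[0]:
            raise ValueError("winter window must span the new year "
                             "(start month after end month)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("winter_start", "winter_end", "breeding_centroid",
                    "projection_centre", "moran_classes_km"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def resolve_breeding_centroid(self) -> GeoPoint:
        if self.breeding_centroid is not None:
            return GeoPoint(*self.breeding_centroid)
        return centroid(list(PEN_SITES))


class PipelineStageError(RuntimeError):
    """Failure inside one pipeline stage, named for context."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    sites: pd.DataFrame
    events: pd.DataFrame
    selected_events: pd.DataFrame
    site_model_rows: pd.DataFrame
    founding_groups: pd.DataFrame
    experience: pd.DataFrame
    shortstop_records: pd.DataFrame
    distance_fit: models.MixedModelFit
    experience_fit: models.MixedModelFit | None
    shortstop_fit: models.MixedModelFit | None
    bootstrap_band: pd.DataFrame | None
    moran_distance: list
    moran_experience: list
    randomization_group: randomization.RandomizationResult | None
    randomization_individual: randomization.RandomizationResult | None
    collinearity: pd.DataFrame
    summary: dict = field(default_factory=dict)


def build_site_model_rows(sites: pd.DataFrame, groups: pd.DataFrame,
                          provider, radius_km: float = 100.0,
                          normalised: bool = False) -> pd.DataFrame:
    """Assemble the per-site regression table (the analysis table)."""
    rows = cov.environmental_covariates(sites, provider)
    rows = rows.merge(groups[["site_id", "max_age"]], on="site_id")
    _, scaled = cov.autocovariate(rows["lat"].to_numpy(), rows["lon"].to_numpy(),
                                  rows["distance_km"].to_numpy(),
                                  radius_km=radius_km, normalised=normalised)
    rows["autocov"] = scaled
    return rows[["site_id", "lat", "lon", "distance_km", "max_age",
                 "temp_anomaly", "grain_cover", "autocov", "first_use_year"]]


def site_model_rows_for(dataset, linkage_method: str = "pairwise_10km",
                        config: PipelineConfig | None = None,
                        provider=None) -> dict:
    """Detection-to-regression-table path for an in-memory dataset.

    Runs preprocessing, event detection, southernmost selection, site
    clustering, founding groups and covariate assembly for a
    :class:`~shortstop.synthetic_data.SyntheticDataset` (or any object
    with ``relocations``/``metadata``/``covariates`` frames), returning
    a dict with keys sites, selected_events, event_set, groups, rows.
    """
    from .synthetic_data import TrueSiteCovariateProvider

    config = config or PipelineConfig()
    provider = provider or TrueSiteCovariateProvider(dataset.covariates)
    breeding = config.resolve_breeding_centroid()
    centre = GeoPoint(*config.projection_centre)
    relocs = site_detection.preprocess_relocations(dataset.relocations)
    event_set = site_detection.detect_bird_winter_events(
        relocs, dataset.metadata, dist_km=config.event_km,
        min_span_days=config.min_span_days,
        winter_start=config.winter_start, winter_end=config.winter_end)
    selected = site_detection.select_southernmost(event_set.events)
    sel_set = site_detection.EventSet(
        events=selected,
        members={int(e): event_set.members[int(e)]
                 for e in selected["event_id"]})
    sites, selected = site_detection.cluster_sites(
        sel_set, linkage_method, breeding, centre,
        pairwise_km=config.pairwise_km)
    groups = site_detection.founding_groups(sites, selected, dataset.metadata)
    rows = build_site_model_rows(sites, groups, provider,
                                 radius_km=config.neighbour_radius_km,
                                 normalised=config.autocov_normalised)
    return {"sites": sites, "selected_events": selected,
            "event_set": event_set, "groups": groups, "rows": rows,
            "relocations": relocs}


def _founder_table(groups: pd.DataFrame) -> pd.DataFrame:
    """Explode founding groups into one row per founder individual."""
    rows = []
    for _, g in groups.iterrows():
        for bird in g["bird_ids"].split(","):
            rows.append({"site_id": int(g["site_id"]), "year": int(g["year"]),
                         "bird_id": bird})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig,
                 relocations: pd.DataFrame | None = None,
                 metadata: pd.DataFrame | None = None,
                 provider=None) -> PipelineResult:
    """Execute the full analysis.

    Inputs come either from ``config`` paths or as in-memory frames.
    ``provider`` supplies environmental covariates; when None, a table
    provider is built from ``config.covariates_path``.  Any stage error
    aborts with the stage name; tables already written stay on disk.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _write(name: str, df: pd.DataFrame) -> None:
        if out is not None:
            df.to_csv(out / name, index=False)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    if relocations is None:
        relocations = _stage("load", site_detection.load_relocations,
                             config.relocations_path)
    if metadata is None:
        metadata = _stage("load", site_detection.load_metadata,
                          config.metadata_path)
    if provider is None:
        if config.covariates_path is None:
            raise ValueError("no covariate provider and no covariates_path")
        provider = cov.TableProvider.from_csv(config.covariates_path)

    breeding = config.resolve_breeding_centroid()
    centre = GeoPoint(*config.projection_centre)

    relocations = _stage("preprocess", site_detection.preprocess_relocations,
                         relocations)
    event_set = _stage("detect_events", site_detection.detect_bird_winter_events,
                       relocations, metadata, dist_km=config.event_km,
                       min_span_days=config.min_span_days,
                       winter_start=config.winter_start,
                       winter_end=config.winter_end)
    _write("events.csv", event_set.events)

    selected = _stage("select_southernmost", site_detection.select_southernmost,
                      event_set.events)
    selected_set = site_detection.EventSet(
        events=selected,
        members={int(e): event_set.members[int(e)] for e in selected["event_id"]},
    )
    sites, selected = _stage("cluster_sites", site_detection.cluster_sites,
                             selected_set, config.linkage_method, breeding,
                             centre, pairwise_km=config.pairwise_km)
    _write("sites.csv", sites)
    _write("selected_events.csv", selected)

    groups = _stage("founding_groups", site_detection.founding_groups,
                    sites, selected, metadata)
    _write("founding_groups.csv", groups)

    rows = _stage("site_model_rows", build_site_model_rows, sites, groups,
                  provider, radius_km=config.neighbour_radius_km,
                  normalised=config.autocov_normalised)
    _write("site_model_rows.csv", rows)

    corr, passed = _stage("collinearity_screen", cov.collinearity_screen,
                          rows, threshold=config.collinearity_threshold)
    if not passed:
        logger.warning("collinearity screen failed: |r| above threshold")

    distance_fit = _stage("distance_lmm", models.fit_distance_lmm, rows)
    moran_distance = _stage(
        "moran_distance", spatial_diag.morans_correlogram,
        rows["lat"].to_numpy(), rows["lon"].to_numpy(), distance_fit.resid,
        classes_km=config.moran_classes_km, n_perm=config.n_moran_perm,
        seed=config.seed + 4)
    _write("moran_distance.csv", spatial_diag.correlogram_frame(moran_distance))

    experience = _stage("experience_table", cov.build_experience_table,
                        sites, groups, relocations, metadata,
                        floor_km=config.experience_floor_km,
                        winter_start=config.winter_start)
    _write("experience.csv", experience)
    experience_fit = None
    moran_experience = []
    if len(experience) >= 10:
        experience_fit = _stage("experience_lmm", models.fit_experience_lmm,
                                experience)
        site_resid = pd.DataFrame({
            "site_id": experience["site_id"], "resid": experience_fit.resid,
        }).groupby("site_id")["resid"].mean()
        locs = sites.set_index("site_id").loc[site_resid.index]
        moran_experience = _stage(
            "moran_experience", spatial_diag.morans_correlogram,
            locs["lat"].to_numpy(), locs["lon"].to_numpy(),
            site_resid.to_numpy(), classes_km=config.moran_classes_km,
            n_perm=config.n_moran_perm, seed=config.seed + 5)
        _write("moran_experience.csv",
               spatial_diag.correlogram_frame(moran_experience))

    shortstops = _stage("classify_shortstop", site_detection.classify_shortstop,
                        selected, breeding, centre,
                        threshold_km=config.shortstop_km)
    _write("shortstop_records.csv", shortstops)
    shortstop_fit = None
    bootstrap_band = None
    if shortstops["shortstopped"].nunique() == 2:
        shortstop_fit = _stage("shortstop_glmm", models.fit_shortstop_glmm,
                               shortstops)
        if config.n_bootstrap_reps > 0:
            bootstrap_band = _stage("bootstrap_band",
                                    models.bootstrap_prediction_band,
                                    shortstop_fit,
                                    n_reps=config.n_bootstrap_reps,
                                    seed=config.seed + 3)
            _write("shortstop_prediction_band.csv", bootstrap_band)

    founders = _founder_table(groups).merge(
        metadata, on="bird_id")
    founders["age"] = founders["year"] - founders["hatch_year"]
    rand_group = rand_ind = None
    if config.n_randomization_reps > 1:
        rand_group = _stage("randomization_group",
                            randomization.run_randomization_test, rows,
                            mode="group", n_reps=config.n_randomization_reps,
                            seed=config.seed + 1)
        rand_ind = _stage("randomization_individual",
                          randomization.run_randomization_test, rows,
                          mode="individual", founders=founders,
                          n_reps=config.n_randomization_reps,
                          seed=config.seed + 2)

    summary = {
        "n_relocations": int(len(relocations)),
        "n_birds": int(metadata["bird_id"].nunique()),
        "n_events": int(len(event_set.events)),
        "n_bird_winters": int(len(selected)),
        "frac_multi_site_winters": float(
            1.0 - len(selected) / max(len(event_set.events), 1)),
        "n_sites": int(len(sites)),
        "breeding_centroid": [breeding.lat, breeding.lon],
        "linkage_method": config.linkage_method,
        "collinearity_pass": bool(passed),
        "collinearity_max_abs_r": float(
            np.abs(corr.to_numpy() - np.eye(len(corr))).max()),
        "distance_lmm": distance_fit.to_summary_dict(),
        "experience_lmm": (experience_fit.to_summary_dict()
                           if experience_fit else None),
        "shortstop_glmm": (shortstop_fit.to_summary_dict()
                           if shortstop_fit else None),
        "moran_distance": [m.to_dict() for m in moran_distance],
        "moran_experience": [m.to_dict() for m in moran_experience],
        "randomization_group": (
            {k: v for k, v in rand_group.to_summary_dict().items()
             if k != "randomized_age_coefs"} if rand_group else None),
        "randomization_individual": (
            {k: v for k, v in rand_ind.to_summary_dict().items()
             if k != "randomized_age_coefs"} if rand_ind else None),
        "seed": config.seed,
    }
    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        for name, robj in (("randomization_group.json", rand_group),
                           ("randomization_individual.json", rand_ind)):
            if robj is not None:
                with open(out / name, "w") as fh:
                    json.dump(robj.to_summary_dict(), fh)

    return PipelineResult(
        sites=sites, events=event_set.events, selected_events=selected,
        site_model_rows=rows, founding_groups=groups, experience=experience,
        shortstop_records=shortstops, distance_fit=distance_fit,
        experience_fit=experience_fit, shortstop_fit=shortstop_fit,
        bootstrap_band=bootstrap_band, moran_distance=moran_distance,
        moran_experience=moran_experience, randomization_group=rand_group,
        randomization_individual=rand_ind, collinearity=corr, summary=summary,
    )


def validate_inputs(relocations_path, metadata_path) -> dict:
    """Schema and consistency report for input files (machine-readable)."""
    issues: list[dict] = []

    def _issue(kind: str, detail: str, row: int | None = None) -> None:
        issues.append({"kind": kind, "detail": detail, "row": row})

    try:
        relocs = pd.read_csv(relocations_path, dtype={"bird_id": str})
    except Exception as exc:
        raise ValueError(f"unparseable relocation file: {exc}") from exc
    try:
        meta = pd.read_csv(metadata_path, dtype={"bird_id": str})
    except Exception as exc:
        raise ValueError(f"unparseable metadata file: {exc}") from exc

    for col in ("bird_id", "date", "lat", "lon"):
        if col not in relocs.columns:
            _issue("schema", f"relocations missing column {col!r}")
    for col in ("bird_id", "hatch_year"):
        if col not in meta.columns:
            _issue("schema", f"metadata missing column {col!r}")
    if not issues:
        dates = pd.to_datetime(relocs["date"], format="ISO8601", errors="coerce")
        for i in relocs.index[dates.isna()]:
            _issue("date", f"unparseable date {relocs.loc[i, 'date']!r}", int(i))
        bad = relocs.index[(relocs["lat"].abs() > 90) | (relocs["lon"].abs() > 180)]
        for i in bad:
            _issue("bounds", f"coordinates ({relocs.loc[i, 'lat']}, "
                             f"{relocs.loc[i, 'lon']}) out of range", int(i))
        missing = sorted(set(relocs["bird_id"]) - set(meta["bird_id"]))
        for b in missing:
            _issue("crossref", f"bird {b!r} absent from metadata")
        n_dup = int(relocs.duplicated(subset=["bird_id", "date", "lat", "lon"]).sum())
        if n_dup:
            _issue("duplicates", f"{n_dup} exact duplicate relocations")
    return {
        "n_relocations": int(len(relocs)),
        "n_birds_meta": int(meta["bird_id"].nunique()) if "bird_id" in meta else 0,
        "n_issues": len(issues),
        "issues": issues,
    }
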