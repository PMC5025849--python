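"""Synthetic relocation datasets with known ground truth.

The generator emulates the structure of the reintroduced eastern
migratory whooping-crane population: cohorts of captive-reared birds
released annually from a Wisconsin breeding area, migrating each autumn
along a corridor toward the Gulf Coast of Florida, overwintering in
small mixed-age groups, and -- the behaviour under study -- groups with
older, more experienced birds founding new overwintering sites closer to
the breeding grounds (shortstopping), with younger birds adopting
northern sites in later years.

Site distances are generated from the exact linear model the analysis
fits, so the full pipeline is a parameter-recovery exercise:

    y = b0 + b_age * max_age + b_temp * temp + b_grain * grain
        + u_year + eps,
    u_year ~ N(0, year_sd^2),  eps ~ N(0, site_noise_sd^2)

with temperature anomaly and grain cover drawn exogenously per site.
Because warmer anomalies and higher grain cover *cause* shorter
distances (negative coefficients), the northward covariate gradients of
the study region emerge in the generated data rather than being painted
on.  The site is placed at exactly distance y from the breeding centroid
along a jittered corridor bearing, so the measured response equals the
generated one up to observation noise.

Migration stopovers carry the individual-experience signal: each bird's
waypoints are offset laterally from its migration path by a lognormal
distance whose log-mean decreases with age, so older birds have passed
closer to the areas where new sites appear.

What this generator does *not* emulate: observation-effort seasonality,
transmitter failure, mortality/permanent emigration, within-winter site
switching southward, or real geography of wetlands -- passing tests on
these data show the pipeline recovers the assumed statistical structure,
not that real field data satisfy it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .geo import GeoPoint, destination_point, haversine_km

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "TrueSiteCovariateProvider",
    "generate",
    "make_fixture",
    "FIXTURES",
    "simulate_site_rows",
    "simulate_experience_records",
    "simulate_shortstop_records",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic population.

    Defaults reproduce the population the analysis was designed around:
    175 individuals released in annual cohorts, winters 2002-2015
    (labelled by the year containing November), 68 overwintering sites,
    a -40 km/yr effect of group maximum age on new-site distance, and
    winter groups of 1-22 birds of mixed ages.
    """

    n_birds: int = 175
    years: tuple[int, int] = (2002, 2015)
    n_sites: int = 68
    breeding_centroid: GeoPoint = GeoPoint(43.87, -89.23)
    corridor_terminus: GeoPoint = GeoPoint(28.76, -82.55)

    # site-distance truth (km; negative = closer to breeding grounds)
    baseline_km: float = 1750.0
    age_effect_km_per_yr: float = -40.0
    temp_effect_km_per_c: float = -120.0
    grain_effect_km_per_pct: float = -12.0
    site_noise_sd_km: float = 150.0
    year_sd_km: float = 100.0
    distance_bounds_km: tuple[float, float] = (100.0, 2300.0)

    # exogenous site covariates (anomaly in deg C, grain in percent)
    temp_anomaly_mean: float = 0.6
    temp_anomaly_sd: float = 0.35
    grain_mean_pct: float = 15.0
    grain_sd_pct: float = 12.0

    # geometry
    bearing_jitter_sd_deg: float = 5.0
    min_site_separation_km: float = 55.0

    # winter-group behaviour
    founding_group_mean_extra: float = 1.3   # size = 1 + Poisson(.)
    founding_group_max: int = 6
    site_fidelity: float = 0.6
    copy_intercept: float = -4.0
    copy_age: float = 0.25
    copy_year: float = 0.35

    # observation process
    obs_per_winter: int = 6
    obs_noise_km: float = 2.0
    p_winter_observed: float = 0.55
    second_site_frac: float = 0.19
    stopovers_per_migration: tuple[int, int] = (1, 3)

    # experience signal: lateral stopover offset, log-km scale
    experience_log_base: float = 5.61
    experience_log_age_slope: float = -0.38
    experience_log_sd: float = 0.5

    seed: int = 0

    def validate(self) -> None:
        for name in ("site_fidelity", "p_winter_observed", "second_site_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_site_separation_km <= 50.0:
            raise ValueError("min_site_separation_km must exceed 50 km so all "
                             "site-linkage variants agree")
        if self.years[1] <= self.years[0]:
            raise ValueError("years must span at least two winters")
        if self.n_birds < 2 or self.n_sites < 2:
            raise ValueError("need at least 2 birds and 2 sites")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    sites: pd.DataFrame          # true_site_id, lat, lon, distance_km,
    #                              first_use_year, temp_anomaly, grain_cover,
    #                              max_age, founder_ids
    assignments: pd.DataFrame    # bird_id, winter_year, true_site_id, age,
    #                              distance_km, shortstopped, observed
    coefficients: dict


@dataclass
class SyntheticDataset:
    relocations: pd.DataFrame
    metadata: pd.DataFrame
    covariates: pd.DataFrame     # per true site: lat, lon, temp_anomaly, grain_cover
    truth: GroundTruth
    config: GeneratorConfig


class TrueSiteCovariateProvider:
    """Covariate lookup by nearest generated site.

    Detected site centroids land within observation noise of the latent
    sites, so a nearest-point join recovers each site's generated
    covariates; a lookup farther than ``max_km`` from every latent site
    raises.
    """

    def __init__(self, covariates: pd.DataFrame, max_km: float = 25.0) -> None:
        self._lat = covariates["lat"].to_numpy(dtype=float)
        self._lon = covariates["lon"].to_numpy(dtype=float)
        self._temp = covariates["temp_anomaly"].to_numpy(dtype=float)
        self._grain = covariates["grain_cover"].to_numpy(dtype=float)
        self.max_km = max_km

    def lookup(self, site_id: int, point: GeoPoint) -> tuple[float, float]:
        d = haversine_km(self._lat, self._lon, point.lat, point.lon)
        i = int(np.argmin(d))
        if d[i] > self.max_km:
            raise KeyError(site_id)
        return float(self._temp[i]), float(self._grain[i])


def _initial_bearing(a: GeoPoint, b: GeoPoint) -> float:
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dlam = math.radians(b.lon - a.lon)
    x = math.sin(dlam) * math.cos(phi2)
    y = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    return math.degrees(math.atan2(x, y)) % 360.0


def _km_offset(lat: float, lon: float, east_km: float, north_km: float) -> tuple[float, float]:
    """Shift a coordinate by small planar offsets in km."""
    dlat = north_km / 111.2
    dlon = east_km / (111.2 * math.cos(math.radians(lat)))
    return lat + dlat, lon + dlon


def generate(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Simulate the population and emit relocation/metadata/covariate tables.

    Deterministic given ``config.seed``; all randomness flows from one
    generator created from that seed.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    y0, y1 = cfg.years
    winters = list(range(y0, y1 + 1))
    n_winters = len(winters)

    # annual release cohorts, hatch years y0-1 .. y1-1
    hatch_years_avail = list(range(y0 - 1, y1))
    base = cfg.n_birds // len(hatch_years_avail)
    sizes = np.full(len(hatch_years_avail), base)
    sizes[: cfg.n_birds - base * len(hatch_years_avail)] += 1
    bird_ids, hatch = [], {}
    k = 0
    for hy, s in zip(hatch_years_avail, sizes):
        for _ in range(s):
            b = f"b{k:03d}"
            bird_ids.append(b)
            hatch[b] = hy
            k += 1
    metadata = pd.DataFrame({"bird_id": bird_ids,
                             "hatch_year": [hatch[b] for b in bird_ids]})

    # spread the site budget over winters, extras to the later winters
    per = cfg.n_sites // n_winters
    alloc = {w: per for w in winters}
    remainder = cfg.n_sites - per * n_winters
    for w in winters[n_winters - remainder:]:
        alloc[w] += 1

    base_bearing = _initial_bearing(cfg.breeding_centroid, cfg.corridor_terminus)
    b = cfg.breeding_centroid

    sites: list[dict] = []          # latent site registry
    assignments: list[dict] = []
    prev_site: dict[str, int] = {}

    def _place_site(dist_km: float) -> GeoPoint | None:
        for attempt in range(120):
            jit = (rng.normal(0.0, cfg.bearing_jitter_sd_deg) if attempt < 40
                   else rng.uniform(-15.0, 15.0))
            p = destination_point(b, base_bearing + jit, dist_km)
            if not sites:
                return p
            d = haversine_km(np.array([s["lat"] for s in sites]),
                             np.array([s["lon"] for s in sites]), p.lat, p.lon)
            if np.min(d) > cfg.min_site_separation_km:
                return p
        return None

    for w in winters:
        active = [bd for bd in bird_ids if w - hatch[bd] >= 1]
        u_year = rng.normal(0.0, cfg.year_sd_km)
        pool = list(rng.permutation(active))
        n_new = min(alloc[w], len(pool))

        established = [s for s in sites if s["first_use_year"] < w]

        # founding groups; in the very first winter there are no
        # established sites yet, so every active bird founds one
        group_members: list[list[str]] = []
        for s_idx in range(n_new):
            remaining_groups = n_new - s_idx - 1
            max_take = len(pool) - remaining_groups
            size = 1 + int(min(rng.poisson(cfg.founding_group_mean_extra),
                               cfg.founding_group_max - 1))
            size = max(1, min(size, max_take))
            group_members.append([pool.pop() for _ in range(size)])
        if not established:
            for i, bd in enumerate(pool):
                group_members[i % max(n_new, 1)].append(bd)
            pool = []

        for group in group_members:
            max_age = max(w - hatch[bd] for bd in group)

            temp = rng.normal(cfg.temp_anomaly_mean, cfg.temp_anomaly_sd)
            grain = float(np.clip(rng.normal(cfg.grain_mean_pct, cfg.grain_sd_pct),
                                  0.0, 100.0))
            point = None
            for _ in range(30):
                dist = (cfg.baseline_km
                        + cfg.age_effect_km_per_yr * max_age
                        + cfg.temp_effect_km_per_c * temp
                        + cfg.grain_effect_km_per_pct * grain
                        + u_year + rng.normal(0.0, cfg.site_noise_sd_km))
                dist = float(np.clip(dist, *cfg.distance_bounds_km))
                point = _place_site(dist)
                if point is not None:
                    break
            if point is None:
                raise RuntimeError("could not place a site with the required "
                                   "separation; corridor too crowded")
            sid = len(sites)
            sites.append({
                "true_site_id": sid, "lat": point.lat, "lon": point.lon,
                "distance_km": dist, "first_use_year": w,
                "temp_anomaly": temp, "grain_cover": grain,
                "max_age": max_age, "founder_ids": ",".join(sorted(group)),
            })
            for bd in group:
                assignments.append({"bird_id": bd, "winter_year": w,
                                    "true_site_id": sid,
                                    "age": w - hatch[bd],
                                    "is_founder": True})
                prev_site[bd] = sid

        # returning birds choose among previously founded sites
        for bd in pool:
            age = w - hatch[bd]
            if bd in prev_site and rng.random() < cfg.site_fidelity:
                sid = prev_site[bd]
            else:
                p_copy = expit(cfg.copy_intercept + cfg.copy_age * age
                               + cfg.copy_year * (w - y0))
                north = [s for s in established if s["distance_km"] < 1200.0]
                south = [s for s in established if s["distance_km"] >= 1200.0]
                if north and rng.random() < p_copy:
                    sid = int(rng.choice([s["true_site_id"] for s in north]))
                else:
                    pick = south or established
                    sid = int(rng.choice([s["true_site_id"] for s in pick]))
            assignments.append({"bird_id": bd, "winter_year": w,
                                "true_site_id": sid, "age": age,
                                "is_founder": False})
            prev_site[bd] = sid

    sites_df = pd.DataFrame(sites)
    asn = pd.DataFrame(assignments)
    asn["distance_km"] = sites_df.loc[asn["true_site_id"], "distance_km"].to_numpy()
    asn["shortstopped"] = asn["distance_km"] < 1200.0

    # ------------------------------------------------------------------
    # observation process
    # ------------------------------------------------------------------
    obs_days = np.linspace(32, 107, cfg.obs_per_winter).round().astype(int)
    rows: list[tuple] = []

    def _emit(bird: str, date: pd.Timestamp, lat: float, lon: float, src: str) -> None:
        rows.append((bird, date, lat, lon, src))

    def _noisy(lat: float, lon: float, sd_km: float) -> tuple[float, float]:
        return _km_offset(lat, lon, rng.normal(0.0, sd_km), rng.normal(0.0, sd_km))

    observed_flags = np.zeros(len(asn), dtype=bool)
    for i, a in enumerate(asn.itertuples()):
        site = sites[a.true_site_id]
        observed = a.is_founder or (rng.random() < cfg.p_winter_observed)
        observed_flags[i] = observed
        w = a.winter_year
        nov1 = pd.Timestamp(year=w, month=11, day=1)

        if observed:
            for d in obs_days:
                lat, lon = _noisy(site["lat"], site["lon"], cfg.obs_noise_km)
                _emit(a.bird_id, nov1 + pd.Timedelta(days=int(d + rng.integers(-3, 4))),
                      lat, lon, "visual")
            # occasional early-winter residence at a more northern site
            if rng.random() < cfg.second_site_frac:
                northern = [s for s in sites
                            if s["first_use_year"] <= w
                            and s["distance_km"] < site["distance_km"] - 100.0]
                if northern:
                    s2 = northern[int(rng.integers(0, len(northern)))]
                    for d in (2, 10, 19):
                        lat, lon = _noisy(s2["lat"], s2["lon"], cfg.obs_noise_km)
                        _emit(a.bird_id, nov1 + pd.Timedelta(days=d), lat, lon, "visual")

            # migration stopovers with the age-dependent lateral offset
            path_dx = site["lon"] - b.lon
            path_dy = site["lat"] - b.lat
            norm = math.hypot(path_dx, path_dy)
            nx, ny = -path_dy / norm, path_dx / norm      # unit normal, degrees
            for leg, (month, day_lo) in (("fall", (10, 8)), ("spring", (5, 1))):
                n_stop = int(rng.integers(cfg.stopovers_per_migration[0],
                                          cfg.stopovers_per_migration[1] + 1))
                yr = w if leg == "fall" else w + 1
                if yr > y1 + 1:
                    continue
                for f in np.sort(rng.uniform(0.2, 0.8, size=n_stop)):
                    off_km = math.exp(rng.normal(
                        cfg.experience_log_base + cfg.experience_log_age_slope * a.age,
                        cfg.experience_log_sd)) * (1 if rng.random() < 0.5 else -1)
                    lat0 = b.lat + f * path_dy
                    lon0 = b.lon + f * path_dx
                    lat = lat0 + ny * off_km / 111.2
                    lon = lon0 + nx * off_km / (111.2 * math.cos(math.radians(lat0)))
                    _emit(a.bird_id,
                          pd.Timestamp(year=yr, month=month,
                                       day=int(day_lo + rng.integers(0, 12))),
                          lat, lon, "vhf")

        # one summer observation near the breeding grounds each year
        lat, lon = _noisy(b.lat, b.lon, 8.0)
        _emit(a.bird_id, pd.Timestamp(year=w, month=7,
                                      day=int(1 + rng.integers(0, 20))),
              lat, lon, "visual")

    asn["observed"] = observed_flags
    relocations = pd.DataFrame(rows, columns=["bird_id", "date", "lat", "lon", "source"])
    relocations = relocations.sort_values(["bird_id", "date"],
                                          kind="mergesort").reset_index(drop=True)

    covariates = sites_df[["true_site_id", "lat", "lon", "temp_anomaly",
                           "grain_cover"]].copy()
    truth = GroundTruth(
        sites=sites_df,
        assignments=asn,
        coefficients={
            "intercept": cfg.baseline_km,
            "max_age": cfg.age_effect_km_per_yr,
            "temp_anomaly": cfg.temp_effect_km_per_c,
            "grain_cover": cfg.grain_effect_km_per_pct,
            "site_noise_sd": cfg.site_noise_sd_km,
            "year_sd": cfg.year_sd_km,
        },
    )
    return SyntheticDataset(relocations=relocations, metadata=metadata,
                            covariates=covariates, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _fixture_two_site_chain() -> SyntheticDataset:
    """Three single-bird events at 0, 8 and 16 km: one site by chaining."""
    base = GeoPoint(34.0, -86.0)
    rows = []
    for i, off_km in enumerate((0.0, 8.0, 16.0)):
        lat = base.lat
        lon = base.lon + off_km / (111.2 * math.cos(math.radians(lat)))
        for d in (5, 15, 28):
            rows.append((f"c{i}", pd.Timestamp(2005, 12, d), lat, lon, "visual"))
    relocs = pd.DataFrame(rows, columns=["bird_id", "date", "lat", "lon", "source"])
    meta = pd.DataFrame({"bird_id": ["c0", "c1", "c2"],
                         "hatch_year": [2001, 2002, 2003]})
    return SyntheticDataset(relocs, meta, pd.DataFrame(), None, None)


def _fixture_tie_latitude() -> SyntheticDataset:
    """One bird, two same-latitude events 300 km apart; west one starts first."""
    rows = []
    for day, lon in ((1, -88.0), (20, -88.0), (8, -84.7), (28, -84.7)):
        rows.append(("t0", pd.Timestamp(2006, 12, day), 33.0, lon, "visual"))
    relocs = pd.DataFrame(rows, columns=["bird_id", "date", "lat", "lon", "source"]) \
        .sort_values("date", kind="mergesort").reset_index(drop=True)
    meta = pd.DataFrame({"bird_id": ["t0"], "hatch_year": [2003]})
    return SyntheticDataset(relocs, meta, pd.DataFrame(), None, None)


def _fixture_single_founder() -> SyntheticDataset:
    """One four-year-old bird founding one site alone."""
    rows = [("s0", pd.Timestamp(2007, 12, d), 31.5, -83.5, "visual")
            for d in (5, 15, 25)]
    relocs = pd.DataFrame(rows, columns=["bird_id", "date", "lat", "lon", "source"])
    meta = pd.DataFrame({"bird_id": ["s0"], "hatch_year": [2003]})
    return SyntheticDataset(relocs, meta, pd.DataFrame(), None, None)


def _fixture_no_age_effect() -> SyntheticDataset:
    """Reduced population with the age effect switched off (null model)."""
    cfg = GeneratorConfig(n_birds=70, years=(2002, 2010), n_sites=36,
                          age_effect_km_per_yr=0.0, seed=901)
    return generate(cfg)


FIXTURES = {
    "two-site-chain": _fixture_two_site_chain,
    "tie-latitude": _fixture_tie_latitude,
    "single-founder": _fixture_single_founder,
    "no-age-effect": _fixture_no_age_effect,
}


def make_fixture(name: str) -> SyntheticDataset:
    """Return a deterministic miniature dataset from the fixture registry."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    return FIXTURES[name]()


# ---------------------------------------------------------------------------
# direct model simulators (unit-test scale)
# ---------------------------------------------------------------------------

def simulate_site_rows(n_sites: int = 68, n_years: int = 13,
                       age_effect: float = -40.0, temp_effect: float = -120.0,
                       grain_effect: float = -12.0, autocov_effect: float = 0.0,
                       noise_sd: float = 150.0, year_sd: float = 100.0,
                       seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Draw site-model rows straight from the LMM, no geography involved."""
    rng = np.random.default_rng(seed)
    years = rng.integers(0, n_years, size=n_sites) + 2003
    u = rng.normal(0.0, year_sd, size=n_years + 1)
    max_age = rng.integers(1, 14, size=n_sites)
    temp = rng.normal(0.6, 0.35, size=n_sites)
    grain = np.clip(rng.normal(15.0, 12.0, size=n_sites), 0.0, 100.0)
    ac = rng.normal(0.0, 1.0, size=n_sites)
    y = (1950.0 + age_effect * max_age + temp_effect * temp
         + grain_effect * grain + autocov_effect * ac
         + u[years - 2003] + rng.normal(0.0, noise_sd, size=n_sites))
    rows = pd.DataFrame({
        "site_id": np.arange(n_sites), "distance_km": y, "max_age": max_age,
        "temp_anomaly": temp, "grain_cover": grain, "autocov": ac,
        "first_use_year": years,
    })
    truth = {"intercept": 1950.0, "max_age": age_effect, "temp_anomaly": temp_effect,
             "grain_cover": grain_effect, "autocov": autocov_effect}
    return rows, truth


def simulate_experience_records(n_birds: int = 60, n_sites: int = 40,
                                n_years: int = 10, age_slope: float = -0.35,
                                intercept: float = 5.5, bird_sd: float = 0.3,
                                year_sd: float = 0.2, site_sd: float = 0.3,
                                resid_sd: float = 0.5, seed: int = 0
                                ) -> tuple[pd.DataFrame, dict]:
    """Draw experience records straight from the crossed-intercepts LMM."""
    rng = np.random.default_rng(seed)
    n = n_sites * 3
    bird = rng.integers(0, n_birds, size=n)
    year = rng.integers(0, n_years, size=n) + 2004
    site = np.repeat(np.arange(n_sites), 3)
    age = rng.integers(1, 13, size=n)
    ub = rng.normal(0, bird_sd, n_birds)
    uy = rng.normal(0, year_sd, n_years + 1)
    us = rng.normal(0, site_sd, n_sites)
    log_d = (intercept + age_slope * age + ub[bird] + uy[year - 2004] + us[site]
             + rng.normal(0, resid_sd, n))
    df = pd.DataFrame({
        "bird_id": [f"b{i}" for i in bird], "site_id": site, "year": year,
        "age": age, "log_min_prev": log_d, "min_prev_km": np.exp(log_d),
    })
    return df, {"intercept": intercept, "age": age_slope}


def simulate_shortstop_records(n_birds: int = 120, n_years: int = 12,
                               beta0: float = -6.0, beta_age: float = 0.35,
                               beta_year: float = 0.3, sigma_u: float = 0.8,
                               seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Draw bird-year shortstop outcomes straight from the logit GLMM.

    Year enters relative to the first study year; the returned truth
    coefficients are on that same scale.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma_u, size=n_birds)
    rows = []
    for bd in range(n_birds):
        hatch = int(rng.integers(0, n_years - 2))
        for yr in range(hatch + 1, n_years):
            age = yr - hatch
            eta = beta0 + beta_age * age + beta_year * yr + u[bd]
            rows.append({"bird_id": f"b{bd:03d}", "year": 2002 + yr, "age": age,
                         "shortstopped": rng.random() < expit(eta)})
    df = pd.DataFrame(rows)
    return df, {"intercept": beta0, "age": beta_age, "year": beta_year,
                "sigma_u": sigma_u}
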