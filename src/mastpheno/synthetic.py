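"""Synthetic climate, roster and phenology generator.

Replicates the monitoring design of the semi-arid savanna study the
analysis pipeline targets, so that every stage is testable without field
data: 18 species across 3 sites, 10 individuals per species-site (290
trees in total), monthly visits over 8 August-July phenological years,
annual tree deaths with August replacement under fresh identifiers.

Climate is a weekly synthetic analogue of a lowveld savanna: an austral
temperature/radiation sinusoid plus a zero-inflated-gamma seasonal
rainfall process calibrated so the long-run mean annual total is about
550 mm and the median wet-season onset (first post-1-July date whose
trailing 30-day rainfall exceeds 25 mm) falls near DOY 298 (25 October).

Phenology is generated forward through the same model the pipeline fits:
one deterministic weekly growth trajectory per species-site from the year
2000 (spin-up), ordinal class probabilities from the cumulative-link
model, and independent categorical draws per tree and visit. Species are
assigned archetypes spanning the observed metric space (resource
matcher, high volatility, low fecundity, aseasonal null).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from mastpheno.io import PHENOPHASES
from mastpheno.ordinal import LAGGED_PHENOPHASES, ObservationParams, ordinal_probs
from mastpheno.process import ProcessParams, simulate_trajectory

# Species x site layout of the monitored community (three sites coded
# Nk, Sk, Su). The tabulated layout gives 28 species-site pairs = 280
# trees at 10 each; the study total is 290, so the default design
# carries one extra (configurable) pair.
SPECIES_SITES = {
    "acager": ["Su"],
    "acagra": ["Sk"],
    "acaexu": ["Nk", "Sk"],
    "acanig": ["Nk", "Sk", "Su"],
    "acanil": ["Su"],
    "acator": ["Sk"],
    "balmau": ["Sk"],
    "comapi": ["Nk", "Sk"],
    "comher": ["Nk", "Su"],
    "comzey": ["Su"],
    "grebic": ["Sk"],
    "grefla": ["Nk", "Sk"],
    "kigafr": ["Sk"],
    "lansch": ["Su"],
    "papcap": ["Nk", "Sk"],
    "sclbir": ["Nk", "Sk"],
    "terser": ["Nk", "Su"],
    "zizmuc": ["Nk", "Su"],
}
EXTRA_PAIR = ("comapi", "Su")


# ---------------------------------------------------------------------------
# climate


@dataclass
class ClimateConfig:
    """Synthetic weekly climate for a semi-arid austral-summer savanna.

    Rainfall is a zero-inflated gamma process: each week is wet with a
    seasonally varying probability and wet-week totals are gamma with a
    seasonally varying mean. Both seasonalities follow
    ``exp(kappa * (cos(2*pi*(doy - peak)/365) - 1))``, peaking in
    mid-summer. The gamma mean scale is set analytically so the expected
    annual total equals ``annual_rain_mm``; ``rain_kappa``/``wet_prob_max``
    were calibrated once against the target onset date and frozen.
    """

    start: str = "2000-01-03"
    end: str = "2023-08-01"
    temp_mean: float = 22.0  # deg C
    temp_amp: float = 6.0
    temp_peak_doy: float = 15.0  # mid-January
    temp_noise_sd: float = 1.2
    rad_mean: float = 230.0  # W m-2
    rad_amp: float = 80.0
    rad_peak_doy: float = 355.0  # summer solstice
    rad_noise_sd: float = 12.0
    annual_rain_mm: float = 550.0
    rain_peak_doy: float = 10.0
    rain_kappa: float = 0.8
    wet_prob_max: float = 0.82
    rain_shape: float = 2.0  # gamma shape of wet-week totals
    # lognormal year-scale anomaly (drought/wet years) applied to wet-week
    # totals within each July-June rain year; mean 1 so the long-run annual
    # total is preserved
    annual_anomaly_sd: float = 0.3


def _seasonal(doy: np.ndarray, peak: float, kappa: float) -> np.ndarray:
    return np.exp(kappa * (np.cos(2 * np.pi * (doy - peak) / 365.0) - 1.0))


def generate_climate(config: ClimateConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Weekly synthetic forcing table; deterministic given the seed."""
    cfg = config or ClimateConfig()
    rng = np.random.default_rng(seed)
    dates = pd.date_range(cfg.start, cfg.end, freq="7D")
    doy = dates.dayofyear.to_numpy().astype(float)

    temp = (
        cfg.temp_mean
        + cfg.temp_amp * np.cos(2 * np.pi * (doy - cfg.temp_peak_doy) / 365.0)
        + rng.normal(0.0, cfg.temp_noise_sd, len(dates))
    )
    rad = np.clip(
        cfg.rad_mean
        + cfg.rad_amp * np.cos(2 * np.pi * (doy - cfg.rad_peak_doy) / 365.0)
        + rng.normal(0.0, cfg.rad_noise_sd, len(dates)),
        20.0,
        None,
    )

    seas = _seasonal(doy, cfg.rain_peak_doy, cfg.rain_kappa)
    p_wet = np.minimum(cfg.wet_prob_max * seas, 0.95)
    # solve the gamma-mean scale m0 so the expected total over the actual
    # weekly grid matches the target annual total
    n_years = (dates[-1] - dates[0] + pd.Timedelta(days=7)) / pd.Timedelta(days=365.25)
    m0 = cfg.annual_rain_mm * n_years / float(np.sum(p_wet * seas))
    mean_amt = m0 * seas

    wet = rng.uniform(size=len(dates)) < p_wet
    amounts = rng.gamma(cfg.rain_shape, mean_amt / cfg.rain_shape)
    if cfg.annual_anomaly_sd > 0:
        sig = cfg.annual_anomaly_sd
        rain_year = np.where(dates.month >= 7, dates.year, dates.year - 1)
        years, inverse = np.unique(rain_year, return_inverse=True)
        mult = np.exp(rng.normal(-0.5 * sig**2, sig, len(years)))
        amounts = amounts * mult[inverse]
    precip = np.where(wet, amounts, 0.0)

    return pd.DataFrame(
        {
            "week_start_date": dates,
            "temperature": temp,
            "precip": precip,
            "radiation": rad,
        }
    )


def annual_rainfall_totals(climate: pd.DataFrame) -> pd.Series:
    """Annual precipitation totals over July-June rain years."""
    d = pd.DatetimeIndex(climate["week_start_date"])
    rain_year = np.where(d.month >= 7, d.year, d.year - 1)
    totals = climate.groupby(rain_year)["precip"].sum()
    # drop partial first/last years
    counts = climate.groupby(rain_year)["precip"].size()
    return totals[counts >= 50]


def wet_season_onsets(climate: pd.DataFrame, threshold_mm: float = 25.0) -> pd.Series:
    """Per rain-year onset DOY: first post-1-July week whose trailing
    30-day rainfall exceeds the threshold; the onset day is that week's
    midpoint."""
    d = pd.DatetimeIndex(climate["week_start_date"])
    trailing = climate["precip"].rolling(5, min_periods=5).sum().to_numpy()
    # 5 weeks = 35 days; rescale to a 30-day window
    trailing = trailing * (30.0 / 35.0)
    rain_year = np.where(d.month >= 7, d.year, d.year - 1)
    doy_mid = d.dayofyear.to_numpy() + 3.5
    onsets = {}
    for year in np.unique(rain_year)[1:-1]:
        mask = rain_year == year
        hit = mask & (trailing > threshold_mm)
        if hit.any():
            onsets[int(year)] = float(doy_mid[hit][0] % 365.0)
    return pd.Series(onsets)


# ---------------------------------------------------------------------------
# study design and roster


@dataclass
class StudyDesign:
    """Monitoring design: roster layout, visit schedule, death process."""

    species_sites: dict = field(default_factory=lambda: {k: list(v) for k, v in SPECIES_SITES.items()})
    extra_pair: tuple | None = EXTRA_PAIR
    n_per_site: int = 10
    first_visit: str = "2015-08-15"
    n_years: int = 8
    visit_day: int = 15
    death_prob: float = 0.02  # annual per-tree hazard
    spinup_start: str = "2000-01-03"

    @property
    def pairs(self) -> list:
        pairs = [(sp, site) for sp, sites in sorted(self.species_sites.items()) for site in sites]
        if self.extra_pair is not None:
            pairs.append(self.extra_pair)
        return pairs

    @property
    def n_trees(self) -> int:
        return len(self.pairs) * self.n_per_site

    @property
    def visit_dates(self) -> pd.DatetimeIndex:
        first = pd.Timestamp(self.first_visit)
        return pd.DatetimeIndex(
            [first + pd.DateOffset(months=m) for m in range(12 * self.n_years)]
        )


def generate_roster(design: StudyDesign | None = None, seed: int = 0) -> pd.DataFrame:
    """Tree roster with annual deaths and August replacements.

    A tree that dies during a phenological year is observed through July
    (the death takes effect at the year boundary) and replaced the
    following August under a fresh identifier, so every slot stays
    occupied for the whole study.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    start_year = pd.Timestamp(design.first_visit).year
    study_start = pd.Timestamp(f"{start_year}-08-01")
    study_end = pd.Timestamp(f"{start_year + design.n_years}-07-31")
    rows = []
    for species, site in design.pairs:
        for slot in range(design.n_per_site):
            serial = 0
            active_from = study_start
            for year in range(start_year, start_year + design.n_years):
                dies = rng.uniform() < design.death_prob
                year_end = pd.Timestamp(f"{year + 1}-07-31")
                if dies and year_end < study_end:
                    rows.append(
                        {
                            "tree_id": f"{species}_{site}_{slot:02d}_{serial}",
                            "species": species,
                            "site": site,
                            "active_from": active_from,
                            "active_to": year_end,
                        }
                    )
                    serial += 1
                    active_from = pd.Timestamp(f"{year + 1}-08-01")
            rows.append(
                {
                    "tree_id": f"{species}_{site}_{slot:02d}_{serial}",
                    "species": species,
                    "site": site,
                    "active_from": active_from,
                    "active_to": pd.NaT,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# species archetypes


@dataclass
class SpeciesArchetype:
    """A point in the masting-metric space used to generate a species.

    The observation parameters are on the z-scored predictor scale used
    throughout the pipeline. ``high_volatility`` places the first
    intercept far into the right tail of the substrate distribution with
    a steep slope, so reproduction is intermittent, large and shared
    among trees (high CV / synchrony / failures); ``aseasonal_null`` has
    beta = 0 (scores iid categorical).
    """

    name: str
    obs_params: ObservationParams
    process_params: ProcessParams = field(default_factory=ProcessParams)


def _leaf_block():
    return {
        "delta": np.array([-1.2, -0.3, 0.6, 1.5]),
        "beta": 2.5,
    }


def default_archetypes() -> dict:
    leaf = _leaf_block()

    def params(delta_fl, beta_fl, delta_fr, beta_fr, lam_fl, lam_fr):
        return ObservationParams(
            delta={
                "leaf": leaf["delta"],
                "flower": np.asarray(delta_fl, dtype=float),
                "fruit": np.asarray(delta_fr, dtype=float),
            },
            beta={"leaf": leaf["beta"], "flower": beta_fl, "fruit": beta_fr},
            lam={"flower": lam_fl, "fruit": lam_fr},
        )

    # the high-volatility archetype carries a drought-sensitive theta:
    # its moisture response saturates only in unusually wet years, so the
    # substrate signal -- and with the steep ordinal threshold, flowering
    # -- is concentrated in a few mast years
    theta_hv = ProcessParams(
        a_C=1.6,
        moisture_response=(10.0, 90.0, 500.0, 1000.0),
        moisture_response_N=(15.0, 100.0, 500.0, 1000.0),
    )
    return {
        "resource_matcher": SpeciesArchetype(
            "resource_matcher",
            params([1.2, 2.2, 3.2, 4.2], 2.0, [1.4, 2.4, 3.4, 4.4], 2.0, 8.0, 20.0),
        ),
        "high_volatility": SpeciesArchetype(
            "high_volatility",
            params([4.5, 5.3, 6.1, 6.9], 4.0, [4.2, 5.0, 5.8, 6.6], 4.0, 6.0, 18.0),
            theta_hv,
        ),
        "low_fecundity": SpeciesArchetype(
            "low_fecundity",
            params([3.0, 3.8, 4.6, 5.4], 1.0, [3.5, 4.3, 5.1, 5.9], 1.0, 10.0, 24.0),
        ),
        "aseasonal_null": SpeciesArchetype(
            "aseasonal_null",
            params([1.0, 2.0, 3.0, 4.0], 0.0, [1.2, 2.2, 3.2, 4.2], 0.0, 0.0, 0.0),
        ),
    }


#: default species -> archetype assignment spanning the metric space
DEFAULT_ARCHETYPE_MAP = {
    "acager": "low_fecundity",
    "acagra": "high_volatility",
    "acaexu": "resource_matcher",
    "acanig": "resource_matcher",
    "acanil": "low_fecundity",
    "acator": "high_volatility",
    "balmau": "low_fecundity",
    "comapi": "resource_matcher",
    "comher": "resource_matcher",
    "comzey": "high_volatility",
    "grebic": "aseasonal_null",
    "grefla": "resource_matcher",
    "kigafr": "aseasonal_null",
    "lansch": "resource_matcher",
    "papcap": "resource_matcher",
    "sclbir": "resource_matcher",
    "terser": "high_volatility",
    "zizmuc": "resource_matcher",
}


# ---------------------------------------------------------------------------
# study generation


def _standardized_predictors(traj: pd.DataFrame, study_start: pd.Timestamp):
    """z-scored (U_C, S) weekly arrays over the study window."""
    win = pd.DatetimeIndex(traj["date"]) >= study_start
    u = traj["U_C"].to_numpy(dtype=float)
    s = traj["S"].to_numpy(dtype=float)
    u = (u - u[win].mean()) / max(u[win].std(), 1e-12)
    s = (s - s[win].mean()) / max(s[win].std(), 1e-12)
    return u, s


def generate_study(
    design: StudyDesign | None = None,
    archetype_map: dict | None = None,
    archetypes: dict | None = None,
    climate: pd.DataFrame | None = None,
    seed: int = 0,
):
    """Generate a full synthetic study.

    Returns ``(observations, roster, climate, truth)`` where ``truth``
    records each species' archetype and generating parameters. All trees
    of a species share the deterministic site trajectory; between-tree
    variation is purely observational (independent categorical draws),
    mirroring the structure of the fitted model.
    """
    design = design or StudyDesign()
    archetype_map = archetype_map or dict(DEFAULT_ARCHETYPE_MAP)
    archetypes = archetypes or default_archetypes()
    missing = set(design.species_sites) - set(archetype_map)
    if missing:
        raise ValueError(f"species without an archetype: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    if climate is None:
        climate = generate_climate(
            ClimateConfig(start=design.spinup_start), seed=int(rng.integers(2**31))
        )
    roster = generate_roster(design, seed=int(rng.integers(2**31)))

    visits = design.visit_dates
    t0 = pd.Timestamp(climate["week_start_date"].iloc[0])
    n_weeks = len(climate)
    grid = np.arange(n_weeks, dtype=float)
    visit_weeks = ((visits - t0) / pd.Timedelta(days=7)).to_numpy(dtype=float)
    study_start = pd.Timestamp(design.first_visit)

    frames = []
    truth = {}
    for species in sorted(design.species_sites):
        arch = archetypes[archetype_map[species]]
        op = arch.obs_params
        traj = simulate_trajectory(climate, arch.process_params)
        u, s = _standardized_predictors(traj, study_start)
        # per-phenophase class probabilities at every visit (shared by all
        # trees and sites of the species: identical forcing, one theta)
        probs = {}
        for ph in PHENOPHASES:
            lam = op.lam.get(ph, 0.0) if ph in LAGGED_PHENOPHASES else 0.0
            series = u if ph == "leaf" else s
            x = np.interp(visit_weeks - lam, grid, series)
            probs[ph] = ordinal_probs(x, op.delta[ph], op.beta[ph])
        trees = roster.loc[roster["species"] == species]
        for _, tree in trees.iterrows():
            active_to = tree["active_to"] if pd.notna(tree["active_to"]) else visits[-1]
            active = (visits >= tree["active_from"]) & (visits <= active_to)
            for ph in PHENOPHASES:
                P = probs[ph][active]
                cum = np.cumsum(P, axis=1)
                draws = rng.uniform(size=(len(P), 1))
                scores = (draws > cum[:, :-1]).sum(axis=1)
                frames.append(
                    pd.DataFrame(
                        {
                            "tree_id": tree["tree_id"],
                            "species": species,
                            "site": tree["site"],
                            "date": visits[active],
                            "phenophase": ph,
                            "score": scores.astype(int),
                        }
                    )
                )
        truth[species] = {
            "archetype": arch.name,
            "obs_params": op.to_dict(),
        }

    observations = pd.concat(frames, ignore_index=True)
    observations = observations.sort_values(
        ["species", "site", "tree_id", "date", "phenophase"], ignore_index=True
    )
    return observations, roster, climate, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
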