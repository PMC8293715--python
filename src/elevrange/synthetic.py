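"""Synthetic community, station-climate and environment-scenario generators.

Everything here is a pure function of ``(config, config.seed)``: independent
seed substreams are derived per stage, so e.g. regenerating the climate
series never perturbs the community draw.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .community import AREAL_TYPE_TABLE, OccurrenceData
from .config import ConfigError, SyntheticConfig

__all__ = [
    "SyntheticCommunity",
    "plot_elevations",
    "generate_community",
    "generate_station_climate",
    "generate_env_scenario",
    "write_community_csvs",
]

# fixed stage keys for seed substreams
_STAGES = {"plots": 1, "community": 2, "climate": 3, "scenario": 4}


def _rng(config: SyntheticConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), _STAGES[stage])))


@dataclasses.dataclass(frozen=True)
class SyntheticCommunity:
    """A generated survey: occurrences, species traits, and the latent truth.

    ``latent`` keeps each species' drawn midpoint and range interval so that
    parameter-recovery checks can compare observed against planted geometry.
    """

    occurrences: OccurrenceData
    traits: pd.DataFrame        # species_id, life_form, areal_type
    latent: pd.DataFrame        # species_id, midpoint_m, latent_size_m, lo_m, hi_m


def plot_elevations(config: SyntheticConfig) -> np.ndarray:
    """Evenly spaced plot elevations on the domain, optionally jittered.

    The jitter substream is independent of the community draw so that every
    generator sees the same plot locations.
    """
    elevs = np.linspace(config.domain_low, config.domain_high, config.n_plots)
    if config.plot_jitter_sd > 0:
        rng = _rng(config, "plots")
        elevs = elevs + rng.normal(0.0, config.plot_jitter_sd, size=config.n_plots)
        elevs = np.clip(np.sort(elevs), config.domain_low, config.domain_high)
    return elevs


def _sample_labels(rng: np.random.Generator, proportions, n: int) -> np.ndarray:
    labels = list(proportions.keys())
    probs = np.asarray([proportions[k] for k in labels], dtype=float)
    return rng.choice(np.asarray(labels, dtype=object), size=n, p=probs / probs.sum())


def _areal_types_for(rng: np.random.Generator, affinity: np.ndarray) -> np.ndarray:
    """Pick concrete distribution-centre labels mapping to each affinity."""
    options = {
        aff: grp.loc[grp["canonical"], "areal_type"].tolist()
        for aff, grp in AREAL_TYPE_TABLE.groupby("affinity")
    }
    out = np.empty(affinity.size, dtype=object)
    for aff in np.unique(affinity):
        idx = np.flatnonzero(affinity == aff)
        out[idx] = rng.choice(np.asarray(options[aff], dtype=object), size=idx.size)
    return out


def generate_community(config: SyntheticConfig) -> SyntheticCommunity:
    """Draw a plot x species presence/absence survey with planted geometry.

    Species ``i`` draws a midpoint ``m_i ~ U(domain)`` and a latent size
    ``r_i = max(0, a + b_i (m_i - domain_low) + eps)``; its occupied interval
    is ``[m_i - r_i/2, m_i + r_i/2]``. With ``truncate_to_domain`` the size
    is capped at the domain width and the midpoint is clamped into the
    feasible interval ``[low + r/2, high - r/2]``, so the interval fits the
    domain with its size intact (a domain-wide range then spans every plot).
    A species is recorded in a plot iff the plot elevation lies in the
    interval (closed) and an independent ``Bernoulli(detection_prob)``
    detection succeeds.
    """
    config.validate()
    rng = _rng(config, "community")
    n_sp = config.n_species
    elevs = plot_elevations(config)

    species_ids = [f"sp{i + 1:04d}" for i in range(n_sp)]
    life_form = _sample_labels(rng, config.life_form_proportions, n_sp)
    affinity = _sample_labels(rng, config.affinity_proportions, n_sp)
    areal_type = _areal_types_for(rng, affinity)

    slopes = np.full(n_sp, config.rapoport_slope_b, dtype=float)
    if config.group_slopes:
        for i in range(n_sp):
            if life_form[i] in config.group_slopes:
                slopes[i] = config.group_slopes[life_form[i]]
            elif affinity[i] in config.group_slopes:
                slopes[i] = config.group_slopes[affinity[i]]

    midpoints = rng.uniform(config.domain_low, config.domain_high, size=n_sp)
    noise = (
        rng.normal(0.0, config.range_noise_sd, size=n_sp)
        if config.range_noise_sd > 0
        else np.zeros(n_sp)
    )
    latent_size = np.maximum(
        0.0, config.base_range_a + slopes * (midpoints - config.domain_low) + noise
    )
    if config.truncate_to_domain:
        # keep the drawn size, shift the midpoint into its feasible interval —
        # the same geometry the mid-domain null model uses
        width = config.domain_high - config.domain_low
        latent_size = np.minimum(latent_size, width)
        eff_mid = np.clip(
            midpoints,
            config.domain_low + latent_size / 2.0,
            config.domain_high - latent_size / 2.0,
        )
    else:
        eff_mid = midpoints
    lo = eff_mid - latent_size / 2.0
    hi = eff_mid + latent_size / 2.0

    inside = (elevs[None, :] >= lo[:, None]) & (elevs[None, :] <= hi[:, None])
    if config.detection_prob < 1.0:
        detected = rng.random((n_sp, config.n_plots)) < config.detection_prob
        inside &= detected
    matrix = pd.DataFrame(
        inside.T.astype(int),
        index=pd.Index([f"p{j + 1:03d}" for j in range(config.n_plots)], name="plot_id"),
        columns=species_ids,
    )
    plots = pd.DataFrame(
        {
            "plot_id": matrix.index,
            "elevation_m": elevs,
            "x": np.zeros(config.n_plots),
            "y": elevs,  # along-valley position proxied by elevation
        }
    )
    occ = OccurrenceData(plots=plots, matrix=matrix)
    traits = pd.DataFrame(
        {"species_id": species_ids, "life_form": life_form, "areal_type": areal_type}
    )
    latent = pd.DataFrame(
        {
            "species_id": species_ids,
            "midpoint_m": midpoints,
            "latent_size_m": latent_size,
            "lo_m": lo,
            "hi_m": hi,
        }
    )
    return SyntheticCommunity(occurrences=occ, traits=traits, latent=latent)


def generate_station_climate(config: SyntheticConfig) -> pd.DataFrame:
    """Monthly station series: station_id, elevation_m, year, month, temp_c, precip_mm.

    Temperature follows a linear lapse with a mid-summer-peaking seasonal
    cosine, ``T(z, m) = T0 - lapse*z/1000 + A*cos(2*pi*(m-7)/12) + noise``;
    monthly precipitation declines linearly with elevation and is floored
    at zero.
    """
    config.validate()
    rng = _rng(config, "climate")
    rows = []
    months = np.arange(1, 13)
    seasonal = config.seasonal_amplitude * np.cos(2.0 * np.pi * (months - 7) / 12.0)
    for si, z in enumerate(config.station_elevations):
        base_t = config.t0_sea_level_c - config.lapse_rate * z / 1000.0
        base_p = (config.precip_base + config.precip_gradient * z) / 12.0
        for yi in range(config.n_years):
            t_noise = (
                rng.normal(0.0, config.temp_noise_sd, size=12)
                if config.temp_noise_sd > 0
                else np.zeros(12)
            )
            p_noise = (
                rng.normal(0.0, config.precip_noise_sd, size=12)
                if config.precip_noise_sd > 0
                else np.zeros(12)
            )
            for mi, month in enumerate(months):
                rows.append(
                    {
                        "station_id": f"st{si + 1}",
                        "elevation_m": float(z),
                        "year": config.first_year + yi,
                        "month": int(month),
                        "temp_c": base_t + seasonal[mi] + t_noise[mi],
                        "precip_mm": max(0.0, base_p + p_noise[mi]),
                    }
                )
    return pd.DataFrame(rows)


def present_climate_formula(config: SyntheticConfig, elevations: np.ndarray):
    """Noise-free annual MAT (°C) and MAP (mm) implied by the generator."""
    z = np.asarray(elevations, dtype=float)
    mat = config.t0_sea_level_c - config.lapse_rate * z / 1000.0
    map_ = np.maximum(0.0, config.precip_base + config.precip_gradient * z)
    return mat, map_


def generate_env_scenario(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the LGM climate table and the village/population table.

    Returns ``(lgm, villages)``. ``lgm`` holds per plot and per model the
    Last-Glacial-Maximum annual climate, built as present climate minus a
    smooth elevation-dependent warming/wetting offset (so the downstream
    present-minus-LGM deltas TC and PC are positive and decline with
    elevation). ``villages`` holds the population centres — by default the
    two towns at 2,700 and 4,200 m — plus minor villages along the valley,
    yielding a bimodal interpolated population surface.
    """
    config.validate()
    rng = _rng(config, "scenario")
    elevs = plot_elevations(config)
    plot_ids = [f"p{j + 1:03d}" for j in range(config.n_plots)]
    mat, map_ = present_climate_formula(config, elevs)
    frac = (elevs - config.domain_low) / (config.domain_high - config.domain_low)
    warming = config.lgm_warming_low + frac * (config.lgm_warming_high - config.lgm_warming_low)
    wetting = config.lgm_wetting_low + frac * (config.lgm_wetting_high - config.lgm_wetting_low)

    lgm_rows = []
    for m in range(config.n_lgm_models):
        dt = rng.normal(0.0, config.lgm_model_sd_t) if config.lgm_model_sd_t > 0 else 0.0
        dp = rng.normal(0.0, config.lgm_model_sd_p) if config.lgm_model_sd_p > 0 else 0.0
        lgm_rows.append(
            pd.DataFrame(
                {
                    "plot_id": plot_ids,
                    "model": f"gcm{m + 1}",
                    "mat_c": mat - (warming + dt),
                    "map_mm": map_ - (wetting + dp),
                }
            )
        )
    lgm = pd.concat(lgm_rows, ignore_index=True)

    vil_rows = [
        {"name": f"town{i + 1}", "elevation_m": float(e), "population": float(p)}
        for i, (e, p) in enumerate(config.pop_centers)
    ]
    if config.n_minor_villages > 0:
        minors = np.linspace(
            config.domain_low, config.domain_high, config.n_minor_villages + 2
        )[1:-1]
        pops = config.minor_village_pop * rng.uniform(0.5, 1.5, size=config.n_minor_villages)
        for i, (e, p) in enumerate(zip(minors, pops)):
            vil_rows.append(
                {"name": f"village{i + 1}", "elevation_m": float(e), "population": float(p)}
            )
    villages = pd.DataFrame(vil_rows)
    return lgm, villages


def write_community_csvs(community: SyntheticCommunity, outdir) -> dict:
    """Write plots.csv / matrix.csv / traits.csv in the pipeline's dialects."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plots": outdir / "plots.csv",
        "matrix": outdir / "matrix.csv",
        "traits": outdir / "traits.csv",
    }
    community.occurrences.plots.to_csv(paths["plots"], index=False)
    community.occurrences.matrix.to_csv(paths["matrix"])
    community.traits.to_csv(paths["traits"], index=False)
    return paths
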