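"""Per-plot environmental predictors along the elevational gradient.

Builds the eight predictors used downstream: station-derived climate
summaries (MAT, MAP, TS, MATR) interpolated to the plots by 1-D ordinary
kriging over elevation, present-minus-LGM climate deltas (TC, PC),
inverse-distance-weighted human population (POP), and the mid-domain-effect
prediction (MDE) from :mod:`elevrange.mde`.

The interpolation is deliberately one-dimensional: along a single valley
the elevation axis carries essentially all of the climatic signal, so the
2-D geostatistical problem reduces to kriging on elevation.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .mde import MdeResult

__all__ = [
    "EnvError",
    "station_summaries",
    "krige_1d",
    "idw_population",
    "lgm_deltas",
    "assemble_env_table",
    "ENV_COLUMNS",
]

logger = logging.getLogger(__name__)

#: fixed predictor order of the assembled table
ENV_COLUMNS = ("mat", "map", "matr", "ts", "tc", "pc", "mde", "pop")


class EnvError(ValueError):
    pass


def station_summaries(series: pd.DataFrame) -> pd.DataFrame:
    """Per-station MAT, MAP, TS and MATR, averaged across years.

    For each station-year: MAT is the mean of the 12 monthly mean
    temperatures; MAP the sum of monthly precipitation; TS the population
    (n = 12) standard deviation of monthly mean temperatures; MATR the
    warmest- minus coldest-month mean. Yearly values are then averaged
    across the years on record. Incomplete months raise an error naming
    the station and year.
    """
    required = {"station_id", "elevation_m", "year", "month", "temp_c", "precip_mm"}
    missing_cols = required - set(series.columns)
    if missing_cols:
        raise EnvError(f"station series missing column(s) {sorted(missing_cols)}")
    rows = []
    for (sid, year), grp in series.groupby(["station_id", "year"], sort=True):
        months = sorted(grp["month"].tolist())
        if months != list(range(1, 13)):
            raise EnvError(f"station {sid!r} year {year}: expected months 1..12, got {months}")
        temps = grp.sort_values("month")["temp_c"].to_numpy(dtype=float)
        precs = grp.sort_values("month")["precip_mm"].to_numpy(dtype=float)
        rows.append(
            {
                "station_id": sid,
                "elevation_m": float(grp["elevation_m"].iloc[0]),
                "year": year,
                "mat": float(temps.mean()),
                "map": float(precs.sum()),
                "ts": float(temps.std(ddof=0)),
                "matr": float(temps.max() - temps.min()),
            }
        )
    per_year = pd.DataFrame(rows)
    out = (
        per_year.groupby(["station_id", "elevation_m"], as_index=False)[
            ["mat", "map", "ts", "matr"]
        ]
        .mean()
        .sort_values("elevation_m")
        .reset_index(drop=True)
    )
    return out


def _variogram(h: np.ndarray, model: str, c: float, vrange: float | None) -> np.ndarray:
    if model == "linear":
        return c * h
    if model == "spherical":
        if not vrange or vrange <= 0:
            raise EnvError("spherical variogram needs a positive range")
        x = np.minimum(h / vrange, 1.0)
        return c * (1.5 * x - 0.5 * x**3)
    raise EnvError(f"unknown variogram model {model!r}")


def krige_1d(
    station_elevs,
    station_values,
    target_elevs,
    variogram: str = "linear",
    c: float = 1.0,
    vrange: float | None = None,
) -> np.ndarray:
    """Ordinary kriging of station values along the elevation axis.

    Solves the standard ordinary-kriging system with variogram
    ``gamma(h)`` (linear ``c*h`` by default — parameter-free up to scale,
    since the weights do not depend on ``c``). The interpolator is exact
    at station elevations; targets outside the station span extrapolate
    and are logged.
    """
    z = np.asarray(station_elevs, dtype=float)
    v = np.asarray(station_values, dtype=float)
    t = np.atleast_1d(np.asarray(target_elevs, dtype=float))
    if z.size != v.size:
        raise EnvError("station elevations and values differ in length")
    if z.size < 2:
        raise EnvError("kriging needs >= 2 stations")
    # collapse duplicate stations; conflicting values are an error
    order = np.argsort(z, kind="stable")
    z, v = z[order], v[order]
    keep_z, keep_v = [z[0]], [v[0]]
    for zi, vi in zip(z[1:], v[1:]):
        if zi == keep_z[-1]:
            if vi != keep_v[-1]:
                raise EnvError(f"conflicting station values {keep_v[-1]} vs {vi} at {zi} m")
            continue
        keep_z.append(zi)
        keep_v.append(vi)
    z = np.asarray(keep_z)
    v = np.asarray(keep_v)
    n = z.size
    if n < 2:
        raise EnvError("kriging needs >= 2 distinct station elevations")
    if (t.min() < z.min()) or (t.max() > z.max()):
        logger.info(
            "kriging extrapolates beyond the station span [%g, %g] m", z.min(), z.max()
        )

    gamma = _variogram(np.abs(z[:, None] - z[None, :]), variogram, c, vrange)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    B = np.empty((n + 1, t.size))
    B[:n, :] = _variogram(np.abs(z[:, None] - t[None, :]), variogram, c, vrange)
    B[n, :] = 1.0
    sol = np.linalg.solve(A, B)
    return sol[:n, :].T @ v


def idw_population(villages: pd.DataFrame, targets, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted population surface at the target locations.

    ``villages`` needs ``population`` plus either ``elevation_m``
    (along-gradient distance, the default geometry) or ``x``/``y``.
    A target coincident with one or more villages takes the mean of the
    coincident populations — the limit of the IDW weights as d -> 0.
    """
    if power <= 0:
        raise EnvError(f"IDW power must be > 0, got {power}")
    if len(villages) == 0:
        raise EnvError("IDW needs >= 1 village")
    pop = villages["population"].to_numpy(dtype=float)
    if "elevation_m" in villages.columns:
        src = villages[["elevation_m"]].to_numpy(dtype=float)
        tgt = np.atleast_1d(np.asarray(targets, dtype=float)).reshape(-1, 1)
    else:
        src = villages[["x", "y"]].to_numpy(dtype=float)
        tgt = np.asarray(targets, dtype=float).reshape(-1, 2)
    d = cdist(tgt, src)
    out = np.empty(tgt.shape[0])
    for i in range(tgt.shape[0]):
        hit = d[i] == 0.0
        if hit.any():
            out[i] = pop[hit].mean()
        else:
            w = d[i] ** (-power)
            out[i] = float(np.dot(w, pop) / w.sum())
    return out


def lgm_deltas(present: pd.DataFrame, lgm: pd.DataFrame) -> pd.DataFrame:
    """Present-minus-LGM climate deltas per plot (TC in °C, PC in mm).

    ``present`` has ``plot_id, mat, map``; ``lgm`` has
    ``plot_id, model, mat_c, map_mm`` and may carry several palaeoclimate
    models, which are averaged first. Positive values mean the present is
    warmer / wetter than the Last Glacial Maximum.
    """
    for col in ("plot_id", "mat", "map"):
        if col not in present.columns:
            raise EnvError(f"present climate table missing column {col!r}")
    for col in ("plot_id", "model", "mat_c", "map_mm"):
        if col not in lgm.columns:
            raise EnvError(f"LGM table missing column {col!r}")
    lgm_mean = lgm.groupby("plot_id", as_index=False)[["mat_c", "map_mm"]].mean()
    merged = present.merge(lgm_mean, on="plot_id", how="left", validate="one_to_one")
    if merged[["mat_c", "map_mm"]].isna().any().any():
        bad = merged.loc[merged["mat_c"].isna(), "plot_id"].iloc[0]
        raise EnvError(f"LGM table missing plot {bad!r}")
    extra = set(lgm_mean["plot_id"]) - set(present["plot_id"])
    if extra:
        raise EnvError(f"LGM table has plots absent from the present table: {sorted(extra)[:3]}")
    return pd.DataFrame(
        {
            "plot_id": merged["plot_id"],
            "tc": merged["mat"] - merged["mat_c"],
            "pc": merged["map"] - merged["map_mm"],
        }
    )


def assemble_env_table(
    plots: pd.DataFrame,
    mat,
    map_,
    matr,
    ts,
    deltas: pd.DataFrame,
    pop,
    mde_result: MdeResult,
) -> pd.DataFrame:
    """Join the eight predictors into one complete row per plot.

    Column order is fixed (``mat, map, matr, ts, tc, pc, mde, pop``); any
    plot missing from any component is an error naming plot and variable.
    """
    n = len(plots)
    out = pd.DataFrame(
        {"plot_id": plots["plot_id"].to_numpy(), "elevation_m": plots["elevation_m"].to_numpy()}
    )
    for name, arr in (("mat", mat), ("map", map_), ("matr", matr), ("ts", ts), ("pop", pop)):
        arr = np.asarray(arr, dtype=float)
        if arr.size != n:
            raise EnvError(f"variable {name!r} covers {arr.size} plots, expected {n}")
        out[name] = arr
    d = deltas.set_index("plot_id")
    for name in ("tc", "pc"):
        vals = d[name].reindex(out["plot_id"])
        if vals.isna().any():
            bad = out["plot_id"][vals.isna().to_numpy()].iloc[0]
            raise EnvError(f"variable {name!r} missing for plot {bad!r}")
        out[name] = vals.to_numpy()
    mde_tab = mde_result.table
    if len(mde_tab) != n:
        raise EnvError(f"variable 'mde' covers {len(mde_tab)} plots, expected {n}")
    out["mde"] = mde_tab["predicted_mean_range_m"].to_numpy()
    for name in ENV_COLUMNS:
        col = out[name].to_numpy()
        if np.isnan(col).any():
            bad = out["plot_id"][np.isnan(col)].iloc[0]
            raise EnvError(f"variable {name!r} is missing (NaN) for plot {bad!r}")
    return out[["plot_id", "elevation_m", *ENV_COLUMNS]]
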