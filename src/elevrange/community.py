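"""Community data model: occurrences, species grouping, elevational ranges,
and Stevens' per-plot mean range-size statistic.

A species' elevational range is the span between the highest and lowest
plot where it was recorded. Stevens' method then averages, within each
plot, the range sizes of the species present there (optionally restricted
to a life-form or biogeographical-affinity group), giving a per-plot mean
range size that can be regressed on elevation.
"""
from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LoadError",
    "OccurrenceData",
    "GROUPS",
    "AREAL_TYPE_TABLE",
    "classify_affinity",
    "load_occurrences",
    "species_ranges",
    "stevens_profile",
    "group_percentages",
]

logger = logging.getLogger(__name__)

#: valid group filters for :func:`stevens_profile`
GROUPS = ("overall", "woody", "herbaceous", "temperate", "tropical")


class LoadError(ValueError):
    """Raised when an input table violates its schema."""


def _normalise_label(label: str) -> str:
    s = str(label).strip().lower().replace("&", "and")
    s = re.sub(r"[.,;]", " ", s)
    return re.sub(r"\s+", " ", s).strip()


def _load_areal_table() -> pd.DataFrame:
    with resources.files("elevrange.data").joinpath("areal_types.csv").open("r") as fh:
        tbl = pd.read_csv(fh)
    tbl["areal_type"] = tbl["areal_type"].map(_normalise_label)
    tbl["canonical"] = tbl["canonical"].astype(bool)
    return tbl


#: shipped lookup of distribution-centre labels -> affinity, kept as data
#: (rather than code) so the classification is auditable
AREAL_TYPE_TABLE = _load_areal_table()
_AREAL_LOOKUP = dict(zip(AREAL_TYPE_TABLE["areal_type"], AREAL_TYPE_TABLE["affinity"]))


def classify_affinity(areal_type: str) -> str:
    """Map a distribution-centre (areal-type) label to a biogeographical affinity.

    Returns one of ``temperate``, ``tropical``, ``cosmopolitan`` — or
    ``unclassified`` (with a warning) for labels outside the shipped lookup.
    Matching is case- and whitespace-insensitive.
    """
    key = _normalise_label(areal_type)
    if key in _AREAL_LOOKUP:
        return _AREAL_LOOKUP[key]
    warnings.warn(
        f"unrecognised areal type {areal_type!r}; species will be 'unclassified'",
        stacklevel=2,
    )
    return "unclassified"


@dataclass(frozen=True)
class OccurrenceData:
    """Plots plus a plot x species presence/absence matrix.

    ``plots`` has columns ``plot_id, elevation_m`` (optionally ``x, y``);
    ``matrix`` is indexed by ``plot_id`` with species ids as columns and
    0/1 integer cells.
    """

    plots: pd.DataFrame
    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        plots, matrix = self.plots, self.matrix
        if plots["plot_id"].duplicated().any():
            dup = plots.loc[plots["plot_id"].duplicated(), "plot_id"].iloc[0]
            raise LoadError(f"duplicate plot id {dup!r}")
        if not np.issubdtype(np.asarray(plots["elevation_m"]).dtype, np.number):
            raise LoadError("non-numeric elevation in plot table")
        if list(matrix.index) != list(plots["plot_id"]):
            raise LoadError("matrix rows do not match the plot table's plot ids")
        values = matrix.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise LoadError(
                f"non-binary occurrence cell at plot {matrix.index[i]!r}, "
                f"species {matrix.columns[j]!r}: {values[i, j]!r}"
            )

    @property
    def elevations(self) -> np.ndarray:
        return np.asarray(self.plots["elevation_m"], dtype=float)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.columns)


def load_occurrences(plot_csv, matrix_csv, traits_csv):
    """Read and validate the plot, occurrence-matrix and traits CSVs.

    Returns ``(OccurrenceData, traits)`` where ``traits`` carries a derived
    ``affinity`` column. Species present in the matrix but absent from the
    traits table are retained with affinity ``unclassified`` and logged.
    """
    for path in (plot_csv, matrix_csv, traits_csv):
        if not Path(path).exists():
            raise LoadError(f"input file not found: {path}")
    plots = pd.read_csv(plot_csv)
    if "plot_id" not in plots.columns or "elevation_m" not in plots.columns:
        raise LoadError(f"{plot_csv}: expected columns plot_id, elevation_m")
    plots["plot_id"] = plots["plot_id"].astype(str)
    elev_numeric = pd.to_numeric(plots["elevation_m"], errors="coerce")
    if elev_numeric.isna().any():
        row = int(elev_numeric.isna().idxmax())
        raise LoadError(
            f"{plot_csv}: non-numeric elevation {plots['elevation_m'][row]!r} "
            f"in row {row} (plot {plots['plot_id'][row]!r})"
        )
    plots["elevation_m"] = elev_numeric

    matrix = pd.read_csv(matrix_csv, index_col=0)
    matrix.index = matrix.index.astype(str)
    cells = matrix.apply(pd.to_numeric, errors="coerce")
    if cells.isna().to_numpy().any():
        i, j = map(int, np.argwhere(cells.isna().to_numpy())[0])
        raise LoadError(
            f"{matrix_csv}: non-numeric cell at plot {matrix.index[i]!r}, "
            f"species {matrix.columns[j]!r}"
        )
    matrix = cells
    data = OccurrenceData(plots=plots, matrix=matrix.astype(int))

    traits = pd.read_csv(traits_csv)
    for col in ("species_id", "life_form", "areal_type"):
        if col not in traits.columns:
            raise LoadError(f"{traits_csv}: missing column {col!r}")
    traits["species_id"] = traits["species_id"].astype(str)
    missing = [s for s in data.species if s not in set(traits["species_id"])]
    if missing:
        logger.warning(
            "%d species in the matrix have no traits row (e.g. %s); "
            "kept with affinity 'unclassified'",
            len(missing),
            missing[0],
        )
        extra = pd.DataFrame(
            {"species_id": missing, "life_form": "unclassified", "areal_type": ""}
        )
        traits = pd.concat([traits, extra], ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traits["affinity"] = [
            classify_affinity(a) if str(a).strip() else "unclassified"
            for a in traits["areal_type"]
        ]
    return data, traits


def species_ranges(data: OccurrenceData) -> pd.DataFrame:
    """Elevational range of each recorded species.

    Range size is the difference between the maximum and minimum elevation
    of the plots where the species was recorded; a single-plot species has
    size 0. Species with no occurrences are excluded and logged.
    """
    elevs = data.elevations
    present = data.matrix.to_numpy().astype(bool)
    n_occ = present.sum(axis=0)
    absent = [s for s, n in zip(data.species, n_occ) if n == 0]
    if absent:
        logger.warning("%d species have zero occurrences and are skipped: %s",
                       len(absent), absent[:5])
    rows = []
    for j, sp in enumerate(data.species):
        if n_occ[j] == 0:
            continue
        occupied = elevs[present[:, j]]
        lo, hi = float(occupied.min()), float(occupied.max())
        rows.append({"species_id": sp, "min_elev": lo, "max_elev": hi, "size": hi - lo})
    return pd.DataFrame(rows, columns=["species_id", "min_elev", "max_elev", "size"])


def _group_members(group: str, traits: pd.DataFrame | None,
                   include_unclassified_in_overall: bool) -> set[str] | None:
    """Species-id set for a group filter; ``None`` means 'all species'."""
    if group == "overall":
        if include_unclassified_in_overall or traits is None:
            return None
        keep = traits["affinity"].isin(("temperate", "tropical", "cosmopolitan"))
        return set(traits.loc[keep, "species_id"])
    if traits is None:
        raise ValueError(f"group filter {group!r} needs a traits table")
    if group in ("woody", "herbaceous"):
        return set(traits.loc[traits["life_form"] == group, "species_id"])
    if group in ("temperate", "tropical"):
        if "affinity" not in traits.columns:
            traits = traits.assign(affinity=[classify_affinity(a) for a in traits["areal_type"]])
        return set(traits.loc[traits["affinity"] == group, "species_id"])
    raise ValueError(f"unknown group filter {group!r}; expected one of {GROUPS}")


def stevens_profile(
    data: OccurrenceData,
    ranges: pd.DataFrame,
    group_filter: str = "overall",
    traits: pd.DataFrame | None = None,
    include_unclassified_in_overall: bool = True,
) -> pd.DataFrame:
    """Per-plot mean elevational range size of the species present (Stevens).

    Returns ``plot_id, elevation_m, group, n_species, mean_range_m``. Plots
    holding no species of the group get ``n_species = 0`` and a missing
    (NaN) mean — an empty average is undefined, not zero, and downstream
    regressions drop such plots.
    """
    if group_filter not in GROUPS:
        raise ValueError(f"unknown group filter {group_filter!r}; expected one of {GROUPS}")
    members = _group_members(group_filter, traits, include_unclassified_in_overall)
    size_by_sp = dict(zip(ranges["species_id"], ranges["size"]))
    rows = []
    present = data.matrix.to_numpy().astype(bool)
    for i, (pid, elev) in enumerate(zip(data.plots["plot_id"], data.elevations)):
        sizes = [
            size_by_sp[sp]
            for j, sp in enumerate(data.species)
            if present[i, j] and sp in size_by_sp and (members is None or sp in members)
        ]
        rows.append(
            {
                "plot_id": pid,
                "elevation_m": float(elev),
                "group": group_filter,
                "n_species": len(sizes),
                "mean_range_m": float(np.mean(sizes)) if sizes else np.nan,
            }
        )
    return pd.DataFrame(rows)


def group_percentages(traits: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of species per life-form and affinity group.

    Percentages are 100 x count / total recorded species, rounded to two
    decimals.
    """
    if len(traits) == 0:
        raise ValueError("empty species traits table")
    if "affinity" in traits.columns:
        affinity = traits["affinity"]
    else:
        affinity = pd.Series([classify_affinity(a) for a in traits["areal_type"]],
                             index=traits.index)
    total = len(traits)
    rows = []
    for group in ("woody", "herbaceous"):
        n = int((traits["life_form"] == group).sum())
        rows.append({"group": group, "count": n, "percentage": round(100.0 * n / total, 2)})
    for group in ("temperate", "tropical", "cosmopolitan", "unclassified"):
        n = int((affinity == group).sum())
        if group in ("temperate", "tropical", "cosmopolitan") or n:
            rows.append({"group": group, "count": n, "percentage": round(100.0 * n / total, 2)})
    rows.append({"group": "total", "count": total, "percentage": 100.0})
    return pd.DataFrame(rows)
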