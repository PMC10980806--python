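"""Survey data model, readers/writers and preprocessing rules.

Raw shipboard observation logs (sightings, effort legs, weather records)
are turned into analysis-ready objects for line-transect distance
sampling: perpendicular distances are derived from radial distance and
sighting angle, sightings are restricted to the target species classes
and each vessel's primary observation quadrant(s), distant sightings are
truncated, contiguous effort is split into transects at course changes,
and missing sea-state covariates are filled from the temporally nearest
weather record.

Internal units are metres for detection distances, kilometres for
effort, and square kilometres for areas.  Nautical-mile effort input is
converted on read (1 nm = 1.852 km).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NM_TO_KM = 1.852

#: species classes retained for analysis
ANALYSIS_SPECIES = ("fin", "like_fin")

#: default primary observation quadrant(s) per vessel as closed intervals
#: of the signed sighting angle (degrees, port negative).  KPH observed
#: the port forward quadrant, CDH the starboard forward quadrant and DIS
#: both forward quadrants.
PRIMARY_QUADRANTS: Mapping[str, tuple[tuple[float, float], ...]] = {
    "KPH": ((-90.0, 0.0),),
    "CDH": ((0.0, 90.0),),
    "DIS": ((-90.0, 90.0),),
}

DEFAULT_TRUNCATION_M = 7000.0

SIGHTING_COLUMNS = [
    "id",
    "vessel",
    "observer",
    "radial_distance_m",
    "angle_deg",
    "perp_distance_m",
    "group_size",
    "species_class",
    "wind_speed_ms",
    "timestamp",
    "stratum",
    "transect_id",
]

EFFORT_COLUMNS = [
    "vessel",
    "start",
    "end",
    "heading_deg",
    "length_km",
    "stratum",
    "on_effort",
]

TRANSECT_COLUMNS = [
    "transect_id",
    "vessel",
    "stratum",
    "length_km",
    "start",
    "end",
]


@dataclass(frozen=True)
class Stratum:
    """A survey stratum: a named region with a known area in km²."""

    name: str
    area_km2: float

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError(f"stratum {self.name!r}: area must be positive")


@dataclass
class SurveyDataset:
    """Analysis-ready survey: sightings, transects and stratum areas.

    ``sightings`` and ``transects`` are data frames with the
    :data:`SIGHTING_COLUMNS` / :data:`TRANSECT_COLUMNS` schemas.
    """

    sightings: pd.DataFrame
    transects: pd.DataFrame
    strata: tuple[Stratum, ...]
    truncation_m: float = DEFAULT_TRUNCATION_M

    def stratum(self, name: str) -> Stratum:
        for s in self.strata:
            if s.name == name:
                return s
        raise KeyError(f"unknown stratum {name!r}")

    @property
    def total_area_km2(self) -> float:
        return float(sum(s.area_km2 for s in self.strata))

    def effort_km(self, stratum: str | None = None) -> float:
        t = self.transects
        if stratum is not None:
            t = t[t["stratum"] == stratum]
        return float(t["length_km"].sum())

    def validate(self) -> None:
        """Check referential integrity and basic invariants."""
        missing = [c for c in SIGHTING_COLUMNS if c not in self.sightings.columns]
        if missing:
            raise ValueError(f"sightings missing columns: {missing}")
        missing = [c for c in TRANSECT_COLUMNS if c not in self.transects.columns]
        if missing:
            raise ValueError(f"transects missing columns: {missing}")
        names = {s.name for s in self.strata}
        bad = set(self.sightings["stratum"]) - names
        if bad:
            raise ValueError(f"sightings reference unknown strata: {sorted(bad)}")
        bad = set(self.transects["stratum"]) - names
        if bad:
            raise ValueError(f"transects reference unknown strata: {sorted(bad)}")
        if (self.transects["length_km"] <= 0).any():
            raise ValueError("transect lengths must be positive")
        for s in self.strata:
            if self.effort_km(s.name) <= 0:
                raise ValueError(f"stratum {s.name!r} has no effort")
        if (self.sightings["group_size"] < 1).any():
            raise ValueError("group sizes must be >= 1")


def perpendicular_distance(radial_m, angle_deg):
    """Perpendicular distance from the trackline, ``r * |sin(angle)|``.

    ``angle_deg`` is the sighting angle relative to the bow, signed
    (port negative) on [-180, 180]; the absolute value of the sine folds
    port-side sightings onto the single-sided detection axis.  Accepts
    scalars or arrays.
    """
    radial = np.asarray(radial_m, dtype=float)
    if np.any(radial < 0):
        raise ValueError("radial distance must be non-negative")
    out = radial * np.abs(np.sin(np.radians(np.asarray(angle_deg, dtype=float))))
    if np.isscalar(radial_m) and np.isscalar(angle_deg):
        return float(out)
    return out


def derive_perpendicular(sightings: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``perp_distance_m`` computed from radial/angle."""
    out = sightings.copy()
    out["perp_distance_m"] = perpendicular_distance(
        out["radial_distance_m"].to_numpy(), out["angle_deg"].to_numpy()
    )
    return out


def truncate_sightings(
    sightings: pd.DataFrame, w_m: float = DEFAULT_TRUNCATION_M
) -> pd.DataFrame:
    """Drop sightings with perpendicular distance beyond ``w_m``.

    The boundary is inclusive: a sighting at exactly ``w_m`` is kept
    (only strictly greater distances are excluded).
    """
    if w_m <= 0:
        raise ValueError("truncation width must be positive")
    keep = sightings["perp_distance_m"] <= w_m
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("truncation at %.0f m removed %d sightings", w_m, n_removed)
    return sightings[keep].reset_index(drop=True)


def filter_species(sightings: pd.DataFrame) -> pd.DataFrame:
    """Keep certain and likely identifications of the target species.

    Both classes are weighted identically downstream.
    """
    keep = sightings["species_class"].isin(ANALYSIS_SPECIES)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("species filter removed %d sightings", n_removed)
    return sightings[keep].reset_index(drop=True)


def filter_primary_quadrant(
    sightings: pd.DataFrame,
    vessel_quadrants: Mapping[str, Sequence[tuple[float, float]]] = PRIMARY_QUADRANTS,
) -> pd.DataFrame:
    """Keep sightings inside each vessel's primary quadrant(s).

    Quadrants are closed intervals of the signed sighting angle.  A
    vessel with no configured quadrant raises.
    """
    vessels = set(sightings["vessel"])
    missing = vessels - set(vessel_quadrants)
    if missing:
        raise ValueError(f"no primary quadrant configured for vessels: {sorted(missing)}")
    angle = sightings["angle_deg"].to_numpy(dtype=float)
    keep = np.zeros(len(sightings), dtype=bool)
    for vessel, quadrants in vessel_quadrants.items():
        in_vessel = (sightings["vessel"] == vessel).to_numpy()
        ok = np.zeros(len(sightings), dtype=bool)
        for lo, hi in quadrants:
            ok |= (angle >= lo) & (angle <= hi)
        keep |= in_vessel & ok
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("quadrant filter removed %d sightings", n_removed)
    return sightings[keep].reset_index(drop=True)


def circular_heading_difference(h1, h2) -> float:
    """Smallest absolute difference between two headings, on [0, 180]."""
    d = np.abs(np.asarray(h1, dtype=float) - np.asarray(h2, dtype=float)) % 360.0
    d = np.where(d > 180.0, 360.0 - d, d)
    if np.isscalar(h1) and np.isscalar(h2):
        return float(d)
    return d


def split_transects(
    legs: pd.DataFrame, heading_threshold_deg: float = 35.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group contiguous on-effort legs into transects.

    A new transect starts at every off-effort gap (an intervening
    off-effort leg or a temporal discontinuity), at every stratum
    change, and at every circular heading change >= the threshold.

    Returns ``(transects, legs_with_ids)`` where the second frame is the
    on-effort legs annotated with their ``transect_id``.
    """
    for col in EFFORT_COLUMNS:
        if col not in legs.columns:
            raise ValueError(f"effort table missing column {col!r}")
    if (legs.loc[legs["on_effort"], "length_km"] <= 0).any():
        raise ValueError("on-effort leg lengths must be positive")

    out_rows = []
    leg_ids = []
    counter = 0
    for vessel, group in legs.groupby("vessel", sort=True):
        starts = pd.to_datetime(group["start"])
        if not starts.is_monotonic_increasing:
            raise ValueError(f"legs for vessel {vessel!r} are not time-ordered")
        prev_end = None
        prev_heading = None
        prev_stratum = None
        current = None  # (id, rows)
        for _, leg in group.iterrows():
            if not leg["on_effort"]:
                prev_end = None  # effort gap closes the transect
                current = None
                continue
            contiguous = (
                current is not None
                and prev_end is not None
                and pd.to_datetime(leg["start"]) == prev_end
                and leg["stratum"] == prev_stratum
                and circular_heading_difference(leg["heading_deg"], prev_heading)
                < heading_threshold_deg
            )
            if not contiguous:
                counter += 1
                current = {
                    "transect_id": f"{vessel}-{counter:04d}",
                    "vessel": vessel,
                    "stratum": leg["stratum"],
                    "length_km": 0.0,
                    "start": pd.to_datetime(leg["start"]),
                    "end": pd.to_datetime(leg["end"]),
                }
                out_rows.append(current)
            current["length_km"] += float(leg["length_km"])
            current["end"] = pd.to_datetime(leg["end"])
            leg_ids.append((leg.name, current["transect_id"]))
            prev_end = pd.to_datetime(leg["end"])
            prev_heading = leg["heading_deg"]
            prev_stratum = leg["stratum"]

    transects = pd.DataFrame(out_rows, columns=TRANSECT_COLUMNS)
    on_legs = legs[legs["on_effort"]].copy()
    id_map = dict(leg_ids)
    on_legs["transect_id"] = [id_map[i] for i in on_legs.index]
    return transects.reset_index(drop=True), on_legs.reset_index(drop=True)


def fill_covariate_nearest(
    sightings: pd.DataFrame,
    series: pd.DataFrame,
    column: str = "wind_speed_ms",
) -> pd.DataFrame:
    """Fill missing covariate values from the temporally nearest record.

    ``series`` has columns ``vessel``, ``timestamp`` and ``column``.
    The nearest record prior or subsequent to the sighting is used; an
    exact tie goes to the prior record.
    """
    out = sightings.copy()
    missing_mask = out[column].isna()
    if not missing_mask.any():
        return out
    affected_vessels = set(out.loc[missing_mask, "vessel"])
    for vessel in sorted(affected_vessels):
        rec = series[series["vessel"] == vessel]
        if rec.empty:
            ids = out.loc[missing_mask & (out["vessel"] == vessel), "id"].tolist()
            raise ValueError(
                f"no covariate records for vessel {vessel!r}; "
                f"affected sightings: {ids}"
            )
        rec_t = pd.to_datetime(rec["timestamp"]).to_numpy()
        order = np.argsort(rec_t, kind="stable")
        rec_t = rec_t[order]
        rec_v = rec[column].to_numpy(dtype=float)[order]
        idx = missing_mask & (out["vessel"] == vessel)
        for i in out.index[idx]:
            t = pd.to_datetime(out.at[i, "timestamp"]).to_numpy()
            deltas = np.abs(rec_t - t)
            # stable argmin prefers the earlier record on exact ties
            out.at[i, column] = rec_v[int(np.argmin(deltas))]
    return out


@dataclass
class PreprocessConfig:
    """Rules applied by :func:`preprocess`."""

    truncation_m: float = DEFAULT_TRUNCATION_M
    heading_threshold_deg: float = 35.0
    quadrants: Mapping[str, Sequence[tuple[float, float]]] = field(
        default_factory=lambda: dict(PRIMARY_QUADRANTS)
    )
    effort_unit: str = "km"  # "km" or "nm"


def preprocess(
    raw_sightings: pd.DataFrame,
    effort_legs: pd.DataFrame,
    strata: Iterable[Stratum],
    config: PreprocessConfig | None = None,
    wind_series: pd.DataFrame | None = None,
) -> tuple[SurveyDataset, dict]:
    """Run the full preprocessing pipeline on raw logs.

    Applies, in order: perpendicular-distance derivation, species and
    primary-quadrant filters, truncation, transect splitting, nearest
    covariate fill, and transect assignment for any sighting lacking a
    transect id.  Returns the dataset and a removal report.
    """
    cfg = config or PreprocessConfig()
    legs = effort_legs.copy()
    if cfg.effort_unit == "nm":
        legs["length_km"] = legs["length_km"] * NM_TO_KM
    elif cfg.effort_unit != "km":
        raise ValueError(f"unknown effort unit {cfg.effort_unit!r}")

    s = derive_perpendicular(raw_sightings)
    n0 = len(s)
    s = filter_species(s)
    n_species = n0 - len(s)
    s = filter_primary_quadrant(s, cfg.quadrants)
    n_quadrant = n0 - n_species - len(s)
    s = truncate_sightings(s, cfg.truncation_m)
    n_trunc = n0 - n_species - n_quadrant - len(s)

    transects, legs_with_ids = split_transects(legs, cfg.heading_threshold_deg)

    if wind_series is not None:
        s = fill_covariate_nearest(s, wind_series)

    if "transect_id" not in s.columns or s["transect_id"].isna().any():
        s = assign_transects(s, transects)

    dataset = SurveyDataset(
        sightings=s.reset_index(drop=True),
        transects=transects,
        strata=tuple(strata),
        truncation_m=cfg.truncation_m,
    )
    dataset.validate()
    report = {
        "input": n0,
        "removed_species": n_species,
        "removed_quadrant": n_quadrant,
        "removed_truncation": n_trunc,
        "retained": len(s),
        "transects": len(transects),
    }
    return dataset, report


def assign_transects(sightings: pd.DataFrame, transects: pd.DataFrame) -> pd.DataFrame:
    """Attach each sighting to the transect covering its timestamp.

    Matches on vessel and the transect's [start, end] interval; a
    sighting matching no interval is attached to the nearest transect of
    its vessel in time.
    """
    out = sightings.copy()
    if "transect_id" not in out.columns:
        out["transect_id"] = pd.NA
    for i in out.index[out["transect_id"].isna()]:
        vessel = out.at[i, "vessel"]
        t = pd.to_datetime(out.at[i, "timestamp"])
        cand = transects[transects["vessel"] == vessel]
        if cand.empty:
            raise ValueError(f"no transects for vessel {vessel!r}")
        starts = pd.to_datetime(cand["start"])
        ends = pd.to_datetime(cand["end"])
        inside = cand[(starts <= t) & (t <= ends)]
        if len(inside):
            out.at[i, "transect_id"] = inside.iloc[0]["transect_id"]
        else:
            gap = np.minimum(np.abs(starts - t), np.abs(ends - t))
            out.at[i, "transect_id"] = cand.iloc[int(np.argmin(gap))]["transect_id"]
    return out


# ---------------------------------------------------------------------------
# readers / writers


def write_survey(dataset: SurveyDataset, directory) -> None:
    """Write a dataset to ``sightings.csv``, ``transects.csv``, ``strata.csv``."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    dataset.sightings.to_csv(d / "sightings.csv", index=False)
    dataset.transects.to_csv(d / "transects.csv", index=False)
    pd.DataFrame(
        {
            "name": [s.name for s in dataset.strata],
            "area_km2": [s.area_km2 for s in dataset.strata],
        }
    ).to_csv(d / "strata.csv", index=False)
    pd.DataFrame({"truncation_m": [dataset.truncation_m]}).to_csv(
        d / "meta.csv", index=False
    )


def read_survey(directory) -> SurveyDataset:
    """Read a dataset written by :func:`write_survey` (round-trip identity)."""
    from pathlib import Path

    d = Path(directory)
    sightings = _read_csv(d / "sightings.csv", SIGHTING_COLUMNS)
    transects = _read_csv(d / "transects.csv", TRANSECT_COLUMNS)
    strata_df = _read_csv(d / "strata.csv", ["name", "area_km2"])
    meta = pd.read_csv(d / "meta.csv")
    dataset = SurveyDataset(
        sightings=sightings,
        transects=transects,
        strata=tuple(
            Stratum(r["name"], float(r["area_km2"])) for _, r in strata_df.iterrows()
        ),
        truncation_m=float(meta["truncation_m"].iloc[0]),
    )
    dataset.validate()
    return dataset


def _read_csv(path, required_columns) -> pd.DataFrame:
    # round_trip parsing keeps write->read->write byte-stable
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
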