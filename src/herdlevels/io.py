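"""Domain types, readers/writers and data-hygiene filters for snapshot sightings.

The raw input of the whole pipeline is a long-format sightings table: one row
per identified individual per sampling period (one drone flight = one period),
with planar coordinates in metres, a zone label, and a visibility flag.
Coordinates must already be projected to a planar metric frame (e.g. UTM);
no geodesy is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

VISIBILITY_LEVELS = ("seen", "tree_hidden", "out_of_frame", "absent")
SEX_LEVELS = ("F", "M")
AGE_LEVELS = ("adult", "young", "infant")

SIGHTING_COLUMNS = [
    "individual_id", "period_id", "date", "time", "zone",
    "x", "y", "visibility", "tree_id",
]
META_COLUMNS = ["individual_id", "sex", "age_class"]

#: floor applied to pairwise distances before any log transform (metres)
MIN_DISTANCE_M = 0.01


class SightingTableError(ValueError):
    """Raised when a sightings table violates its invariants."""


@dataclass
class SightingTable:
    """Validated sightings + individual metadata.

    ``sightings`` has the columns of :data:`SIGHTING_COLUMNS`; ``meta`` has
    ``individual_id, sex, age_class``.  Rows with visibility ``seen`` carry the
    individual's head position; ``tree_hidden`` rows carry the centre of the
    occluding tree in ``x, y`` plus its ``tree_id``; other rows carry no
    coordinates.
    """

    sightings: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.sightings = _validate_sightings(self.sightings)
        self.meta = _validate_meta(self.meta, self.sightings)

    # -- convenience accessors -------------------------------------------------
    @property
    def periods(self) -> list[str]:
        return list(dict.fromkeys(self.sightings["period_id"]))

    def non_infant_ids(self) -> set[str]:
        m = self.meta
        return set(m.loc[m["age_class"] != "infant", "individual_id"])

    def observed(self) -> pd.DataFrame:
        """Rows where the individual was observed at the site (seen or tree-hidden)."""
        s = self.sightings
        return s[s["visibility"].isin(["seen", "tree_hidden"])]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SightingTable):
            return NotImplemented
        a = self.sightings.reset_index(drop=True)
        b = other.sightings.reset_index(drop=True)
        ma = self.meta.sort_values("individual_id").reset_index(drop=True)
        mb = other.meta.sort_values("individual_id").reset_index(drop=True)
        return a.equals(b) and ma.equals(mb)

    def __len__(self) -> int:
        return len(self.sightings)


def _validate_sightings(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SIGHTING_COLUMNS if c not in df.columns]
    if missing:
        raise SightingTableError(f"missing sightings column(s): {missing}")
    df = df[SIGHTING_COLUMNS].copy()
    df["individual_id"] = df["individual_id"].astype(str)
    df["period_id"] = df["period_id"].astype(str)
    df["zone"] = df["zone"].astype(str)
    df["time"] = df["time"].astype(int)
    df["x"] = pd.to_numeric(df["x"])
    df["y"] = pd.to_numeric(df["y"])

    bad_vis = ~df["visibility"].isin(VISIBILITY_LEVELS)
    if bad_vis.any():
        rows = df.index[bad_vis].tolist()[:5]
        raise SightingTableError(f"invalid visibility value(s) at rows {rows}")

    dup = df.duplicated(subset=["individual_id", "period_id"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["individual_id", "period_id"]].iloc[0]
        raise SightingTableError(
            "duplicate (individual_id, period_id) pair: "
            f"({pair['individual_id']}, {pair['period_id']}) "
            f"at rows {df.index[dup].tolist()}"
        )

    positioned = df["visibility"].isin(["seen", "tree_hidden"])
    coords = df[["x", "y"]].to_numpy(dtype=float)
    nonfinite = positioned.to_numpy() & ~np.isfinite(coords).all(axis=1)
    if nonfinite.any():
        rows = df.index[np.nonzero(nonfinite)[0]].tolist()[:5]
        raise SightingTableError(f"non-finite coordinate(s) at rows {rows}")

    # every period maps to exactly one (date, time)
    per = df.groupby("period_id")[["date", "time"]].nunique()
    bad = per[(per["date"] > 1) | (per["time"] > 1)]
    if len(bad):
        raise SightingTableError(
            f"period(s) with inconsistent date/time: {bad.index.tolist()}"
        )
    return df.reset_index(drop=True)


def _validate_meta(meta: pd.DataFrame, sightings: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SightingTableError(f"missing metadata column(s): {missing}")
    meta = meta[META_COLUMNS].copy()
    meta["individual_id"] = meta["individual_id"].astype(str)
    if meta["individual_id"].duplicated().any():
        dups = meta.loc[meta["individual_id"].duplicated(), "individual_id"].tolist()
        raise SightingTableError(f"duplicate metadata id(s): {dups}")
    if not meta["sex"].isin(SEX_LEVELS).all():
        raise SightingTableError("metadata sex must be F or M")
    if not meta["age_class"].isin(AGE_LEVELS).all():
        raise SightingTableError("metadata age_class must be adult/young/infant")
    unknown = set(sightings["individual_id"]) - set(meta["individual_id"])
    if unknown:
        raise SightingTableError(f"sighted individual(s) missing from metadata: {sorted(unknown)}")
    return meta.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers


def read_sightings(path, meta_path) -> SightingTable:
    """Read and validate a sightings CSV plus its individual-metadata CSV.

    Infants are retained in the table (they are excluded downstream when
    distances are extracted).
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "period_id": str,
                                  "zone": str, "tree_id": str})
    meta = pd.read_csv(meta_path, dtype={"individual_id": str})
    if "tree_id" not in df.columns:
        df["tree_id"] = pd.NA
    return SightingTable(df, meta)


def write_sightings(table: SightingTable, path, meta_path) -> None:
    table.sightings.to_csv(path, index=False)
    table.meta.to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# data-hygiene filters


def filter_snapshots(table: SightingTable, max_out_fraction: float = 0.30) -> SightingTable:
    """Drop sampling periods where too many available horses were out of frame.

    "Available" individuals in a period are those with visibility other than
    ``absent``.  A period is removed entirely when the out-of-frame fraction is
    strictly greater than ``max_out_fraction`` (default 30%).  Idempotent.
    """
    s = table.sightings
    avail = s[s["visibility"] != "absent"]
    frac = avail.groupby("period_id")["visibility"].apply(
        lambda v: (v == "out_of_frame").mean() if len(v) else 0.0
    )
    keep = set(frac.index[frac <= max_out_fraction])
    # periods with no available horses at all carry no information either way
    keep |= set(s["period_id"]) - set(frac.index)
    out = s[s["period_id"].isin(keep)].reset_index(drop=True)
    return SightingTable(out, table.meta)


def pairwise_distances(table: SightingTable) -> pd.DataFrame:
    """Euclidean distances for all same-period, same-zone pairs of seen non-infants.

    Tree-hidden individuals contribute no distances (their stored coordinate is
    the tree centre, not the animal).  Distances below :data:`MIN_DISTANCE_M`
    are floored to it (guard for the downstream log transform); the number of
    floored pairs is reported via a warning.

    Returns a DataFrame with columns ``period_id, zone, id_a, id_b,
    distance_m`` and ``id_a < id_b``.
    """
    s = table.sightings
    noninf = table.non_infant_ids()
    seen = s[(s["visibility"] == "seen") & s["individual_id"].isin(noninf)]
    frames: list[pd.DataFrame] = []
    n_floored = 0
    for (period, zone), grp in seen.groupby(["period_id", "zone"], sort=False):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("individual_id")
        ids = grp["individual_id"].to_numpy()
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        d = squareform(pdist(xy))
        iu, ju = np.triu_indices(len(ids), k=1)
        dv = d[iu, ju]
        n_floored += int((dv < MIN_DISTANCE_M).sum())
        dv = np.maximum(dv, MIN_DISTANCE_M)
        frames.append(pd.DataFrame({
            "period_id": period, "zone": zone,
            "id_a": ids[iu], "id_b": ids[ju], "distance_m": dv,
        }))
    if n_floored:
        warnings.warn(f"{n_floored} near-zero distance(s) floored to {MIN_DISTANCE_M} m")
    cols = ["period_id", "zone", "id_a", "id_b", "distance_m"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def write_distances(distances: pd.DataFrame, path) -> None:
    distances.to_csv(path, index=False)


def read_distances(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"period_id": str, "zone": str,
                                    "id_a": str, "id_b": str})
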