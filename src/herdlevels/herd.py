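"""Herd-level aggregation tests: unit tracks, home-range overlap, permutation null.

A herd exists when units do not merely share a site but actively stay close.
Three lines of evidence are computed here: (1) kernel home ranges of unit
centres overlap strongly (UDOI); (2) observed inter-unit distances are smaller
than under a daily time-shift randomization that preserves each unit's own
trajectory; (3) nearest-unit distances can be compared between two halves of
the study window (Welch's test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ks_2samp

from .io import SightingTable
from .units import UnitPartition


@dataclass
class UnitTrack:
    """Per (unit, period) centre positions.

    ``fixes`` columns: unit, period_id, date, time, zone, x, y,
    n_members_observed.  The centre is the mean position of the unit's
    observed non-infant members (tree centres substituting for tree-hidden
    horses); the zone is the majority member zone, with ties dropping the
    unit for that period.
    """

    fixes: pd.DataFrame
    units: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.units:
            self.units = sorted(set(self.fixes["unit"]))


@dataclass
class PermutationResult:
    """Observed statistic vs a permutation null, with one-sided rank p."""

    observed: float
    null_values: np.ndarray
    p: float
    n_perm: int
    seed: int | None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.p <= 1):
            raise ValueError("permutation p must lie in (0, 1]")


def unit_centres(table: SightingTable, part: UnitPartition) -> UnitTrack:
    """Mean position of each unit's observed non-infant members per period."""
    obs = table.observed()
    noninf = table.non_infant_ids()
    obs = obs[obs["individual_id"].isin(noninf)].copy()
    member_of = part.membership
    obs["unit"] = obs["individual_id"].map(member_of)
    obs = obs.dropna(subset=["unit"])
    rows = []
    for (unit, pid), grp in obs.groupby(["unit", "period_id"], sort=True):
        zones = grp["zone"].value_counts()
        if len(zones) > 1 and zones.iloc[0] == zones.iloc[1]:
            continue  # ambiguous zone: unit excluded this period
        zone = zones.index[0]
        zgrp = grp[grp["zone"] == zone]
        rows.append((unit, pid, zgrp["date"].iloc[0], int(zgrp["time"].iloc[0]),
                     zone, float(zgrp["x"].mean()), float(zgrp["y"].mean()),
                     len(zgrp)))
    fixes = pd.DataFrame(rows, columns=[
        "unit", "period_id", "date", "time", "zone", "x", "y",
        "n_members_observed"])
    return UnitTrack(fixes, units=[name for name, _, _ in part.units])


# ---------------------------------------------------------------------------
# utilization distributions and UDOI


def _kde_grid(xy: np.ndarray, gx: np.ndarray, gy: np.ndarray,
              bandwidth) -> np.ndarray:
    """Gaussian KDE evaluated on the grid, normalized to integrate to 1."""
    n = len(xy)
    if bandwidth == "href":
        sd = np.sqrt(0.5 * (xy[:, 0].var(ddof=1) + xy[:, 1].var(ddof=1)))
        h = max(sd * n ** (-1.0 / 6.0), 1e-6)
    else:
        h = float(bandwidth)
    # separable kernel: density = Ax @ Ay.T up to constants
    ax = np.exp(-0.5 * ((gx[:, None] - xy[None, :, 0]) / h) ** 2)
    ay = np.exp(-0.5 * ((gy[:, None] - xy[None, :, 1]) / h) ** 2)
    dens = ax @ ay.T / (n * 2 * np.pi * h * h)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0]) if len(gx) > 1 and len(gy) > 1 else 1.0
    total = dens.sum() * cell
    return dens / total if total > 0 else dens


def home_range_mask(ud: np.ndarray, cell_area: float, level: float = 0.95) -> np.ndarray:
    """Cells of the ``level`` home range: highest-density cells capturing the mass.

    All cells with density >= the level-set threshold are included (ties kept),
    so a uniform UD yields its full support.
    """
    flat = np.sort(ud.ravel())[::-1]
    cum = np.cumsum(flat) * cell_area
    k = int(np.searchsorted(cum, level))
    thr = flat[min(k, flat.size - 1)]
    return ud >= thr


def udoi_from_uds(ud1: np.ndarray, ud2: np.ndarray, cell_area: float,
                  level: float = 0.95) -> float:
    """Utilization distribution overlap index of two gridded UDs.

    UDOI = A12 * sum(UD1 * UD2) * cell_area, with A12 the area where the two
    ``level`` home ranges overlap.  Equals 1 for two identical uniform UDs,
    0 for disjoint ranges, and exceeds 1 for strongly concentrated overlap.
    """
    overlap = home_range_mask(ud1, cell_area, level) & home_range_mask(ud2, cell_area, level)
    a12 = overlap.sum() * cell_area
    return float(a12 * (ud1 * ud2).sum() * cell_area)


def udoi_matrix(track: UnitTrack, grid_res: float = 5.0, bandwidth="href",
                min_fixes: int = 5, level: float = 0.95) -> pd.DataFrame:
    """UDOI for all pairs of units with at least ``min_fixes`` centre fixes."""
    import warnings

    fixes = track.fixes
    counts = fixes.groupby("unit").size()
    units = [u for u in track.units if counts.get(u, 0) >= min_fixes]
    skipped = [u for u in track.units if counts.get(u, 0) < min_fixes]
    if skipped:
        warnings.warn(f"units omitted from UDOI (fewer than {min_fixes} fixes): {skipped}")
    xy_all = fixes[fixes["unit"].isin(units)][["x", "y"]].to_numpy(dtype=float)
    pad = 4.0 * max(xy_all[:, 0].std(), xy_all[:, 1].std(), grid_res)
    gx = np.arange(xy_all[:, 0].min() - pad, xy_all[:, 0].max() + pad, grid_res)
    gy = np.arange(xy_all[:, 1].min() - pad, xy_all[:, 1].max() + pad, grid_res)
    cell = grid_res * grid_res
    uds = {}
    for u in units:
        xy = fixes.loc[fixes["unit"] == u, ["x", "y"]].to_numpy(dtype=float)
        uds[u] = _kde_grid(xy, gx, gy, bandwidth)
    out = pd.DataFrame(np.nan, index=units, columns=units)
    for i, a in enumerate(units):
        for b in units[i + 1:]:
            val = udoi_from_uds(uds[a], uds[b], cell, level)
            out.loc[a, b] = out.loc[b, a] = val
    return out


# ---------------------------------------------------------------------------
# time-shift permutation test


def _pooled_pair_distances(pos: pd.DataFrame) -> np.ndarray:
    """All inter-unit centre distances within each (date, time, zone) group."""
    chunks = []
    for _, grp in pos.groupby(["date", "time", "zone"], sort=False):
        if len(grp) > 1:
            chunks.append(pdist(grp[["x", "y"]].to_numpy(dtype=float)))
    return np.concatenate(chunks) if chunks else np.array([])


def _nearest_distances(pos: pd.DataFrame) -> np.ndarray:
    chunks = []
    for _, grp in pos.groupby(["date", "time", "zone"], sort=False):
        if len(grp) > 1:
            d = squareform(pdist(grp[["x", "y"]].to_numpy(dtype=float)))
            np.fill_diagonal(d, np.inf)
            chunks.append(d.min(axis=1))
    return np.concatenate(chunks) if chunks else np.array([])


def timeshift_permutation(track: UnitTrack, n_perm: int = 1000,
                          shifts: tuple[int, ...] = (-30, 0, 30),
                          seed: int | None = None,
                          statistic: str = "all_pairs") -> PermutationResult:
    """Daily time-shift randomization of unit trajectories.

    Each unit receives, per day and per replicate, one time shift drawn from
    ``shifts`` (minutes); its whole trajectory that day moves by that shift.
    Shifted fixes whose (date, time) no longer matches an observed sampling
    slot are dropped for that replicate.  The statistic is the median
    inter-unit centre distance over all co-present unit pairs (same date,
    time and zone); ``statistic="nearest"`` uses nearest-unit distances
    instead.  One-sided: aggregation means the observed median is *smaller*
    than the null, so p = (1 + #{null <= observed}) / (n_perm + 1).

    A two-sample KS comparison of the pooled observed vs pooled permuted
    distance distributions is reported in ``extras``.
    """
    if statistic not in ("all_pairs", "nearest"):
        raise ValueError("statistic must be 'all_pairs' or 'nearest'")
    fixes = track.fixes

    # integer codes for fast per-replicate regrouping
    day_codes, _ = pd.factorize(fixes["date"], sort=True)
    zone_codes, _ = pd.factorize(fixes["zone"], sort=True)
    times = fixes["time"].to_numpy(dtype=np.int64)
    xy = fixes[["x", "y"]].to_numpy(dtype=float)
    nz = int(zone_codes.max()) + 1
    day_key = day_codes.astype(np.int64) * 100_000 + times
    valid_keys = np.unique(day_key)

    def pooled(new_times: np.ndarray) -> np.ndarray:
        key = day_codes.astype(np.int64) * 100_000 + new_times
        pos = np.searchsorted(valid_keys, key)
        pos = np.clip(pos, 0, valid_keys.size - 1)
        ok = valid_keys[pos] == key
        gid = key[ok] * nz + zone_codes[ok]
        pts = xy[ok]
        order = np.argsort(gid, kind="stable")
        gid, pts = gid[order], pts[order]
        bounds = np.flatnonzero(np.r_[True, gid[1:] != gid[:-1], True])
        chunks = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < 2:
                continue
            d = pdist(pts[a:b])
            if statistic == "nearest":
                sq = squareform(d)
                np.fill_diagonal(sq, np.inf)
                d = sq.min(axis=1)
            chunks.append(d)
        return np.concatenate(chunks) if chunks else np.array([])

    obs_d = pooled(times)
    if obs_d.size == 0:
        raise ValueError("no co-present unit pairs in the observed data")
    observed = float(np.median(obs_d))

    unit_days = sorted(set(zip(fixes["unit"], fixes["date"])))
    ud_index = {k: i for i, k in enumerate(unit_days)}
    row_ud = np.array([ud_index[(u, d)] for u, d in zip(fixes["unit"], fixes["date"])])
    shifts_arr = np.asarray(shifts, dtype=np.int64)

    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    null_pool: list[np.ndarray] = []
    n_resampled = 0
    i = 0
    attempts = 0
    while i < n_perm:
        attempts += 1
        if attempts > 20 * n_perm:
            raise RuntimeError("too many degenerate replicates (no co-present pairs)")
        assign = rng.choice(shifts_arr, size=len(unit_days))
        d = pooled(times + assign[row_ud])
        if d.size == 0:
            n_resampled += 1
            continue
        nulls[i] = np.median(d)
        if len(null_pool) < 50:  # bounded pooled sample for the KS comparison
            null_pool.append(d)
        i += 1
    p = (1 + int((nulls <= observed).sum())) / (n_perm + 1)
    pooled_null = np.concatenate(null_pool)
    ks = ks_2samp(obs_d, pooled_null)
    return PermutationResult(
        observed=observed, null_values=nulls, p=p, n_perm=n_perm, seed=seed,
        extras={"ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue),
                "n_resampled": n_resampled, "statistic": statistic})


def nearest_unit_split_test(track: UnitTrack, split_date: str) -> dict:
    """Welch's t-test of nearest-unit distances before vs after a split date.

    The early stratum is all fixes with date <= ``split_date``.  Returns the
    statistic, Welch degrees of freedom, p-value and per-stratum summaries.
    """
    from scipy.stats import ttest_ind

    fixes = track.fixes.copy()
    early_mask = fixes["date"].astype(str) <= str(split_date)
    a = _nearest_distances(fixes[early_mask])
    b = _nearest_distances(fixes[~early_mask])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each stratum needs at least 2 nearest-unit distances")
    res = ttest_ind(a, b, equal_var=False)
    return {
        "t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue),
        "early_mean": float(a.mean()), "early_sd": float(a.std(ddof=1)),
        "late_mean": float(b.mean()), "late_sd": float(b.std(ddof=1)),
        "n_early": int(len(a)), "n_late": int(len(b)),
    }
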