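"""Unit-level social network: snapshot groups, unit SRI, distance network, Mantel.

Per snapshot, units whose centres lie closer than p2 are linked; connected
components of that graph ("gambit of the group": direct or chained proximity)
define co-membership.  Pooling snapshots yields a unit-level simple-ratio
association network, which can be compared against an inverse-squared-distance
network with a Mantel test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _perms

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .herd import UnitTrack


@dataclass
class SnapshotGroups:
    """Per-(period, zone) unit groupings plus per-period site presence."""

    units: list[str]
    strata: list[tuple[str, str, list[frozenset[str]]]]  # (period, zone, groups)
    presence: dict[str, frozenset[str]]  # period -> units present at the site

    def groups_of(self, period_id: str) -> list[frozenset[str]]:
        return [g for p, _, gs in self.strata if p == period_id for g in gs]


@dataclass
class UnitNetwork:
    """Symmetric unit-level SRI network with its counts."""

    units: list[str]
    sri: np.ndarray
    together_counts: np.ndarray
    either_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sri, index=self.units, columns=self.units)

    def strength(self) -> pd.Series:
        """Strength centrality: weighted row sum (zero edges included)."""
        return pd.Series(self.sri.sum(axis=1), index=self.units)


def snapshot_groups(track: UnitTrack, p2: float) -> SnapshotGroups:
    """Chain-connected unit groups per (period, zone) at threshold ``p2``.

    Edges join co-present units whose centre distance is strictly smaller
    than p2; groups are the connected components of that graph.
    """
    fixes = track.fixes
    units = sorted(track.units)
    strata = []
    presence: dict[str, frozenset[str]] = {}
    for pid, pgrp in fixes.groupby("period_id", sort=True):
        presence[pid] = frozenset(pgrp["unit"])
        for zone, zgrp in pgrp.groupby("zone", sort=True):
            names = zgrp["unit"].tolist()
            xy = zgrp[["x", "y"]].to_numpy(dtype=float)
            groups = _components_by_distance(names, xy, p2)
            strata.append((pid, zone, groups))
    return SnapshotGroups(units=units, strata=strata, presence=presence)


def _components_by_distance(names: list[str], xy: np.ndarray, p2: float
                            ) -> list[frozenset[str]]:
    n = len(names)
    if n == 0:
        return []
    if n == 1:
        return [frozenset(names)]
    adj = squareform(pdist(xy)) < p2
    np.fill_diagonal(adj, False)
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(adj[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(frozenset(names[i] for i in comp))
    return comps


def unit_sri(groups: SnapshotGroups) -> UnitNetwork:
    """Unit-level SRI: together = periods sharing a group; either = periods
    at least one of the two was present at the site."""
    units = groups.units
    idx = {u: i for i, u in enumerate(units)}
    n = len(units)
    together = np.zeros((n, n), dtype=int)
    either = np.zeros((n, n), dtype=int)
    for pid, present in groups.presence.items():
        pi = [idx[u] for u in present if u in idx]
        mask = np.zeros(n, dtype=bool)
        mask[pi] = True
        either[mask, :] += 1
        either[:, mask] += 1
        either[np.ix_(mask, mask)] -= 1
    for _, _, gs in groups.strata:
        for g in gs:
            gi = sorted(idx[u] for u in g if u in idx)
            for a in range(len(gi)):
                for b in range(a + 1, len(gi)):
                    together[gi[a], gi[b]] += 1
    together = together + together.T
    np.fill_diagonal(together, 0)
    np.fill_diagonal(either, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(either > 0, together / np.maximum(either, 1), 0.0)
    return UnitNetwork(units, sri, together, either)


def distance_network(track: UnitTrack, basis: str = "centres",
                     table=None, partition=None) -> pd.DataFrame:
    """Inverse-squared-mean-distance association network between units.

    For each unit dyad, the mean distance over co-present (period, zone)
    snapshots is taken and the edge weight is 1 / mean^2; dyads never
    co-present get weight 0.  ``basis="centres"`` (default) uses unit-centre
    distances; ``basis="members"`` averages over all cross-unit member pairs
    (requires ``table`` and ``partition``).
    """
    units = sorted(track.units)
    idx = {u: i for i, u in enumerate(units)}
    n = len(units)
    dsum = np.zeros((n, n))
    dcount = np.zeros((n, n), dtype=int)
    if basis == "centres":
        for _, grp in track.fixes.groupby(["period_id", "zone"], sort=False):
            names = [idx[u] for u in grp["unit"]]
            if len(names) < 2:
                continue
            d = squareform(pdist(grp[["x", "y"]].to_numpy(dtype=float)))
            for a in range(len(names)):
                for b in range(a + 1, len(names)):
                    dsum[names[a], names[b]] += d[a, b]
                    dcount[names[a], names[b]] += 1
    elif basis == "members":
        if table is None or partition is None:
            raise ValueError("basis='members' requires table and partition")
        member_of = partition.membership
        obs = table.sightings
        obs = obs[obs["visibility"] == "seen"].copy()
        obs = obs[obs["individual_id"].isin(table.non_infant_ids())]
        obs["unit"] = obs["individual_id"].map(member_of)
        obs = obs.dropna(subset=["unit"])
        for _, grp in obs.groupby(["period_id", "zone"], sort=False):
            unames = grp["unit"].to_numpy()
            if len(set(unames)) < 2:
                continue
            d = squareform(pdist(grp[["x", "y"]].to_numpy(dtype=float)))
            for ua in set(unames):
                for ub in set(unames):
                    if ua >= ub:
                        continue
                    sub = d[np.ix_(unames == ua, unames == ub)]
                    dsum[idx[ua], idx[ub]] += sub.mean()
                    dcount[idx[ua], idx[ub]] += 1
    else:
        raise ValueError("basis must be 'centres' or 'members'")
    dsum = dsum + dsum.T
    dcount = dcount + dcount.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d = np.where(dcount > 0, dsum / np.maximum(dcount, 1), np.nan)
        w = np.where(dcount > 0, 1.0 / mean_d ** 2, 0.0)
    np.fill_diagonal(w, 0.0)
    return pd.DataFrame(w, index=units, columns=units)


def mantel(m1, m2, n_perm: int = 9999, seed: int | None = None,
           alternative: str = "greater", exact: bool = False) -> tuple[float, float]:
    """Mantel correlation between two square symmetric matrices.

    Pearson r over the off-diagonal upper triangles; p by joint row/column
    permutation of the second matrix (one-sided ``greater`` by default,
    with the +1 rank correction).  ``exact=True`` enumerates all node
    permutations (small matrices only).
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and conformable")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    if va.std() == 0 or b[iu].std() == 0:
        raise ValueError("constant matrix: Mantel correlation undefined")

    def corr(mat):
        vb = mat[iu]
        if vb.std() == 0:
            return 0.0
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr(b)
    if exact:
        stats = np.array([corr(b[np.ix_(p, p)]) for p in _perms(range(n))])
        if alternative == "greater":
            p = float((stats >= r_obs - 1e-12).mean())
        elif alternative == "less":
            p = float((stats <= r_obs + 1e-12).mean())
        else:
            p = float((np.abs(stats) >= abs(r_obs) - 1e-12).mean())
        return r_obs, p
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = corr(b[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r >= r_obs - 1e-12
        elif alternative == "less":
            count += r <= r_obs + 1e-12
        else:
            count += abs(r) >= abs(r_obs) - 1e-12
    return r_obs, (1 + count) / (n_perm + 1)
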