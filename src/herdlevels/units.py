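"""Unit detection: intra-unit association rates (SRI) and clique partitioning.

Associations are scored with the simple ratio index: the probability that a
dyad was observed together (closer than the valley threshold v12) given that
at least one of the two was observed.  The positive SRI values of a two-level
society are strongly bimodal; the widest empty interval between them yields a
membership threshold, and individuals are partitioned into units — maximal
groups that are *completely* connected at that threshold.  Units with no adult
females are all-male units (AMUs); the rest are harems.  Individuals that end
up in no unit are solitary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .io import SightingTable


@dataclass
class AssociationMatrix:
    """Symmetric SRI matrix with its together / either-seen counts."""

    ids: list[str]
    sri: np.ndarray
    together_counts: np.ndarray
    either_seen_counts: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        for m in (self.sri, self.together_counts, self.either_seen_counts):
            if m.shape != (n, n):
                raise ValueError("matrix shape does not match ids")
            if not np.allclose(m, m.T):
                raise ValueError("association matrices must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sri, index=self.ids, columns=self.ids)


@dataclass
class UnitPartition:
    """Named units (member ids + harem/AMU type) and solitary individuals."""

    units: list[tuple[str, frozenset[str], str]]
    solitaries: list[str] = field(default_factory=list)

    @property
    def membership(self) -> dict[str, str]:
        return {m: name for name, members, _ in self.units for m in members}

    def to_dict(self) -> dict:
        return {"units": [{"name": n, "members": sorted(m), "type": t}
                          for n, m, t in self.units],
                "solitaries": list(self.solitaries)}

    @classmethod
    def from_dict(cls, data: dict) -> "UnitPartition":
        return cls(units=[(u["name"], frozenset(u["members"]), u["type"])
                          for u in data["units"]],
                   solitaries=list(data.get("solitaries", [])))

    def labels_for(self, ids: list[str]) -> np.ndarray:
        """Integer labels aligned to ``ids``; solitaries get unique labels."""
        mapping = {name: i for i, (name, _, _) in enumerate(self.units)}
        member_of = self.membership
        labels = np.empty(len(ids), dtype=int)
        next_free = len(self.units)
        for i, ind in enumerate(ids):
            if ind in member_of:
                labels[i] = mapping[member_of[ind]]
            else:
                labels[i] = next_free
                next_free += 1
        return labels


def intra_unit_association(table: SightingTable, v12: float) -> AssociationMatrix:
    """SRI at threshold ``v12`` over all non-infant dyads.

    together = periods in which both were observed and closer than v12, with
    the tree-occlusion convention: two individuals hidden under the same tree
    are together, and a seen individual closer than v12 to a tree centre is
    together with that tree's occupants.  either = periods in which at least
    one of the two was observed (seen or tree-hidden).
    """
    if v12 <= 0:
        raise ValueError("v12 must be positive")
    obs = table.observed()
    noninf = table.non_infant_ids()
    obs = obs[obs["individual_id"].isin(noninf)]
    ids = sorted(set(obs["individual_id"]))
    idx = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)
    together = np.zeros((n, n), dtype=int)
    either = np.zeros((n, n), dtype=int)

    for _, grp in obs.groupby("period_id", sort=False):
        present = np.array([idx[i] for i in grp["individual_id"]])
        mask = np.zeros(n, dtype=bool)
        mask[present] = True
        # |A present or B present|: rows + cols, minus double count on both
        either[mask, :] += 1
        either[:, mask] += 1
        either[np.ix_(mask, mask)] -= 1

        for zone, zgrp in grp.groupby("zone", sort=False):
            seen = zgrp[zgrp["visibility"] == "seen"]
            hidden = zgrp[zgrp["visibility"] == "tree_hidden"]
            s_idx = np.array([idx[i] for i in seen["individual_id"]], dtype=int)
            s_xy = seen[["x", "y"]].to_numpy(dtype=float)
            if len(s_idx) > 1:
                close = np.triu(cdist(s_xy, s_xy) < v12, k=1)
                a, b = np.nonzero(close)
                np.add.at(together, (s_idx[a], s_idx[b]), 1)
            for tree, tgrp in hidden.groupby("tree_id", sort=False):
                t_idx = np.array([idx[i] for i in tgrp["individual_id"]], dtype=int)
                # co-resting under one tree: pairwise together
                if len(t_idx) > 1:
                    a, b = np.triu_indices(len(t_idx), k=1)
                    np.add.at(together, (t_idx[a], t_idx[b]), 1)
                # seen horses within v12 of the tree centre join the occupants
                if len(s_idx):
                    centre = tgrp[["x", "y"]].to_numpy(dtype=float)[:1]
                    near = s_idx[cdist(s_xy, centre)[:, 0] < v12]
                    if len(near):
                        si = np.repeat(near, len(t_idx))
                        ti = np.tile(t_idx, len(near))
                        np.add.at(together, (si, ti), 1)
    together = together + together.T - np.diag(np.diag(together))
    np.fill_diagonal(together, 0)
    np.fill_diagonal(either, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(either > 0, together / np.maximum(either, 1), 0.0)
    return AssociationMatrix(ids, sri, together, either)


def membership_gap(m: AssociationMatrix) -> float:
    """Upper edge of the widest empty interval among the positive SRI values.

    This is the automatic analogue of reading the bimodal association-rate
    histogram by eye: the gap between the between-unit cloud near zero and the
    within-unit cloud near one.
    """
    vals = np.unique(m.sri[np.triu_indices(len(m.ids), k=1)])
    vals = vals[vals > 0]
    if vals.size < 2:
        raise ValueError("not enough distinct positive SRI values to find a gap")
    gaps = np.diff(vals)
    return float(vals[int(np.argmax(gaps)) + 1])


class UnitPartitioner(ClusterMixin, BaseEstimator):
    """Partition individuals into completely connected units at an SRI threshold.

    Edges are drawn where SRI >= threshold (``threshold=None`` uses the
    automatic widest-gap rule).  Each connected component is then reduced to a
    complete subgraph by iteratively peeling the member with the fewest
    intra-component edges (ties: lowest summed SRI, then lexicographic id).
    Peeled members and singleton components become solitaries.  A unit is an
    AMU when it contains no adult females, else a harem.

    After ``fit``: ``partition_`` (:class:`UnitPartition`), ``labels_``
    (integer labels aligned to the matrix ids, solitaries unique), and
    ``threshold_`` (the threshold actually used).
    """

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    def fit(self, X: AssociationMatrix, y=None, meta: pd.DataFrame | None = None):
        m = X
        thr = self.threshold if self.threshold is not None else membership_gap(m)
        if not (0 < thr <= 1):
            raise ValueError("threshold must lie in (0, 1]")
        ids = list(m.ids)
        n = len(ids)
        adj = (m.sri >= thr) & ~np.eye(n, dtype=bool)

        units: list[frozenset[str]] = []
        solitaries: list[str] = []
        for comp in _connected_components(adj):
            keep = _peel_to_clique(comp, adj, m.sri, ids)
            dropped = sorted(set(comp) - set(keep), key=lambda i: ids[i])
            solitaries.extend(ids[i] for i in dropped)
            if len(keep) >= 2:
                units.append(frozenset(ids[i] for i in keep))
            else:
                solitaries.extend(ids[i] for i in keep)
        # post-condition: every unit is complete at the threshold
        for members in units:
            mi = [ids.index(x) for x in members]
            assert all(adj[a, b] for a in mi for b in mi if a != b), \
                "unit not complete at threshold"

        sex_age = None
        if meta is not None:
            meta = meta.set_index("individual_id")
            sex_age = meta
        named: list[tuple[str, frozenset[str], str]] = []
        for members in sorted(units, key=lambda s: sorted(s)[0]):
            if sex_age is not None:
                sub = sex_age.loc[sorted(members)]
                has_adult_female = bool(((sub["sex"] == "F")
                                         & (sub["age_class"] == "adult")).any())
            else:
                has_adult_female = True
            utype = "harem" if has_adult_female else "AMU"
            named.append((f"U{len(named) + 1:02d}", members, utype))
        self.partition_ = UnitPartition(units=named, solitaries=sorted(solitaries))
        self.labels_ = self.partition_.labels_for(ids)
        self.threshold_ = float(thr)
        return self

    def fit_predict(self, X, y=None, **kw):
        return self.fit(X, y, **kw).labels_


def _connected_components(adj: np.ndarray) -> list[list[int]]:
    n = adj.shape[0]
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
        comps.append(sorted(comp))
    return comps


def _peel_to_clique(comp: list[int], adj: np.ndarray, sri: np.ndarray,
                    ids: list[str]) -> list[int]:
    comp = list(comp)
    while len(comp) >= 2:
        sub = adj[np.ix_(comp, comp)]
        deg = sub.sum(axis=1)
        if deg.min() == len(comp) - 1:
            return comp  # complete
        worst = np.min(deg)
        cand = [i for i, d in zip(comp, deg) if d == worst]
        if len(cand) > 1:
            ssum = {i: sri[i, comp].sum() for i in cand}
            lo = min(ssum.values())
            cand = sorted((i for i in cand if np.isclose(ssum[i], lo)),
                          key=lambda i: ids[i])
        comp.remove(cand[0])
    return comp


def partition_units(m: AssociationMatrix, threshold: float | None = None,
                    meta: pd.DataFrame | None = None) -> UnitPartition:
    """Functional wrapper over :class:`UnitPartitioner`."""
    if len(m.ids) == 0:
        return UnitPartition(units=[], solitaries=[])
    return UnitPartitioner(threshold=threshold).fit(m, meta=meta).partition_


def summarize_partition(table: SightingTable, part: UnitPartition,
                        v12: float) -> dict[str, pd.DataFrame]:
    """Within/between-unit summary statistics and a unit composition table.

    Returns ``{"association": ..., "distance": ..., "units": ...}`` where the
    first gives mean ± SD of SRI within and between units, the second the
    nearest-individual and all-pair distance summaries, and the third one row
    per unit (name, type, size, composition).
    """
    from .io import pairwise_distances

    m = intra_unit_association(table, v12)
    member_of = part.membership
    iu = np.triu_indices(len(m.ids), k=1)
    same = np.array([
        member_of.get(m.ids[a]) is not None
        and member_of.get(m.ids[a]) == member_of.get(m.ids[b])
        for a, b in zip(*iu)
    ])
    sri_vals = m.sri[iu]
    assoc_rows = []
    for label, mask in (("within_unit", same), ("between_unit", ~same)):
        v = sri_vals[mask]
        assoc_rows.append((label, v.mean() if v.size else np.nan,
                           v.std(ddof=1) if v.size > 1 else (0.0 if v.size else np.nan),
                           v.size))
    assoc = pd.DataFrame(assoc_rows, columns=["scope", "mean", "sd", "n_dyads"])

    dists = pairwise_distances(table)
    key_same = dists.apply(
        lambda r: member_of.get(r["id_a"]) is not None
        and member_of.get(r["id_a"]) == member_of.get(r["id_b"]), axis=1
    ) if len(dists) else pd.Series(dtype=bool)
    dist_rows = []
    for label, mask in (("within_unit", key_same), ("between_unit", ~key_same)):
        sub = dists[mask] if len(dists) else dists
        allpair = sub["distance_m"]
        nearest = (sub.groupby(["period_id", "id_a"])["distance_m"].min()
                   if len(sub) else pd.Series(dtype=float))
        dist_rows.append((label,
                          allpair.mean() if len(allpair) else np.nan,
                          allpair.std(ddof=1) if len(allpair) > 1 else np.nan,
                          nearest.mean() if len(nearest) else np.nan,
                          nearest.std(ddof=1) if len(nearest) > 1 else np.nan))
    dist = pd.DataFrame(dist_rows, columns=[
        "scope", "all_pair_mean_m", "all_pair_sd_m",
        "nearest_mean_m", "nearest_sd_m"])

    meta = table.meta.set_index("individual_id")
    unit_rows = []
    for name, members, utype in part.units:
        sub = meta.loc[sorted(members)]
        unit_rows.append((name, utype, len(members),
                          int(((sub["sex"] == "M") & (sub["age_class"] == "adult")).sum()),
                          int(((sub["sex"] == "F") & (sub["age_class"] == "adult")).sum()),
                          int((sub["age_class"] == "young").sum())))
    units_df = pd.DataFrame(unit_rows, columns=[
        "unit", "type", "size", "adult_males", "adult_females", "young"])
    return {"association": assoc, "distance": dist, "units": units_df}
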