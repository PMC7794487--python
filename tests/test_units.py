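import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from herdlevels.units import (AssociationMatrix, intra_unit_association,
                              membership_gap, partition_units, UnitPartitioner,
                              summarize_partition)
from conftest import make_table


def row(i, p, vis="seen", x=0.0, y=0.0, zone="Z1", tree=None, time=540):
    return (i, p, "2018-06-06", time, zone, x, y, vis, tree)


def sri_of(m, a, b):
    i, j = m.ids.index(a), m.ids.index(b)
    return m.sri[i, j]


class TestSRI:
    def test_always_together_is_one(self):
        rows = []
        for p in range(10):
            rows += [row("a", f"P{p}", x=0, time=540 + 30 * p),
                     row("b", f"P{p}", x=5, time=540 + 30 * p)]
        m = intra_unit_association(make_table(rows), v12=15.5)
        assert sri_of(m, "a", "b") == 1.0

    def test_hand_counted_ratio(self):
        # together 7, A-only 2, B-only 0, both-seen-but-apart 1 -> 7/10
        rows = []
        t = 540
        for p in range(7):
            rows += [row("a", f"T{p}", x=0, time=t), row("b", f"T{p}", x=5, time=t)]
            t += 30
        for p in range(2):
            rows += [row("a", f"A{p}", x=0, time=t)]
            t += 30
        rows += [row("a", "F0", x=0, time=t), row("b", "F0", x=500, time=t)]
        m = intra_unit_association(make_table(rows), v12=15.5)
        assert sri_of(m, "a", "b") == pytest.approx(0.70)

    def test_same_tree_counts_as_together(self):
        rows = [row("a", "P1", vis="tree_hidden", x=10, y=10, tree="T1"),
                row("b", "P1", vis="tree_hidden", x=10, y=10, tree="T1")]
        m = intra_unit_association(make_table(rows), v12=15.5)
        assert sri_of(m, "a", "b") == 1.0

    def test_seen_horse_near_tree_joins_occupants(self):
        rows = [row("h", "P1", vis="tree_hidden", x=10, y=10, tree="T1"),
                row("near", "P1", x=12, y=10),
                row("far", "P1", x=100, y=10)]
        m = intra_unit_association(make_table(rows), v12=15.5)
        assert sri_of(m, "h", "near") == 1.0
        assert sri_of(m, "h", "far") == 0.0

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(21)
        v12 = 10.0
        rows = []
        for p in range(12):
            for i in range(6):
                r = rng.random()
                if r < 0.25:
                    continue  # absent this period
                if r < 0.35:
                    rows.append(row(f"i{i}", f"P{p}", vis="out_of_frame",
                                    x=np.nan, y=np.nan, time=540 + 30 * p))
                else:
                    rows.append(row(f"i{i}", f"P{p}",
                                    x=float(rng.uniform(0, 30)),
                                    y=float(rng.uniform(0, 30)),
                                    time=540 + 30 * p))
        t = make_table(rows)
        m = intra_unit_association(t, v12)
        s = t.sightings
        for a in m.ids:
            for b in m.ids:
                if a >= b:
                    continue
                together = either = 0
                for p, grp in s.groupby("period_id"):
                    ga = grp[grp["individual_id"] == a]
                    gb = grp[grp["individual_id"] == b]
                    a_obs = len(ga) and ga["visibility"].iloc[0] in ("seen", "tree_hidden")
                    b_obs = len(gb) and gb["visibility"].iloc[0] in ("seen", "tree_hidden")
                    if a_obs or b_obs:
                        either += 1
                    if (a_obs and b_obs
                            and ga["visibility"].iloc[0] == "seen"
                            and gb["visibility"].iloc[0] == "seen"):
                        d = np.hypot(ga["x"].iloc[0] - gb["x"].iloc[0],
                                     ga["y"].iloc[0] - gb["y"].iloc[0])
                        if d < v12:
                            together += 1
                expect = together / either if either else 0.0
                assert sri_of(m, a, b) == pytest.approx(expect), (a, b)


class TestMembershipGap:
    def test_gap_upper_edge_returned(self):
        ids = list("abcd")
        sri = np.zeros((4, 4))
        sri[0, 1] = sri[1, 0] = 0.9
        sri[2, 3] = sri[3, 2] = 0.85
        sri[0, 2] = sri[2, 0] = 0.12
        sri[1, 3] = sri[3, 1] = 0.05
        m = AssociationMatrix(ids, sri, np.zeros((4, 4), int), np.ones((4, 4), int))
        assert membership_gap(m) == pytest.approx(0.85)


class TestPartition:
    def _matrix(self, ids, edges):
        n = len(ids)
        sri = np.zeros((n, n))
        for (a, b), v in edges.items():
            i, j = ids.index(a), ids.index(b)
            sri[i, j] = sri[j, i] = v
        return AssociationMatrix(ids, sri, np.zeros((n, n), int),
                                 np.ones((n, n), int))

    def test_incomplete_member_peeled_to_solitary(self):
        # {A,B,C} complete; D attached only to C; E isolated
        m = self._matrix(list("ABCDE"), {("A", "B"): 0.9, ("A", "C"): 0.95,
                                         ("B", "C"): 0.92, ("C", "D"): 1.0})
        part = partition_units(m, threshold=0.7)
        assert [set(mem) for _, mem, _ in part.units] == [{"A", "B", "C"}]
        assert part.solitaries == ["D", "E"]

    def test_units_complete_at_threshold(self, herd_pipeline):
        part = herd_pipeline["part"]
        m = herd_pipeline["assoc"]
        thr = membership_gap(m)
        idx = {i: k for k, i in enumerate(m.ids)}
        for _, members, _ in part.units:
            for a in members:
                for b in members:
                    if a < b:
                        assert m.sri[idx[a], idx[b]] >= thr

    def test_recovers_ground_truth_exactly(self, herd_pipeline):
        part = herd_pipeline["part"]
        truth = herd_pipeline["truth"]
        ids = herd_pipeline["assoc"].ids
        est = UnitPartitioner().fit(herd_pipeline["assoc"],
                                    meta=herd_pipeline["table"].meta)
        ari = adjusted_rand_score(truth.partition.labels_for(ids), est.labels_)
        assert ari == 1.0
        assert len(part.units) == 23
        assert len(part.solitaries) == 5

    def test_types_follow_adult_female_rule(self, herd_pipeline):
        truth_types = {frozenset(m): t
                       for n, m, t in herd_pipeline["truth"].partition.units}
        for _, members, utype in herd_pipeline["part"].units:
            assert truth_types[frozenset(members)] == utype

    def test_relabelling_invariance(self):
        ids = list("ABCDE")
        edges = {("A", "B"): 0.9, ("A", "C"): 0.95, ("B", "C"): 0.92,
                 ("C", "D"): 1.0}
        m1 = self._matrix(ids, edges)
        mapping = dict(zip(ids, "VWXYZ"))
        m2 = self._matrix([mapping[i] for i in ids],
                          {(mapping[a], mapping[b]): v
                           for (a, b), v in edges.items()})
        p1 = partition_units(m1, threshold=0.7)
        p2 = partition_units(m2, threshold=0.7)
        mapped = [{mapping[x] for x in mem} for _, mem, _ in p1.units]
        assert mapped == [set(mem) for _, mem, _ in p2.units]
        assert sorted(mapping[s] for s in p1.solitaries) == p2.solitaries

    def test_empty_matrix_gives_empty_partition(self):
        m = AssociationMatrix([], np.zeros((0, 0)), np.zeros((0, 0), int),
                              np.zeros((0, 0), int))
        part = partition_units(m, threshold=0.5)
        assert part.units == [] and part.solitaries == []


class TestSummaries:
    def test_perfect_unit_has_unit_sri_one(self):
        rows = []
        for p in range(5):
            rows += [row("a", f"P{p}", x=0, time=540 + 30 * p),
                     row("b", f"P{p}", x=5, time=540 + 30 * p)]
        t = make_table(rows)
        m = intra_unit_association(t, 15.5)
        part = partition_units(m, threshold=0.7, meta=t.meta)
        s = summarize_partition(t, part, 15.5)
        within = s["association"].set_index("scope").loc["within_unit"]
        assert within["mean"] == 1.0 and within["sd"] == 0.0
        between = s["distance"].set_index("scope").loc["between_unit"]
        assert np.isnan(between["all_pair_mean_m"])  # single unit: no rows

    def test_synthetic_defaults_separate_sharply(self, herd_pipeline):
        s = summarize_partition(herd_pipeline["table"], herd_pipeline["part"],
                                herd_pipeline["thr"].v12)
        assoc = s["association"].set_index("scope")
        assert assoc.loc["within_unit", "mean"] > 0.85
        assert assoc.loc["between_unit", "mean"] < 0.05
        sizes = s["units"]["size"]
        assert sizes.between(2, 9).all()
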