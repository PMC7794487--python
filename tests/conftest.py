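import numpy as np
import pandas as pd
import pytest

from herdlevels import (SocietyConfig, generate, filter_snapshots,
                        pairwise_distances, fit_mixture, derive_thresholds,
                        intra_unit_association, partition_units, unit_centres,
                        snapshot_groups, unit_sri)
from herdlevels.io import SightingTable


def make_table(rows, meta=None):
    """Build a SightingTable from (id, period, date, time, zone, x, y, vis, tree) rows."""
    df = pd.DataFrame(rows, columns=[
        "individual_id", "period_id", "date", "time", "zone",
        "x", "y", "visibility", "tree_id"])
    if meta is None:
        ids = sorted(set(df["individual_id"]))
        meta = pd.DataFrame({"individual_id": ids, "sex": "F",
                             "age_class": "adult"})
    return SightingTable(df, meta)


@pytest.fixture(scope="session")
def herd_pipeline():
    """One seeded herd-mode dataset run through every stage, shared by tests."""
    cfg = SocietyConfig(seed=1)
    table, truth = generate(cfg)
    table = filter_snapshots(table)
    dists = pairwise_distances(table)
    fit = fit_mixture(dists, k=2, seed=1, max_n=50_000)
    thr = derive_thresholds(fit)
    assoc = intra_unit_association(table, thr.v12)
    part = partition_units(assoc, meta=table.meta)
    track = unit_centres(table, part)
    groups = snapshot_groups(track, thr.p2)
    net = unit_sri(groups)
    return {
        "cfg": cfg, "table": table, "truth": truth, "dists": dists,
        "fit": fit, "thr": thr, "assoc": assoc, "part": part,
        "track": track, "groups": groups, "net": net,
    }
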