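"""End-to-end pipeline: sightings -> thresholds -> units -> herd test -> network -> regressions.

Every stage writes plain CSV/JSON so any stage can be rerun and audited in
isolation; a manifest records inputs, outputs, parameters and seeds.  Reruns
with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (SightingTable, read_sightings, write_sightings,
                 filter_snapshots, pairwise_distances, write_distances)
from .simulate import SocietyConfig, generate
from .mixture import fit_mixture, select_k, derive_thresholds
from .units import intra_unit_association, partition_units, summarize_partition
from .herd import unit_centres, udoi_matrix, timeshift_permutation, nearest_unit_split_test
from .network import snapshot_groups, unit_sri, distance_network, mantel
from .permutation import (datastream_permute, sd_test, mrqap_dsp, nodal_dsp,
                          build_dyadic_design, build_nodal_design)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; round-trips losslessly through YAML."""

    output_dir: str = "herdlevels_out"
    # input: either a synthetic society or a sightings CSV pair
    synthetic: bool = True
    society: dict = field(default_factory=dict)
    sightings_csv: str | None = None
    meta_csv: str | None = None
    # filters and thresholds
    max_out_fraction: float = 0.30
    k: int | None = 2          # None -> select by BIC elbow
    k_max: int = 10
    k_rule: str = "elbow"
    membership_threshold: float | None = None  # None -> widest-gap rule
    # permutation sizes
    n_perm_timeshift: int = 200
    n_perm_datastream: int = 1000
    datastream_burn_in: int = 1000
    n_perm_mrqap: int = 1000
    n_perm_nodal: int = 1000
    n_perm_mantel: int = 999
    # home ranges
    grid_res: float = 20.0
    bandwidth: str | float = "href"
    split_date: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, write artifacts under ``cfg.output_dir``, return the manifest."""
    if not cfg.synthetic:
        if not cfg.sightings_csv or not cfg.meta_csv:
            raise ValueError("file input requires sightings_csv and meta_csv")
        for p in (cfg.sightings_csv, cfg.meta_csv):
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "parameters": asdict(cfg), "stages": {}}

    def record(stage, **files):
        manifest["stages"][stage] = {k: str(v) for k, v in files.items()}

    # -- stage 1: input -------------------------------------------------------
    if cfg.synthetic:
        soc = SocietyConfig(**{"seed": cfg.seed, **cfg.society})
        table, gt = generate(soc)
        write_sightings(table, out / "sightings.csv", out / "meta.csv")
        _dump_json({
            "units": {name: sorted(members) for name, members, _ in gt.partition.units},
            "types": gt.unit_types, "sizes": gt.unit_sizes,
            "solitaries": gt.partition.solitaries,
        }, out / "ground_truth.json")
        record("input", sightings=out / "sightings.csv", meta=out / "meta.csv",
               ground_truth=out / "ground_truth.json")
    else:
        table = read_sightings(cfg.sightings_csv, cfg.meta_csv)
        gt = None
        record("input", sightings=cfg.sightings_csv, meta=cfg.meta_csv)

    # -- stage 2: hygiene + distances ----------------------------------------
    table = filter_snapshots(table, cfg.max_out_fraction)
    dists = pairwise_distances(table)
    write_distances(dists, out / "distances.csv")
    record("distances", distances=out / "distances.csv")

    # -- stage 3: mixture thresholds -----------------------------------------
    k = cfg.k or select_k(dists, k_max=cfg.k_max, rule=cfg.k_rule, seed=cfg.seed)
    fit = fit_mixture(dists, k=k, seed=cfg.seed)
    thr = derive_thresholds(fit) if k == 2 else None
    _dump_json({
        "k": fit.k, "weights": fit.weights.tolist(), "means": fit.means.tolist(),
        "sds": fit.sds.tolist(), "loglik": fit.loglik, "bic": fit.bic, "n": fit.n,
        "thresholds": None if thr is None else {
            "p1_m": thr.p1, "p2_m": thr.p2, "v12_m": thr.v12,
            "log10_v12": thr.log10_v12},
    }, out / "thresholds.json")
    record("thresholds", thresholds=out / "thresholds.json")
    if thr is None:
        raise RuntimeError("mixture selected k != 2; no valley threshold to continue with")

    # -- stage 4: units -------------------------------------------------------
    assoc = intra_unit_association(table, thr.v12)
    assoc.to_frame().to_csv(out / "association.csv")
    part = partition_units(assoc, threshold=cfg.membership_threshold, meta=table.meta)
    _dump_json(part.to_dict(), out / "partition.json")
    summary = summarize_partition(table, part, thr.v12)
    summary["association"].to_csv(out / "summary_association.csv", index=False)
    summary["distance"].to_csv(out / "summary_distance.csv", index=False)
    summary["units"].to_csv(out / "summary_units.csv", index=False)
    record("units", association=out / "association.csv",
           partition=out / "partition.json",
           summary_units=out / "summary_units.csv")

    # -- stage 5: herd test ---------------------------------------------------
    track = unit_centres(table, part)
    res = timeshift_permutation(track, n_perm=cfg.n_perm_timeshift, seed=cfg.seed)
    herd_json = {
        "observed_median_m": res.observed, "p": res.p, "n_perm": res.n_perm,
        "null_median_of_medians_m": float(np.median(res.null_values)),
        **res.extras,
    }
    if cfg.split_date:
        herd_json["split_test"] = nearest_unit_split_test(track, cfg.split_date)
    _dump_json(herd_json, out / "herd_test.json")
    udoi = udoi_matrix(track, grid_res=cfg.grid_res, bandwidth=cfg.bandwidth)
    udoi.to_csv(out / "udoi.csv")
    record("herd", herd_test=out / "herd_test.json", udoi=out / "udoi.csv")

    # -- stage 6: unit network ------------------------------------------------
    sg = snapshot_groups(track, thr.p2)
    net = unit_sri(sg)
    net.to_frame().to_csv(out / "unit_network.csv")
    dist_net = distance_network(track)
    dist_net.to_csv(out / "distance_network.csv")
    r, mp = mantel(net.sri, dist_net.to_numpy(), n_perm=cfg.n_perm_mantel,
                   seed=cfg.seed)
    _dump_json({"mantel_r": r, "p": mp, "n_perm": cfg.n_perm_mantel},
               out / "mantel.json")
    record("network", unit_network=out / "unit_network.csv",
           distance_network=out / "distance_network.csv",
           mantel=out / "mantel.json")

    # -- stage 7: permutation statistics --------------------------------------
    nulls = datastream_permute(sg, n_perm=cfg.n_perm_datastream,
                               seed=cfg.seed, burn_in=cfg.datastream_burn_in)
    sd_res = sd_test(net, nulls, seed=cfg.seed)
    _dump_json({"observed_sd": sd_res.observed, "p_right": sd_res.p,
                "n_perm": sd_res.n_perm}, out / "sd_test.json")

    meta_idx = table.meta.set_index("individual_id")
    unit_types = {name: t for name, _, t in part.units}
    unit_sizes = {name: len(m) for name, m, _ in part.units}
    stallions = {
        name: int(((meta_idx.loc[sorted(m), "sex"] == "M")
                   & (meta_idx.loc[sorted(m), "age_class"] == "adult")).sum())
        for name, m, _ in part.units}
    obs_counts = {u: sum(1 for p_ in sg.presence.values() if u in p_)
                  for u in net.units}
    dyadic = build_dyadic_design(net, track, unit_types, unit_sizes)
    t1 = mrqap_dsp(dyadic, n_perm=cfg.n_perm_mrqap, seed=cfg.seed)
    t1.to_csv(out / "regression_dyadic.csv")
    t2 = nodal_dsp(build_nodal_design(net, unit_types, unit_sizes, stallions,
                                      obs_counts, model="type"),
                   n_perm=cfg.n_perm_nodal, seed=cfg.seed)
    t2.to_csv(out / "regression_nodal_type.csv")
    if sum(1 for t in unit_types.values() if t == "harem") >= 5:
        t3 = nodal_dsp(build_nodal_design(net, unit_types, unit_sizes, stallions,
                                          obs_counts, model="harem"),
                       n_perm=cfg.n_perm_nodal, seed=cfg.seed)
        t3.to_csv(out / "regression_nodal_harem.csv")
    record("regressions", sd_test=out / "sd_test.json",
           dyadic=out / "regression_dyadic.csv",
           nodal_type=out / "regression_nodal_type.csv")

    cfg.to_yaml(out / "config.yaml")
    _dump_json(manifest, out / "manifest.json")
    return manifest
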