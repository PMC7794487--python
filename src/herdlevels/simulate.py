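"""Synthetic two-level society generator with ground truth.

Emulates the statistical structure of a drone-surveyed feral-horse herd: a
fixed roster of stable units (harems and all-male units, plus a few solitary
males) observed in repeated snapshots over several days.  In ``herd`` mode
unit centres pack around a wandering herd centre so that the log10
inter-individual distance distribution is bimodal (intra-unit and inter-unit
modes); in ``null`` mode each unit wanders independently over the same zone,
removing inter-unit attraction while preserving rosters, zone schedules and
dropout.  Every dataset is emitted with its ground truth.

Field structure emulated beyond the two spacing modes: units come and go from
the observation site between snapshots (per-period unit absence), the herd
occasionally splits between the two zones for a day, whole units co-rest
under trees (tree-hidden, with the tree centre recorded), individuals drop
out of frame, and the herd's dispersion varies between snapshots
(expansion-only spread factor — herds string out but do not over-compact).

Calibration by construction: members are displaced isotropically (Gaussian)
around their unit centre with the scale chosen so the *median* intra-unit
pairwise distance is 10**log10_intra_mu; unit centres are drawn from a
Gaussian cloud with a hard minimum-separation floor (the lower edge of the
lognormal envelope implied by log10_inter_mu, log10_inter_sigma) and a cloud
scale fixed so that, under the default absence/split/spread conditions, a
two-component mixture fitted to the resulting log10 distances recovers
(log10_intra_mu, log10_inter_mu).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd

from .io import SightingTable
from .units import UnitPartition

_RAYLEIGH_MEDIAN = np.sqrt(2 * np.log(2))  # median/scale of a Rayleigh, ~1.1774
#: unit-centre cloud scale / 10**log10_inter_mu (packing calibration constant)
_PACKING_SCALE = 0.28


@dataclass
class SocietyConfig:
    """Parameters of the synthetic society.

    Defaults mirror the structure of the motivating field study: 23 stable
    units of 2-9 non-infant horses (about 9% of them AMUs) plus 5 solitary
    males, observed 12 times a day over 19 days in two disjoint zones, with
    intra- and inter-unit log10 distance modes at 1.02 and 2.09 (metres),
    roughly three quarters of the units at the site in any one snapshot, and
    light per-snapshot dropout.
    """

    n_units: int = 23
    unit_size_range: tuple[int, int] = (2, 9)
    amu_fraction: float = 2 / 23
    n_solitary: int = 5
    log10_intra_mu: float = 1.02
    log10_intra_sigma: float = 0.30
    log10_inter_mu: float = 2.09
    log10_inter_sigma: float = 0.25
    amu_periphery_factor: float = 1.6
    herd_attraction: str = "herd"  # "herd" | "null"
    n_days: int = 19
    periods_per_day: int = 12
    zones: tuple[tuple[float, float, float, float], ...] = (
        (0.0, 0.0, 2500.0, 2500.0),
        (3500.0, 0.0, 6000.0, 2500.0),
    )
    p_tree_hidden: float = 0.02
    p_out_of_frame: float = 0.05
    p_unit_absent: float = 0.25
    p_zone_split: float = 0.5
    zone_split_fraction: float = 0.35
    spread_sigma: float = 0.15
    seed: int = 0
    start_date: str = "2018-06-06"

    def __post_init__(self):
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.unit_size_range[0] < 2:
            raise ValueError("unit sizes must be >= 2")
        for p in (self.amu_fraction, self.p_tree_hidden, self.p_out_of_frame,
                  self.p_unit_absent, self.p_zone_split, self.zone_split_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.amu_periphery_factor < 1:
            raise ValueError("amu_periphery_factor must be >= 1")
        if self.herd_attraction not in ("herd", "null"):
            raise ValueError("herd_attraction must be 'herd' or 'null'")

    # calibrated scales -------------------------------------------------------
    @property
    def member_sd(self) -> float:
        """Isotropic member displacement sd (m); median pair distance = 10^intra_mu."""
        return 10.0 ** self.log10_intra_mu / (np.sqrt(2) * _RAYLEIGH_MEDIAN)

    @property
    def centre_sd(self) -> float:
        """Unit-centre cloud scale (m) in herd mode."""
        return _PACKING_SCALE * 10.0 ** self.log10_inter_mu

    @property
    def sep_min(self) -> float:
        """Minimum nearest-centre separation (lognormal envelope, lower edge)."""
        return 10.0 ** (self.log10_inter_mu - 1.7 * self.log10_inter_sigma)


@dataclass
class GroundTruth:
    """True partition, unit attributes and per-period herd centre(s)."""

    partition: UnitPartition
    unit_types: dict[str, str]
    unit_sizes: dict[str, int]
    herd_centres: pd.DataFrame  # period_id, zone, x, y


@dataclass
class _Roster:
    units: list[tuple[str, list[str], str]]  # (name, member ids, type)
    solitaries: list[str]
    meta: pd.DataFrame
    radial_factors: np.ndarray = None  # persistent per-group placement factor


def _build_roster(cfg: SocietyConfig, rng: np.random.Generator) -> _Roster:
    n_amu = int(round(cfg.amu_fraction * cfg.n_units))
    types = ["harem"] * (cfg.n_units - n_amu) + ["AMU"] * n_amu
    units, meta_rows = [], []
    lo, hi = cfg.unit_size_range
    for u in range(cfg.n_units):
        name = f"U{u + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        members = [f"{name}i{k + 1}" for k in range(size)]
        utype = types[u]
        if utype == "AMU":
            comp = [("M", "adult")] * size
        else:
            n_stallions = min(size - 1, 1 + int(rng.random() < 0.2))
            n_young = int(rng.integers(0, min(2, size - n_stallions - 1) + 1))
            n_females = size - n_stallions - n_young
            comp = ([("M", "adult")] * n_stallions + [("F", "adult")] * n_females
                    + [(str(rng.choice(["F", "M"])), "young") for _ in range(n_young)])
        for m, (sex, age) in zip(members, comp):
            meta_rows.append((m, sex, age))
        units.append((name, members, utype))
    solitaries = [f"S{k + 1}" for k in range(cfg.n_solitary)]
    meta_rows += [(s, "M", "adult") for s in solitaries]
    meta = pd.DataFrame(meta_rows, columns=["individual_id", "sex", "age_class"])
    # persistent spatial preference: large harems central, small ones and
    # bachelor groups peripheral (dominance-by-size gradient), with a little
    # unit-to-unit idiosyncrasy
    lo_, hi_ = cfg.unit_size_range
    gradient = 0.8 * (cfg.amu_periphery_factor - 1.0)
    factors = []
    for name, members, utype in units:
        if utype == "AMU":
            f = cfg.amu_periphery_factor
        else:
            rel = (len(members) - lo_) / max(1, hi_ - lo_)
            f = 1.0 + gradient * (1.0 - rel)
        factors.append(f * 10.0 ** rng.normal(0.0, 0.12))
    factors += [cfg.amu_periphery_factor * 10.0 ** rng.normal(0.0, 0.12)
                for _ in solitaries]
    return _Roster(units, solitaries, meta, np.asarray(factors))


def _zone_inset(zone, margin):
    x0, y0, x1, y1 = zone
    if x1 - x0 <= 2 * margin or y1 - y0 <= 2 * margin:
        raise ValueError(
            f"infeasible geometry: zone {zone} cannot contain the society at the "
            f"requested spacing (needs a {2 * margin:.0f} m margin)")
    return x0 + margin, y0 + margin, x1 - margin, y1 - margin


def _reflect(v, lo, hi):
    width = hi - lo
    v = (v - lo) % (2 * width)
    v = np.where(v > width, 2 * width - v, v)
    return v + lo


def _place_centres(cfg: SocietyConfig, herd_xy: np.ndarray,
                   factors: np.ndarray, spread: float,
                   rng: np.random.Generator, zone) -> np.ndarray:
    """Pack one centre per group around ``herd_xy`` with the separation floor.

    Candidates come from the calibrated Gaussian cloud (scaled by the
    per-period ``spread`` factor); those closer than ``sep_min`` to an
    already-placed centre are rejected.  Each group's persistent radial
    ``factor`` (peripheral AMUs/solitaries, size-graded harems) scales its
    displacement from the herd centre.  If packing stalls the cloud is
    widened and retried before giving up.
    """
    x0, y0, x1, y1 = zone
    for escalation in range(4):
        s = cfg.centre_sd * spread * (1.3 ** escalation)
        placed: list[np.ndarray] = []
        ok = True
        for factor in factors:
            for _ in range(300):
                cand = herd_xy + factor * rng.normal(0.0, s, 2)
                if not (x0 <= cand[0] <= x1 and y0 <= cand[1] <= y1):
                    continue
                if placed and min(float(np.hypot(*(cand - p))) for p in placed) < cfg.sep_min:
                    continue
                placed.append(cand)
                break
            else:
                ok = False
                break
        if ok:
            return np.vstack(placed)
    raise ValueError(
        "infeasible geometry: could not pack unit centres at minimum separation "
        f"{cfg.sep_min:.0f} m inside zone {zone}")


def generate(cfg: SocietyConfig) -> tuple[SightingTable, GroundTruth]:
    """Generate one synthetic sightings dataset plus its ground truth.

    Deterministic given ``cfg.seed``.  Roster, zone schedule, absence and
    dropout draws depend only on the seed (not on ``herd_attraction``), so a
    matched herd/null pair differs only in the spatial process.
    """
    rng_roster = np.random.default_rng([cfg.seed, 11])
    rng_sched = np.random.default_rng([cfg.seed, 12])
    rng_drop = np.random.default_rng([cfg.seed, 13])
    rng_motion = np.random.default_rng(
        [cfg.seed, 14, 0 if cfg.herd_attraction == "herd" else 1])

    roster = _build_roster(cfg, rng_roster)
    group_names = [name for name, _, _ in roster.units] + roster.solitaries
    group_types = [t for _, _, t in roster.units] + ["solitary"] * len(roster.solitaries)
    group_members = {name: mem for name, mem, _ in roster.units}
    group_members.update({s: [s] for s in roster.solitaries})
    all_ids = [m for name in group_names for m in group_members[name]]
    id_pos = {m: i for i, m in enumerate(all_ids)}
    n_ind = len(all_ids)
    n_groups = len(group_names)
    n_periods = cfg.n_days * cfg.periods_per_day
    multi_zone = len(cfg.zones) > 1

    # schedule (shared across modes): per-day base zone, split days, per-unit
    # zone assignment; then per-period absence and dropout draws
    base_zone = rng_sched.integers(0, len(cfg.zones), size=cfg.n_days)
    split_day = (rng_sched.random(cfg.n_days) < cfg.p_zone_split) & multi_zone
    # peripheral units split off and skip the site more often than central
    # ones (loose attachment gradient, as in the field availability numbers)
    rel_factor = roster.radial_factors / roster.radial_factors.mean()
    p_move = np.clip(cfg.zone_split_fraction * rel_factor, 0.0, 0.9)
    p_absent = np.clip(cfg.p_unit_absent * rel_factor ** 1.5, 0.0, 0.9)
    zassign = np.zeros((cfg.n_days, n_groups), dtype=int)
    for day in range(cfg.n_days):
        zassign[day] = base_zone[day]
        if split_day[day]:
            other = (base_zone[day] + 1) % len(cfg.zones)
            moved = rng_sched.random(n_groups) < p_move
            zassign[day, moved] = other
    u_absent = rng_drop.random((n_groups, n_periods))
    u_tree = rng_drop.random((n_groups, n_periods))
    u_oof = rng_drop.random((n_ind, n_periods))

    margin = 3.0 * cfg.centre_sd * cfg.amu_periphery_factor
    start = _date.fromisoformat(cfg.start_date)
    def member_offset():
        return rng_motion.normal(0.0, cfg.member_sd, 2)

    rows: list[tuple] = []
    herd_rows: list[tuple] = []
    period_index = -1
    for day in range(cfg.n_days):
        zones_today = sorted(set(zassign[day]))
        boxes = {z: _zone_inset(cfg.zones[z], margin) for z in zones_today}
        herd_xy = {z: np.array([rng_motion.uniform(b[0], b[2]),
                                rng_motion.uniform(b[1], b[3])])
                   for z, b in boxes.items()}
        null_state = None
        if cfg.herd_attraction == "null":
            null_state = np.empty((n_groups, 2))
            for g in range(n_groups):
                b = boxes[zassign[day, g]]
                null_state[g] = [rng_motion.uniform(b[0], b[2]),
                                 rng_motion.uniform(b[1], b[3])]
        for slot in range(cfg.periods_per_day):
            period_index += 1
            pid = f"D{day + 1:02d}P{slot + 1:02d}"
            pdate = (start + timedelta(days=day)).isoformat()
            ptime = 9 * 60 + slot * 30
            present = u_absent[:, period_index] >= p_absent
            spread = 10.0 ** (cfg.spread_sigma * abs(rng_motion.normal()))
            centres = np.full((n_groups, 2), np.nan)
            if cfg.herd_attraction == "herd":
                for z in zones_today:
                    b = boxes[z]
                    step = rng_motion.normal(0.0, 60.0, 2)
                    herd_xy[z] = np.array([
                        _reflect(herd_xy[z][0] + step[0], b[0], b[2]),
                        _reflect(herd_xy[z][1] + step[1], b[1], b[3])])
                    sel = np.nonzero(present & (zassign[day] == z))[0]
                    if len(sel):
                        # random placement order: sequential packing pushes
                        # late placements outward, which must not correlate
                        # with unit identity
                        order = rng_motion.permutation(len(sel))
                        placed = _place_centres(
                            cfg, herd_xy[z], roster.radial_factors[sel][order],
                            spread, rng_motion, cfg.zones[z])
                        centres[sel[order]] = placed
                    herd_rows.append((pid, f"Z{z + 1}",
                                      float(herd_xy[z][0]), float(herd_xy[z][1])))
            else:
                step = rng_motion.normal(0.0, 120.0, (n_groups, 2))
                for g in range(n_groups):
                    b = boxes[zassign[day, g]]
                    null_state[g, 0] = _reflect(null_state[g, 0] + step[g, 0], b[0], b[2])
                    null_state[g, 1] = _reflect(null_state[g, 1] + step[g, 1], b[1], b[3])
                centres[:] = null_state
                for z in zones_today:
                    sel = present & (zassign[day] == z)
                    if sel.any():
                        cm = centres[sel].mean(axis=0)
                        herd_rows.append((pid, f"Z{z + 1}", float(cm[0]), float(cm[1])))

            for g, name in enumerate(group_names):
                members = group_members[name]
                zlabel = f"Z{zassign[day, g] + 1}"
                if not present[g]:
                    for m in members:
                        rows.append((m, pid, pdate, ptime, zlabel,
                                     np.nan, np.nan, "absent", None))
                    continue
                tree_resting = u_tree[g, period_index] < cfg.p_tree_hidden
                if tree_resting:
                    tree_xy = centres[g] + member_offset()
                    tree_id = f"T_{pid}_{name}"
                for m in members:
                    if tree_resting:
                        rows.append((m, pid, pdate, ptime, zlabel,
                                     float(tree_xy[0]), float(tree_xy[1]),
                                     "tree_hidden", tree_id))
                    elif u_oof[id_pos[m], period_index] < cfg.p_out_of_frame:
                        rows.append((m, pid, pdate, ptime, zlabel,
                                     np.nan, np.nan, "out_of_frame", None))
                    else:
                        xy = centres[g] + member_offset()
                        rows.append((m, pid, pdate, ptime, zlabel,
                                     float(xy[0]), float(xy[1]), "seen", None))

    sightings = pd.DataFrame(rows, columns=[
        "individual_id", "period_id", "date", "time", "zone",
        "x", "y", "visibility", "tree_id"])
    table = SightingTable(sightings, roster.meta)
    partition = UnitPartition(
        units=[(name, frozenset(mem), t) for name, mem, t in roster.units],
        solitaries=list(roster.solitaries))
    gt = GroundTruth(
        partition=partition,
        unit_types={name: t for name, _, t in roster.units},
        unit_sizes={name: len(mem) for name, mem, _ in roster.units},
        herd_centres=pd.DataFrame(herd_rows, columns=["period_id", "zone", "x", "y"]),
    )
    return table, gt


def generate_null_pair(cfg: SocietyConfig):
    """Matched (herd, null) datasets sharing roster, schedule and dropout."""
    herd_cfg = SocietyConfig(**{**asdict(cfg), "herd_attraction": "herd"})
    null_cfg = SocietyConfig(**{**asdict(cfg), "herd_attraction": "null"})
    return generate(herd_cfg), generate(null_cfg)
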