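"""Permutation inference on the unit network.

Three procedures: (1) data-stream permutation — group memberships are swapped
within (period, zone) strata before the network is rebuilt, preserving each
unit's presence pattern and the per-stratum group counts; the SD of edge
weights is tested against the resulting null networks.  (2) MRQAP with
double-semi-partialing (Dekker): each dyadic predictor is residualized on the
others, the residual matrix is permuted by simultaneous row/column
relabelling, and the refitted coefficient's tails are tabulated.  (3) Nodal
DSP regression: OLS on node attributes with per-predictor significance from
residual (Freedman–Lane-style) permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _perms
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .herd import PermutationResult, UnitTrack
from .network import SnapshotGroups, UnitNetwork, unit_sri


# ---------------------------------------------------------------------------
# data-stream permutation


def datastream_permute(groups: SnapshotGroups, n_perm: int = 10000,
                       seed: int | None = None, burn_in: int = 1000,
                       return_networks: bool = False,
                       return_final_groups: bool = False):
    """Sequential within-stratum membership swaps; one network per swap.

    Each swap picks a (period, zone) stratum with at least two groups and a
    donor group of size >= 2, and moves one unit into another group of the
    same stratum.  Group counts per stratum and every unit's presence pattern
    are conserved.  After ``burn_in`` unrecorded swaps, ``n_perm`` networks
    are recorded along the accumulated chain.  Returns a list of SRI matrices
    (or :class:`UnitNetwork` objects when ``return_networks``).
    """
    units = groups.units
    idx = {u: i for i, u in enumerate(units)}
    n = len(units)

    # base "either" counts are invariant under swaps (presence is conserved)
    base = unit_sri(groups)
    either = base.either_counts
    together = base.together_counts.astype(np.int64).copy()

    strata = [[set(idx[u] for u in g) for g in gs] for _, _, gs in groups.strata]
    eligible = [k for k, gs in enumerate(strata)
                if len(gs) >= 2 and any(len(g) >= 2 for g in gs)]
    if not eligible:
        raise ValueError("degenerate grouping: no stratum allows a swap")

    rng = np.random.default_rng(seed)
    out = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for step in range(burn_in + n_perm):
            k = eligible[rng.integers(len(eligible))]
            gs = strata[k]
            donors = [i for i, g in enumerate(gs) if len(g) >= 2]
            src = donors[rng.integers(len(donors))]
            others = [i for i in range(len(gs)) if i != src]
            dst = others[rng.integers(len(others))]
            members = sorted(gs[src])
            u = members[rng.integers(len(members))]
            for v in gs[src]:
                if v != u:
                    together[u, v] -= 1
                    together[v, u] -= 1
            for v in gs[dst]:
                together[u, v] += 1
                together[v, u] += 1
            gs[src].remove(u)
            gs[dst].add(u)
            if step >= burn_in:
                sri = np.where(either > 0, together / np.maximum(either, 1), 0.0)
                if return_networks:
                    out.append(UnitNetwork(units, sri, together.copy(), either))
                else:
                    out.append(sri)
    if return_final_groups:
        final = SnapshotGroups(
            units=units,
            strata=[(p, z, [frozenset(units[i] for i in g) for g in strata[k]])
                    for k, (p, z, _) in enumerate(groups.strata)],
            presence=groups.presence)
        return out, final
    return out


def edge_weight_sd(sri: np.ndarray, either: np.ndarray) -> float:
    """SD of edge weights over dyads that were observable (either > 0)."""
    iu = np.triu_indices(sri.shape[0], k=1)
    mask = either[iu] > 0
    return float(np.std(sri[iu][mask], ddof=1))


def sd_test(observed: UnitNetwork, nulls, seed: int | None = None) -> PermutationResult:
    """Right-tailed test of the edge-weight SD against data-stream nulls.

    A larger-than-null SD means association is more heterogeneous than chance
    grouping would produce.  p_right = (1 + #{null >= observed}) / (n + 1).
    """
    if len(nulls) < 100:
        raise ValueError("need at least 100 null networks")
    obs = edge_weight_sd(observed.sri, observed.either_counts)
    null_sds = np.array([
        edge_weight_sd(m.sri if isinstance(m, UnitNetwork) else np.asarray(m),
                       observed.either_counts)
        for m in nulls])
    p = (1 + int((null_sds >= obs).sum())) / (len(null_sds) + 1)
    return PermutationResult(observed=obs, null_values=null_sds, p=p,
                             n_perm=len(null_sds), seed=seed,
                             extras={"statistic": "edge_weight_sd"})


# ---------------------------------------------------------------------------
# MRQAP with double semi-partialing


@dataclass
class DyadicDesign:
    """Square symmetric response and named predictor matrices."""

    response: np.ndarray
    predictors: dict[str, np.ndarray]

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        n = self.response.shape[0]
        for name, m in list(self.predictors.items()):
            m = np.asarray(m, dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"predictor {name!r} not conformable")
            if not np.allclose(m, m.T):
                raise ValueError(f"predictor {name!r} not symmetric")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"predictor {name!r} has non-finite entries")
            self.predictors[name] = m


class MRQAPRegressor(RegressorMixin, BaseEstimator):
    """Multiple regression on dyadic matrices with DSP permutation inference.

    Fits OLS of the vectorized response on the vectorized predictors plus an
    intercept.  For each term, the double-semi-partialing null permutes the
    term's residual matrix (residualized on all other terms) by simultaneous
    row/column relabelling and refits; the three tail probabilities
    p(perm >= obs), p(perm <= obs) and p(|perm| >= |obs|) are tabulated with
    the +1 rank correction.  ``exact=True`` enumerates all node permutations.

    After ``fit``: ``results_`` (DataFrame with coefficient, partial
    correlation and the three p-values per term) and ``coef_``.
    """

    def __init__(self, n_perm: int = 10000, seed: int | None = None,
                 exact: bool = False):
        self.n_perm = n_perm
        self.seed = seed
        self.exact = exact

    def fit(self, X: DyadicDesign, y=None):
        design = X
        names = list(design.predictors)
        n = design.response.shape[0]
        if n < 4:
            raise ValueError("need at least 4 nodes")
        iu = np.triu_indices(n, k=1)
        yv = design.response[iu]
        cols = {"(Intercept)": np.ones((n, n)) - np.eye(n)}
        cols.update(design.predictors)
        mat = np.column_stack([cols[c][iu] for c in cols])
        rank = np.linalg.matrix_rank(mat)
        if rank < mat.shape[1]:
            raise ValueError(f"collinear predictors among {list(cols)}")
        beta_full, *_ = np.linalg.lstsq(mat, yv, rcond=None)
        self.coef_ = dict(zip(cols, beta_full))

        rng = np.random.default_rng(self.seed)
        rows = []
        all_names = list(cols)
        for j, name in enumerate(all_names):
            others = np.column_stack([cols[c][iu] for c in all_names if c != name])
            q, _ = np.linalg.qr(others)
            xv = cols[name][iu]
            e_vec = xv - q @ (q.T @ xv)           # DSP residual of the term
            ry = yv - q @ (q.T @ yv)              # response residual (for partial r)
            denom = np.linalg.norm(e_vec) * np.linalg.norm(ry)
            partial_r = float(e_vec @ ry / denom) if denom > 0 else 0.0
            obs = float(e_vec @ yv / (e_vec @ e_vec))  # FWL coefficient

            e_mat = np.zeros((n, n))
            e_mat[iu] = e_vec
            e_mat = e_mat + e_mat.T

            def stat_for(perm):
                ev = e_mat[np.ix_(perm, perm)][iu]
                r = ev - q @ (q.T @ ev)
                d = r @ r
                return float(r @ yv / d) if d > 0 else 0.0

            if self.exact:
                stats_null = np.array([stat_for(np.array(p))
                                       for p in _perms(range(n))])
                p_ge = float((stats_null >= obs - 1e-12).mean())
                p_le = float((stats_null <= obs + 1e-12).mean())
                p_two = float((np.abs(stats_null) >= abs(obs) - 1e-12).mean())
            else:
                stats_null = np.array([stat_for(rng.permutation(n))
                                       for _ in range(self.n_perm)])
                m = self.n_perm + 1
                p_ge = (1 + int((stats_null >= obs - 1e-12).sum())) / m
                p_le = (1 + int((stats_null <= obs + 1e-12).sum())) / m
                p_two = (1 + int((np.abs(stats_null) >= abs(obs) - 1e-12).sum())) / m
            rows.append((name, self.coef_[name], partial_r, p_ge, p_le, p_two))
        self.results_ = pd.DataFrame(rows, columns=[
            "term", "coefficient", "partial_correlation",
            "p(beta>=r)", "p(beta<=r)", "p(|beta|<=|r|)"]).set_index("term")
        return self

    def predict(self, X: DyadicDesign):
        n = X.response.shape[0]
        iu = np.triu_indices(n, k=1)
        out = self.coef_["(Intercept)"] * np.ones(iu[0].size)
        for name, m in X.predictors.items():
            out = out + self.coef_[name] * m[iu]
        return out


def mrqap_dsp(design: DyadicDesign, n_perm: int = 10000,
              seed: int | None = None, exact: bool = False) -> pd.DataFrame:
    """Functional wrapper over :class:`MRQAPRegressor`."""
    return MRQAPRegressor(n_perm=n_perm, seed=seed, exact=exact).fit(design).results_


# ---------------------------------------------------------------------------
# nodal DSP regression


@dataclass
class NodalDesign:
    """Node-level response vector and predictor table."""

    response: pd.Series
    predictors: pd.DataFrame

    def __post_init__(self):
        if len(self.response) != len(self.predictors):
            raise ValueError("response and predictors must align")
        if not np.all(np.isfinite(self.predictors.to_numpy(dtype=float))):
            raise ValueError("predictors must be finite")


class NodalDSPRegressor(RegressorMixin, BaseEstimator):
    """OLS on node attributes with residual-permutation p-values.

    Coefficients, SEs, t-values and classical p(<|t|) come from ordinary
    least squares.  The permutation p of each predictor follows the
    Freedman–Lane scheme: fit the reduced model without the focal predictor,
    permute its residuals, add them back to the reduced fit, refit the full
    model and compare |t|.  The intercept gets no permutation p.
    """

    def __init__(self, n_perm: int = 10000, seed: int | None = None):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xa.shape[1])]
        yv = np.asarray(y, dtype=float).ravel()
        n, p = Xa.shape
        if n <= p + 1:
            raise ValueError("need more nodes than predictors + intercept")
        M = np.column_stack([np.ones(n), Xa])
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError("rank-deficient design")
        terms = ["(Intercept)"] + names

        def ols_t(Mm, yy):
            beta, *_ = np.linalg.lstsq(Mm, yy, rcond=None)
            resid = yy - Mm @ beta
            dof = len(yy) - Mm.shape[1]
            s2 = resid @ resid / dof
            cov = s2 * np.linalg.inv(Mm.T @ Mm)
            se = np.sqrt(np.diag(cov))
            return beta, se, beta / se, dof

        beta, se, tval, dof = ols_t(M, yv)
        p_classical = 2 * stats.t.sf(np.abs(tval), dof)

        rng = np.random.default_rng(self.seed)
        p_perm = [np.nan]  # intercept
        for j in range(1, M.shape[1]):
            reduced = np.delete(M, j, axis=1)
            b_red, *_ = np.linalg.lstsq(reduced, yv, rcond=None)
            fitted = reduced @ b_red
            resid = yv - fitted
            count = 0
            for _ in range(self.n_perm):
                y_star = fitted + resid[rng.permutation(n)]
                _, _, t_star, _ = ols_t(M, y_star)
                count += abs(t_star[j]) >= abs(tval[j]) - 1e-12
            p_perm.append((1 + count) / (self.n_perm + 1))
        self.results_ = pd.DataFrame({
            "term": terms, "coefficient": beta, "se": se, "t": tval,
            "p(<|t|)": p_classical, "p(perm)": p_perm,
        }).set_index("term")
        self.coef_ = beta[1:]
        self.intercept_ = beta[0]
        return self

    def predict(self, X):
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return self.intercept_ + Xa @ self.coef_


def nodal_dsp(design: NodalDesign, n_perm: int = 10000,
              seed: int | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`NodalDSPRegressor`."""
    est = NodalDSPRegressor(n_perm=n_perm, seed=seed)
    return est.fit(design.predictors, design.response).results_


# ---------------------------------------------------------------------------
# design builders


def build_dyadic_design(network: UnitNetwork, track: UnitTrack,
                        unit_types: dict[str, str],
                        unit_sizes: dict[str, int]) -> DyadicDesign:
    """Standard dyadic design: size difference, type similarity, centrality
    difference, and the proportion of shared observation days in which the
    two units used the same zone (location overlap)."""
    units = network.units
    n = len(units)
    sizes = np.array([unit_sizes[u] for u in units], dtype=float)
    types = np.array([unit_types[u] for u in units])
    strength = network.strength().to_numpy()

    size_diff = np.abs(sizes[:, None] - sizes[None, :])
    type_sim = (types[:, None] != types[None, :]).astype(float)
    cent_diff = np.abs(strength[:, None] - strength[None, :])

    day_zones: dict[str, dict[str, set]] = {}
    for (unit, date), grp in track.fixes.groupby(["unit", "date"], sort=False):
        day_zones.setdefault(unit, {})[date] = set(grp["zone"])
    overlap = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            da, db = day_zones.get(units[a], {}), day_zones.get(units[b], {})
            shared = set(da) & set(db)
            if shared:
                same = sum(1 for d in shared if da[d] & db[d])
                overlap[a, b] = overlap[b, a] = same / len(shared)
    return DyadicDesign(response=network.sri, predictors={
        "size_difference": size_diff,
        "type_similarity": type_sim,
        "centrality_difference": cent_diff,
        "location_overlap": overlap,
    })


def build_nodal_design(network: UnitNetwork, unit_types: dict[str, str],
                       unit_sizes: dict[str, int],
                       stallion_counts: dict[str, int] | None,
                       observation_counts: dict[str, int],
                       model: str = "type") -> NodalDesign:
    """Nodal designs for strength centrality.

    ``model="type"``: harem (+1) vs AMU (-1) indicator plus mean-centred
    observation count, over all units.  ``model="harem"``: harem size and
    stallion count plus mean-centred observation count, harems only.
    """
    units = network.units
    strength = network.strength()
    obs = pd.Series({u: observation_counts[u] for u in units}, dtype=float)
    obs_centred = obs - obs.mean()
    if model == "type":
        ind = pd.Series({u: 1.0 if unit_types[u] == "harem" else -1.0 for u in units})
        X = pd.DataFrame({"harem_vs_amu": ind, "observation_no": obs_centred})
        return NodalDesign(response=strength, predictors=X.loc[units])
    if model == "harem":
        harems = [u for u in units if unit_types[u] == "harem"]
        if stallion_counts is None:
            raise ValueError("model='harem' requires stallion counts")
        obs_h = obs.loc[harems] - obs.loc[harems].mean()
        X = pd.DataFrame({
            "harem_size": pd.Series({u: float(unit_sizes[u]) for u in harems}),
            "stallion_no": pd.Series({u: float(stallion_counts[u]) for u in harems}),
            "observation_no": obs_h,
        })
        return NodalDesign(response=strength.loc[harems], predictors=X.loc[harems])
    raise ValueError("model must be 'type' or 'harem'")
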