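"""Economic index, co-ancestry accounting and mate-allocation optimization
trading genetic gain against co-ancestry at a target angle.

The optimizer builds a gain/co-ancestry frontier by maximizing, over integer
contribution vectors, a weighted scalarization of the (min-max normalized)
mean economic index and mean co-ancestry. The target angle theta in
[0, 90] degrees selects the frontier point maximizing
sin(theta) * gain_norm - cos(theta) * coancestry_norm: 0 degrees returns the
minimum-co-ancestry plan, 90 degrees the maximum-gain plan, and both
summaries move monotonically in between. This angle convention is a
documented re-expression of the target-degrees contract, not a clone of any
proprietary solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cicerscan.prediction import GRM

logger = logging.getLogger("cicerscan.ocs")


@dataclass
class EconomicIndexParams:
    base_price: float = 400.0        # $/tonne
    yield_per_gram: float = 0.1      # t/ha per g of YPP (18 g = 1.8 t/ha)
    mean_ypp: float = 18.0           # g/plant population anchor
    seed_bonus_rate: float = 35.0    # $/g above the 100SW threshold
    seed_bonus_threshold: float = 5.9  # g (GEBV 100SW); no bonus at or below
    earliness_bonus_rate: float = 10.0  # $/day for negative earliness GEBV

    def __post_init__(self) -> None:
        for name in ("base_price", "seed_bonus_rate", "earliness_bonus_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def economic_index(gebvs: pd.DataFrame, params: EconomicIndexParams | None = None) -> pd.Series:
    """Dollar-per-hectare index from GEBVs for YPP, 100SW, DF and DM.

    earliness = (GEBV_DF + GEBV_DM)/2; price $/t = base + 35 * max(0,
    GEBV_100SW - 5.9) + 10 * max(0, -earliness); yield t/ha = (mean YPP +
    GEBV_YPP) * 0.1; index = price * yield. Accessions missing any trait
    GEBV are excluded with a log entry.
    """
    params = params or EconomicIndexParams()
    required = ["YPP", "100SW", "DF", "DM"]
    missing_cols = [c for c in required if c not in gebvs.columns]
    if missing_cols:
        raise ValueError(f"GEBV table missing traits: {missing_cols}")
    complete = gebvs[required].notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("economic_index: %d accessions excluded for missing GEBVs", n_drop)
    sub = gebvs.loc[complete]
    earliness = (sub["DF"] + sub["DM"]) / 2.0
    price = (
        params.base_price
        + params.seed_bonus_rate * np.maximum(0.0, sub["100SW"] - params.seed_bonus_threshold)
        + params.earliness_bonus_rate * np.maximum(0.0, -earliness)
    )
    yield_t_ha = (params.mean_ypp + sub["YPP"]) * params.yield_per_gram
    return (price * yield_t_ha).rename("index")


def coancestry(grm: GRM, i: int, j: int) -> float:
    """Kinship f_ij = G_ij / 2; equals the inbreeding of an i x j progeny."""
    return grm.kinship(i, j)


@dataclass
class MatingPlan:
    matings: pd.DataFrame  # parent1, parent2, progeny_index, progeny_inbreeding
    contributions: pd.Series  # matings per parent id
    mean_progeny_index: float
    mean_coancestry: float  # contribution-weighted c'Gc/2
    target_degrees: float
    group: str | None = None


def _plan_stats(c: np.ndarray, index: np.ndarray, kin: np.ndarray) -> tuple[float, float]:
    """Mean parental index and contribution-weighted mean co-ancestry x'Gx/2."""
    total = c.sum()
    x = c / total
    return float(x @ index), float(x @ kin @ x)


def _hill_climb(
    objective,
    n: int,
    total: int,
    cap: int,
    rng: np.random.Generator,
    restarts: int = 3,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy-exchange maximization over integer contribution vectors with
    sum(c) = total and 0 <= c_i <= cap."""
    best_c, best_v = None, -np.inf
    starts = []
    if init is not None:
        starts.append(init.copy())
    for _ in range(restarts):
        c = np.zeros(n, dtype=int)
        slots = rng.permutation(np.repeat(np.arange(n), cap))[:total]
        for s in slots:
            c[s] += 1
        if c.sum() == total:
            starts.append(c)
    for c in starts:
        v = objective(c)
        improved = True
        while improved:
            improved = False
            donors = np.flatnonzero(c > 0)
            receivers = np.flatnonzero(c < cap)
            move_best, move_v = None, v
            for a in donors:
                for b in receivers:
                    if a == b:
                        continue
                    c[a] -= 1
                    c[b] += 1
                    nv = objective(c)
                    c[a] += 1
                    c[b] -= 1
                    if nv > move_v + 1e-12:
                        move_v, move_best = nv, (a, b)
            if move_best is not None:
                a, b = move_best
                c[a] -= 1
                c[b] += 1
                v = move_v
                improved = True
        if v > best_v:
            best_v, best_c = v, c.copy()
    return best_c


def _allocate_mates(c: np.ndarray, kin: np.ndarray, ids: np.ndarray, index: np.ndarray) -> pd.DataFrame:
    """Pair contribution slots greedily by lowest pairwise kinship; selfing
    only when a single parent holds all remaining slots."""
    remaining = c.copy()
    rows = []
    while remaining.sum() >= 2:
        active = np.flatnonzero(remaining > 0)
        best = None
        best_f = np.inf
        for ai in range(active.size):
            for bi in range(ai, active.size):
                i, j = active[ai], active[bi]
                if i == j:
                    if remaining[i] < 2 or active.size > 1:
                        continue
                f = kin[i, j]
                if f < best_f:
                    best_f, best = f, (i, j)
        i, j = best
        remaining[i] -= 1
        remaining[j] -= 1
        rows.append(
            (ids[i], ids[j], float((index[i] + index[j]) / 2.0), float(kin[i, j]))
        )
    return pd.DataFrame(rows, columns=["parent1", "parent2", "progeny_index", "progeny_inbreeding"])


def optimize_matings(
    index: pd.Series,
    grm: GRM,
    n_matings: int,
    target_degrees: float,
    max_use: int = 4,
    seed: int = 0,
    n_weights: int = 15,
    group: str | None = None,
) -> MatingPlan:
    """Select parental contributions and allocate mates at a target angle on
    the gain/co-ancestry frontier.

    ``index`` is keyed by candidate id and must align with ``grm.ids``.
    Contributions are integers in [0, max_use] summing to 2 * n_matings.
    """
    if not 0.0 <= target_degrees <= 90.0:
        raise ValueError("target_degrees must be in [0, 90]")
    ids = np.asarray(index.index)
    order = {s: k for k, s in enumerate(grm.ids)}
    missing = set(ids) - set(order)
    if missing:
        raise ValueError(f"candidates without GRM entry: {sorted(missing)[:5]}")
    gi = np.array([order[s] for s in ids])
    kin = grm.matrix[np.ix_(gi, gi)] / 2.0
    vals = index.to_numpy(dtype=float)
    n = vals.size
    total = 2 * n_matings
    if n < 2:
        raise ValueError("need at least 2 candidates")
    if n * max_use < total:
        raise ValueError("per-parent cap makes the requested mating count infeasible")
    rng = np.random.default_rng(seed)

    def raw(c):
        return _plan_stats(np.asarray(c), vals, kin)

    # frontier endpoints
    c_gain = _hill_climb(lambda c: raw(c)[0], n, total, max_use, rng)
    c_div = _hill_climb(lambda c: -raw(c)[1], n, total, max_use, rng)
    i_div, f_div = raw(c_div)
    i_gain, f_gain = raw(c_gain)
    i_span = max(i_gain - i_div, 1e-12)
    f_span = max(f_gain - f_div, 1e-12)

    def norm(c):
        i_raw, f_raw = raw(c)
        return (i_raw - i_div) / i_span, (f_raw - f_div) / f_span

    frontier = [c_div]
    for w in np.linspace(0.0, 1.0, n_weights)[1:-1]:
        def obj(c, w=w):
            gi_n, fi_n = norm(c)
            return (1.0 - w) * gi_n - w * fi_n
        frontier.append(_hill_climb(obj, n, total, max_use, rng, init=frontier[-1]))
    frontier.append(c_gain)

    theta = np.deg2rad(target_degrees)
    best_c, best_v = None, -np.inf
    for c in frontier:
        gi_n, fi_n = norm(c)
        v = np.sin(theta) * gi_n - np.cos(theta) * fi_n
        if v > best_v + 1e-12:
            best_v, best_c = v, c
    chosen = np.asarray(best_c)
    matings = _allocate_mates(chosen, kin, ids, vals)
    mean_idx, mean_f = raw(chosen)
    return MatingPlan(
        matings=matings,
        contributions=pd.Series(chosen, index=ids, name="contributions"),
        mean_progeny_index=mean_idx,
        mean_coancestry=mean_f,
        target_degrees=float(target_degrees),
        group=group,
    )


def optimize_matings_by_group(
    index: pd.Series,
    grm: GRM,
    groups: pd.Series,
    n_matings: dict[str, int],
    target_degrees: float,
    **kwargs,
) -> dict[str, MatingPlan]:
    """Run the optimizer independently within each group (matings never cross
    groups)."""
    plans = {}
    for grp, n_mat in n_matings.items():
        members = groups.index[groups == grp]
        if len(members) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 candidates")
        plans[grp] = optimize_matings(
            index.loc[members], grm, n_mat, target_degrees, group=grp, **kwargs
        )
    return plans


def summarize_response(
    plan: MatingPlan,
    gebvs: pd.DataFrame,
    grm: GRM | None = None,
) -> pd.DataFrame:
    """Per-trait response to selection of the plan's predicted progeny.

    response = mean mid-parent GEBV over matings - mean candidate GEBV,
    reported absolute and as percent of the candidate mean. When a GRM is
    given, the progeny-inbreeding increase over the candidates' mean kinship
    is appended as a pseudo-trait row.
    """
    if plan.matings.empty:
        raise ValueError("empty mating plan")
    rows = []
    for trait in gebvs.columns:
        mid = (
            gebvs[trait].reindex(plan.matings["parent1"]).to_numpy()
            + gebvs[trait].reindex(plan.matings["parent2"]).to_numpy()
        ) / 2.0
        cand_mean = float(gebvs[trait].mean())
        resp = float(np.mean(mid) - cand_mean)
        pct = 100.0 * resp / cand_mean if cand_mean != 0 else np.nan
        rows.append((trait, float(np.mean(mid)), cand_mean, resp, pct))
    out = pd.DataFrame(
        rows, columns=["trait", "progeny_mean", "candidate_mean", "response", "percent_response"]
    )
    if grm is not None:
        order = {s: k for k, s in enumerate(grm.ids)}
        gi = np.array([order[s] for s in gebvs.index if s in order])
        kin = grm.matrix[np.ix_(gi, gi)] / 2.0
        off_diag = kin[~np.eye(kin.shape[0], dtype=bool)]
        base_f = float(off_diag.mean()) if off_diag.size else 0.0
        prog_f = float(plan.matings["progeny_inbreeding"].mean())
        out.attrs["inbreeding_increase"] = prog_f - base_f
        out.attrs["mean_progeny_inbreeding"] = prog_f
    return out
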