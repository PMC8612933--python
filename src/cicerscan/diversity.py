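"""Windowed diversity statistics, Weir–Cockerham F_ST, ROD, LD decay, and the
combined selection-window caller.

Per-window pi uses the covered window length as denominator (per-bp,
VCFtools-style): monomorphic and uncalled positions contribute zero. A site
contributes only if the population has at least two non-missing diploid calls
there. Watterson's theta and Tajima's D constants are evaluated at the
window's median per-site allele count, since missingness varies by site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from cicerscan.core_io import MISSING, GenotypeMatrix, Window

logger = logging.getLogger("cicerscan.diversity")


@dataclass
class ScanParams:
    """Selection-window criterion: upper-q ROD and F_ST plus D below threshold."""

    quantile: float = 0.90
    d_threshold: float = -2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sequences."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _site_stats(g: GenotypeMatrix, sample_idx: np.ndarray):
    """Per-site allele counts, frequencies and pi contribution for one population.

    Returns (used mask: >=2 diploid calls, n alleles, alt count, pi_site).
    """
    d = g.dosages[sample_idx]
    called = d != MISSING
    n_dip = called.sum(axis=0)
    n = 2 * n_dip
    alt = np.where(called, d, 0).sum(axis=0)
    used = n_dip >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        pi_site = np.where(
            used, (n / np.maximum(n - 1.0, 1.0)) * 2.0 * p * (1.0 - p), 0.0
        )
    return used, n.astype(np.int64), alt.astype(np.int64), pi_site


def _window_slices(g: GenotypeMatrix, windows: Sequence[Window]) -> list[np.ndarray]:
    """Variant index arrays per window (1-based pos in (start, end])."""
    chrom = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy()
    out = []
    for w in windows:
        on_chrom = np.flatnonzero(chrom == w.chrom)
        p = pos[on_chrom]
        lo = np.searchsorted(p, w.start + 1, side="left")
        hi = np.searchsorted(p, w.end, side="right")
        out.append(on_chrom[lo:hi])
    return out


def window_diversity(
    g: GenotypeMatrix,
    windows: Sequence[Window],
    population: str | np.ndarray,
) -> pd.DataFrame:
    """Per-window S, per-bp pi, per-bp Watterson's theta and Tajima's D."""
    idx = (
        g.population_index(population) if isinstance(population, str) else np.asarray(population)
    )
    if idx.size < 2:
        raise ValueError("population must have at least 2 samples")
    used, n_alleles, alt, pi_site = _site_stats(g, idx)
    seg = used & (alt > 0) & (alt < n_alleles)

    rows = []
    for w, vmask in zip(windows, _window_slices(g, windows)):
        site_used = vmask[used[vmask]]
        length = w.length
        n_used = site_used.size
        s = int(seg[vmask].sum())
        pi_total = float(pi_site[site_used].sum())
        pi = pi_total / length
        if n_used == 0:
            rows.append((w.chrom, w.start, w.end, w.partial, length, 0, 0, np.nan, np.nan, np.nan))
            continue
        n_med = int(np.median(n_alleles[site_used]))
        theta_w = np.nan
        d = np.nan
        if n_med >= 2:
            k = tajima_constants(n_med)
            theta_w = s / (k["a1"] * length)
            if s > 0:
                var = k["e1"] * s + k["e2"] * s * (s - 1)
                d = (pi_total - s / k["a1"]) / np.sqrt(var)
        rows.append((w.chrom, w.start, w.end, w.partial, length, n_used, s, pi, theta_w, d))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "partial", "covered", "n_sites", "S",
            "pi", "theta_w", "tajima_d",
        ],
    )


def _wc_site_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
):
    """Weir & Cockerham (1984) per-site variance components a, b, c for r=2.

    n_i: called individuals; p_i: alt frequency; h_i: het individual fraction.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    return a, b, c


def weir_cockerham_fst(
    g: GenotypeMatrix,
    windows: Sequence[Window],
    pop_a: str,
    pop_b: str,
) -> tuple[pd.DataFrame, float]:
    """Windowed and global weighted Weir–Cockerham F_ST between two populations.

    Window (and global) estimates are ratios of summed components sum(a) /
    sum(a+b+c) — never means of per-site ratios. Negative ratios are reported
    as computed and flagged. A site contributes only when both populations
    have >= 2 called individuals.
    """
    ia = g.population_index(pop_a)
    ib = g.population_index(pop_b)
    da, db = g.dosages[ia], g.dosages[ib]

    def pop_site(d):
        called = d != MISSING
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
            h = np.where(n > 0, (d == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        return n, p, h

    n1, p1, h1 = pop_site(da)
    n2, p2, h2 = pop_site(db)
    usable = (n1 >= 2) & (n2 >= 2)
    a, b, c = _wc_site_components(n1, p1, h1, n2, p2, h2)
    a = np.where(usable, a, 0.0)
    denom_site = np.where(usable, a + b + c, 0.0)

    rows = []
    for w, vmask in zip(windows, _window_slices(g, windows)):
        m = vmask[usable[vmask]]
        sum_a = float(a[m].sum())
        sum_abc = float(denom_site[m].sum())
        if m.size == 0 or sum_abc == 0.0:
            rows.append((w.chrom, w.start, w.end, w.partial, m.size, sum_a, sum_abc, np.nan, False))
        else:
            fst = sum_a / sum_abc
            rows.append((w.chrom, w.start, w.end, w.partial, m.size, sum_a, sum_abc, fst, fst < 0))
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "partial", "n_sites", "sum_a", "sum_abc", "fst", "negative"],
    )
    total_abc = float(denom_site[usable].sum())
    global_fst = float(a[usable].sum() / total_abc) if total_abc > 0 else np.nan
    return table, global_fst


def rod(div_ref: pd.DataFrame, div_target: pd.DataFrame) -> pd.Series:
    """Reduction of diversity per window: 1 - pi_target / pi_ref.

    Direction: large ROD = strong diversity loss in the target population, so
    the "upper" tail of its distribution is sweep-like. Missing where the
    reference window has pi = 0 or missing.
    """
    for col in ("chrom", "start", "end"):
        if not (div_ref[col].to_numpy() == div_target[col].to_numpy()).all():
            raise ValueError("window sets of the two diversity tables differ")
    pi_r = div_ref["pi"].to_numpy(dtype=float)
    pi_t = div_target["pi"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((pi_r > 0) & np.isfinite(pi_r) & np.isfinite(pi_t), 1.0 - pi_t / pi_r, np.nan)
    return pd.Series(out, name="rod")


def ld_decay(
    g: GenotypeMatrix,
    population: str | np.ndarray,
    max_dist: int = 1_000_000,
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Mean genotype r² by pairwise distance bin (intra-chromosomal pairs).

    Also reports, via attribute ``half_decay_distance`` on the returned frame,
    the bin midpoint at which mean r² first falls below half its maximum.
    """
    idx = (
        g.population_index(population) if isinstance(population, str) else np.asarray(population)
    )
    chrom = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy()
    d = g.dosages[idx].astype(float)
    d[d == MISSING] = np.nan

    n_bins = int(np.ceil(max_dist / bin_size))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        p = pos[cols]
        for ai in range(cols.size):
            hi = np.searchsorted(p, p[ai] + max_dist, side="right")
            for bi in range(ai + 1, hi):
                x, y = d[:, cols[ai]], d[:, cols[bi]]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 2:
                    continue
                xs, ys = x[ok], y[ok]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                b = min(int((p[bi] - p[ai]) // bin_size), n_bins - 1)
                sums[b] += r * r
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(
        {
            "dist_lo": np.arange(n_bins) * bin_size,
            "dist_hi": (np.arange(n_bins) + 1) * bin_size,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )
    half = np.nan
    finite = np.isfinite(mean_r2)
    if finite.any():
        peak = np.nanmax(mean_r2)
        below = np.flatnonzero(finite & (mean_r2 < peak / 2.0))
        if below.size:
            half = float((below[0] + 0.5) * bin_size)
    table.attrs["half_decay_distance"] = half
    return table


def call_selection_windows(
    rod_values: pd.Series | np.ndarray,
    fst_values: pd.Series | np.ndarray,
    d_values: pd.Series | np.ndarray,
    params: ScanParams | None = None,
) -> pd.DataFrame:
    """Combined sweep criterion: ROD and F_ST in the upper tail (empirical
    q-quantile, type-7) AND target-population Tajima's D below the threshold.
    """
    params = params or ScanParams()
    rod_v = np.asarray(rod_values, dtype=float)
    fst_v = np.asarray(fst_values, dtype=float)
    d_v = np.asarray(d_values, dtype=float)
    if not (rod_v.size == fst_v.size == d_v.size):
        raise ValueError("statistic vectors differ in length")
    for name, v in (("ROD", rod_v), ("F_ST", fst_v), ("Tajima's D", d_v)):
        if not np.isfinite(v).any():
            raise ValueError(f"all values of {name} are missing")
    q_rod = float(np.quantile(rod_v[np.isfinite(rod_v)], params.quantile))
    q_fst = float(np.quantile(fst_v[np.isfinite(fst_v)], params.quantile))
    selected = (
        np.nan_to_num(rod_v, nan=-np.inf) >= q_rod
    ) & (np.nan_to_num(fst_v, nan=-np.inf) >= q_fst) & (
        np.nan_to_num(d_v, nan=np.inf) < params.d_threshold
    )
    return pd.DataFrame(
        {
            "rod": rod_v,
            "fst": fst_v,
            "tajima_d": d_v,
            "selected": selected,
            "rod_cutoff": q_rod,
            "fst_cutoff": q_fst,
        }
    )


def cluster_snps_to_intervals(
    positions: Sequence[int] | np.ndarray,
    chrom: Sequence[str] | str = "chr",
    gap: int = 10_000,
) -> pd.DataFrame:
    """Single-linkage chaining of candidate SNP positions into intervals.

    Consecutive candidates <= ``gap`` apart (per chromosome) share an
    interval; an interval spans the min..max member positions (1-based
    inclusive on both ends).
    """
    positions = np.asarray(positions, dtype=np.int64)
    if isinstance(chrom, str):
        chroms = np.full(positions.size, chrom, dtype=object)
    else:
        chroms = np.asarray(chrom, dtype=object)
    rows = []
    for c in pd.unique(chroms):
        p = np.sort(positions[chroms == c])
        if p.size == 0:
            continue
        start = p[0]
        prev = p[0]
        n = 1
        for x in p[1:]:
            if x - prev <= gap:
                prev = x
                n += 1
            else:
                rows.append((c, int(start), int(prev), n))
                start = prev = x
                n = 1
        rows.append((c, int(start), int(prev), n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps"])
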