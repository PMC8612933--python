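"""Private / population-enriched allele classification and structural-variant
merging plus population-frequency filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cicerscan.core_io import MISSING, GenotypeMatrix

logger = logging.getLogger("cicerscan.varclass")

SV_TYPES = ("INS", "DEL", "INV", "ITX", "CTX")

SV_COLUMNS = ["sv_type", "chrom", "pos1", "chrom2", "pos2", "sample", "caller"]


@dataclass
class ClassParams:
    private_min_accessions: int = 4
    enriched_min_freq: float = 0.20
    enriched_other_max_freq: float = 0.02
    pooled_other: bool = False  # pool other populations instead of per-population

    def __post_init__(self) -> None:
        for name in ("enriched_min_freq", "enriched_other_max_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SVParams:
    merge_max_dist: int = 100  # strict upper bound on both breakpoint distances
    min_pop_fraction: float = 0.05  # inclusive carrier-fraction threshold

    def __post_init__(self) -> None:
        if self.merge_max_dist <= 0 or self.min_pop_fraction <= 0:
            raise ValueError("SV parameters must be positive")


def classify_alleles(g: GenotypeMatrix, params: ClassParams | None = None) -> pd.DataFrame:
    """Classify the alt allele per variant per population.

    private: carried by >= private_min_accessions accessions in the
    population and by none elsewhere. enriched: frequency >= enriched_min_freq
    in the population and <= enriched_other_max_freq in each other population
    (or in the pooled others, with ``pooled_other``). Carrier semantics are
    presence/absence: het and hom-alt count equally. Frequencies use
    non-missing alleles.
    """
    params = params or ClassParams()
    pops = list(pd.unique(g.samples["population"]))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    carriers = {}
    freqs = {}
    counts_n = {}
    counts_alt = {}
    for p in pops:
        idx = g.population_index(p)
        d = g.dosages[idx]
        carriers[p] = (d >= 1).sum(axis=0)
        n, alt = g.allele_counts(idx)
        counts_n[p], counts_alt[p] = n, alt
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[p] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    frames = []
    for p in pops:
        others = [q for q in pops if q != p]
        other_carriers = sum(carriers[q] for q in others)
        is_private = (carriers[p] >= params.private_min_accessions) & (other_carriers == 0)
        if params.pooled_other:
            pooled_n = sum(counts_n[q] for q in others)
            pooled_alt = sum(counts_alt[q] for q in others)
            with np.errstate(invalid="ignore", divide="ignore"):
                pooled_f = np.where(pooled_n > 0, pooled_alt / np.maximum(pooled_n, 1), np.nan)
            other_ok = np.nan_to_num(pooled_f, nan=0.0) <= params.enriched_other_max_freq
        else:
            other_ok = np.ones(g.n_variants, dtype=bool)
            for q in others:
                other_ok &= np.nan_to_num(freqs[q], nan=0.0) <= params.enriched_other_max_freq
        is_enriched = (np.nan_to_num(freqs[p], nan=0.0) >= params.enriched_min_freq) & other_ok
        cls = np.where(is_private, "private", np.where(is_enriched, "enriched", "neither"))
        frames.append(
            pd.DataFrame(
                {
                    "variant_index": np.arange(g.n_variants),
                    "population": p,
                    "carriers": carriers[p],
                    "freq": freqs[p],
                    "class": cls,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Structural variants


def _check_sv_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "chrom2" not in df.columns:
        df["chrom2"] = df["chrom"]
    df["chrom2"] = df["chrom2"].fillna(df["chrom"])
    unknown = set(df["sv_type"]) - set(SV_TYPES)
    if unknown:
        raise ValueError(f"unknown SV types: {sorted(unknown)}")
    intra = df["sv_type"].isin(("INS", "DEL", "INV", "ITX"))
    bad = intra & (df["pos1"] > df["pos2"])
    if bad.any():
        raise ValueError("pos1 must be <= pos2 for intra-chromosomal SV types")
    return df


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _cluster_calls(df: pd.DataFrame, max_dist: int, group_cols: list[str]) -> np.ndarray:
    """Transitive-closure clustering of SV calls; both breakpoint distances
    must be < max_dist and type/chromosome identities must match."""
    labels = np.full(len(df), -1, dtype=np.int64)
    next_label = 0
    for _, sub in df.groupby(group_cols, sort=False, dropna=False):
        idx = sub.index.to_numpy()
        order = np.argsort(sub["pos1"].to_numpy(), kind="stable")
        idx = idx[order]
        p1 = df.loc[idx, "pos1"].to_numpy()
        p2 = df.loc[idx, "pos2"].to_numpy()
        uf = _UnionFind(idx.size)
        for i in range(idx.size):
            for j in range(i + 1, idx.size):
                if p1[j] - p1[i] >= max_dist:
                    break
                if abs(p2[j] - p2[i]) < max_dist:
                    uf.union(i, j)
        roots = {}
        for i in range(idx.size):
            r = uf.find(i)
            if r not in roots:
                roots[r] = next_label
                next_label += 1
            labels[df.index.get_loc(idx[i])] = roots[r]
    return labels


def merge_sv_calls(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    params: SVParams | None = None,
) -> pd.DataFrame:
    """Merge two callers' SV calls per sample.

    Calls of the same type (and chromosome identities) merge when both
    breakpoint distances are < merge_max_dist; merging is a transitive
    closure. The merged representative keeps caller_A coordinates when the
    cluster contains a caller_A call, otherwise the first caller_B call.
    """
    params = params or SVParams()
    a = _check_sv_frame(calls_a)
    b = _check_sv_frame(calls_b)
    allc = pd.concat([a, b], ignore_index=True)
    if allc.empty:
        return allc
    # representative precedence by caller id (lexicographic), so the merge is
    # commutative in argument order; with callers named caller_A/caller_B the
    # first caller's coordinates win
    allc = allc.assign(_prio=allc["caller"].astype(str))
    labels = _cluster_calls(
        allc, params.merge_max_dist, ["sample", "sv_type", "chrom", "chrom2"]
    )
    allc = allc.assign(_cluster=labels)
    reps = (
        allc.sort_values(["_cluster", "_prio", "pos1"], kind="stable")
        .groupby("_cluster", sort=True)
        .first()
        .reset_index(drop=True)
    )
    n_merged = len(allc) - len(reps)
    if n_merged:
        logger.info("merge_sv_calls: merged %d duplicate calls", n_merged)
    return reps.drop(columns=["_prio"]).reset_index(drop=True)


def filter_sv_frequency(
    merged: pd.DataFrame,
    sample_to_pop: dict[str, str] | pd.Series,
    params: SVParams | None = None,
) -> pd.DataFrame:
    """Cluster merged calls across samples into loci (same breakpoint-distance
    rule) and keep a locus for a population when the carrier fraction is
    >= min_pop_fraction (inclusive)."""
    params = params or SVParams()
    if merged.empty:
        return pd.DataFrame(
            columns=["locus", "sv_type", "chrom", "pos1", "chrom2", "pos2",
                     "population", "n_carriers", "pop_size", "fraction"]
        )
    s2p = pd.Series(sample_to_pop)
    missing = set(merged["sample"]) - set(s2p.index)
    if missing:
        raise ValueError(f"samples without population assignment: {sorted(missing)[:5]}")
    df = _check_sv_frame(merged).reset_index(drop=True)
    labels = _cluster_calls(df, params.merge_max_dist, ["sv_type", "chrom", "chrom2"])
    df = df.assign(_locus=labels, _pop=s2p.loc[df["sample"]].to_numpy())
    pop_sizes = s2p.value_counts()
    rows = []
    for locus, sub in df.groupby("_locus", sort=True):
        rep = sub.iloc[0]
        for popn, psub in sub.groupby("_pop"):
            n_car = psub["sample"].nunique()
            size = int(pop_sizes[popn])
            frac = n_car / size
            if frac >= params.min_pop_fraction:
                rows.append(
                    (int(locus), rep["sv_type"], rep["chrom"], rep["pos1"],
                     rep["chrom2"], rep["pos2"], popn, n_car, size, frac)
                )
    return pd.DataFrame(
        rows,
        columns=["locus", "sv_type", "chrom", "pos1", "chrom2", "pos2",
                 "population", "n_carriers", "pop_size", "fraction"],
    )
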