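"""LD-block construction, local breeding values per haplotype, in-silico
haplotype stacking, and haplo-pheno superior-haplotype mining with donors.

Since genotypes are unphased, haplotypes are read off accessions that are
homozygous (and called) at every marker of a block/region; heterozygous
accessions contribute no haplotype there. Local GEBVs apply raw allele
coding (0/1 per haplotype copy), so summing 2x the accession's own haplotype
values over all blocks reproduces its uncentered marker-effect score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, studentized_range

from cicerscan.core_io import MISSING, GenotypeMatrix
from cicerscan.prediction import MarkerEffects

logger = logging.getLogger("cicerscan.haplotypes")


@dataclass
class LDBlock:
    chrom: str
    marker_index: np.ndarray  # contiguous variant indices
    span: tuple[int, int]  # first/last member positions (1-based)
    haplotypes: dict[str, list[int]] = field(default_factory=dict)  # allele string -> carriers
    local_gebv: dict[str, float] = field(default_factory=dict)
    gebv_variance: float = np.nan


def build_ld_blocks(
    g: GenotypeMatrix,
    r2_min: float = 0.7,
    max_span: int = 500_000,
    marker_index: np.ndarray | None = None,
) -> list[LDBlock]:
    """Greedy contiguous chaining: extend a block while the adjacent-marker
    genotype r² is >= r2_min and the block span stays <= max_span. Every
    marker lands in exactly one block (singletons allowed)."""
    from cicerscan.core_io import genotype_r2

    idx = np.arange(g.n_variants) if marker_index is None else np.asarray(marker_index)
    chrom = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy()
    blocks: list[LDBlock] = []
    for c in pd.unique(chrom[idx]):
        members = idx[chrom[idx] == c]
        current = [members[0]]
        for j_prev, j in zip(members[:-1], members[1:]):
            r2 = genotype_r2(g.dosages[:, j_prev], g.dosages[:, j])
            within_span = pos[j] - pos[current[0]] <= max_span
            if np.isfinite(r2) and r2 >= r2_min and within_span:
                current.append(j)
            else:
                blocks.append(_new_block(c, current, pos))
                current = [j]
        blocks.append(_new_block(c, current, pos))
    return blocks


def _new_block(chrom, members, pos) -> LDBlock:
    arr = np.asarray(members)
    return LDBlock(chrom=str(chrom), marker_index=arr, span=(int(pos[arr[0]]), int(pos[arr[-1]])))


def _homozygous_haplotypes(g: GenotypeMatrix, marker_index: np.ndarray):
    """Haplotype strings (one '0'/'1' char per marker) for accessions
    homozygous and called at every marker; returns {hap: [sample indices]}."""
    d = g.dosages[:, marker_index]
    eligible = np.all((d == 0) | (d == 2), axis=1)
    catalogue: dict[str, list[int]] = {}
    for i in np.flatnonzero(eligible):
        hap = "".join("1" if x == 2 else "0" for x in d[i])
        catalogue.setdefault(hap, []).append(int(i))
    return catalogue


def local_gebvs(
    blocks: list[LDBlock],
    effects: MarkerEffects,
    g: GenotypeMatrix,
) -> list[LDBlock]:
    """Catalogue observed haplotypes per block and score them.

    local GEBV(h) = sum over block markers of beta_j * allele_j(h) with raw
    0/1 alleles. The per-block variance is over the catalogued haplotypes'
    values (unweighted). Blocks with no fully homozygous accession get an
    empty catalogue and a logged flag.
    """
    beta = np.asarray(effects.beta, dtype=float)
    if beta.size != g.n_variants:
        raise ValueError("effects do not cover the genotype matrix markers")
    for blk in blocks:
        catalogue = _homozygous_haplotypes(g, blk.marker_index)
        blk.haplotypes = catalogue
        if not catalogue:
            logger.info("block %s:%d-%d has no fully homozygous accession", blk.chrom, *blk.span)
            blk.local_gebv = {}
            blk.gebv_variance = np.nan
            continue
        b = beta[blk.marker_index]
        blk.local_gebv = {
            hap: float(np.dot(b, np.frombuffer(hap.encode(), dtype=np.uint8) - ord("0")))
            for hap in catalogue
        }
        vals = np.array(list(blk.local_gebv.values()))
        blk.gebv_variance = float(np.var(vals))
    return blocks


def accession_scores(effects: MarkerEffects, g: GenotypeMatrix) -> np.ndarray:
    """Uncentered marker score per accession over all markers (missing -> 0)."""
    d = g.dosages.astype(float)
    d[d == MISSING] = 0.0
    return d @ np.asarray(effects.beta, dtype=float)


def stack_haplotypes(
    blocks: list[LDBlock],
    effects: MarkerEffects,
    g: GenotypeMatrix,
) -> dict:
    """In-silico genotype stacking the best haplotype (homozygous) per block.

    Returns the stacked score, the best accession's score over the same
    markers, their ratio, and the fraction of blocks with a usable
    catalogue. Blocks with an empty catalogue are excluded with a warning.
    """
    usable = [b for b in blocks if b.local_gebv]
    n_skipped = len(blocks) - len(usable)
    if n_skipped:
        logger.warning("stack_haplotypes: %d blocks without catalogued haplotypes excluded", n_skipped)
    if not usable:
        raise ValueError("no block has a catalogued haplotype")
    covered = np.concatenate([b.marker_index for b in usable])
    stacked_total = float(sum(2.0 * max(b.local_gebv.values()) for b in usable))
    d = g.dosages[:, covered].astype(float)
    d[d == MISSING] = 0.0
    acc = d @ np.asarray(effects.beta, dtype=float)[covered]
    best_idx = int(np.argmax(acc))
    best = float(acc[best_idx])
    return {
        "stacked_value": stacked_total,
        "best_accession": str(g.samples["id"].iloc[best_idx]),
        "best_accession_value": best,
        "ratio": stacked_total / best if best != 0 else np.inf,
        "block_coverage": len(usable) / len(blocks),
        "accession_values": acc,
    }


# ---------------------------------------------------------------------------
# Duncan's multiple range test


def duncan_letters(means: np.ndarray, ns: np.ndarray, mse: float, df_error: int, alpha: float = 0.05) -> list[str]:
    """Compact letter display from Duncan's multiple range test.

    Means are compared with the studentized-range critical value at
    protection level (1-alpha)^(p-1) for means p ranks apart, using the
    harmonic mean of group sizes in the standard error.
    """
    k = means.size
    order = np.argsort(means)[::-1]  # descending
    sorted_means = means[order]
    n_h = k / np.sum(1.0 / ns)
    se = np.sqrt(mse / n_h)

    def significant(i: int, j: int) -> bool:
        # i < j in descending order; p = span in ranks
        p = j - i + 1
        q_crit = studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df_error)
        return (sorted_means[i] - sorted_means[j]) > q_crit * se

    # maximal non-significant ranges -> letters
    letters_sorted = ["" for _ in range(k)]
    letter_ord = 0
    i = 0
    covered_until = -1
    for i in range(k):
        j = i
        while j + 1 < k and not significant(i, j + 1):
            j += 1
        if j > covered_until or i == 0:
            ch = chr(ord("a") + letter_ord)
            letter_ord += 1
            for t in range(i, j + 1):
                letters_sorted[t] += ch
            covered_until = j
    out = ["" for _ in range(k)]
    for rank, orig in enumerate(order):
        out[orig] = letters_sorted[rank]
    return out


@dataclass
class HaploPhenoResult:
    region: str
    trait: str
    groups: pd.DataFrame  # haplotype, environment, mean, n, letters
    superior: str | None
    direction: str
    consistency: int
    n_environments: int
    is_superior_stable: bool
    donors: list[str] = field(default_factory=list)
    skipped_reason: str | None = None


def haplo_pheno_scan(
    g: GenotypeMatrix,
    regions: dict[str, np.ndarray],
    phenotypes: pd.DataFrame,
    trait: str,
    direction: str = "max",
    alpha: float = 0.05,
    min_group_size: int = 2,
    stability_fraction: float = 0.5,
) -> list[HaploPhenoResult]:
    """Superior-haplotype mining per region.

    Accessions are grouped by homozygous-call haplotype; groups carrying a
    single genotype are removed. Per environment, a one-way ANOVA across
    groups is followed by Duncan's multiple range test; the superior
    haplotype has the best mean in ``direction`` and shares no letter with
    the worst group. Stability requires superiority in more than
    ``stability_fraction`` of environments.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    ph = phenotypes[phenotypes["trait"] == trait]
    ids = g.samples["id"].to_numpy()
    results = []
    for region, marker_index in regions.items():
        catalogue = _homozygous_haplotypes(g, np.asarray(marker_index))
        catalogue = {h: c for h, c in catalogue.items() if len(c) >= min_group_size}
        if len(catalogue) < 2:
            results.append(HaploPhenoResult(region, trait, pd.DataFrame(), None, direction,
                                            0, 0, False, skipped_reason="fewer than 2 haplotype groups"))
            continue
        rows = []
        per_env_best: list[str | None] = []
        envs = sorted(ph["environment"].unique())
        for env in envs:
            sub = ph[ph["environment"] == env].set_index("accession")["value"]
            samples_values = {}
            for hap, carriers in catalogue.items():
                vals = sub.reindex(ids[carriers]).dropna().to_numpy()
                if vals.size >= min_group_size:
                    samples_values[hap] = vals
            if len(samples_values) < 2:
                per_env_best.append(None)
                continue
            haps = list(samples_values)
            arrays = [samples_values[h] for h in haps]
            means = np.array([a.mean() for a in arrays])
            ns = np.array([a.size for a in arrays])
            n_tot = int(ns.sum())
            df_err = n_tot - len(haps)
            if df_err < 1 or all(a.size < 2 for a in arrays):
                per_env_best.append(None)
                continue
            sse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
            mse = sse / df_err if df_err else np.nan
            anova_p = f_oneway(*arrays).pvalue if mse > 0 else np.nan
            letters = (
                duncan_letters(means, ns, mse, df_err, alpha)
                if mse > 0
                else ["a"] * len(haps)
            )
            best_i = int(np.argmax(means) if direction == "max" else np.argmin(means))
            worst_i = int(np.argmin(means) if direction == "max" else np.argmax(means))
            distinct = not (set(letters[best_i]) & set(letters[worst_i]))
            per_env_best.append(haps[best_i] if distinct else None)
            for i, h in enumerate(haps):
                rows.append((env, h, float(means[i]), int(ns[i]), letters[i], float(anova_p)))
        groups = pd.DataFrame(rows, columns=["environment", "haplotype", "mean", "n", "letters", "anova_p"])
        n_env = len(envs)
        superior, consistency = None, 0
        candidates = [b for b in per_env_best if b is not None]
        if candidates:
            counts = pd.Series(candidates).value_counts()
            superior = str(counts.index[0])
            consistency = int(counts.iloc[0])
        stable = superior is not None and consistency > stability_fraction * n_env
        donors = []
        if superior is not None:
            donors = [str(ids[i]) for i in catalogue[superior]]
        results.append(
            HaploPhenoResult(region, trait, groups, superior, direction, consistency,
                             n_env, stable, donors=donors)
        )
    return results


def identify_donors(
    result: HaploPhenoResult,
    g: GenotypeMatrix,
    regions: dict[str, np.ndarray],
    phenotypes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Accessions homozygous for the superior haplotype, annotated with
    germplasm group and sorted by trait mean (descending) when phenotypes
    are supplied."""
    if result.superior is None:
        raise ValueError("no superior haplotype in result")
    catalogue = _homozygous_haplotypes(g, np.asarray(regions[result.region]))
    carriers = catalogue.get(result.superior, [])
    ids = g.samples["id"].to_numpy()
    groups = g.samples["group"].to_numpy()
    df = pd.DataFrame({"id": ids[carriers], "group": groups[carriers]})
    if phenotypes is not None and not df.empty:
        tm = (
            phenotypes[phenotypes["trait"] == result.trait]
            .groupby("accession")["value"].mean()
        )
        df["trait_mean"] = tm.reindex(df["id"]).to_numpy()
        df = df.sort_values("trait_mean", ascending=False).reset_index(drop=True)
    return df
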