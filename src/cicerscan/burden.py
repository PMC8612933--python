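"""Allele polarization against an outgroup, deleterious-mutation
classification, per-sample burden counts and group comparison.

Burden counts derived-allele dosage by default (a homozygote contributes 2);
the per-site carrier mode is available for sensitivity analysis. The group
comparison uses a seeded label-permutation test on the mean difference,
distribution-free and appropriate for counting data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cicerscan.core_io import MISSING, GenotypeMatrix

logger = logging.getLogger("cicerscan.burden")


@dataclass
class BurdenParams:
    sift_max: float = 0.05          # strict: deleterious iff SIFT < sift_max
    gerp_min: float = 2.0           # strict: deleterious iff GERP > gerp_min
    constrained_gerp_min: float = 0.0  # fallback mask when no BED is given
    daf_fixed_min: float = 0.8      # strict: "fixed" subset iff DAF > this

    def __post_init__(self) -> None:
        if not 0.0 < self.sift_max < 1.0:
            raise ValueError("sift_max must be in (0, 1)")


def polarize(g: GenotypeMatrix, outgroup_alleles) -> pd.DataFrame:
    """Designate ancestral/derived alleles from an outgroup and compute DAF.

    The ancestral allele is the outgroup allele when it matches ref or alt;
    the derived allele is the other one. Variants whose outgroup allele is
    missing or matches neither are excluded (``usable`` False) with a logged
    count. DAF is the derived-allele frequency over non-missing calls.
    """
    out = pd.Series(outgroup_alleles).astype("object").to_numpy()
    if out.size != g.n_variants:
        raise ValueError("outgroup allele vector length mismatch")
    ref = g.variants["ref"].to_numpy()
    alt = g.variants["alt"].to_numpy()
    anc_is_ref = out == ref
    anc_is_alt = out == alt
    usable = anc_is_ref | anc_is_alt
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("polarize: %d variants excluded (outgroup allele not in {ref, alt})", n_excluded)
    p_alt = g.alt_freq()
    daf = np.where(anc_is_ref, p_alt, 1.0 - p_alt)
    daf = np.where(usable, daf, np.nan)
    return pd.DataFrame(
        {
            "variant_index": np.arange(g.n_variants),
            "ancestral": np.where(anc_is_ref, ref, np.where(anc_is_alt, alt, None)),
            "derived": np.where(anc_is_ref, alt, np.where(anc_is_alt, ref, None)),
            "derived_is_alt": anc_is_ref,
            "daf": daf,
            "usable": usable,
        }
    )


def _in_regions(variants: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Membership of 1-based variant positions in 0-based half-open regions."""
    mask = np.zeros(len(variants), dtype=bool)
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    for _, r in regions.iterrows():
        mask |= (chrom == r["chrom"]) & (pos > r["start"]) & (pos <= r["end"])
    return mask


def classify_deleterious(
    annotation: pd.DataFrame,
    polarized: pd.DataFrame,
    params: BurdenParams | None = None,
    constrained_regions: pd.DataFrame | None = None,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Conjunction classifier: nonsynonymous AND SIFT < sift_max AND
    GERP > gerp_min AND inside the constrained mask, plus a "fixed" subset
    with DAF > daf_fixed_min.

    The constrained mask is a BED-style frame; when absent, the per-variant
    condition GERP > constrained_gerp_min substitutes. Variants with missing
    SIFT/GERP or unusable polarization are excluded with a logged count.
    """
    params = params or BurdenParams()
    ann = annotation.set_index("variant_index")
    pol = polarized.set_index("variant_index")
    idx = ann.index.to_numpy()
    sift = ann["sift"].to_numpy(dtype=float)
    gerp = ann["gerp"].to_numpy(dtype=float)
    nonsyn = ann["nonsynonymous"].to_numpy(dtype=bool)
    have_scores = np.isfinite(sift) & np.isfinite(gerp)
    n_noscore = int((~have_scores).sum())
    if n_noscore:
        logger.info("classify_deleterious: %d variants lack SIFT/GERP, excluded", n_noscore)
    usable = pol.reindex(idx)["usable"].fillna(False).to_numpy(dtype=bool)
    daf = pol.reindex(idx)["daf"].to_numpy(dtype=float)

    if constrained_regions is not None:
        if variants is None:
            raise ValueError("variants table required with a constrained-region mask")
        constrained = _in_regions(variants.iloc[idx], constrained_regions)
    else:
        constrained = gerp > params.constrained_gerp_min

    deleterious = (
        have_scores
        & usable
        & nonsyn
        & (sift < params.sift_max)
        & (gerp > params.gerp_min)
        & constrained
    )
    fixed = deleterious & (np.nan_to_num(daf, nan=0.0) > params.daf_fixed_min)
    return pd.DataFrame(
        {
            "variant_index": idx,
            "deleterious": deleterious,
            "fixed": fixed,
            "daf": daf,
            "constrained": constrained,
        }
    )


def burden_per_sample(
    g: GenotypeMatrix,
    deleterious_index: np.ndarray,
    derived_is_alt: np.ndarray,
    mode: str = "alleles",
    normalize_by_called: bool = False,
) -> pd.DataFrame:
    """Per-sample derived deleterious burden.

    ``mode='alleles'`` sums derived-allele dosage (0/1/2); ``mode='sites'``
    counts carrier sites (presence). Missing genotypes contribute 0;
    ``normalize_by_called`` divides by the fraction of deleterious sites
    called in the sample.
    """
    deleterious_index = np.asarray(deleterious_index, dtype=np.int64)
    if deleterious_index.size == 0:
        raise ValueError("deleterious set is empty")
    d = g.dosages[:, deleterious_index].astype(np.int64)
    is_alt = np.asarray(derived_is_alt, dtype=bool)[deleterious_index]
    called = d != MISSING
    derived = np.where(is_alt[None, :], d, 2 - d)
    derived = np.where(called, derived, 0)
    if mode == "alleles":
        burden = derived.sum(axis=1).astype(float)
    elif mode == "sites":
        burden = (derived >= 1).sum(axis=1).astype(float)
    else:
        raise ValueError(f"unknown burden mode {mode!r}")
    if normalize_by_called:
        frac = called.mean(axis=1)
        burden = np.where(frac > 0, burden / frac, np.nan)
    return pd.DataFrame(
        {
            "id": g.samples["id"],
            "group": g.samples["group"],
            "population": g.samples["population"],
            "burden": burden,
        }
    )


def compare_burden(
    profiles: pd.DataFrame,
    group_a: str,
    group_b: str,
    n_perm: int = 10_000,
    seed: int = 0,
    group_col: str = "group",
) -> dict:
    """Percent burden difference of group A over group B with a two-sided
    label-permutation p-value of the mean difference."""
    a = profiles.loc[profiles[group_col] == group_a, "burden"].to_numpy(dtype=float)
    b = profiles.loc[profiles[group_col] == group_b, "burden"].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 samples")
    mean_a, mean_b = a.mean(), b.mean()
    obs = mean_a - mean_b
    if mean_b == 0:
        percent = np.nan
        logger.warning("compare_burden: group B mean is 0; percent difference undefined")
    else:
        percent = 100.0 * obs / mean_b
    pooled = np.concatenate([a, b])
    n_a = a.size
    rng = np.random.default_rng(seed)
    # vectorized permutation of group labels
    n_hit = 0
    block = 1000
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        perms = np.argsort(rng.random((k, pooled.size)), axis=1)[:, :n_a]
        perm_means_a = pooled[perms].mean(axis=1)
        perm_diff = perm_means_a - (pooled.sum() - pooled[perms].sum(axis=1)) / b.size
        n_hit += int(np.sum(np.abs(perm_diff) >= abs(obs) - 1e-12))
        done += k
    p = (1 + n_hit) / (n_perm + 1)
    return {
        "mean_a": float(mean_a),
        "mean_b": float(mean_b),
        "difference": float(obs),
        "percent_difference": float(percent),
        "p_value": float(p),
        "n_perm": int(n_perm),
    }
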