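"""Structured genotype / sweep / phenotype / annotation simulator.

Population structure follows the Balding–Nichols model: per site an ancestral
frequency p is drawn, and each population's frequency is drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F), giving E[F_ST] ~ F in closed form. Sweeps are
injected by collapsing a region onto a handful of founder haplotypes with
skewed frequencies, which produces the low-pi / high-F_ST / negative-D
signature a sweep caller must detect. All randomness flows from a single
numpy PCG64 generator seeded from the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cicerscan.core_io import MISSING, GenotypeMatrix

logger = logging.getLogger("cicerscan.simulate")


@dataclass
class PopulationSpec:
    label: str
    n_samples: int
    f: float  # Balding–Nichols drift parameter, in (0, 1)
    group: str = "landrace"
    market_type: str = "NA"

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"drift parameter F must be in (0, 1), got {self.f}")
        if self.n_samples < 1:
            raise ValueError("population must have at least one sample")


@dataclass
class SweepSpec:
    population: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_founders: int = 4
    major_weight: float = 0.94  # frequency of the dominant founder haplotype

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if not self.start < self.end:
            raise ValueError("sweep interval must be non-empty")


@dataclass
class TraitSpec:
    name: str
    n_qtl: int
    h2: float
    effect_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")


@dataclass
class DeleteriousSpec:
    frac_nonsyn: float = 0.3
    frac_deleterious: float = 0.3  # of nonsynonymous sites
    enriched_group: str | None = None
    enrichment: float = 1.0
    ref_derived_fraction: float = 0.0  # fraction of sites where ref is derived

    def __post_init__(self) -> None:
        for name in ("frac_nonsyn", "frac_deleterious", "ref_derived_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment <= 0:
            raise ValueError("enrichment factor must be positive")


@dataclass
class SimConfig:
    seed: int
    populations: list[PopulationSpec]
    chrom_lengths: dict[str, int]
    n_variants_per_chrom: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    inbred: bool = False  # draw fully homozygous genotypes (selfing species)
    sweeps: list[SweepSpec] = field(default_factory=list)
    traits: list[TraitSpec] = field(default_factory=list)
    environments: list[str] = field(default_factory=lambda: ["E1"])
    env_effect_sd: float = 1.0
    rho_ge: float = 1.0
    deleterious: DeleteriousSpec | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_ge <= 1.0:
            raise ValueError("rho_ge must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Simulation ground truth aligned with the emitted genotype/phenotype ids."""

    pop_f: dict[str, float] = field(default_factory=dict)
    sweeps: list[SweepSpec] = field(default_factory=list)
    qtl: pd.DataFrame | None = None  # variant index, trait, per-env effects
    tbv: pd.DataFrame | None = None  # accession, trait, environment, tbv
    deleterious_sites: np.ndarray | None = None  # variant indices
    ancestral_is_ref: np.ndarray | None = None


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw a structured multi-population diploid SNP panel."""
    rng = cfg.rng() if rng is None else rng
    var_rows = []
    for chrom, length in cfg.chrom_lengths.items():
        m = cfg.n_variants_per_chrom
        if m > length:
            raise ValueError(f"more variants than positions on {chrom}")
        pos = np.sort(rng.choice(length, size=m, replace=False)) + 1
        for p in pos:
            var_rows.append((chrom, int(p)))
    variants = pd.DataFrame(var_rows, columns=["chrom", "pos"])
    m_total = len(variants)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, m_total)]
    alt_offset = rng.integers(1, 4, m_total)
    alt = bases[(np.char.find("ACGT", ref) + alt_offset) % 4]
    variants["ref"] = ref
    variants["alt"] = alt

    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, m_total)

    sample_rows = []
    dosage_blocks = []
    truth = GroundTruth()
    for pop in cfg.populations:
        f = pop.f
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p_pop = rng.beta(a, b)
        if cfg.inbred:
            alleles = rng.random((pop.n_samples, m_total)) < p_pop
            block = (2 * alleles).astype(np.int8)
        else:
            block = rng.binomial(2, p_pop, size=(pop.n_samples, m_total)).astype(np.int8)
        dosage_blocks.append(block)
        for k in range(pop.n_samples):
            sample_rows.append(
                (f"{pop.label}_{k:04d}", pop.label, pop.group, pop.market_type)
            )
        truth.pop_f[pop.label] = f
    dosages = np.vstack(dosage_blocks)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING
    samples = pd.DataFrame(sample_rows, columns=["id", "population", "group", "market_type"])
    g = GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)
    return g, truth


def inject_sweep(
    g: GenotypeMatrix,
    truth: GroundTruth,
    sweep: SweepSpec,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Collapse a region of one population onto few founder haplotypes.

    Founder haplotypes are sampled from the population's existing genotype
    columns; haplotype frequencies are skewed (one dominant founder, the rest
    rare) so the swept region carries mostly low-frequency variants.
    """
    if sweep.chrom not in set(g.variants["chrom"]):
        raise ValueError(f"sweep chromosome {sweep.chrom!r} not in genotype matrix")
    chrom_pos = g.variants["pos"].to_numpy()
    in_region = (
        (g.variants["chrom"].to_numpy() == sweep.chrom)
        & (chrom_pos > sweep.start)
        & (chrom_pos <= sweep.end)
    )
    max_pos = chrom_pos[g.variants["chrom"].to_numpy() == sweep.chrom].max()
    if sweep.start >= max_pos:
        raise ValueError("sweep interval lies outside the simulated contig")
    var_idx = np.flatnonzero(in_region)
    samp_idx = g.population_index(sweep.population)
    if sweep.n_founders > 2 * samp_idx.size:
        raise ValueError("more founder haplotypes than population chromosomes")

    # founder haplotype alleles derived from existing columns
    sources = rng.choice(samp_idx, size=sweep.n_founders, replace=False)
    founders = np.empty((sweep.n_founders, var_idx.size), dtype=np.int8)
    for i, s in enumerate(sources):
        d = g.dosages[s, var_idx].astype(np.int16)
        allele = np.where(d == 2, 1, 0)
        het = d == 1
        allele = np.where(het, rng.integers(0, 2, var_idx.size), allele)
        founders[i] = np.where(d == MISSING, 0, allele)

    if sweep.n_founders == 1:
        weights = np.array([1.0])
    else:
        rest = (1.0 - sweep.major_weight) / (sweep.n_founders - 1)
        weights = np.full(sweep.n_founders, rest)
        weights[0] = sweep.major_weight
    draws = rng.choice(sweep.n_founders, size=(samp_idx.size, 2), p=weights)
    new = founders[draws[:, 0]] + founders[draws[:, 1]]
    dosages = g.dosages.copy()
    dosages[np.ix_(samp_idx, var_idx)] = new.astype(np.int8)
    g2 = GenotypeMatrix(dosages, g.variants.copy(), g.samples.copy())
    truth.sweeps.append(sweep)
    return g2, truth


def simulate_phenotypes(
    g: GenotypeMatrix,
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Additive multi-environment phenotypes with controlled h² and G×E.

    Per trait, ``n_qtl`` segregating sites get effects with cross-environment
    correlation ``rho_ge``; per environment, noise is scaled so the realized
    narrow-sense h² equals the target (h²=1 yields noise-free phenotypes).
    """
    rng = cfg.rng() if rng is None else rng
    if not cfg.traits:
        raise ValueError("no traits configured")
    envs = list(cfg.environments)
    n_env = len(envs)
    freqs = g.alt_freq()
    seg = np.flatnonzero((freqs > 0) & (freqs < 1))
    X = g.dosages.astype(float)
    miss = X == MISSING
    if miss.any():
        col_mean = np.where(np.isnan(freqs), 0.0, 2 * freqs)
        X = np.where(miss, col_mean[None, :], X)

    qtl_rows = []
    pheno_rows = []
    tbv_rows = []
    ids = g.samples["id"].to_numpy()
    env_means = rng.normal(0.0, cfg.env_effect_sd, n_env)
    for trait in cfg.traits:
        if trait.n_qtl < 1:
            raise ValueError(f"trait {trait.name}: h2 > 0 requires at least one QTL")
        if trait.n_qtl > seg.size:
            raise ValueError(f"trait {trait.name}: not enough segregating sites")
        qtl = np.sort(rng.choice(seg, trait.n_qtl, replace=False))
        common = rng.normal(0.0, trait.effect_sd, trait.n_qtl)
        rho = cfg.rho_ge
        betas = np.empty((n_env, trait.n_qtl))
        for e in range(n_env):
            own = rng.normal(0.0, trait.effect_sd, trait.n_qtl)
            betas[e] = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * own
        for e, env in enumerate(envs):
            tbv = X[:, qtl] @ betas[e]
            var_tbv = tbv.var()
            if var_tbv == 0:
                raise ValueError(f"trait {trait.name}: QTL carry no variance in {env}")
            if trait.h2 >= 1.0:
                noise = np.zeros_like(tbv)
            else:
                sd = np.sqrt(var_tbv * (1.0 - trait.h2) / trait.h2)
                noise = rng.normal(0.0, sd, tbv.size)
            values = env_means[e] + tbv + noise
            for i, acc in enumerate(ids):
                pheno_rows.append((acc, trait.name, env, values[i]))
                tbv_rows.append((acc, trait.name, env, tbv[i]))
        for q, b in zip(qtl, common):
            qtl_rows.append((int(q), trait.name, float(b)))
    pheno = pd.DataFrame(pheno_rows, columns=["accession", "trait", "environment", "value"])
    truth.tbv = pd.DataFrame(tbv_rows, columns=["accession", "trait", "environment", "tbv"])
    truth.qtl = pd.DataFrame(qtl_rows, columns=["variant_index", "trait", "common_effect"])
    return pheno, truth


def annotate_functional(
    g: GenotypeMatrix,
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GenotypeMatrix, GroundTruth]:
    """Emit SIFT/GERP/outgroup annotations with a known deleterious truth set.

    Deleterious sites get SIFT < 0.05 and GERP > 2; benign sites fail at
    least one threshold. When an enrichment factor != 1 is configured, the
    enriched group's genotypes at deleterious sites are re-drawn with the
    derived-allele frequency inflated by that factor, so burden comparisons
    have a planted signal. Returns (annotation table, updated genotypes,
    updated truth).
    """
    spec = cfg.deleterious or DeleteriousSpec()
    rng = cfg.rng() if rng is None else rng
    m = g.n_variants
    if m == 0:
        raise ValueError("empty genotype matrix")
    nonsyn = rng.random(m) < spec.frac_nonsyn
    deleterious = nonsyn & (rng.random(m) < spec.frac_deleterious)

    sift = np.where(
        deleterious, rng.uniform(0.0, 0.049, m), rng.uniform(0.05, 1.0, m)
    )
    gerp = np.where(deleterious, rng.uniform(2.01, 6.0, m), rng.uniform(-5.0, 2.0, m))
    ancestral_is_ref = rng.random(m) >= spec.ref_derived_fraction
    ref = g.variants["ref"].to_numpy()
    alt = g.variants["alt"].to_numpy()
    outgroup = np.where(ancestral_is_ref, ref, alt)

    dosages = g.dosages.copy()
    if spec.enriched_group is not None and spec.enrichment != 1.0:
        members = np.flatnonzero((g.samples["group"] == spec.enriched_group).to_numpy())
        if members.size == 0:
            raise ValueError(f"no samples in group {spec.enriched_group!r}")
        del_idx = np.flatnonzero(deleterious)
        p_alt = g.alt_freq()[del_idx]
        p_derived = np.where(ancestral_is_ref[del_idx], p_alt, 1.0 - p_alt)
        p_new = np.minimum(0.98, p_derived * spec.enrichment)
        derived_dos = rng.binomial(2, p_new, size=(members.size, del_idx.size))
        new_alt = np.where(
            ancestral_is_ref[del_idx][None, :], derived_dos, 2 - derived_dos
        ).astype(np.int8)
        dosages[np.ix_(members, del_idx)] = new_alt
    g2 = GenotypeMatrix(dosages, g.variants.copy(), g.samples.copy())

    ann = pd.DataFrame(
        {
            "variant_index": np.arange(m),
            "chrom": g.variants["chrom"],
            "pos": g.variants["pos"],
            "sift": sift,
            "gerp": gerp,
            "nonsynonymous": nonsyn,
            "outgroup_allele": outgroup,
        }
    )
    truth.deleterious_sites = np.flatnonzero(deleterious)
    truth.ancestral_is_ref = ancestral_is_ref
    return ann, g2, truth
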