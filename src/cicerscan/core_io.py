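"""Genotype/phenotype data model, VCF round-trip, variant filtering, windowing.

Coordinates are 0-based half-open internally; VCF and all reported tables use
1-based inclusive positions.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cicerscan.core_io")

#: dosage code for a missing diploid genotype
MISSING = -1

GERMPLASM_GROUPS = ("wild", "landrace", "breeding_line", "cultivar")
MARKET_TYPES = ("desi", "kabuli", "intermediate", "NA")


@dataclass
class FilterParams:
    """Variant-level filter thresholds.

    ``maf_min`` retains variants with MAF >= maf_min by default ("cut-off"
    semantics); set ``maf_strict`` for a strict ``>`` comparison.
    ``missing_max`` is a strict upper bound on the per-variant missing-call
    fraction. ``het_max`` (optional) retains variants whose observed
    heterozygous-call fraction is <= het_max. ``ld_prune`` is a
    (window_snps, step_snps, r2_threshold) triple; pruning greedily drops one
    variant of each pair with genotype r² above the threshold.
    """

    maf_min: float = 0.0
    maf_strict: bool = False
    missing_max: float = 1.0
    biallelic_only: bool = True
    het_max: float | None = None
    ld_prune: tuple[int, int, float] | None = None

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.het_max is not None and not 0.0 <= self.het_max <= 1.0:
            raise ValueError(f"het_max must be in [0, 1], got {self.het_max}")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP dosage matrix with variant/sample metadata.

    ``dosages`` holds alt-allele counts in {0, 1, 2} with :data:`MISSING`
    (-1) for no-calls, shaped (n_samples, n_variants). ``variants`` has
    columns chrom, pos (1-based), ref, alt; ``samples`` has columns id,
    population, group, market_type.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n_s, n_v = self.dosages.shape
        if len(self.samples) != n_s:
            raise ValueError("sample table length does not match dosage rows")
        if len(self.variants) != n_v:
            raise ValueError("variant table length does not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, missing}")
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in self.variants.columns:
                raise ValueError(f"variant table missing column {col!r}")
        if "id" not in self.samples.columns:
            raise ValueError("sample table missing column 'id'")
        for col, default in (
            ("population", "pop0"),
            ("group", "NA"),
            ("market_type", "NA"),
        ):
            if col not in self.samples.columns:
                self.samples = self.samples.assign(**{col: default})
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        # positions strictly increasing within each chromosome
        pos = self.variants["pos"].to_numpy()
        chrom = self.variants["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (np.diff(pos) <= 0)):
            raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def called_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def allele_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (non-missing allele count, alt allele count) per variant."""
        d = self.dosages if sample_idx is None else self.dosages[sample_idx]
        called = d != MISSING
        n = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        return n.astype(np.int64), alt.astype(np.int64)

    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        n, alt = self.allele_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    def het_fraction(self) -> np.ndarray:
        called = (self.dosages != MISSING).sum(axis=0)
        het = (self.dosages == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, het / np.maximum(called, 1), np.nan)

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index].copy(),
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=self.samples.copy(),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[index].copy(),
            variants=self.variants.copy(),
            samples=self.samples.iloc[index].reset_index(drop=True),
        )

    def population_index(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise ValueError(f"population {population!r} has no samples")
        return idx

    def attach_metadata(self, meta: pd.DataFrame) -> "GenotypeMatrix":
        """Merge a metadata table (keyed by ``id``) into the sample table."""
        merged = self.samples[["id"]].merge(meta, on="id", how="left")
        for col, default in (("population", "pop0"), ("group", "NA"), ("market_type", "NA")):
            if col not in merged.columns:
                merged[col] = default
            merged[col] = merged[col].fillna(default)
        return GenotypeMatrix(self.dosages.copy(), self.variants.copy(), merged)

    def contig_lengths(self) -> dict[str, int]:
        """Upper bounds on contig lengths inferred from the last variant."""
        return {
            str(c): int(g["pos"].max())
            for c, g in self.variants.groupby("chrom", sort=False)
        }


@dataclass(frozen=True)
class Window:
    """Half-open genomic window [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def pos1_start(self) -> int:
        return self.start + 1


def make_windows(
    contig_lengths: Mapping[str, int],
    size: int,
    step: int | None = None,
) -> list[Window]:
    """Tile each contig with windows of ``size`` bp.

    ``step=None`` (or ``step == size``) produces non-overlapping windows,
    ceil(L/size) per contig. A smaller step produces a sliding scheme with
    floor((L-size)/step)+1 full windows; a single trailing partial window is
    emitted (flagged) when the last full window does not already reach the
    contig end.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if step is None:
        step = size
    if step <= 0:
        raise ValueError("window step must be positive")
    if step > size:
        raise ValueError(f"step ({step}) must not exceed window size ({size})")
    out: list[Window] = []
    for chrom, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {chrom!r} has non-positive length {length}")
        if step == size:  # non-overlapping
            for start in range(0, length, size):
                end = min(start + size, length)
                out.append(Window(str(chrom), start, end, partial=end - start < size))
        else:
            if length < size:
                out.append(Window(str(chrom), 0, length, partial=True))
                continue
            n_full = (length - size) // step + 1
            for k in range(n_full):
                out.append(Window(str(chrom), k * step, k * step + size))
            last_full = (n_full - 1) * step
            if last_full + size < length:
                out.append(Window(str(chrom), last_full + step, length, partial=True))
    return out


# ---------------------------------------------------------------------------
# VCF I/O


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_vcf(path, params: FilterParams | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained (drops are counted and logged).
    Diploid GT is mapped to alt-allele dosage; half-missing or unknown calls
    become :data:`MISSING`. ``params`` (optional) is applied via
    :func:`filter_variants` after loading.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"VCF {path} contains no samples")

    rows = []
    dosage_rows = []
    n_dropped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or not rec.is_snp or rec.is_indel:
            n_dropped += 1
            continue
        # decode allele indices directly so half-missing calls (./1) are
        # treated as missing, not as het
        alleles = np.asarray([gt[:2] for gt in rec.genotypes], dtype=np.int8)
        gt = alleles.sum(axis=1)
        gt[(alleles < 0).any(axis=1)] = MISSING
        dosage_rows.append(gt.astype(np.int8))
        rows.append((rec.CHROM, rec.POS, rec.REF, alts[0]))
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic/non-SNP records", n_dropped)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    if dosage_rows:
        dosages = np.vstack(dosage_rows).T
    else:
        dosages = np.zeros((len(sample_ids), 0), dtype=np.int8)
    g = GenotypeMatrix(
        dosages=dosages,
        variants=variants,
        samples=pd.DataFrame({"id": sample_ids}),
    )
    if params is not None:
        g = filter_variants(g, params)
    return g


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 (GT only) that round-trips through read_vcf."""
    if contig_lengths is None:
        contig_lengths = g.contig_lengths()
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cicerscan\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        cols += [str(s) for s in g.samples["id"]]
        fh.write("\t".join(cols) + "\n")
        variants = g.variants
        for j in range(g.n_variants):
            row = variants.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(d)] for d in g.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Filtering


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    sx = xs.std()
    sy = ys.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _ld_prune_pass(g: GenotypeMatrix, window: int, step: int, r2_max: float) -> np.ndarray:
    """One greedy pruning pass; returns a keep mask."""
    keep = np.ones(g.n_variants, dtype=bool)
    chrom = g.variants["chrom"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < idx.size:
            win = [i for i in idx[start : start + window] if keep[i]]
            for a in range(len(win)):
                if not keep[win[a]]:
                    continue
                for b in range(a + 1, len(win)):
                    if not keep[win[b]]:
                        continue
                    r2 = genotype_r2(g.dosages[:, win[a]], g.dosages[:, win[b]])
                    if np.isfinite(r2) and r2 > r2_max:
                        keep[win[b]] = False
            start += step
    return keep


def filter_variants(g: GenotypeMatrix, params: FilterParams) -> GenotypeMatrix:
    """Apply MAF / missingness / heterozygosity / LD-pruning filters.

    MAF is computed on non-missing alleles. LD pruning iterates greedy passes
    to a fixed point so the operation is idempotent.
    """
    if g.n_variants == 0:
        logger.warning("filter_variants: empty input matrix")
        return g
    keep = np.ones(g.n_variants, dtype=bool)
    maf = g.maf()
    if params.maf_strict:
        keep &= np.nan_to_num(maf, nan=-1.0) > params.maf_min
    else:
        keep &= np.nan_to_num(maf, nan=-1.0) >= params.maf_min
    keep &= g.missing_fraction() < params.missing_max
    if params.het_max is not None:
        keep &= np.nan_to_num(g.het_fraction(), nan=2.0) <= params.het_max
    out = g.take_variants(keep)
    if params.ld_prune is not None and out.n_variants > 1:
        window, step, r2_max = params.ld_prune
        while True:
            mask = _ld_prune_pass(out, int(window), int(step), float(r2_max))
            if mask.all():
                break
            out = out.take_variants(mask)
    if out.n_variants == 0:
        logger.warning("filter_variants: all variants removed")
    return out


# ---------------------------------------------------------------------------
# Phenotypes and tables


def read_phenotypes(path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format phenotype table (accession, trait, environment, value).

    Non-numeric values are coerced to missing with a warning; duplicate
    (accession, trait, environment) keys raise.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = {"accession", "trait", "environment", "value"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"phenotype table missing columns: {sorted(missing_cols)}")
    coerced = pd.to_numeric(df["value"], errors="coerce")
    n_bad = int((coerced.isna() & df["value"].notna() & (df["value"].astype(str).str.upper() != "NA")).sum())
    if n_bad:
        logger.warning("read_phenotypes: %d non-numeric values coerced to missing", n_bad)
    df = df.assign(value=coerced)
    key = ["accession", "trait", "environment"]
    dup = df.duplicated(key, keep=False)
    if dup.any():
        dups = df.loc[dup, key].drop_duplicates().to_records(index=False).tolist()
        raise ValueError(f"duplicate phenotype keys: {dups[:10]}")
    return df


def read_sample_metadata(path, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if "id" not in df.columns:
        raise ValueError("sample metadata must have an 'id' column")
    return df


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into (chrom, start, end [, name]); 0-based half-open."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            rows.append(
                (parts[0], int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else ".")
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        for _, row in df.iterrows():
            name = row["name"] if "name" in df.columns else "."
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{name}\n")
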