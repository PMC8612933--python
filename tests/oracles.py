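"""Independent brute-force oracles used only by the test suite.

These are direct transcriptions of the published statistics, written without
reference to the package implementation: pairwise-difference pi, Watterson's
theta, Tajima's D, Weir & Cockerham (1984) variance components for r
populations, and genotype r². They are intentionally slow and simple.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISS = -1


def site_alleles(dosages_1site):
    """Diploid dosage codes -> explicit allele list (skipping missing)."""
    alleles = []
    for d in dosages_1site:
        if d == MISS:
            continue
        alleles.extend({0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(d)])
    return alleles


def pi_site_pairwise(dosages_1site) -> float:
    """Average pairwise difference over all allele pairs at one site."""
    alleles = site_alleles(dosages_1site)
    n = len(alleles)
    if n < 2:
        return 0.0
    diffs = sum(1 for a, b in itertools.combinations(alleles, 2) if a != b)
    return diffs / math.comb(n, 2)


def pi_window(dosage_block) -> float:
    """Sum of per-site pairwise diversity over a site x sample block
    (samples in rows)."""
    return sum(pi_site_pairwise(col) for col in np.asarray(dosage_block).T)


def harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(s: int, n_seq: int) -> float:
    """Watterson estimator (total, not per-bp)."""
    return s / harmonic(n_seq)


def tajima_d(dosage_block) -> float:
    """Tajima's D from the 1989 formulas for a complete-call diploid block."""
    block = np.asarray(dosage_block)
    assert not (block == MISS).any(), "oracle assumes complete calls"
    n = 2 * block.shape[0]
    freqs = block.sum(axis=0) / n
    seg = (freqs > 0) & (freqs < 1)
    s = int(seg.sum())
    if s == 0:
        return float("nan")
    pi_hat = pi_window(block)
    a1 = harmonic(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_hat - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def wc_fst_components(pop_blocks) -> tuple[float, float]:
    """Weir & Cockerham 1984 theta-hat components summed over sites.

    pop_blocks: list of (samples x sites) dosage arrays, one per population.
    Returns (sum of a, sum of a+b+c) over usable sites (>=2 called
    individuals in every population).
    """
    r = len(pop_blocks)
    n_sites = pop_blocks[0].shape[1]
    total_a = 0.0
    total_abc = 0.0
    for j in range(n_sites):
        ns, ps, hs = [], [], []
        ok = True
        for block in pop_blocks:
            col = np.asarray(block)[:, j]
            called = col[col != MISS]
            if called.size < 2:
                ok = False
                break
            ns.append(called.size)
            ps.append(called.sum() / (2 * called.size))
            hs.append(np.mean(called == 1))
        if not ok:
            continue
        nbar = sum(ns) / r
        nc = (r * nbar - sum(x * x for x in ns) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        total_a += a
        total_abc += a + b + c
    return total_a, total_abc


def genotype_r2_bruteforce(x, y) -> float:
    """Squared Pearson correlation over complete pairs, from first principles."""
    pairs = [(a, b) for a, b in zip(x, y) if a != MISS and b != MISS]
    n = len(pairs)
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx, my = sum(xs) / n, sum(ys) / n
    cov = sum((a - mx) * (b - my) for a, b in pairs) / n
    vx = sum((a - mx) ** 2 for a in xs) / n
    vy = sum((b - my) ** 2 for b in ys) / n
    if vx == 0 or vy == 0:
        return float("nan")
    return cov * cov / (vx * vy)
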