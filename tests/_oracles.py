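"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's own algorithms: EHH by exhaustive
pair enumeration, Weir-Cockerham theta by a direct per-locus transcription
of the variance-components definitions, r^2 by haplotype-frequency counting.
"""

from itertools import combinations

import numpy as np

MISSING = -1


def ehh_enumeration(haps: np.ndarray, core: int, target: int,
                    allele: int | None = None) -> float:
    """EHH by checking every unordered haplotype pair over the span."""
    lo, hi = sorted((core, target))
    rows = []
    for r in range(haps.shape[0]):
        span = haps[r, lo:hi + 1]
        if (span == MISSING).any():
            continue
        if allele is not None and haps[r, core] != allele:
            continue
        rows.append(tuple(span))
    if len(rows) < 2:
        return np.nan
    same = sum(1 for a, b in combinations(rows, 2) if a == b)
    return same / (len(rows) * (len(rows) - 1) / 2)


def wc_theta(pop_genotypes: list[np.ndarray]) -> float:
    """Multi-locus Weir-Cockerham theta from per-population genotype
    matrices (individuals x loci, dosages 0/1/2 of allele 2).

    Written as an explicit per-locus loop over the 1984 definitions,
    independently of the package's vectorised bookkeeping.
    """
    r = len(pop_genotypes)
    sum_a = 0.0
    sum_abc = 0.0
    n_loci = pop_genotypes[0].shape[1]
    for locus in range(n_loci):
        n = []
        p = []
        h = []
        for g in pop_genotypes:
            dos = g[:, locus]
            n.append(len(dos))
            p.append(dos.mean() / 2.0)
            h.append(np.mean(dos == 1))
        n = np.array(n, float)
        p = np.array(p, float)
        h = np.array(h, float)
        nbar = n.mean()
        pbar = float((n * p).sum() / n.sum())
        if pbar in (0.0, 1.0):
            continue
        nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
        s2 = float((n * (p - pbar) ** 2).sum() / ((r - 1) * nbar))
        hbar = float((n * h).sum() / n.sum())
        a = (nbar / nc) * (s2 - 1.0 / (nbar - 1)
                           * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


def r2_counting(haps: np.ndarray, i: int, j: int) -> float:
    """r^2 from explicit two-locus haplotype counts."""
    a = haps[:, i]
    b = haps[:, j]
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    n = len(a)
    p_ab = np.mean((a == 1) & (b == 1))
    p_a = np.mean(a == 1)
    p_b = np.mean(b == 1)
    d = p_ab - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
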