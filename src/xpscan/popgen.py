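"""Population-genetic summaries: Weir-Cockerham F_ST, PCA, LD and Ne-from-LD.

Effective population size is recovered from the decay of linkage
disequilibrium with genetic distance: pairwise r^2 values are grouped in
50-kb physical-distance bins from 975 kb to 10,025 kb (bin midpoints 1-10 Mb,
i.e. c = 0.01-0.10 Morgan under the 1 cM/Mb proxy) and each bin's mean
E(r^2) yields

    Ne = ( 1/E(r^2) - 1/(n-1) - 1 ) / (4c),      n = 2 x analysed animals,

an estimate referring to 1/(2c) generations ago — 50 generations for the
1 Mb bin down to 5 for the 10 Mb bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GENO_MISSING, MISSING, MORGAN_PER_BP, BreedPanel, PanelError


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    breed_a: str
    breed_b: str
    theta: float
    n_loci: int


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray
                   ) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one bi-allelic locus, r populations.

    n: sample sizes (individuals), p: allele frequencies, h: observed
    heterozygote proportions.
    """
    r = len(n)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def wc_fst(panel: BreedPanel, breed_a: str, breed_b: str) -> FstResult:
    """Multi-locus Weir-Cockerham theta: ratio of summed a over summed a+b+c.

    Loci monomorphic in the pooled pair (or without calls in either breed)
    are skipped.
    """
    sums = np.zeros(2)
    n_used = 0
    ga = panel.subset(individuals=panel.individuals_of(breed_a)).to_genotypes()
    gb = panel.subset(individuals=panel.individuals_of(breed_b)).to_genotypes()
    for j in range(panel.n_markers):
        ca = ga.codes[:, j]
        cb = gb.codes[:, j]
        ca = ca[ca != GENO_MISSING]
        cb = cb[cb != GENO_MISSING]
        if len(ca) < 2 or len(cb) < 2:
            continue
        n = np.array([len(ca), len(cb)], dtype=float)
        p = np.array([(ca + 1).mean() / 2.0, (cb + 1).mean() / 2.0])
        pooled = (n * p).sum() / n.sum()
        if pooled in (0.0, 1.0):
            continue
        h = np.array([(ca == 0).mean(), (cb == 0).mean()])
        a, b, c = _wc_components(n, p, h)
        sums += (a, a + b + c)
        n_used += 1
    if n_used == 0 or sums[1] == 0:
        raise PanelError(f"no polymorphic locus in pooled pair {breed_a}/{breed_b}")
    return FstResult(breed_a, breed_b, float(sums[0] / sums[1]), n_used)


def fst_matrix(panel: BreedPanel) -> pd.DataFrame:
    """Full pairwise theta matrix with a 'Mean' row (mean over the partners)."""
    breeds = panel.breeds()
    mat = pd.DataFrame(np.nan, index=breeds + ["Mean"], columns=breeds)
    for i, a in enumerate(breeds):
        for b in breeds[i + 1:]:
            th = wc_fst(panel, a, b).theta
            mat.loc[a, b] = th
            mat.loc[b, a] = th
    for b in breeds:
        mat.loc["Mean", b] = mat.loc[breeds, b].mean()
    return mat


# ---------------------------------------------------------------------------
# PCA on -1/0/1 genotype codes
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame       # individuals x components
    importance: np.ndarray     # share of variance per component


def pca(panel: BreedPanel, n_components: int = 10) -> PcaResult:
    """PCA of mean-centered -1/0/1 genotype codes (missing set to column mean)."""
    geno = panel.to_genotypes()
    x = geno.codes.astype(float)
    x[geno.codes == GENO_MISSING] = np.nan
    if np.isnan(x).all(axis=0).any():
        raise PanelError("PCA input contains an all-missing marker column")
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    x -= x.mean(axis=0)
    rank = np.linalg.matrix_rank(x)
    if n_components > min(x.shape):
        raise PanelError(f"requested {n_components} components exceeds rank {rank}")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    importance = var / var.sum()
    scores = u * s
    k = n_components
    return PcaResult(
        pd.DataFrame(scores[:, :k], index=geno.individual_ids,
                     columns=[f"PC{i + 1}" for i in range(k)]),
        importance[:k])


# ---------------------------------------------------------------------------
# LD and Ne
# ---------------------------------------------------------------------------

def pairwise_r2(haplotypes: np.ndarray, i: int, j: int) -> float:
    """Squared allelic correlation r^2 between two markers from phased
    haplotype frequencies: D^2 / (pA qA pB qB). nan when either marker is
    monomorphic among the jointly called haplotypes."""
    a = haplotypes[:, i]
    b = haplotypes[:, j]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if len(a) < 2:
        return np.nan
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


@dataclass
class LdBinSeries:
    """Binned LD decay and per-bin Ne for one breed."""

    breed: str
    n: int                 # 2 x analysed animals
    table: pd.DataFrame    # midpoint_bp, c_morgan, e_r2, n_pairs, ne, generations_ago

    @property
    def ne5(self) -> float:
        """Ne at the 10,000 kb bin midpoint (5 generations ago)."""
        return float(self.table.loc[self.table["midpoint_bp"] == 10_000_000, "ne"].iloc[0])

    @property
    def ne50(self) -> float:
        """Ne at the 1,000 kb bin midpoint (50 generations ago)."""
        return float(self.table.loc[self.table["midpoint_bp"] == 1_000_000, "ne"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def ld_bins(bin_start_bp: int = 975_000, bin_stop_bp: int = 10_025_000,
            bin_width_bp: int = 50_000) -> pd.DataFrame:
    """Distance-bin scaffold: edges, midpoints, c (Morgan) and 1/(2c) index."""
    lo = np.arange(bin_start_bp, bin_stop_bp, bin_width_bp)
    mid = lo + bin_width_bp // 2
    c = mid * MORGAN_PER_BP
    return pd.DataFrame({"lower_bp": lo, "upper_bp": lo + bin_width_bp,
                         "midpoint_bp": mid, "c_morgan": c,
                         "generations_ago": 1.0 / (2.0 * c)})


def ne_estimate(e_r2: float, n: int, c_morgan: float) -> float:
    """Ne from one bin's mean r^2: (1/E(r^2) - 1/(n-1) - 1) / (4c)."""
    return (1.0 / e_r2 - 1.0 / (n - 1) - 1.0) / (4.0 * c_morgan)


def ne_from_ld(panel: BreedPanel, breed: str, maf_min: float = 0.10,
               bin_start_bp: int = 975_000, bin_stop_bp: int = 10_025_000,
               bin_width_bp: int = 50_000) -> LdBinSeries:
    """Binned E(r^2) and Ne for one breed.

    Markers with within-breed MAF below ``maf_min`` (or monomorphic) are
    excluded; pairs are formed within chromosomes with physical distance in
    [bin_start_bp, bin_stop_bp), assigned to half-open 50-kb bins. Empty
    bins report nan Ne.
    """
    haps = panel.breed_haplotypes(breed).astype(float)
    haps[haps == MISSING] = np.nan
    bins = ld_bins(bin_start_bp, bin_stop_bp, bin_width_bp)
    nbins = len(bins)
    sum_r2 = np.zeros(nbins)
    n_pairs = np.zeros(nbins, dtype=int)
    mm = panel.markers
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(haps, axis=0)
    maf = np.minimum(p, 1 - p)
    usable = np.isfinite(maf) & (maf >= maf_min)
    for chrom in mm.chromosomes():
        sl = mm.chrom_slice(chrom)
        cols = np.flatnonzero(usable[sl]) + sl.start
        if len(cols) < 2:
            continue
        x = haps[:, cols]
        pos = mm.position_bp[cols].astype(np.int64)
        # r^2 between 0/1 columns is the squared Pearson correlation
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.corrcoef(x, rowvar=False)
        r2 = r * r
        ii, jj = np.triu_indices(len(cols), k=1)
        dist = pos[jj] - pos[ii]
        inside = (dist >= bin_start_bp) & (dist < bin_stop_bp)
        if not inside.any():
            continue
        b = ((dist[inside] - bin_start_bp) // bin_width_bp).astype(int)
        vals = r2[ii[inside], jj[inside]]
        ok = np.isfinite(vals)
        np.add.at(sum_r2, b[ok], vals[ok])
        np.add.at(n_pairs, b[ok], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_r2 = np.where(n_pairs > 0, sum_r2 / np.maximum(n_pairs, 1), np.nan)
    n = 2 * len(panel.individuals_of(breed))
    c = bins["c_morgan"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ne = (1.0 / e_r2 - 1.0 / (n - 1) - 1.0) / (4.0 * c)
    table = bins.assign(e_r2=e_r2, n_pairs=n_pairs, ne=ne)
    return LdBinSeries(breed, n, table)


# ---------------------------------------------------------------------------
# correlations between breed-level series
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    table: pd.DataFrame  # series_x, series_y, r, p, n

    def r(self, x: str, y: str) -> float:
        sub = self.table[(self.table["series_x"] == x) & (self.table["series_y"] == y)]
        return float(sub["r"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def correlation_report(summary: pd.DataFrame,
                       x_series: list[str] | None = None,
                       y_series: list[str] | None = None) -> CorrelationReport:
    """Pearson correlations (two-sided p, t transform with n-2 df) between
    breed-level series of a summary table (breeds as columns or index)."""
    if x_series is None or y_series is None:
        raise PanelError("specify the series to correlate")
    rows = []
    for xs in x_series:
        for ys in y_series:
            x = summary.loc[xs].astype(float)
            y = summary.loc[ys].astype(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                raise PanelError(f"need >= 3 breeds for correlation {xs} vs {ys}")
            if x[ok].std() == 0 or y[ok].std() == 0:
                raise PanelError(f"constant series in correlation {xs} vs {ys}")
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"series_x": xs, "series_y": ys, "r": r, "p": p,
                         "n": int(ok.sum())})
    return CorrelationReport(pd.DataFrame(rows))
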