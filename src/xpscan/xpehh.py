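"""Extended haplotype homozygosity (EHH) and cross-population XP-EHH.

EHH at a target marker is the probability that two randomly chosen
haplotypes are identical over the whole interval from the core SNP to that
marker. For the cross-population statistic the EHH curve is computed within
each population over all of its haplotypes (pairs implicitly share the core
allele by being identical at the core), integrated against genetic distance
(trapezoids; 1 cM/Mb physical proxy), and the raw score is the natural log
of the ratio of the two integrals:

    XP-EHH = ln( I_case / I_control )

Positive values mean unusually long haplotype homozygosity in the case
population. The curve is extended marker by marker on each side of the core
until the EHH of the COMBINED (case + control) sample drops below a stop
cutoff (default 0.05) or the chromosome ends; the marker where the stop
fires still contributes its trapezoid. Raw scores of one ordered comparison
are then standardized genome-wide to zero mean and unit (population)
variance (sXPEHH).

Haplotypes with missing alleles are dropped from the pair counts only for
the spans where they are missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, MORGAN_PER_BP, BreedPanel, PanelError


@dataclass
class EhhCurve:
    """One side of an EHH curve around a core SNP."""

    core_index: int
    direction: str  # "left" or "right"
    marker_indices: np.ndarray
    ehh: np.ndarray
    gdist: np.ndarray  # Morgan from core, non-negative increasing


@dataclass
class ComparisonScores:
    """Per-core-SNP XP-EHH scores for one ordered (case, control) comparison."""

    case: str
    control: str
    table: pd.DataFrame  # marker_id, chrom, pos_bp, i_case, i_control, raw, sxpehh

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _pair_hom(ids: np.ndarray) -> float:
    """Fraction of unordered pairs with equal group id; nan when < 2 items."""
    n = len(ids)
    if n < 2:
        return np.nan
    _, counts = np.unique(ids, return_counts=True)
    same = (counts * (counts - 1) // 2).sum()
    return same / (n * (n - 1) / 2)


def ehh_at(haplotypes: np.ndarray, core_index: int, target_index: int,
           condition_on_allele: int | None = None) -> float:
    """EHH between core and target (inclusive), by exhaustive span comparison.

    In population mode (``condition_on_allele is None``) all haplotypes are
    considered and a pair counts when identical at every marker of the span.
    In allele mode only carriers of the stated core allele are considered.
    Haplotypes with missing data anywhere in the span are excluded. Returns
    nan (undefined, distinct from 0) when fewer than two haplotypes remain.
    """
    lo, hi = sorted((core_index, target_index))
    span = haplotypes[:, lo:hi + 1]
    keep = ~(span == MISSING).any(axis=1)
    if condition_on_allele is not None:
        keep &= haplotypes[:, core_index] == condition_on_allele
    span = span[keep]
    if span.shape[0] < 2:
        return np.nan
    _, ids = np.unique(span, axis=0, return_inverse=True)
    return _pair_hom(ids)


def ehh_curve(haplotypes: np.ndarray, core_index: int, direction: str,
              markers, condition_on_allele: int | None = None) -> EhhCurve:
    """One flank's EHH curve (utility; the scorer integrates on the fly)."""
    sl = markers.chrom_slice(markers.chromosome[core_index])
    if direction == "left":
        targets = list(range(core_index, sl.start - 1, -1))
    elif direction == "right":
        targets = list(range(core_index, sl.stop))
    else:
        raise PanelError("direction must be 'left' or 'right'")
    vals = [ehh_at(haplotypes, core_index, t, condition_on_allele)
            for t in targets]
    gpos = markers.genetic_pos
    dists = np.array([abs(gpos[t] - gpos[core_index]) for t in targets])
    return EhhCurve(core_index, direction, np.array(targets), np.array(vals),
                    dists)


def _hom_from_counts(counts: np.ndarray, n: int) -> float:
    """Pair homozygosity from per-group counts; nan when n < 2."""
    if n < 2:
        return np.nan
    return float((counts * (counts - 1)).sum()) / (n * (n - 1))


def _side_walk(case_rows: np.ndarray, ctrl_rows: np.ndarray, haps: np.ndarray,
               gpos: np.ndarray, core: int, lo: int, hi: int, step: int,
               stop_ehh: float, max_gap_bp: float | None,
               pos_bp: np.ndarray) -> tuple[float, float]:
    """Walk one flank; returns (case integral, control integral) in Morgan.

    ``haps`` holds the pooled case+control haplotypes; ``case_rows`` /
    ``ctrl_rows`` are boolean masks into its rows. The partition by identity
    over the growing span is shared (refined with bincount relabelling), so
    the combined-sample stop rule and the two population curves stay
    consistent.
    """
    col = haps[:, core]
    alive = col != MISSING
    ids = col[alive].astype(np.intp)
    is_case = case_rows[alive]
    is_ctrl = ctrl_rows[alive]

    disjoint = not bool((case_rows & ctrl_rows).any())

    def _homs(ids, is_case, is_ctrl):
        k = int(ids.max()) + 1 if len(ids) else 1
        all_counts = np.bincount(ids, minlength=k)
        case_counts = np.bincount(ids[is_case], minlength=k)
        e_case = _hom_from_counts(case_counts, int(is_case.sum()))
        if disjoint:
            ctrl_counts = all_counts - case_counts
        else:
            ctrl_counts = np.bincount(ids[is_ctrl], minlength=k)
        e_ctrl = _hom_from_counts(ctrl_counts, int(is_ctrl.sum()))
        e_all = _hom_from_counts(all_counts, len(ids))
        return e_case, e_ctrl, e_all

    e_case, e_ctrl, _ = _homs(ids, is_case, is_ctrl)
    i_case = i_ctrl = 0.0
    d_prev = 0.0
    j = core
    while True:
        j += step
        if j < lo or j >= hi:
            break
        if max_gap_bp is not None and abs(pos_bp[j] - pos_bp[j - step]) > max_gap_bp:
            break
        col = haps[:, j][alive]
        ok = col != MISSING
        if not ok.all():
            alive_idx = np.flatnonzero(alive)
            alive[alive_idx[~ok]] = False
            ids, is_case, is_ctrl, col = ids[ok], is_case[ok], is_ctrl[ok], col[ok]
        codes = ids * 2 + col
        counts = np.bincount(codes)
        remap = np.cumsum(counts > 0) - 1
        ids = remap[codes]
        ec, et, ea = _homs(ids, is_case, is_ctrl)
        d = abs(gpos[j] - gpos[core])
        if np.isfinite(ec) and np.isfinite(e_case):
            i_case += (d - d_prev) * (e_case + ec) / 2.0
        if np.isfinite(et) and np.isfinite(e_ctrl):
            i_ctrl += (d - d_prev) * (e_ctrl + et) / 2.0
        e_case, e_ctrl, d_prev = ec, et, d
        if not np.isfinite(ea) or ea < stop_ehh:
            break
    return i_case, i_ctrl


def integrate_ehh(pop_haplotypes: np.ndarray, combined_haplotypes: np.ndarray,
                  core_index: int, markers, stop_ehh: float = 0.05,
                  max_gap_bp: float | None = None) -> float:
    """Integrated EHH (Morgan) of one population around a core SNP.

    The population EHH curve is integrated by trapezoids over genetic
    distance, marker by marker left and right of the core; a side stops when
    the combined-sample EHH falls below ``stop_ehh`` (that marker's trapezoid
    is still included) or at the chromosome end.

    ``combined_haplotypes`` must contain ``pop_haplotypes`` as its leading
    rows (the usual pooled layout); they define the stop rule only.
    """
    n_pop = pop_haplotypes.shape[0]
    pooled = combined_haplotypes
    case_rows = np.zeros(pooled.shape[0], dtype=bool)
    case_rows[:n_pop] = True
    all_rows = np.ones(pooled.shape[0], dtype=bool)
    if len(np.unique(pooled[pooled[:, core_index] != MISSING, core_index])) < 2:
        raise PanelError("core SNP must segregate in the combined sample")
    sl = markers.chrom_slice(markers.chromosome[core_index])
    gpos = markers.genetic_pos
    pos = markers.position_bp
    il_case, _ = _side_walk(case_rows, all_rows, pooled, gpos, core_index,
                            sl.start, sl.stop, -1, stop_ehh, max_gap_bp, pos)
    ir_case, _ = _side_walk(case_rows, all_rows, pooled, gpos, core_index,
                            sl.start, sl.stop, +1, stop_ehh, max_gap_bp, pos)
    return il_case + ir_case


def xpehh_raw(i_case: float, i_control: float) -> float:
    """ln(I_case / I_control); nan (missing) when either integral is not > 0."""
    if not (i_case > 0 and i_control > 0):
        return np.nan
    return float(np.log(i_case / i_control))


def standardize(raw_scores: np.ndarray) -> np.ndarray:
    """Standardize one comparison's raw scores to mean 0, population variance 1.

    Missing (nan) scores are carried through; the mean and SD are taken over
    all scored SNPs genome-wide.
    """
    x = np.asarray(raw_scores, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise PanelError("need >= 2 scored SNPs to standardize")
    mu = x[ok].mean()
    sd = x[ok].std()  # population (divide-by-N) SD
    if sd == 0:
        raise PanelError("cannot standardize scores with zero spread")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - mu) / sd
    return out


try:  # numba accelerates the per-core flank walks; the pure-Python
    # implementation above remains the reference path used by integrate_ehh
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _score_cores_py(pooled, n_case, gpos, pos, starts, stops, stop_ehh,
                    max_gap_bp, i_case, i_ctrl):
    case_rows = np.zeros(pooled.shape[0], dtype=bool)
    case_rows[:n_case] = True
    ctrl_rows = ~case_rows
    gap = None if max_gap_bp <= 0 else max_gap_bp
    for b in range(len(starts)):
        for core in range(starts[b], stops[b]):
            col = pooled[:, core]
            seg = np.unique(col[col != MISSING])
            if len(seg) < 2:
                continue
            lc, lt = _side_walk(case_rows, ctrl_rows, pooled, gpos, core,
                                starts[b], stops[b], -1, stop_ehh, gap, pos)
            rc, rt = _side_walk(case_rows, ctrl_rows, pooled, gpos, core,
                                starts[b], stops[b], +1, stop_ehh, gap, pos)
            i_case[core] = lc + rc
            i_ctrl[core] = lt + rt


def _make_kernel():
    if _njit is None:
        return _score_cores_py

    @_njit(cache=True)
    def kernel(pooled, n_case, gpos, pos, starts, stops, stop_ehh,
               max_gap_bp, i_case, i_ctrl):  # pragma: no cover - numba
        nh, m = pooled.shape
        ids = np.empty(nh, np.int64)
        ids2 = np.empty(nh, np.int64)
        alive = np.empty(nh, np.bool_)
        cnt_all = np.zeros(2 * nh + 2, np.int64)
        cnt_case = np.zeros(2 * nh + 2, np.int64)
        remap = np.empty(2 * nh + 2, np.int64)
        for b in range(len(starts)):
            lo, hi = starts[b], stops[b]
            for core in range(lo, hi):
                a0 = 0
                a1 = 0
                for r in range(nh):
                    v = pooled[r, core]
                    if v == 0:
                        a0 += 1
                    elif v == 1:
                        a1 += 1
                if a0 == 0 or a1 == 0:
                    continue
                tot_case = 0.0
                tot_ctrl = 0.0
                for sdir in range(2):
                    step = -1 if sdir == 0 else 1
                    n_alive = 0
                    n_acase = 0
                    for r in range(nh):
                        v = pooled[r, core]
                        if v >= 0:
                            alive[r] = True
                            ids[r] = v
                            n_alive += 1
                            if r < n_case:
                                n_acase += 1
                        else:
                            alive[r] = False
                            ids[r] = -1
                    # homozygosity at the core partition
                    for g in range(2):
                        cnt_all[g] = 0
                        cnt_case[g] = 0
                    for r in range(nh):
                        if alive[r]:
                            cnt_all[ids[r]] += 1
                            if r < n_case:
                                cnt_case[ids[r]] += 1
                    e_case = -1.0
                    e_ctrl = -1.0
                    n_actrl = n_alive - n_acase
                    if n_acase >= 2:
                        sc = 0
                        for g in range(2):
                            sc += cnt_case[g] * (cnt_case[g] - 1)
                        e_case = sc / (n_acase * (n_acase - 1))
                    if n_actrl >= 2:
                        st = 0
                        for g in range(2):
                            cg = cnt_all[g] - cnt_case[g]
                            st += cg * (cg - 1)
                        e_ctrl = st / (n_actrl * (n_actrl - 1))
                    k_groups = 2
                    d_prev = 0.0
                    j = core
                    while True:
                        j += step
                        if j < lo or j >= hi:
                            break
                        if max_gap_bp > 0:
                            gap = pos[j] - pos[j - step]
                            if gap < 0:
                                gap = -gap
                            if gap > max_gap_bp:
                                break
                        # refine partition by marker j, dropping missing
                        for g in range(2 * k_groups + 2):
                            cnt_all[g] = 0
                            cnt_case[g] = 0
                        n_alive = 0
                        n_acase = 0
                        for r in range(nh):
                            if alive[r]:
                                v = pooled[r, j]
                                if v < 0:
                                    alive[r] = False
                                else:
                                    code = ids[r] * 2 + v
                                    ids2[r] = code
                                    cnt_all[code] += 1
                                    n_alive += 1
                                    if r < n_case:
                                        cnt_case[code] += 1
                                        n_acase += 1
                        # compact relabel + pair counts
                        kk = 0
                        s_all = 0
                        s_case = 0
                        s_ctrl = 0
                        for code in range(2 * k_groups + 2):
                            c = cnt_all[code]
                            if c > 0:
                                remap[code] = kk
                                kk += 1
                                s_all += c * (c - 1)
                                cc = cnt_case[code]
                                s_case += cc * (cc - 1)
                                ct = c - cc
                                s_ctrl += ct * (ct - 1)
                        for r in range(nh):
                            if alive[r]:
                                ids[r] = remap[ids2[r]]
                        k_groups = kk
                        n_actrl = n_alive - n_acase
                        ec = s_case / (n_acase * (n_acase - 1)) if n_acase >= 2 else -1.0
                        et = s_ctrl / (n_actrl * (n_actrl - 1)) if n_actrl >= 2 else -1.0
                        ea = s_all / (n_alive * (n_alive - 1)) if n_alive >= 2 else -1.0
                        d = gpos[j] - gpos[core]
                        if d < 0:
                            d = -d
                        if ec >= 0.0 and e_case >= 0.0:
                            tot_case += (d - d_prev) * (e_case + ec) / 2.0
                        if et >= 0.0 and e_ctrl >= 0.0:
                            tot_ctrl += (d - d_prev) * (e_ctrl + et) / 2.0
                        e_case = ec
                        e_ctrl = et
                        d_prev = d
                        if ea < stop_ehh:
                            break
                i_case[core] = tot_case
                i_ctrl[core] = tot_ctrl

    return kernel


_score_cores = _make_kernel()


def score_all(panel: BreedPanel, case: str, control: str,
              stop_ehh: float = 0.05,
              max_gap_bp: float | None = None) -> ComparisonScores:
    """Score every marker of the panel as core SNP for one ordered comparison.

    SNPs not segregating in the combined case+control sample, or with a zero
    integral on either side of the ratio, are recorded with nan scores and
    excluded from standardization.
    """
    mm = panel.markers
    case_h = panel.breed_haplotypes(case)
    ctrl_h = panel.breed_haplotypes(control)
    pooled = np.ascontiguousarray(np.vstack([case_h, ctrl_h]))
    gpos = mm.genetic_pos
    pos = mm.position_bp.astype(np.float64)
    starts = np.array([mm.chrom_slice(c).start for c in mm.chromosomes()],
                      dtype=np.int64)
    stops = np.array([mm.chrom_slice(c).stop for c in mm.chromosomes()],
                     dtype=np.int64)
    i_case = np.full(mm.n_markers, np.nan)
    i_ctrl = np.full(mm.n_markers, np.nan)
    _score_cores(pooled, case_h.shape[0], gpos, pos, starts, stops,
                 float(stop_ehh),
                 float(max_gap_bp) if max_gap_bp is not None else -1.0,
                 i_case, i_ctrl)
    raw = np.array([xpehh_raw(a, b) for a, b in zip(i_case, i_ctrl)])
    sx = standardize(raw)
    table = pd.DataFrame({
        "marker_id": mm.marker_id, "chrom": mm.chromosome, "pos_bp": mm.position_bp,
        "i_case": i_case, "i_control": i_ctrl, "raw": raw, "sxpehh": sx,
    })
    return ComparisonScores(case, control, table)
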