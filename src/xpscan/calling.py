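"""Significance thresholds, per-SNP calls, signature merging and annotation.

Thresholds are calibrated empirically from two drift-only ("calibration")
breeds: for each (control breed, chromosome) the threshold is the arithmetic
mean of the maximum sXPEHH the two calibration breeds reach as case breeds
against that control on that chromosome. A case-breed SNP is significant for
a control when its sXPEHH strictly exceeds that control's chromosome
threshold; significant calls are pooled over all controls (nSC = number of
significant comparisons per SNP).

Significant SNPs separated by at most one non-significant SNP merge into a
common signature; each signature is extended on both sides by half the
physical distance to the neighbouring non-significant marker (to bp 1 on the
left / the chromosome's last marker position on the right when the run
touches a chromosome terminus). Signatures with a single significant SNP
("singletons") are kept only if confirmed against more than one control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import BreedPanel, MarkerMap, PanelError
from .xpehh import ComparisonScores


@dataclass
class ThresholdTable:
    """Per (control breed, chromosome) significance thresholds."""

    cal1: str
    cal2: str
    table: pd.DataFrame  # control, chrom, max_cal1, max_cal2, threshold

    def threshold(self, control: str, chrom: str) -> float:
        sub = self.table[(self.table["control"] == control)
                         & (self.table["chrom"] == chrom)]
        if len(sub) != 1:
            raise PanelError(f"no threshold for control {control!r}, chromosome {chrom!r}")
        return float(sub["threshold"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class SnpSignificance:
    """Per-SNP significant-control sets and counts (nSC) for one case breed."""

    case: str
    table: pd.DataFrame
    # columns: marker_id, chrom, pos_bp, one sxpehh column per control
    # (nan when not significant), nsc
    controls: list[str]


@dataclass
class Signature:
    """A called selection-signature interval for one case breed."""

    case: str
    chrom: str
    member_indices: list[int]     # map indices of significant member SNPs
    member_positions: list[int]
    start_bp: int
    end_bp: int
    nsc: list[int]                # per member SNP
    singleton: bool
    genes: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.member_indices)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def build_thresholds(calibration_scores: dict[tuple[str, str], ComparisonScores],
                     calibration: tuple[str, str]) -> ThresholdTable:
    """Thresholds from calibration-breed comparisons.

    ``calibration_scores`` maps (calibration breed, control breed) to scores;
    both calibration breeds must be scored against every control on every
    autosome present.
    """
    cal1, cal2 = calibration
    controls = sorted({ctrl for (_, ctrl) in calibration_scores})
    rows = []
    for ctrl in controls:
        for cal in (cal1, cal2):
            if (cal, ctrl) not in calibration_scores:
                raise PanelError(f"missing calibration comparison {cal} vs {ctrl}")
        t1 = calibration_scores[(cal1, ctrl)].table
        t2 = calibration_scores[(cal2, ctrl)].table
        for chrom in pd.unique(t1["chrom"]):
            m1 = t1.loc[t1["chrom"] == chrom, "sxpehh"].max()
            m2 = t2.loc[t2["chrom"] == chrom, "sxpehh"].max()
            if not (np.isfinite(m1) and np.isfinite(m2)):
                raise PanelError(f"no scored SNP for control {ctrl}, chromosome {chrom}")
            rows.append({"control": ctrl, "chrom": chrom, "max_cal1": m1,
                         "max_cal2": m2, "threshold": (m1 + m2) / 2.0})
    return ThresholdTable(cal1, cal2, pd.DataFrame(rows))


def flag_significant(case_scores: dict[str, ComparisonScores],
                     thresholds: ThresholdTable) -> SnpSignificance:
    """Flag SNPs whose sXPEHH strictly exceeds the per-control chromosome
    threshold; pool over controls and count significant comparisons (nSC)."""
    controls = sorted(case_scores)
    case = case_scores[controls[0]].case
    base = case_scores[controls[0]].table[["marker_id", "chrom", "pos_bp"]].copy()
    nsc = np.zeros(len(base), dtype=int)
    for ctrl in controls:
        t = case_scores[ctrl].table
        sig_col = np.full(len(base), np.nan)
        for chrom in pd.unique(t["chrom"]):
            thr = thresholds.threshold(ctrl, chrom)
            rows = (t["chrom"] == chrom).to_numpy()
            vals = t.loc[rows, "sxpehh"].to_numpy()
            hit = np.isfinite(vals) & (vals > thr)
            col = np.full(hit.shape, np.nan)
            col[hit] = vals[hit]
            sig_col[rows] = col
        base[ctrl] = sig_col
        nsc += np.isfinite(sig_col).astype(int)
    base["nsc"] = nsc
    return SnpSignificance(case, base, controls)


def merge_signatures(significance: SnpSignificance,
                     markers: MarkerMap) -> list[Signature]:
    """Merge significant SNPs (nSC >= 1) into signatures per chromosome.

    Runs tolerate at most one intervening non-significant SNP; boundaries
    extend half-way to the flanking non-significant marker (midpoint floored
    on the left, ceiled on the right), or to bp 1 / the last marker position
    at a chromosome terminus.
    """
    t = significance.table
    out: list[Signature] = []
    for chrom in markers.chromosomes():
        sl = markers.chrom_slice(chrom)
        sig_idx = [j for j in range(sl.start, sl.stop)
                   if t["nsc"].iloc[j] >= 1]
        if not sig_idx:
            continue
        runs: list[list[int]] = [[sig_idx[0]]]
        for j in sig_idx[1:]:
            if j - runs[-1][-1] <= 2:  # at most one non-significant SNP between
                runs[-1].append(j)
            else:
                runs.append([j])
        pos = markers.position_bp
        for run in runs:
            first, last = run[0], run[-1]
            if first == sl.start:
                start = 1
            else:
                start = math.floor((pos[first] + pos[first - 1]) / 2)
            if last == sl.stop - 1:
                end = int(pos[sl.stop - 1])
            else:
                end = math.ceil((pos[last] + pos[last + 1]) / 2)
            out.append(Signature(
                case=significance.case, chrom=chrom,
                member_indices=list(run),
                member_positions=[int(pos[j]) for j in run],
                start_bp=int(start), end_bp=int(end),
                nsc=[int(t["nsc"].iloc[j]) for j in run],
                singleton=len(run) == 1))
    return out


def filter_singletons(signatures: list[Signature], min_controls: int = 2
                      ) -> tuple[list[Signature], dict[str, int]]:
    """Drop singleton signatures not confirmed by >= min_controls controls.

    Returns (final signatures, {"total": ..., "final": ...}) mirroring the
    before/after counts.
    """
    final = [s for s in signatures
             if not s.singleton or s.nsc[0] >= min_controls]
    return final, {"total": len(signatures), "final": len(final)}


def read_gene_intervals(path, format: str = "auto") -> pd.DataFrame:
    """Gene intervals as a DataFrame (chrom, start_bp, end_bp, name),
    1-based inclusive. BED input (0-based half-open) is converted."""
    path = str(path)
    if format == "auto":
        format = "gff3" if path.endswith((".gff", ".gff3")) else "bed"
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        genes = pd.DataFrame({
            "chrom": df[0], "start_bp": df[1].astype(int) + 1,
            "end_bp": df[2].astype(int),
            "name": df[3] if df.shape[1] > 3 else df[0] + ":" + df[1],
        })
    elif format == "gff3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                         names=["chrom", "source", "type", "start", "end",
                                "score", "strand", "phase", "attrs"])
        if (df["type"] == "gene").any():
            df = df[df["type"] == "gene"]
        def _name(attrs: str) -> str:
            for key in ("Name=", "gene_name=", "ID="):
                for part in attrs.split(";"):
                    if part.startswith(key):
                        return part[len(key):]
            return attrs
        genes = pd.DataFrame({
            "chrom": df["chrom"], "start_bp": df["start"].astype(int),
            "end_bp": df["end"].astype(int), "name": df["attrs"].map(_name),
        })
    else:
        raise PanelError(f"unknown gene-interval format {format!r}")
    return genes.reset_index(drop=True)


def annotate_genes(signatures: list[Signature],
                   genes: pd.DataFrame) -> list[Signature]:
    """Attach genes with any base-pair overlap with [start_bp, end_bp].

    Raises when the chromosome naming conventions are fully disjoint.
    """
    if signatures and len(genes):
        sig_chroms = {s.chrom for s in signatures}
        gene_chroms = set(genes["chrom"])
        if not sig_chroms & gene_chroms:
            raise PanelError(
                "chromosome names of signatures and gene intervals do not "
                f"overlap: {sorted(sig_chroms)} vs {sorted(gene_chroms)}")
    for s in signatures:
        sub = genes[(genes["chrom"] == s.chrom)
                    & (genes["end_bp"] >= s.start_bp)
                    & (genes["start_bp"] <= s.end_bp)]
        s.genes = list(sub["name"])
    return signatures


def signatures_frame(signatures: list[Signature],
                     significance: SnpSignificance | None = None) -> pd.DataFrame:
    """Flat per-member-SNP table mirroring the audit-file layout: SNP row,
    chromosome, position, per-control sXPEHH (blank when not significant),
    nSC, signature bounds and genes."""
    rows = []
    for k, s in enumerate(signatures, start=1):
        for j, p, n in zip(s.member_indices, s.member_positions, s.nsc):
            row = {"signature": k, "case": s.case, "chrom": s.chrom,
                   "pos_bp": p, "nsc": n,
                   "start_of_sig": s.start_bp, "end_of_sig": s.end_bp,
                   "singleton": s.singleton,
                   "genes": ",".join(s.genes)}
            if significance is not None:
                for ctrl in significance.controls:
                    row[ctrl] = significance.table[ctrl].iloc[j]
            rows.append(row)
    return pd.DataFrame(rows)
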