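"""The selection-signature scan as a model/results pair.

:class:`SelectionScan` is built from a :class:`~xpscan.panel.BreedPanel`
(plus a :class:`ScanConfig`); ``fit()`` runs QC, within-breed relatedness
pruning, XP-EHH scoring of every required ordered comparison,
calibration-breed threshold building, signature calling, LD-based Ne
estimation and pairwise F_ST, and returns a :class:`ScanResults` carrying
all stage outputs, a per-breed summary table and the between-breed
correlation report, with ``summary()`` and ``save()`` for reporting.

Case breeds are compared against the selected controls only; the two
calibration breeds never serve as controls but are themselves scored as
case breeds (against every control) to build the thresholds, and may be
scanned with those same thresholds.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calling, popgen, relatedness
from .panel import BreedPanel, PanelError, qc_filter
from .xpehh import ComparisonScores, score_all


@dataclass
class ScanConfig:
    """Tunable parameters of the full scan (defaults are the study values)."""

    maf_min: float = 0.0023
    callrate_min: float = 0.90
    uar_threshold: float = 0.20
    stop_ehh: float = 0.05
    max_gap_bp: float | None = None
    singleton_min_controls: int = 2
    ld_maf_min: float = 0.10
    ld_bin_start_bp: int = 975_000
    ld_bin_stop_bp: int = 10_025_000
    ld_bin_width_bp: int = 50_000
    do_qc: bool = True
    do_prune: bool = True
    do_fst: bool = True
    do_ne: bool = True
    seed: int = 0


class SelectionScan:
    """Cross-population EHH scan over a breed panel."""

    def __init__(self, panel: BreedPanel, config: ScanConfig | None = None):
        self.panel = panel
        self.config = config or ScanConfig()
        cal = panel.calibration_breeds()
        if len(cal) != 2:
            raise PanelError(f"exactly two calibration breeds required, got {cal}")
        if len(panel.selected_breeds()) < 2:
            raise PanelError("need >= 2 selected breeds (a case and a control)")

    def fit(self, case_breeds: list[str] | None = None,
            progress: bool = False) -> "ScanResults":
        cfg = self.config
        panel = self.panel
        qc_report = None
        if cfg.do_qc:
            panel, qc_report = qc_filter(panel, cfg.maf_min, cfg.callrate_min)
        prune_logs: dict[str, pd.DataFrame] = {}
        if cfg.do_prune:
            panel, prune_logs = relatedness.prune_panel(panel, cfg.uar_threshold)
        cal = panel.calibration_breeds()
        controls = panel.selected_breeds()
        cases = case_breeds or list(controls)
        scores: dict[tuple[str, str], ComparisonScores] = {}

        def _score(case: str, control: str) -> ComparisonScores:
            key = (case, control)
            if key not in scores:
                if progress:
                    print(f"scoring {case} vs {control}", flush=True)
                scores[key] = score_all(panel, case, control,
                                        cfg.stop_ehh, cfg.max_gap_bp)
            return scores[key]

        cal_scores = {(cb, ctrl): _score(cb, ctrl)
                      for cb in cal for ctrl in controls}
        thresholds = calling.build_thresholds(cal_scores, (cal[0], cal[1]))
        significance: dict[str, calling.SnpSignificance] = {}
        sig_total: dict[str, list[calling.Signature]] = {}
        sig_final: dict[str, list[calling.Signature]] = {}
        comparison_counts: dict[str, dict[str, int]] = {}
        for case in cases:
            ctrls = [c for c in controls if c != case]
            if not ctrls:
                raise PanelError(f"case breed {case!r} has no control breeds")
            case_scores = {ctrl: _score(case, ctrl) for ctrl in ctrls}
            sig = calling.flag_significant(case_scores, thresholds)
            significance[case] = sig
            total = calling.merge_signatures(sig, panel.markers)
            final, _counts = calling.filter_singletons(
                total, cfg.singleton_min_controls)
            sig_total[case] = total
            sig_final[case] = final
            # comparison-specific counts: merge using each control alone
            per_ctrl = {}
            for ctrl in ctrls:
                solo = calling.flag_significant({ctrl: case_scores[ctrl]},
                                                thresholds)
                per_ctrl[ctrl] = len(calling.merge_signatures(solo, panel.markers))
            comparison_counts[case] = per_ctrl
        ne_series = {}
        if cfg.do_ne:
            for breed in panel.breeds():
                ne_series[breed] = popgen.ne_from_ld(
                    panel, breed, cfg.ld_maf_min, cfg.ld_bin_start_bp,
                    cfg.ld_bin_stop_bp, cfg.ld_bin_width_bp)
        fst = popgen.fst_matrix(panel) if cfg.do_fst else None
        summary_tbl, correlations = summarize_breeds(
            sig_total, sig_final, comparison_counts, ne_series)
        return ScanResults(panel=panel, config=cfg, qc_report=qc_report,
                           prune_logs=prune_logs, scores=scores,
                           thresholds=thresholds, significance=significance,
                           signatures_total=sig_total,
                           signatures_final=sig_final,
                           comparison_counts=comparison_counts,
                           ne_series=ne_series, fst=fst,
                           breed_summary=summary_tbl,
                           correlations=correlations)


def summarize_breeds(sig_total: dict[str, list],
                     sig_final: dict[str, list],
                     comparison_counts: dict[str, dict[str, int]],
                     ne_series: dict) -> tuple[pd.DataFrame,
                                               popgen.CorrelationReport | None]:
    """Per-breed summary rows (total, final, mean SNPs/signature, Ne5, Ne50,
    ratio) and, when >= 3 breeds have complete series, the Pearson
    correlation grid of {total, final, snps_per_signature} against
    {ne50, ne5, ne5_ne50_ratio}."""
    breeds = list(sig_total)
    rows: dict[str, list] = {k: [] for k in
                             ("total", "final", "snps_per_signature",
                              "ne5", "ne50", "ne5_ne50_ratio")}
    for b in breeds:
        rows["total"].append(sum(comparison_counts[b].values())
                             if comparison_counts.get(b) else len(sig_total[b]))
        rows["final"].append(len(sig_final[b]))
        counts = [s.n_snps for s in sig_final[b]]
        rows["snps_per_signature"].append(float(np.mean(counts)) if counts else np.nan)
        if b in ne_series:
            ne5, ne50 = ne_series[b].ne5, ne_series[b].ne50
        else:
            ne5 = ne50 = np.nan
        rows["ne5"].append(ne5)
        rows["ne50"].append(ne50)
        rows["ne5_ne50_ratio"].append(ne5 / ne50 if np.isfinite(ne5) and
                                      np.isfinite(ne50) and ne50 else np.nan)
    table = pd.DataFrame(rows, index=breeds).T
    corr = None
    complete = table.notna().all(axis=0)
    if complete.sum() >= 3:
        sub = table.loc[:, complete]
        try:
            corr = popgen.correlation_report(
                sub, ["total", "final", "snps_per_signature"],
                ["ne50", "ne5", "ne5_ne50_ratio"])
        except PanelError:
            corr = None
    return table, corr


@dataclass
class ScanResults:
    """All outputs of a fitted :class:`SelectionScan`."""

    panel: BreedPanel
    config: ScanConfig
    qc_report: object
    prune_logs: dict[str, pd.DataFrame]
    scores: dict[tuple[str, str], ComparisonScores]
    thresholds: calling.ThresholdTable
    significance: dict[str, calling.SnpSignificance]
    signatures_total: dict[str, list[calling.Signature]]
    signatures_final: dict[str, list[calling.Signature]]
    comparison_counts: dict[str, dict[str, int]]
    ne_series: dict[str, popgen.LdBinSeries]
    fst: pd.DataFrame | None
    breed_summary: pd.DataFrame
    correlations: popgen.CorrelationReport | None

    def annotate(self, genes: pd.DataFrame) -> None:
        """Attach positional candidate genes to every final signature."""
        for sigs in self.signatures_final.values():
            calling.annotate_genes(sigs, genes)

    def summary(self) -> str:
        lines = ["Cross-population EHH selection scan", "=" * 40]
        lines.append(f"panel: {self.panel.n_individuals} individuals, "
                     f"{self.panel.n_markers} markers, "
                     f"{len(self.panel.breeds())} breeds")
        cal = self.panel.calibration_breeds()
        lines.append(f"calibration breeds: {', '.join(cal)}")
        if self.qc_report is not None:
            lines.append(f"QC removed {self.qc_report.n_removed} markers "
                         f"({self.qc_report.n_retained} retained)")
        for b, log in self.prune_logs.items():
            if len(log):
                lines.append(f"pruned {len(log)} related individuals from {b}")
        lines.append("")
        lines.append("breed summary (signatures and LD-based Ne):")
        lines.append(self.breed_summary.round(2).to_string())
        if self.correlations is not None:
            lines.append("")
            lines.append("correlations of signature counts with Ne:")
            lines.append(self.correlations.table.round(3).to_string(index=False))
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        """Write every stage output as TSV plus a manifest with SHA-256 hashes."""
        os.makedirs(outdir, exist_ok=True)
        written: dict[str, str] = {}

        def _put(name: str, writer) -> None:
            path = os.path.join(outdir, name)
            writer(path)
            with open(path, "rb") as fh:
                written[name] = hashlib.sha256(fh.read()).hexdigest()

        if self.qc_report is not None:
            _put("qc_report.tsv", self.qc_report.to_tsv)
        for b, log in self.prune_logs.items():
            _put(f"prune_{b}.tsv", lambda p, log=log: log.to_csv(p, sep="\t", index=False))
        for (case, ctrl), sc in self.scores.items():
            _put(f"scores_{case}_vs_{ctrl}.tsv", sc.to_tsv)
        _put("thresholds.tsv", self.thresholds.to_tsv)
        for case, sigs in self.signatures_final.items():
            frame = calling.signatures_frame(sigs, self.significance[case])
            _put(f"signatures_{case}.tsv",
                 lambda p, f=frame: f.to_csv(p, sep="\t", index=False))
        for b, series in self.ne_series.items():
            _put(f"ne_{b}.tsv", series.to_tsv)
        if self.fst is not None:
            _put("fst.tsv", lambda p: self.fst.to_csv(p, sep="\t",
                                                      float_format="%.4f"))
        _put("breed_summary.tsv",
             lambda p: self.breed_summary.to_csv(p, sep="\t", float_format="%.4f"))
        if self.correlations is not None:
            _put("correlations.tsv", self.correlations.to_tsv)
        manifest = {"files": written, "config": vars(self.config)}
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return manifest
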