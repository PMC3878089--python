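"""Calibration thresholds, significance flags, merging and annotation."""

import numpy as np
import pandas as pd
import pytest

import xpscan as xs
from xpscan.xpehh import ComparisonScores

from conftest import build_panel


def _scores(case, control, sxpehh, chroms=None, positions=None):
    m = len(sxpehh)
    chroms = chroms or ["1"] * m
    positions = positions if positions is not None else (np.arange(m) + 1) * 100_000
    table = pd.DataFrame({
        "marker_id": [f"m{j}" for j in range(m)],
        "chrom": chroms, "pos_bp": positions,
        "i_case": 0.01, "i_control": 0.01,
        "raw": sxpehh, "sxpehh": np.asarray(sxpehh, dtype=float),
    })
    return ComparisonScores(case, control, table)


class TestBuildThresholds:
    def test_worked_example_mean(self):
        cal = {("IMB", "RH"): _scores("IMB", "RH", [0.1, 2.658523, -1.0]),
               ("ABB", "RH"): _scores("ABB", "RH", [3.056731, 0.2, 0.0])}
        tt = xs.build_thresholds(cal, ("IMB", "ABB"))
        assert tt.threshold("RH", "1") == pytest.approx(2.857627, abs=1e-9)

    def test_equal_maxima(self):
        cal = {("X", "C"): _scores("X", "C", [1.5, 0.2]),
               ("Y", "C"): _scores("Y", "C", [1.5, -0.3])}
        assert xs.build_thresholds(cal, ("X", "Y")).threshold("C", "1") == 1.5

    def test_arithmetic_mean(self):
        cal = {("X", "C"): _scores("X", "C", [0.0, -1.0]),
               ("Y", "C"): _scores("Y", "C", [4.0, 2.0])}
        assert xs.build_thresholds(cal, ("X", "Y")).threshold("C", "1") == 2.0

    def test_per_chromosome_entries(self):
        cal = {("X", "C"): _scores("X", "C", [1.0, 3.0], chroms=["1", "2"]),
               ("Y", "C"): _scores("Y", "C", [2.0, 1.0], chroms=["1", "2"])}
        tt = xs.build_thresholds(cal, ("X", "Y"))
        assert tt.threshold("C", "1") == 1.5
        assert tt.threshold("C", "2") == 2.0

    def test_missing_comparison_named(self):
        cal = {("X", "C"): _scores("X", "C", [1.0])}
        with pytest.raises(xs.PanelError, match="Y vs C"):
            xs.build_thresholds(cal, ("X", "Y"))


class TestFlagSignificant:
    def _thresholds(self):
        cal = {("X", "C"): _scores("X", "C", [2.658523]),
               ("Y", "C"): _scores("Y", "C", [3.056731])}
        return xs.build_thresholds(cal, ("X", "Y"))  # threshold 2.857627

    def test_strictly_above_flags(self):
        sig = xs.flag_significant({"C": _scores("A", "C", [2.86, 1.0])},
                                  self._thresholds())
        assert sig.table["nsc"].tolist() == [1, 0]

    def test_exact_threshold_not_significant(self):
        sig = xs.flag_significant({"C": _scores("A", "C", [2.857627])},
                                  self._thresholds())
        assert sig.table["nsc"].tolist() == [0]

    def test_nsc_counts_controls(self):
        cal = {}
        for ctrl in ("C1", "C2", "C3"):
            cal[("X", ctrl)] = _scores("X", ctrl, [1.0, 1.0])
            cal[("Y", ctrl)] = _scores("Y", ctrl, [1.0, 1.0])
        tt = xs.build_thresholds(cal, ("X", "Y"))  # thresholds all 1.0
        case_scores = {c: _scores("A", c, [2.0, 0.5]) for c in ("C1", "C2", "C3")}
        sig = xs.flag_significant(case_scores, tt)
        assert sig.table["nsc"].tolist() == [3, 0]


def _significance(flags, positions, chroms=None, nsc=None):
    m = len(flags)
    nsc = nsc or [1 if f else 0 for f in flags]
    table = pd.DataFrame({
        "marker_id": [f"m{j}" for j in range(m)],
        "chrom": chroms or ["1"] * m, "pos_bp": positions, "nsc": nsc,
    })
    from xpscan.calling import SnpSignificance
    return SnpSignificance("A", table, ["C"])


def _map(positions, chroms=None):
    return build_panel(np.zeros((2, len(positions)), np.int8),
                       positions=positions, chroms=chroms).markers


class TestMergeSignatures:
    def test_single_gap_joins_and_half_distance_extends(self):
        pos = [100_000, 200_000, 300_000, 400_000, 500_000]
        sigs = xs.merge_signatures(
            _significance([False, True, False, True, False], pos), _map(pos))
        assert len(sigs) == 1
        s = sigs[0]
        assert s.member_positions == [200_000, 400_000]
        assert (s.start_bp, s.end_bp) == (150_000, 450_000)
        assert not s.singleton

    def test_two_snp_gap_splits(self):
        pos = [100_000, 200_000, 300_000, 400_000]
        sigs = xs.merge_signatures(
            _significance([True, False, False, True], pos), _map(pos))
        assert len(sigs) == 2
        assert all(s.singleton for s in sigs)

    def test_chromosome_terminus_extends_to_bp_one(self):
        pos = [100_000, 200_000, 300_000]
        sigs = xs.merge_signatures(
            _significance([True, True, False], pos), _map(pos))
        assert sigs[0].start_bp == 1
        assert sigs[0].end_bp == 250_000

    def test_right_terminus_extends_to_last_marker(self):
        pos = [100_000, 200_000, 300_000]
        sigs = xs.merge_signatures(
            _significance([False, True, True], pos), _map(pos))
        assert sigs[0].start_bp == 150_000
        assert sigs[0].end_bp == 300_000

    def test_signatures_do_not_overlap(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 10_000) * 1_000, size=60,
                                 replace=False))
        flags = rng.random(60) < 0.3
        sigs = xs.merge_signatures(_significance(list(flags), pos), _map(pos))
        spans = sorted((s.start_bp, s.end_bp) for s in sigs)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 < a2


class TestFilterSingletons:
    def _sig(self, n_members, nscs):
        from xpscan.calling import Signature
        return Signature("A", "1", list(range(n_members)),
                         [100_000 * (j + 1) for j in range(n_members)],
                         50_000, 100_000 * n_members + 50_000,
                         nscs, n_members == 1)

    def test_singleton_unconfirmed_removed(self):
        final, counts = xs.filter_singletons([self._sig(1, [1])])
        assert final == [] and counts == {"total": 1, "final": 0}

    def test_singleton_confirmed_twice_retained(self):
        final, counts = xs.filter_singletons([self._sig(1, [2])])
        assert len(final) == 1 and counts["final"] == 1

    def test_multi_snp_signature_always_retained(self):
        final, _ = xs.filter_singletons([self._sig(2, [1, 1])])
        assert len(final) == 1


class TestAnnotateGenes:
    def _genes(self):
        return pd.DataFrame({
            "chrom": ["1", "1", "2"],
            "start_bp": [120_000, 440_000, 100_000],
            "end_bp": [130_000, 460_000, 200_000],
            "name": ["inside", "flank", "other_chrom"],
        })

    def _signature(self):
        from xpscan.calling import Signature
        return Signature("A", "1", [1, 2], [200_000, 400_000],
                         100_000, 450_000, [1, 1], False)

    def test_overlap_rules(self):
        sigs = xs.annotate_genes([self._signature()], self._genes())
        assert sigs[0].genes == ["inside", "flank"]

    def test_disjoint_chromosome_names_error(self):
        genes = self._genes().assign(chrom=["chr1", "chr1", "chr2"])
        with pytest.raises(xs.PanelError, match="chromosome names"):
            xs.annotate_genes([self._signature()], genes)

    def test_bed_and_gff_readers(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("1\t119999\t130000\tinside\n2\t99999\t200000\tg2\n")
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\n"
                       "1\tsrc\tgene\t120000\t130000\t.\t+\t.\tID=g1;Name=inside\n"
                       "1\tsrc\texon\t120000\t121000\t.\t+\t.\tID=e1\n")
        b = xs.read_gene_intervals(str(bed))
        g = xs.read_gene_intervals(str(gff))
        assert b.loc[0, "start_bp"] == 120_000 and b.loc[0, "end_bp"] == 130_000
        assert list(g["name"]) == ["inside"]
        assert g.loc[0, "start_bp"] == 120_000
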