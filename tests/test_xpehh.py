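"""EHH pair probabilities, integration, XP-EHH scores and standardization."""

import numpy as np
import pytest
from scipy import stats

import xpscan as xs
from xpscan.panel import MISSING

from _oracles import ehh_enumeration
from conftest import build_panel


class TestEhhAt:
    def test_core_population_mode(self):
        haps = np.array([[0], [0], [1], [1]], dtype=np.int8)
        # homozygous pairs share the core allele: 2 of 6
        assert xs.ehh_at(haps, 0, 0) == pytest.approx(1 / 3)

    def test_two_marker_span(self):
        # spans read AB, AB, AC, AC -> 2 identical pairs of 6
        haps = np.array([[0, 0], [0, 0], [0, 1], [0, 1]], dtype=np.int8)
        assert xs.ehh_at(haps, 0, 1) == pytest.approx(1 / 3)

    def test_identical_haplotypes_give_one(self):
        haps = np.tile(np.array([0, 1, 0, 1], dtype=np.int8), (5, 1))
        assert xs.ehh_at(haps, 0, 3) == 1.0

    def test_allele_conditioned_is_one_at_core(self):
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        assert xs.ehh_at(haps, 0, 0, condition_on_allele=0) == 1.0
        assert xs.ehh_at(haps, 0, 0, condition_on_allele=1) == 1.0

    def test_fewer_than_two_considered_is_undefined(self):
        haps = np.array([[0, 0], [1, 0], [1, 1]], dtype=np.int8)
        assert np.isnan(xs.ehh_at(haps, 0, 1, condition_on_allele=0))

    def test_missing_haplotypes_excluded(self):
        haps = np.array([[0, MISSING], [0, 0], [0, 0], [0, 1]], dtype=np.int8)
        # row 0 is dropped over the 2-marker span: pairs among 3 rows
        assert xs.ehh_at(haps, 0, 1) == pytest.approx(1 / 3)

    def test_equals_pair_enumeration_on_random_panels(self, rng):
        """Exhaustive-pair oracle equality on panels up to 12 x 20."""
        for _ in range(25):
            nh = int(rng.integers(3, 13))
            m = int(rng.integers(2, 21))
            haps = rng.integers(0, 2, size=(nh, m)).astype(np.int8)
            haps[rng.random(size=haps.shape) < 0.05] = MISSING
            core = int(rng.integers(m))
            target = int(rng.integers(m))
            got = xs.ehh_at(haps, core, target)
            want = ehh_enumeration(haps, core, target)
            assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)


def test_ehh_curve_starts_at_one_and_never_rises(small_panel):
    haps = small_panel.breed_haplotypes("A")
    curve = xs.ehh_curve(haps, 10, "right", small_panel.markers,
                         condition_on_allele=int(haps[0, 10]))
    finite = curve.ehh[np.isfinite(curve.ehh)]
    assert finite[0] == 1.0
    assert np.all(np.diff(finite) <= 1e-12)
    assert np.all(np.diff(curve.gdist) >= 0)


class TestIntegrateEhh:
    def test_single_trapezoid(self):
        # pop EHH 1.0 at core, 0.5 at the flanking marker 1 Mb away
        pop = np.array([[0, 0], [0, 0], [0, 0], [0, 1]], dtype=np.int8)
        comb = np.vstack([pop, [[1, 0], [1, 1]]])
        panel = build_panel(np.zeros((2, 2), np.int8),
                            positions=[1_000_000, 2_000_000])
        i = xs.integrate_ehh(pop, comb, 0, panel.markers)
        assert i == pytest.approx(0.01 * (1.0 + 0.5) / 2)

    def test_rectangle_when_curve_stays_one(self):
        pop = np.tile(np.array([0, 1], dtype=np.int8), (4, 1))
        comb = np.vstack([pop, np.array([[1, 0]] * 2, dtype=np.int8)])
        panel = build_panel(np.zeros((2, 2), np.int8),
                            positions=[1_000_000, 2_000_000])
        i = xs.integrate_ehh(pop, comb, 0, panel.markers)
        assert i == pytest.approx(0.01)

    def test_symmetry_of_mirrored_flanks(self, rng):
        half = rng.integers(0, 2, size=(8, 5)).astype(np.int8)
        haps = np.hstack([half[:, ::-1], half[:, [0]], half])
        pos = (np.arange(11) + 1) * 500_000
        panel = build_panel(np.zeros((2, 11), np.int8), positions=pos)
        left = xs.integrate_ehh(haps, haps, 5, panel.markers)
        only_right = haps[:, 5:]
        pr = build_panel(np.zeros((2, 6), np.int8), positions=pos[5:])
        right = xs.integrate_ehh(only_right, only_right, 0, pr.markers)
        assert left == pytest.approx(2 * right)

    def test_monotone_in_stop_cutoff(self, small_panel):
        haps = small_panel.breed_haplotypes("A")
        comb = np.vstack([haps, small_panel.breed_haplotypes("B")])
        for core in (3, 40, 70):
            loose = xs.integrate_ehh(haps, comb, core, small_panel.markers,
                                     stop_ehh=0.2)
            tight = xs.integrate_ehh(haps, comb, core, small_panel.markers,
                                     stop_ehh=0.02)
            assert tight >= loose - 1e-12

    def test_non_segregating_core_rejected(self):
        pop = np.zeros((4, 3), dtype=np.int8)
        with pytest.raises(xs.PanelError, match="segregate"):
            xs.integrate_ehh(pop, pop, 1,
                             build_panel(np.zeros((2, 3), np.int8)).markers)


class TestRawAndStandardize:
    @pytest.mark.parametrize("ic,it,expect", [
        (0.01, 0.01, 0.0),
        (np.e * 0.01, 0.01, 1.0),
        (0.02, 0.01, 0.6931),
    ])
    def test_log_ratio(self, ic, it, expect):
        assert xs.xpehh_raw(ic, it) == pytest.approx(expect, abs=1e-4)

    def test_zero_integral_is_missing(self):
        assert np.isnan(xs.xpehh_raw(0.0, 0.01))
        assert np.isnan(xs.xpehh_raw(0.01, 0.0))

    def test_standardize_known_values(self):
        out = xs.standardize(np.array([0.0, 0.0, 2.0, 2.0]))
        assert np.allclose(out, [-1, -1, 1, 1])

    def test_standardize_moments_and_permutation(self, rng):
        x = rng.normal(1.5, 3.0, size=200)
        z = xs.standardize(x)
        assert z.mean() == pytest.approx(0, abs=1e-9)
        assert z.var() == pytest.approx(1, abs=1e-9)
        perm = rng.permutation(200)
        assert np.allclose(xs.standardize(x[perm]), z[perm])

    def test_standardize_carries_missing(self):
        z = xs.standardize(np.array([1.0, np.nan, 3.0]))
        assert np.isnan(z[1]) and np.isfinite(z[0])

    def test_zero_spread_errors(self):
        with pytest.raises(xs.PanelError):
            xs.standardize(np.array([1.0, 1.0, 1.0]))


class TestScoreAll:
    def test_antisymmetric_in_direction(self, small_panel):
        ab = xs.score_all(small_panel, "A", "B").table
        ba = xs.score_all(small_panel, "B", "A").table
        ok = np.isfinite(ab["raw"]) & np.isfinite(ba["raw"])
        assert ok.sum() > 50
        assert np.allclose(ab.loc[ok, "raw"], -ba.loc[ok, "raw"])

    def test_scores_match_integrate_ehh(self, small_panel):
        """The fast scorer equals the reference integrator marker by marker."""
        sc = xs.score_all(small_panel, "A", "B").table
        case = small_panel.breed_haplotypes("A")
        comb = np.vstack([case, small_panel.breed_haplotypes("B")])
        for core in (2, 30, 61, 100):
            if np.isnan(sc["i_case"].iloc[core]):
                continue
            want = xs.integrate_ehh(case, comb, core, small_panel.markers)
            assert sc["i_case"].iloc[core] == pytest.approx(want, rel=1e-12)

    def test_sweep_peak_localizes_to_planted_core(self):
        """With a compact-origin strong sweep in breed A the genome-wide
        maximum sXPEHH(A vs B) lands within 1 Mb of the core."""
        hits = 0
        for seed in range(20):
            cfg = xs.SimConfig(
                breeds=[xs.BreedConfig("A", 500, 100, 40, 30),
                        xs.BreedConfig("B", 500, 100, 40, 30)],
                n_markers=1000, n_chromosomes=5,
                sweeps=[xs.SweepTruth("A", 100, s=1.5, start_gen=25,
                                      initial_freq=0.02, origin_window=15)],
                seed=seed)
            panel, _ = xs.simulate_panel(cfg)
            t = xs.score_all(panel, "A", "B").table
            core_pos = panel.markers.position_bp[100]
            best = t.loc[t["sxpehh"].idxmax()]
            if best["chrom"] == "1" and abs(best["pos_bp"] - core_pos) <= 1_000_000:
                hits += 1
        assert hits >= 16

    def test_neutral_directions_indistinguishable(self):
        """Without selection the two scan directions of a split pair give
        exchangeable maximum scores."""
        amax, bmax = [], []
        for seed in range(20):
            cfg = xs.SimConfig(
                breeds=[xs.BreedConfig("A", 300, 120, 30, 25),
                        xs.BreedConfig("B", 300, 120, 30, 25)],
                n_markers=300, n_chromosomes=2, seed=seed + 100)
            panel, _ = xs.simulate_panel(cfg)
            t = xs.score_all(panel, "A", "B").table
            amax.append(t["sxpehh"].max())
            bmax.append((-t["sxpehh"]).max())
        p = stats.mannwhitneyu(amax, bmax).pvalue
        assert p > 0.01
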