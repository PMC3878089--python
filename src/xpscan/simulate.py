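"""Forward Wright-Fisher simulation of breed-structured SNP-chip panels.

The generator emulates the study design this package targets: several breeds
split from a common founder pool, each evolving independently under discrete
Wright-Fisher reproduction with recombination (crossovers Poisson with rate
equal to the genetic length, 1 cM/Mb), per-breed census trajectories with
recent decline, two large-Ne "calibration" breeds without directional
selection, and optional selective sweeps of configurable strength planted in
selected breeds. Founder haplotypes are drawn in linkage equilibrium at a
uniform(0.05, 0.95) allele-frequency spectrum, mimicking the ascertained
common variants on a genotyping chip; LD then accrues through drift during
the simulated epoch.

All randomness flows through one ``numpy`` Generator seeded from
``SimConfig.seed``; draws are consumed in a fixed documented order
(marker map, founder frequencies, founder haplotypes, then breeds in listed
order, generation by generation), so a given config is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import MORGAN_PER_BP, BreedPanel, MarkerMap, PanelError, ROLE_CALIBRATION, ROLE_SELECTED

DEFAULT_SPACING_BP = 48_780  # mean inter-marker distance of a 54k bovine chip


@dataclass
class SweepTruth:
    """A planted sweep: per-copy fitness multiplier (1+s) on the favoured allele.

    ``s = 0`` reduces to neutrality.  If ``initial_freq`` is given, the core
    column of the breed's founding haplotypes is re-assigned so the favoured
    allele (allele 1) starts at that frequency; otherwise the founder-pool
    frequency is kept. A core lost to drift is recorded, not an error.
    """

    breed: str
    core_index: int
    s: float = 0.0
    start_gen: int = 0
    initial_freq: float | None = None
    origin_window: int = 60  # markers each side sharing the ancestral background

    def __post_init__(self):
        if self.s < 0:
            raise PanelError("selection coefficient must be >= 0")


@dataclass
class BreedConfig:
    """One breed's demography: linear diploid-size trajectory since the split."""

    name: str
    size_at_split: int
    size_recent: int
    n_generations: int
    n_sampled: int
    role: str = ROLE_SELECTED

    def sizes(self) -> np.ndarray:
        """Diploid census size per generation (length n_generations)."""
        if self.n_generations == 0:
            return np.array([], dtype=int)
        t = np.linspace(0.0, 1.0, self.n_generations)
        return np.maximum(2, np.round(
            self.size_at_split + t * (self.size_recent - self.size_at_split)
        ).astype(int))


@dataclass
class SimConfig:
    breeds: list[BreedConfig]
    n_markers: int = 500
    n_chromosomes: int = 1
    mean_spacing_bp: float = DEFAULT_SPACING_BP
    founder_pool_size: int = 500          # diploid founders shared by all breeds
    founder_maf_range: tuple[float, float] = (0.05, 0.95)
    sweeps: list[SweepTruth] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        names = [b.name for b in self.breeds]
        if len(set(names)) != len(names):
            raise PanelError("duplicate breed names in SimConfig")
        for b in self.breeds:
            if min(b.size_at_split, b.size_recent) < 2 or b.n_sampled < 2:
                raise PanelError("all breed sizes must be >= 2")
            if b.n_sampled > b.size_recent:
                raise PanelError(f"cannot sample {b.n_sampled} from {b.size_recent} "
                                 f"in breed {b.name}")
        for sw in self.sweeps:
            if sw.breed not in names:
                raise PanelError(f"sweep breed {sw.breed!r} not in config")
            if not 0 <= sw.core_index < self.n_markers:
                raise PanelError("sweep core index out of range")


@dataclass
class PanelTruth:
    """Ground truth: sweep trajectories and final frequencies, founder freqs."""

    founder_freq: np.ndarray
    sweep_final_freq: dict[tuple[str, int], float]
    sweep_trajectory: dict[tuple[str, int], np.ndarray]
    breed_sizes: dict[str, np.ndarray]

    def to_frame(self):
        import pandas as pd
        rows = [{"breed": b, "core_index": j, "final_freq": f}
                for (b, j), f in self.sweep_final_freq.items()]
        return pd.DataFrame(rows, columns=["breed", "core_index", "final_freq"])


def generate_marker_map(n_markers: int, mean_spacing_bp: float = DEFAULT_SPACING_BP,
                        seed=0, n_chromosomes: int = 1) -> MarkerMap:
    """Marker map with exponential inter-marker gaps of the requested mean.

    Markers are split as evenly as possible over ``n_chromosomes``; positions
    start near the chromosome origin and strictly increase (gaps >= 1 bp).
    ``seed`` may be an int or an existing Generator (the global-stream case).
    """
    if n_markers < 2:
        raise PanelError("need at least 2 markers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per = np.full(n_chromosomes, n_markers // n_chromosomes, dtype=int)
    per[: n_markers % n_chromosomes] += 1
    ids, chroms, pos = [], [], []
    for c, m in enumerate(per, start=1):
        gaps = np.maximum(1, np.round(rng.exponential(mean_spacing_bp, size=m)).astype(np.int64))
        p = np.cumsum(gaps)
        pos.append(p)
        chroms.extend([str(c)] * m)
        ids.extend([f"snp{c}_{k + 1}" for k in range(m)])
    alleles = np.array([["A", "B"]] * n_markers, dtype=object)
    return MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                     np.concatenate(pos), alleles)


def _chrom_blocks(mm: MarkerMap) -> list[tuple[slice, float, np.ndarray]]:
    """(column slice, genetic length in Morgan, genetic positions) per chromosome."""
    out = []
    for c in mm.chromosomes():
        sl = mm.chrom_slice(c)
        g = mm.position_bp[sl] * MORGAN_PER_BP
        out.append((sl, float(g[-1] - g[0]), g))
    return out


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, blocks, rng) -> np.ndarray:
    """One gamete from a diploid parent; independent recombination per chromosome."""
    out = np.empty_like(hap_a)
    for sl, length, gpos in blocks:
        start = rng.integers(2)
        k = rng.poisson(length)
        if k == 0:
            out[sl] = hap_a[sl] if start == 0 else hap_b[sl]
            continue
        cuts = np.sort(rng.uniform(gpos[0], gpos[-1], size=k))
        seg = start + np.searchsorted(cuts, gpos, side="right")
        use_a = (seg % 2) == 0
        out[sl] = np.where(use_a, hap_a[sl], hap_b[sl])
    return out


def simulate_panel(config: SimConfig) -> tuple[BreedPanel, PanelTruth]:
    """Simulate a breed-structured phased panel with known truth.

    Returns the sampled panel (phase known exactly) and a :class:`PanelTruth`
    with founder frequencies and per-sweep allele-frequency trajectories.
    """
    rng = np.random.default_rng(config.seed)
    mm = generate_marker_map(config.n_markers, config.mean_spacing_bp, rng,
                             config.n_chromosomes)
    blocks = _chrom_blocks(mm)
    lo, hi = config.founder_maf_range
    founder_freq = rng.uniform(lo, hi, size=config.n_markers)
    pool = (rng.random((2 * config.founder_pool_size, config.n_markers))
            < founder_freq).astype(np.int8)

    all_haps, ids, breed_of, roles = [], [], {}, {}
    final_freq: dict[tuple[str, int], float] = {}
    traj: dict[tuple[str, int], np.ndarray] = {}
    sizes_rec: dict[str, np.ndarray] = {}

    for bc in config.breeds:
        roles[bc.name] = bc.role
        sizes = bc.sizes()
        sizes_rec[bc.name] = sizes
        n0 = sizes[0] if len(sizes) else bc.size_recent
        rows = rng.integers(0, pool.shape[0], size=2 * n0)
        haps = pool[rows].copy()
        sweeps = [sw for sw in config.sweeps if sw.breed == bc.name]
        paths = {sw.core_index: [] for sw in sweeps}
        for sw in sweeps:
            if sw.initial_freq is not None and sw.start_gen == 0:
                _plant(haps, sw, mm, rng)
        for gen, n_next in enumerate(sizes):
            for sw in sweeps:
                if sw.initial_freq is not None and sw.start_gen == gen and gen > 0:
                    _plant(haps, sw, mm, rng)
            w = np.ones(haps.shape[0] // 2)
            for sw in sweeps:
                if gen >= sw.start_gen and sw.s > 0:
                    copies = haps[0::2, sw.core_index] + haps[1::2, sw.core_index]
                    w *= (1.0 + sw.s) ** copies
            p = w / w.sum()
            nxt = np.empty((2 * n_next, config.n_markers), dtype=np.int8)
            mothers = rng.choice(len(p), size=n_next, p=p)
            fathers = rng.choice(len(p), size=n_next, p=p)
            for i in range(n_next):
                m, f = mothers[i], fathers[i]
                nxt[2 * i] = _meiosis(haps[2 * m], haps[2 * m + 1], blocks, rng)
                nxt[2 * i + 1] = _meiosis(haps[2 * f], haps[2 * f + 1], blocks, rng)
            haps = nxt
            for sw in sweeps:
                paths[sw.core_index].append(haps[:, sw.core_index].mean())
        for sw in sweeps:
            key = (bc.name, sw.core_index)
            traj[key] = np.array(paths[sw.core_index])
            final_freq[key] = float(haps[:, sw.core_index].mean())
        pick = rng.choice(haps.shape[0] // 2, size=bc.n_sampled, replace=False)
        for k, ind in enumerate(pick):
            iid = f"{bc.name}_{k + 1:03d}"
            ids.append(iid)
            breed_of[iid] = bc.name
            all_haps.append(haps[2 * ind])
            all_haps.append(haps[2 * ind + 1])

    panel = BreedPanel(mm, np.array(all_haps, dtype=np.int8), ids, breed_of, roles)
    return panel, PanelTruth(founder_freq, final_freq, traj, sizes_rec)


def _plant(haps: np.ndarray, sw: SweepTruth, mm: MarkerMap, rng) -> None:
    """Place the favoured allele at the requested frequency on a single
    ancestral background.

    A hard sweep descends from one origin: all early carriers are near-exact
    copies of the ancestral haplotype around the core. The carriers therefore
    receive a copy of a random focal haplotype over ``origin_window`` markers
    each side of the core (clipped to the chromosome); scattering the allele
    over unrelated backgrounds would emulate a soft sweep instead, which
    leaves little extended-homozygosity signal by design.
    """
    sl = mm.chrom_slice(mm.chromosome[sw.core_index])
    lo = max(sl.start, sw.core_index - sw.origin_window)
    hi = min(sl.stop, sw.core_index + sw.origin_window + 1)
    n = haps.shape[0]
    k = max(1, int(round(sw.initial_freq * n)))
    focal = int(rng.integers(n))
    carriers = rng.choice(n, size=k, replace=False)
    haps[:, sw.core_index] = 0
    haps[np.ix_(carriers, np.arange(lo, hi))] = haps[focal, lo:hi]
    haps[carriers, sw.core_index] = 1


# ---------------------------------------------------------------------------
# canned demography templates
# ---------------------------------------------------------------------------

def study_template(n_selected: int = 8, n_generations: int = 45,
                   n_sampled: int = 40, n_markers: int = 1000,
                   n_chromosomes: int = 2, seed: int = 0,
                   sweeps: list[SweepTruth] | None = None) -> SimConfig:
    """A ten-breed-style template: ``n_selected`` selected breeds with small,
    declining Ne (split sizes ~250-550 declining to ~50-130) plus two
    calibration breeds that were effectively large at the split (~1,000-1,700)
    and remain comparatively large (~150-185) today.
    """
    rng = np.random.default_rng(seed)
    breeds = []
    for k in range(n_selected):
        split = int(rng.integers(250, 551))
        recent = int(rng.integers(50, 131))
        breeds.append(BreedConfig(f"SEL{k + 1}", split, recent, n_generations,
                                  n_sampled, ROLE_SELECTED))
    for k, (split, recent) in enumerate([(1700, 185), (1000, 150)]):
        breeds.append(BreedConfig(f"CAL{k + 1}", split, recent, n_generations,
                                  n_sampled, ROLE_CALIBRATION))
    return SimConfig(breeds=breeds, n_markers=n_markers,
                     n_chromosomes=n_chromosomes, sweeps=sweeps or [], seed=seed)
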