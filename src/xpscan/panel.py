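"""Phased breed panels: marker maps, haplotype matrices, file I/O and marker QC.

A :class:`BreedPanel` is the universe every downstream stage consumes: a
phased bi-allelic haplotype matrix (rows = haplotypes, two consecutive rows
per individual), a physical marker map, per-individual breed labels and
per-breed roles ("selected" breeds are case/control eligible; "calibration"
breeds are the drift-only populations that set significance thresholds).

Genetic positions are derived from physical positions at 1 cM per Mb
(position_bp x 1e-8 Morgan), the proxy used throughout the scan.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # haplotype allele code for missing data

ROLE_SELECTED = "selected"
ROLE_CALIBRATION = "calibration"
_VALID_ROLES = {ROLE_SELECTED, ROLE_CALIBRATION}

MORGAN_PER_BP = 1e-8  # 1 Mb = 1 cM


class PanelError(ValueError):
    """Raised when a panel, map or input file violates its contract."""


@dataclass(frozen=True)
class MarkerMap:
    """Physical map of bi-allelic markers, ordered by chromosome then position.

    Positions are 1-based base pairs on autosome labels (e.g. "1".."29").
    Chromosome blocks must be contiguous and positions strictly increasing
    within each chromosome. Markers with unknown position carry
    ``position_bp <= 0`` (they are removed by QC, reason "no-position").
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    alleles: np.ndarray  # (M, 2) allele labels

    def __post_init__(self):
        m = len(self.marker_id)
        if not (len(self.chromosome) == len(self.position_bp) == m):
            raise PanelError("marker map arrays have inconsistent lengths")
        if self.alleles.shape != (m, 2):
            raise PanelError("alleles must be an (n_markers, 2) array")
        # contiguity of chromosome blocks
        seen = set()
        prev = None
        for c in self.chromosome:
            if c != prev:
                if c in seen:
                    raise PanelError(f"chromosome {c!r} appears in non-contiguous blocks")
                seen.add(c)
                prev = c
        for c in seen:
            pos = self.position_bp[self.chromosome == c]
            known = pos[pos > 0]
            if len(known) > 1 and not np.all(np.diff(known) > 0):
                raise PanelError(f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def genetic_pos(self) -> np.ndarray:
        """Genetic position in Morgan (1 cM/Mb proxy)."""
        return self.position_bp * MORGAN_PER_BP

    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order."""
        out, prev = [], None
        for c in self.chromosome:
            if c != prev:
                out.append(c)
                prev = c
        return out

    def chrom_slice(self, chrom: str) -> slice:
        """Column slice [start, stop) of one chromosome's markers."""
        idx = np.flatnonzero(self.chromosome == chrom)
        if len(idx) == 0:
            raise PanelError(f"chromosome {chrom!r} not in map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.marker_id[mask], self.chromosome[mask],
                         self.position_bp[mask], self.alleles[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_id, "chrom": self.chromosome,
            "pos_bp": self.position_bp,
            "a1": self.alleles[:, 0], "a2": self.alleles[:, 1],
        })


@dataclass
class BreedPanel:
    """Phased haplotypes + map + breed labels and roles.

    ``haplotypes`` is int8, shape (2 * n_individuals, n_markers); entries are
    0/1 allele indices with :data:`MISSING` for missing. Individual ``i`` owns
    rows ``2*i`` and ``2*i + 1``.
    """

    markers: MarkerMap
    haplotypes: np.ndarray
    individual_ids: list[str]
    breed_of: dict[str, str]
    breed_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.individual_ids)
        if self.haplotypes.shape != (2 * n, self.markers.n_markers):
            raise PanelError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"{n} individuals x {self.markers.n_markers} markers")
        missing = [i for i in self.individual_ids if i not in self.breed_of]
        if missing:
            raise PanelError(f"individuals without breed label: {missing[:5]}")
        bad = {b: r for b, r in self.breed_roles.items() if r not in _VALID_ROLES}
        if bad:
            raise PanelError(f"unknown breed roles: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def breeds(self) -> list[str]:
        out = []
        for i in self.individual_ids:
            b = self.breed_of[i]
            if b not in out:
                out.append(b)
        return out

    def role_of(self, breed: str) -> str:
        return self.breed_roles.get(breed, ROLE_SELECTED)

    def calibration_breeds(self) -> list[str]:
        return [b for b in self.breeds() if self.role_of(b) == ROLE_CALIBRATION]

    def selected_breeds(self) -> list[str]:
        return [b for b in self.breeds() if self.role_of(b) == ROLE_SELECTED]

    def individuals_of(self, breed: str) -> list[str]:
        return [i for i in self.individual_ids if self.breed_of[i] == breed]

    def hap_rows(self, breed: str) -> np.ndarray:
        """Row indices of the haplotypes belonging to one breed."""
        idx = [k for k, i in enumerate(self.individual_ids)
               if self.breed_of[i] == breed]
        return np.array([r for k in idx for r in (2 * k, 2 * k + 1)], dtype=int)

    def breed_haplotypes(self, breed: str) -> np.ndarray:
        rows = self.hap_rows(breed)
        if len(rows) == 0:
            raise PanelError(f"breed {breed!r} has no individuals")
        return self.haplotypes[rows]

    def subset(self, individuals: list[str] | None = None,
               marker_mask: np.ndarray | None = None) -> "BreedPanel":
        """Restrict to a subset of individuals and/or a boolean marker mask."""
        panel = self
        if individuals is not None:
            keep = set(individuals)
            pos = [k for k, i in enumerate(panel.individual_ids) if i in keep]
            rows = [r for k in pos for r in (2 * k, 2 * k + 1)]
            ids = [panel.individual_ids[k] for k in pos]
            panel = BreedPanel(panel.markers, panel.haplotypes[rows], ids,
                               {i: panel.breed_of[i] for i in ids},
                               dict(panel.breed_roles))
        if marker_mask is not None:
            panel = BreedPanel(panel.markers.subset(marker_mask),
                               panel.haplotypes[:, marker_mask],
                               list(panel.individual_ids), dict(panel.breed_of),
                               dict(panel.breed_roles))
        return panel

    def to_genotypes(self) -> "GenotypeMatrix":
        return to_genotypes(self)


@dataclass
class GenotypeMatrix:
    """Diploid genotypes coded -1 (hom allele 1), 0 (het), +1 (hom allele 2).

    Missing genotypes (either haplotype missing) carry :data:`GENO_MISSING`.
    ``allele_freq`` is the per-marker frequency of allele 2 over non-missing
    genotypes.
    """

    codes: np.ndarray  # (n_individuals, n_markers), int8
    allele_freq: np.ndarray
    individual_ids: list[str]


GENO_MISSING = np.int8(-9)


def to_genotypes(panel: BreedPanel) -> GenotypeMatrix:
    """Collapse phased haplotypes to -1/0/1 genotype codes.

    The per-individual sum of the two haplotype alleles {0,1,2} is mapped
    0 -> -1, 1 -> 0, 2 -> +1; a missing allele makes the genotype missing.
    """
    h = panel.haplotypes
    h1, h2 = h[0::2], h[1::2]
    s = (h1 + h2).astype(np.int8)
    codes = (s - 1).astype(np.int8)
    miss = (h1 == MISSING) | (h2 == MISSING)
    codes[miss] = GENO_MISSING
    ok = ~miss
    with np.errstate(invalid="ignore"):
        freq = np.where(ok.sum(0) > 0,
                        np.where(miss, 0, s).sum(0) / (2.0 * np.maximum(ok.sum(0), 1)),
                        np.nan)
    return GenotypeMatrix(codes, freq, list(panel.individual_ids))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Marker-removal report: one row per removed marker with a reason code.

    Reason codes, applied in order with first match winning:
    ``no-position``, ``low-maf``, ``low-callrate``.
    """

    removed: pd.DataFrame  # columns: marker_id, chrom, pos_bp, reason
    maf_min: float
    callrate_min: float
    n_input: int

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# maf_min={self.maf_min}\tcallrate_min={self.callrate_min}\n")
            self.removed.to_csv(fh, sep="\t", index=False)


def pooled_maf(panel: BreedPanel) -> np.ndarray:
    """Minor allele frequency per marker over all individuals pooled."""
    h = panel.haplotypes
    ok = h != MISSING
    n = ok.sum(0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, np.where(ok, h, 0).sum(0) / np.maximum(n, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def marker_callrate(panel: BreedPanel) -> np.ndarray:
    """Fraction of individuals with a complete (both-haplotype) call."""
    h = panel.haplotypes
    full = (h[0::2] != MISSING) & (h[1::2] != MISSING)
    return full.mean(0)


def qc_filter(panel: BreedPanel, maf_min: float = 0.0023,
              callrate_min: float = 0.90) -> tuple[BreedPanel, QcReport]:
    """Remove markers with unknown position, MAF < maf_min, or call rate
    < callrate_min (all comparisons strict, so boundary values survive).

    MAF is computed across all individuals pooled over breeds.
    """
    if not (0 <= maf_min <= 1 and 0 <= callrate_min <= 1):
        raise PanelError("QC thresholds must lie in [0, 1]")
    mm = panel.markers
    no_pos = mm.position_bp <= 0
    maf = pooled_maf(panel)
    low_maf = ~no_pos & (np.nan_to_num(maf, nan=0.0) < maf_min)
    cr = marker_callrate(panel)
    low_cr = ~no_pos & ~low_maf & (cr < callrate_min)
    removed_mask = no_pos | low_maf | low_cr
    reason = np.full(mm.n_markers, "", dtype=object)
    reason[no_pos] = "no-position"
    reason[low_maf] = "low-maf"
    reason[low_cr] = "low-callrate"
    removed = pd.DataFrame({
        "marker_id": mm.marker_id[removed_mask],
        "chrom": mm.chromosome[removed_mask],
        "pos_bp": mm.position_bp[removed_mask],
        "reason": reason[removed_mask],
    })
    keep = ~removed_mask
    if not keep.any():
        raise PanelError("no markers retained after QC filtering")
    report = QcReport(removed, maf_min, callrate_min, mm.n_markers)
    return panel.subset(marker_mask=keep), report


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_breed_table(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read the breed sidecar TSV: individual <TAB> breed <TAB> role."""
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str,
                     names=["individual", "breed", "role"], header=None)
    if df.iloc[0, 0].lstrip("#").strip().lower() == "individual":
        df = df.iloc[1:]
    breed_of = dict(zip(df["individual"], df["breed"]))
    roles: dict[str, str] = {}
    for _, row in df.iterrows():
        r = (row["role"] or ROLE_SELECTED).strip()
        if r not in _VALID_ROLES:
            raise PanelError(f"unknown role {r!r} for breed {row['breed']!r}")
        prev = roles.setdefault(row["breed"], r)
        if prev != r:
            raise PanelError(f"conflicting roles for breed {row['breed']!r}")
    return breed_of, roles


def write_breed_table(panel: BreedPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("#individual\tbreed\trole\n")
        for i in panel.individual_ids:
            b = panel.breed_of[i]
            fh.write(f"{i}\t{b}\t{panel.role_of(b)}\n")


def read_panel(path, format: str = "auto", breeds=None) -> BreedPanel:
    """Read a phased panel from haplotype-TSV or phased VCF.

    ``breeds`` is the sidecar breed-table path (required for VCF; for TSV it
    may be omitted only if a ``<path>.breeds.tsv`` sidecar exists).
    Haplotype phase is taken as given; an unphased VCF genotype is an error.
    """
    path = str(path)
    if format == "auto":
        format = "phased-VCF" if path.endswith((".vcf", ".vcf.gz")) else "haplotype-TSV"
    if breeds is None:
        breeds = path + ".breeds.tsv"
    breed_of, roles = read_breed_table(breeds)
    if format == "haplotype-TSV":
        panel = _read_tsv(path, breed_of, roles)
    elif format == "phased-VCF":
        panel = _read_vcf(path, breed_of, roles)
    else:
        raise PanelError(f"unknown panel format {format!r}")
    unknown = [i for i in panel.individual_ids if i not in breed_of]
    if unknown:
        raise PanelError(f"individuals with no breed label: {unknown[:5]}")
    return panel


def _read_tsv(path, breed_of, roles) -> BreedPanel:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise PanelError("haplotype-TSV must start with a '#'-prefixed header")
        cols = header.lstrip("#").strip().split("\t")
        body = pd.read_csv(io.StringIO(fh.read()), sep="\t", names=cols, dtype=str)
    fixed = ["marker_id", "chrom", "pos_bp", "a1", "a2"]
    if cols[:5] != fixed:
        raise PanelError(f"haplotype-TSV header must begin with {fixed}")
    hapcols = cols[5:]
    ids: list[str] = []
    for k in range(0, len(hapcols), 2):
        a, b = hapcols[k], hapcols[k + 1]
        if not (a.endswith("_h1") and b.endswith("_h2") and a[:-3] == b[:-3]):
            raise PanelError(f"haplotype columns must pair as <id>_h1/<id>_h2; got {a}, {b}")
        ids.append(a[:-3])
    mm = MarkerMap(body["marker_id"].to_numpy(dtype=object),
                   body["chrom"].to_numpy(dtype=object),
                   body["pos_bp"].to_numpy(dtype=np.int64),
                   body[["a1", "a2"]].to_numpy(dtype=object))
    raw = body[hapcols].to_numpy(dtype=object).T
    haps = np.where(raw == ".", MISSING, raw).astype(np.int8)
    return BreedPanel(mm, haps, ids, {i: breed_of[i] for i in ids if i in breed_of},
                      roles)


def _read_vcf(path, breed_of, roles) -> BreedPanel:
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids = list(vcf.samples)
    mids, chroms, pos, alleles, rows = [], [], [], [], []
    for var in vcf:
        gts = var.genotypes  # list of [a0, a1, phased]
        col = np.empty(2 * len(ids), dtype=np.int8)
        for k, g in enumerate(gts):
            if len(g) == 2:  # haploid record
                raise PanelError(f"haploid genotype at {var.CHROM}:{var.POS}")
            if not g[2]:
                raise PanelError(
                    f"unphased genotype for sample {ids[k]} at {var.CHROM}:{var.POS}")
            col[2 * k] = MISSING if g[0] < 0 else g[0]
            col[2 * k + 1] = MISSING if g[1] < 0 else g[1]
        if len(var.ALT) != 1:
            raise PanelError(f"non-bi-allelic record at {var.CHROM}:{var.POS}")
        mids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
        alleles.append([var.REF, var.ALT[0]])
        rows.append(col)
    mm = MarkerMap(np.array(mids, dtype=object), np.array(chroms, dtype=object),
                   np.array(pos, dtype=np.int64), np.array(alleles, dtype=object))
    haps = np.array(rows, dtype=np.int8).T
    return BreedPanel(mm, haps, ids, {i: breed_of[i] for i in ids if i in breed_of},
                      roles)


def write_panel(panel: BreedPanel, path, format: str = "auto",
                breeds=None) -> None:
    """Write a panel as haplotype-TSV or plain phased VCF, plus breed sidecar."""
    path = str(path)
    if format == "auto":
        format = "phased-VCF" if path.endswith(".vcf") else "haplotype-TSV"
    if breeds is None:
        breeds = path + ".breeds.tsv"
    write_breed_table(panel, breeds)
    if format == "haplotype-TSV":
        _write_tsv(panel, path)
    elif format == "phased-VCF":
        _write_vcf(panel, path)
    else:
        raise PanelError(f"unknown panel format {format!r}")


def _write_tsv(panel: BreedPanel, path) -> None:
    mm = panel.markers
    hapnames = [f"{i}_h{k}" for i in panel.individual_ids for k in (1, 2)]
    with open(path, "w") as fh:
        fh.write("#marker_id\tchrom\tpos_bp\ta1\ta2\t" + "\t".join(hapnames) + "\n")
        h = panel.haplotypes
        for j in range(mm.n_markers):
            col = ["." if v == MISSING else str(int(v)) for v in h[:, j]]
            fh.write(f"{mm.marker_id[j]}\t{mm.chromosome[j]}\t{mm.position_bp[j]}"
                     f"\t{mm.alleles[j, 0]}\t{mm.alleles[j, 1]}\t" + "\t".join(col) + "\n")


def _write_vcf(panel: BreedPanel, path) -> None:
    mm = panel.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=xpscan\n")
        for c in mm.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.individual_ids) + "\n")
        h = panel.haplotypes
        for j in range(mm.n_markers):
            gts = []
            for k in range(panel.n_individuals):
                a = h[2 * k, j]
                b = h[2 * k + 1, j]
                gts.append(f"{'.' if a == MISSING else int(a)}|"
                           f"{'.' if b == MISSING else int(b)}")
            fh.write(f"{mm.chromosome[j]}\t{mm.position_bp[j]}\t{mm.marker_id[j]}\t"
                     f"{mm.alleles[j, 0]}\t{mm.alleles[j, 1]}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")
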