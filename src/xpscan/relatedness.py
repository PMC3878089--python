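"""Genomic relatedness (unified additive relationships) and iterative pruning.

The UAR estimator weights each marker by its allele frequency: for
individuals j, k and marker i with within-breed allele-2 frequency p_i and
genotype dosage x in {0, 1, 2},

    UAR_jk = mean_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with the companion single-individual diagonal

    UAR_jj = 1 + mean_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i)).

Frequencies are estimated within the breed being examined, so relatedness is
not inflated by population structure. Monomorphic markers are skipped.

Pruning removes one animal per iteration until no within-breed pair reaches
the threshold (default 0.20): the animal with the most partners at/above the
threshold goes first, ties broken by larger maximum UAR, then by later
input order. The removal order is returned for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GENO_MISSING, BreedPanel, PanelError


@dataclass
class RelationshipMatrix:
    """Symmetric UAR matrix for the individuals of one breed."""

    values: np.ndarray
    individual_ids: list[str]
    breed: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids,
                            columns=self.individual_ids)


def uar_matrix(panel: BreedPanel, breed: str) -> RelationshipMatrix:
    """UAR matrix for one breed, from post-QC genotypes.

    Markers monomorphic within the breed (p in {0, 1}) are skipped; a pair's
    average runs over markers where both genotypes are called.
    """
    ids = panel.individuals_of(breed)
    if len(ids) < 2:
        raise PanelError(f"breed {breed!r} needs >= 2 individuals for UAR")
    sub = panel.subset(individuals=ids)
    geno = sub.to_genotypes()
    x = geno.codes.astype(float) + 1.0  # dosage 0/1/2
    called = geno.codes != GENO_MISSING
    x[~called] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(x, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise PanelError(f"all markers monomorphic within breed {breed!r}")
    x = x[:, poly]
    p = p[poly]
    called = called[:, poly]
    denom = 2.0 * p * (1.0 - p)
    w = (np.nan_to_num(x) - 2.0 * p) * called / np.sqrt(denom)
    counts = called.astype(float) @ called.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (w @ w.T) / counts
    # diagonal: single-individual formula
    num = np.nan_to_num(x**2 - (1.0 + 2.0 * p) * x + 2.0 * p**2) * called
    diag_counts = called.sum(axis=1).astype(float)
    diag = 1.0 + (num / denom).sum(axis=1) / diag_counts
    np.fill_diagonal(R, diag)
    return RelationshipMatrix(R, ids, breed)


def prune_related(R: RelationshipMatrix, threshold: float = 0.20
                  ) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the most-related animal until max pairwise UAR < threshold.

    Returns (kept ids, removal log) where the log has one row per iteration:
    iteration, removed_id, max_uar, n_partners.
    """
    vals = R.values.copy().astype(float)
    np.fill_diagonal(vals, -np.inf)
    active = list(range(len(R.individual_ids)))
    log_rows = []
    it = 0
    while len(active) > 1:
        sub = vals[np.ix_(active, active)]
        offending = sub >= threshold
        counts = offending.sum(axis=1)
        if counts.max() == 0:
            break
        maxima = sub.max(axis=1)
        # most partners, then largest max UAR, then latest input order
        best, key = None, None
        for local, gi in enumerate(active):
            cand = (counts[local], maxima[local], gi)
            if key is None or cand >= key:
                best, key = local, cand
        it += 1
        log_rows.append({"iteration": it,
                         "removed_id": R.individual_ids[active[best]],
                         "max_uar": float(maxima[best]),
                         "n_partners": int(counts[best])})
        del active[best]
    if len(active) == 1:
        warnings.warn(f"pruning of breed {R.breed!r} left a single individual")
    kept = [R.individual_ids[i] for i in active]
    log = pd.DataFrame(log_rows, columns=["iteration", "removed_id",
                                          "max_uar", "n_partners"])
    return kept, log


def prune_panel(panel: BreedPanel, threshold: float = 0.20
                ) -> tuple[BreedPanel, dict[str, pd.DataFrame]]:
    """Apply within-breed UAR pruning to every breed of a panel."""
    kept_all: list[str] = []
    logs: dict[str, pd.DataFrame] = {}
    for breed in panel.breeds():
        R = uar_matrix(panel, breed)
        kept, log = prune_related(R, threshold)
        kept_all.extend(kept)
        logs[breed] = log
    order = {i: k for k, i in enumerate(panel.individual_ids)}
    kept_all.sort(key=order.get)
    return panel.subset(individuals=kept_all), logs
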