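"""Pairwise genotypic linkage disequilibrium (r²) and LD pruning.

r² here is the squared Pearson correlation of allele-dosage vectors over the
samples that are non-missing at both loci ("composite"/genotypic LD).  It is
phase-free, which is what unphased reduced-representation genotypes support,
and it is symmetric and invariant to allele relabeling (dosage -> 2 - dosage).

All locus pairs are considered regardless of scaffold or distance: with
thousands of short scaffolds, linkage must be detectable among markers whose
physical relationship is unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .io import MISSING, GenotypeMatrix
from .qc import minor_allele_frequency

logger = logging.getLogger(__name__)


@dataclass
class LDEdgeList:
    """Sparse upper-triangular list of locus pairs with r² >= ``min_r2_stored``."""

    a: np.ndarray  # locus indices, a < b
    b: np.ndarray
    r2: np.ndarray
    n_loci: int
    min_r2_stored: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.b = np.asarray(self.b, dtype=np.int64)
        self.r2 = np.asarray(self.r2, dtype=float)
        if not (self.a < self.b).all():
            raise ValueError("edges must satisfy a < b")
        if self.r2.size and (self.r2.min() < 0 or self.r2.max() > 1 + 1e-9):
            raise ValueError("r2 outside [0, 1]")

    def __len__(self) -> int:
        return len(self.r2)

    def to_dataframe(self, locus_ids=None) -> pd.DataFrame:
        if locus_ids is not None:
            locus_ids = np.asarray(locus_ids)
            ida, idb = locus_ids[self.a], locus_ids[self.b]
        else:
            ida, idb = self.a, self.b
        return pd.DataFrame({"locus_id_a": ida, "locus_id_b": idb, "r2": self.r2})

    def to_tsv(self, path, locus_ids=None) -> None:
        self.to_dataframe(locus_ids).to_csv(path, sep="\t", index=False)

    def dense(self) -> np.ndarray:
        """Symmetric dense r² matrix; absent edges are 0, diagonal 1."""
        R = np.zeros((self.n_loci, self.n_loci))
        R[self.a, self.b] = self.r2
        R[self.b, self.a] = self.r2
        np.fill_diagonal(R, 1.0)
        return R


def _dosages(gm) -> np.ndarray:
    return gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm)


def r2_matrix(gm) -> np.ndarray:
    """Full pairwise complete-case genotypic r² matrix.

    Entry (i, j) is the squared Pearson correlation of dosages at loci i and j
    over samples called at both.  Pairs with fewer than two complete cases or a
    monomorphic locus over the complete cases are NaN.  Computed with masked
    cross-products, so it stays a handful of matrix multiplications.
    """
    X = _dosages(gm)
    if X.shape[1] < 2:
        raise ValueError("need at least two loci")
    M = (X != MISSING).astype(np.float64)  # samples x loci indicator
    V = np.where(X == MISSING, 0, X).astype(np.float64)
    V2 = V * V

    n = M.T @ M                     # complete cases per pair
    sx = V.T @ M                    # sum of x over pair-complete cases
    sxx = V2.T @ M
    sxy = V.T @ V

    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx * sx    # var of locus i over cases complete with j
        vary = varx.T
        denom = varx * vary
        r2 = np.where(denom > 0, cov * cov / denom, np.nan)
    r2[n < 2] = np.nan
    # clip tiny overshoots from floating point
    np.clip(r2, 0.0, 1.0, out=r2)
    return r2


def pairwise_r2(gm, min_r2_stored: float = 0.1) -> LDEdgeList:
    """All locus pairs with r² >= ``min_r2_stored`` as an :class:`LDEdgeList`.

    Degenerate pairs (monomorphic over complete cases, or < 2 complete cases)
    are skipped with a logged count.
    """
    R = r2_matrix(gm)
    n_loci = R.shape[0]
    iu = np.triu_indices(n_loci, k=1)
    vals = R[iu]
    n_degenerate = int(np.isnan(vals).sum())
    if n_degenerate:
        logger.info("pairwise_r2: skipped %d degenerate pairs", n_degenerate)
    keep = ~np.isnan(vals) & (vals >= min_r2_stored)
    return LDEdgeList(
        a=iu[0][keep],
        b=iu[1][keep],
        r2=vals[keep],
        n_loci=n_loci,
        min_r2_stored=min_r2_stored,
    )


class LDPruner(SelectorMixin, BaseEstimator):
    """Greedy LD pruning: feature selector keeping a set with max pairwise r² <= cutoff.

    Loci are swept in a caller-supplied order (genome order when driven from a
    :class:`~ldcohorts.io.GenotypeMatrix`; column order otherwise).  A locus is
    removed when its r² with any already-retained locus strictly exceeds
    ``r2_cutoff``.  ``tie="first"`` keeps the earlier locus in the sweep;
    ``tie="maf"`` re-orders the sweep by descending MAF so the more informative
    member of a linked pair survives.
    """

    def __init__(self, r2_cutoff: float = 0.5, tie: str = "first"):
        self.r2_cutoff = r2_cutoff
        self.tie = tie

    def fit(self, X, y=None, order=None):
        X = np.asarray(X)
        n_loci = X.shape[1]
        self.n_features_in_ = n_loci
        if order is None:
            order = np.arange(n_loci)
        else:
            order = np.asarray(order)
        if self.tie == "maf":
            maf = minor_allele_frequency(X)
            order = order[np.argsort(-maf[order], kind="stable")]
        elif self.tie != "first":
            raise ValueError(f"unknown tie rule {self.tie!r}")

        R = r2_matrix(X)
        R = np.nan_to_num(R, nan=0.0)
        keep = np.zeros(n_loci, dtype=bool)
        retained: list[int] = []
        for j in order:
            if not retained or R[j, retained].max() <= self.r2_cutoff:
                keep[j] = True
                retained.append(j)
        self.support_ = keep
        return self

    def _get_support_mask(self):
        return self.support_


def ld_prune(gm: GenotypeMatrix, r2_cutoff: float = 0.5, tie: str = "first"):
    """Prune a genotype matrix in genome order (scaffold, then position).

    Returns ``(retained locus ids, removed locus ids)`` as lists.
    """
    est = LDPruner(r2_cutoff=r2_cutoff, tie=tie).fit(gm.dosages, order=gm.genome_order())
    ids = gm.locus_ids
    return list(ids[est.support_]), list(ids[~est.support_])
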