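"""Integration of PCA loading cohorts with LD-network clusters, per-scaffold
summaries, between-group allele-frequency differentials, and SNP-based sex
imputation.

In a neo-XY system, X/Y paralogous loci make the heterogametic sex (males)
appear constitutively heterozygous, so the fraction of heterozygous calls over
a sex-linked cohort separates the sexes into two clusters sitting near 1 and
near 0; any mid threshold tells them apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import MISSING, GenotypeMatrix

DEFAULT_BINS = ((1, 2), (3, 5), (6, 9), (10, 14), (15, None))


# ---------------------------------------------------------------------------
# cohort x cluster overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapTable:
    """Shared-locus counts between PC cohorts (rows) and LD clusters (columns)."""

    counts: pd.DataFrame            # rows: cohort names, cols: cluster names
    cluster_sizes: pd.Series
    cohort_sizes: pd.Series

    @property
    def pct_of_cluster(self) -> pd.DataFrame:
        """Shared / cluster size x 100 (the reporting direction used for the
        100%/99%/100% correspondence); columns with empty clusters are NaN."""
        return self.counts.div(self.cluster_sizes, axis=1) * 100.0

    @property
    def pct_of_cohort(self) -> pd.DataFrame:
        return self.counts.div(self.cohort_sizes, axis=0) * 100.0

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.to_dict(),
            "pct_of_cluster": self.pct_of_cluster.round(4).to_dict(),
            "pct_of_cohort": self.pct_of_cohort.round(4).to_dict(),
        }


def overlap_table(pc_cohorts: dict, ld_clusters: dict) -> OverlapTable:
    """Exact set-intersection counts between named locus sets."""
    pc = {k: set(v) for k, v in pc_cohorts.items()}
    ld = {k: set(v) for k, v in ld_clusters.items()}
    counts = pd.DataFrame(
        {cl: {co: len(pc[co] & ld[cl]) for co in pc} for cl in ld}, dtype=int
    )
    counts = counts.reindex(index=list(pc), columns=list(ld))
    return OverlapTable(
        counts=counts,
        cluster_sizes=pd.Series({k: len(v) for k, v in ld.items()}),
        cohort_sizes=pd.Series({k: len(v) for k, v in pc.items()}),
    )


# ---------------------------------------------------------------------------
# scaffold summaries
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldSummary:
    """Distribution of a cohort's SNPs over scaffolds, with density bins."""

    per_scaffold: pd.Series          # scaffold -> SNP count, descending
    binned: pd.DataFrame             # bin label, n_scaffolds, n_snps
    total_snps: int
    total_scaffolds: int

    def top_share(self, k: int) -> float:
        """Fraction of cohort SNPs on the k most SNP-dense scaffolds.

        Ties are broken by scaffold id (ascending) for determinism.
        """
        return float(self.per_scaffold.iloc[:k].sum()) / self.total_snps

    def to_dict(self) -> dict:
        return {
            "total_snps": self.total_snps,
            "total_scaffolds": self.total_scaffolds,
            "bins": self.binned.to_dict(orient="records"),
            "per_scaffold": self.per_scaffold.to_dict(),
        }


def _bin_label(lo: int, hi) -> str:
    return f">={lo}" if hi is None else f"{lo}-{hi}"


def scaffold_summary(
    cohort_locus_ids, loci: pd.DataFrame, bins=DEFAULT_BINS
) -> ScaffoldSummary:
    """Per-scaffold counts and density-binned totals for a cohort of loci.

    ``loci`` must carry ``locus_id`` and ``scaffold`` columns covering every
    cohort member.  Bin SNP counts sum to the cohort size and bin scaffold
    counts to the number of distinct scaffolds (conservation).
    """
    wanted = set(cohort_locus_ids)
    sub = loci[loci["locus_id"].isin(wanted)]
    if len(sub) != len(wanted):
        missing = wanted - set(sub["locus_id"])
        raise ValueError(f"loci without scaffold metadata: {sorted(missing)[:5]} ...")
    counts = sub.groupby("scaffold").size()
    # descending by count, ties by scaffold id ascending
    counts = counts.sort_index().sort_values(ascending=False, kind="stable")
    rows = []
    for lo, hi in bins:
        in_bin = (counts >= lo) & (counts <= (hi if hi is not None else np.inf))
        rows.append(
            {
                "bin": _bin_label(lo, hi),
                "n_scaffolds": int(in_bin.sum()),
                "n_snps": int(counts[in_bin].sum()),
            }
        )
    binned = pd.DataFrame(rows)
    return ScaffoldSummary(
        per_scaffold=counts,
        binned=binned,
        total_snps=int(counts.sum()),
        total_scaffolds=int(len(counts)),
    )


def top_share_from_bins(binned: pd.DataFrame, n_scaffolds: int) -> float:
    """Top-k scaffold share computed from density-binned rows alone.

    Accumulates whole bins from the densest down until ``n_scaffolds``
    scaffolds are covered; if the target falls inside a bin, that bin's SNPs
    are apportioned at its average density.  Exact whenever the target aligns
    with bin boundaries, which is how the printed concentration figures are
    bookkept.
    """
    total = float(binned["n_snps"].sum())
    if total == 0:
        raise ValueError("empty binned table")
    got_snps = 0.0
    remaining = n_scaffolds
    for _, row in binned.iloc[::-1].iterrows():  # densest bin last in table
        if remaining <= 0:
            break
        ns, nsnp = int(row["n_scaffolds"]), float(row["n_snps"])
        if ns == 0:
            continue
        take = min(ns, remaining)
        got_snps += nsnp * (take / ns)
        remaining -= take
    return got_snps / total


# ---------------------------------------------------------------------------
# sex imputation from cohort heterozygosity
# ---------------------------------------------------------------------------

class HeterozygositySexClassifier(ClassifierMixin, BaseEstimator):
    """Call sample sex from the heterozygous fraction over a locus cohort.

    For each sample, the fraction of heterozygous calls (dosage 1) among
    non-missing calls over ``cohort`` loci is computed; above
    ``threshold + dead_zone/2`` the sample is called male (heterogametic),
    below ``threshold - dead_zone/2`` female, otherwise ambiguous.  Samples
    with no called cohort genotype are ambiguous.
    """

    def __init__(self, cohort=None, threshold: float = 0.5, dead_zone: float = 0.0):
        self.cohort = cohort
        self.threshold = threshold
        self.dead_zone = dead_zone

    def fit(self, X, y=None):
        X = np.asarray(X)
        self.n_features_in_ = X.shape[1]
        self.cohort_ = (
            np.arange(X.shape[1]) if self.cohort is None else np.asarray(self.cohort)
        )
        if self.cohort_.size == 0:
            raise ValueError("cohort is empty")
        self.classes_ = np.array(["ambiguous", "female", "male"])
        return self

    def het_fraction(self, X) -> np.ndarray:
        """Per-sample heterozygous fraction over cohort loci (NaN if no calls)."""
        sub = np.asarray(X)[:, self.cohort_]
        called = (sub != MISSING).sum(axis=1)
        het = (sub == 1).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(called > 0, het / called, np.nan)

    def predict(self, X) -> np.ndarray:
        frac = self.het_fraction(X)
        hi = self.threshold + self.dead_zone / 2.0
        lo = self.threshold - self.dead_zone / 2.0
        out = np.full(len(frac), "ambiguous", dtype=object)
        out[frac > hi] = "male"
        out[frac < lo] = "female"
        return out


def heterozygosity_sex_call(
    gm: GenotypeMatrix,
    cohort_locus_ids,
    male_threshold: float = 0.5,
    dead_zone: float = 0.0,
) -> pd.DataFrame:
    """Sex calls for every sample; returns sample_id, het_fraction, call."""
    idx = _cohort_indices(gm, cohort_locus_ids)
    clf = HeterozygositySexClassifier(
        cohort=idx, threshold=male_threshold, dead_zone=dead_zone
    ).fit(gm.dosages)
    frac = clf.het_fraction(gm.dosages)
    return pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "het_fraction": frac,
            "call": clf.predict(gm.dosages),
        }
    )


def _cohort_indices(gm: GenotypeMatrix, cohort_locus_ids) -> np.ndarray:
    wanted = set(cohort_locus_ids)
    if not wanted:
        raise ValueError("cohort is empty")
    idx = np.flatnonzero(np.isin(gm.locus_ids, list(wanted)))
    if len(idx) != len(wanted):
        missing = wanted - set(gm.locus_ids[idx])
        raise ValueError(f"cohort loci absent from matrix: {sorted(missing)[:5]} ...")
    return idx


# ---------------------------------------------------------------------------
# between-group allele-frequency differential
# ---------------------------------------------------------------------------

def group_allele_freq_diff(
    gm: GenotypeMatrix, cohort_locus_ids, grouping=None
) -> tuple[pd.DataFrame, dict]:
    """|alt-allele frequency difference| between two sample groups per cohort locus.

    ``grouping`` maps sample_id -> label (defaults to the matrix's ``group``
    column); exactly two labels must be present among mapped samples.  Loci
    where either group has zero non-missing calls are flagged and excluded
    from the summary.  Returns (per-locus table, summary dict with
    median/mean over clean loci).
    """
    idx = _cohort_indices(gm, cohort_locus_ids)
    if grouping is None:
        labels = gm.samples["group"]
    else:
        labels = gm.samples["sample_id"].map(grouping)
    labels = labels.to_numpy(dtype=object)
    present = pd.unique(labels[pd.notna(labels)])
    if len(present) != 2:
        raise ValueError(f"need exactly two group labels, found {list(present)}")
    g1, g2 = sorted(map(str, present))

    rows = []
    for j in idx:
        col = gm.dosages[:, j]
        freqs = {}
        for g in (g1, g2):
            vals = col[(labels == g) & (col != MISSING)]
            freqs[g] = vals.sum() / (2.0 * len(vals)) if len(vals) else np.nan
        rows.append(
            {
                "locus_id": gm.locus_ids[j],
                f"freq_{g1}": freqs[g1],
                f"freq_{g2}": freqs[g2],
                "abs_diff": abs(freqs[g1] - freqs[g2]),
            }
        )
    table = pd.DataFrame(rows)
    clean = table["abs_diff"].dropna()
    if clean.empty:
        raise ValueError("no locus with calls in both groups")
    summary = {
        "groups": [g1, g2],
        "n_loci": int(len(table)),
        "n_excluded": int(table["abs_diff"].isna().sum()),
        "median_abs_diff": float(clean.median()),
        "mean_abs_diff": float(clean.mean()),
    }
    return table, summary


# ---------------------------------------------------------------------------
# cohort totals with designated de-duplication
# ---------------------------------------------------------------------------

def cohort_totals(cohorts: dict, dedup_pairs=()) -> dict:
    """Sizes, pairwise shared counts, and a de-duplicated grand total.

    ``dedup_pairs`` is an iterable of ``(counted_under, removed_from)`` cohort
    name pairs: loci shared between the two are counted once, under
    ``counted_under`` (the convention used when a later axis subsumes loci it
    shares with an earlier one).  The grand total is the sum of the adjusted
    sizes; ``union`` is the plain union size for cross-checking.
    """
    sets = {k: set(v) for k, v in cohorts.items()}
    names = list(sets)
    shared = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    adjusted = {k: set(v) for k, v in sets.items()}
    for keep, strip in dedup_pairs:
        adjusted[strip] = adjusted[strip] - sets[keep]
    return {
        "sizes": {k: len(v) for k, v in sets.items()},
        "adjusted_sizes": {k: len(v) for k, v in adjusted.items()},
        "pairwise_shared": {f"{a}&{b}": v for (a, b), v in shared.items()},
        "grand_total": sum(len(v) for v in adjusted.values()),
        "union": len(set().union(*sets.values())) if sets else 0,
    }
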