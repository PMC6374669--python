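"""Sample- and locus-level quality-control filters.

Three-tier filtering of a SNP genotype matrix:

1. sample filter — drop individuals missing more than ``sample_max_missing`` of
   their calls, assessed over loci pre-filtered to ``locus_prefilter_missing``
   maximum missingness;
2. locus filter — drop loci with missingness above ``locus_max_missing`` or
   minor allele frequency below ``min_maf`` (the "5%-only" treatment at the
   defaults);
3. Hardy–Weinberg filter — drop loci whose exact-test p-value falls below a
   Bonferroni-style absolute threshold (the "FF" treatment once combined with
   LD pruning, see :mod:`ldcohorts.ld`).

Inequality directions are literal: a locus is removed if missingness > 0.05 or
MAF < 0.05 or HWE p < 2.5e-5; boundary values are retained.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .io import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# configuration and report containers
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Thresholds for the three-tier filter.

    ``hwe_bonferroni_p`` is an absolute p-value cutoff (the printed,
    pre-corrected threshold).  Set it to ``None`` to use ``hwe_alpha / n_tests``
    instead.
    """

    sample_max_missing: float = 0.20
    locus_prefilter_missing: float = 0.20
    locus_max_missing: float = 0.05
    min_maf: float = 0.05
    hwe_alpha: float = 0.05
    hwe_bonferroni_p: float | None = 2.5e-5

    def __post_init__(self) -> None:
        for name in (
            "sample_max_missing",
            "locus_prefilter_missing",
            "locus_max_missing",
            "min_maf",
            "hwe_alpha",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.hwe_bonferroni_p is not None and not 0.0 < self.hwe_bonferroni_p <= 1.0:
            raise ValueError("hwe_bonferroni_p outside (0, 1]")


@dataclass
class FilterStage:
    name: str
    axis: str  # "samples" or "loci"
    n_input: int
    n_removed: int
    n_retained: int
    removed_ids: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed + self.n_retained:
            raise ValueError(
                f"stage {self.name}: {self.n_input} != "
                f"{self.n_removed} removed + {self.n_retained} retained"
            )


@dataclass
class FilterReport:
    """Ordered record of filter stages; counts reconcile exactly per stage."""

    stages: list = field(default_factory=list)

    def add(self, stage: FilterStage) -> None:
        self.stages.append(stage)

    def extend(self, other: "FilterReport") -> None:
        self.stages.extend(other.stages)

    def stage(self, name: str) -> FilterStage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {"stages": [asdict(s) for s in self.stages]}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        """Human-readable filter table (treatment, axis, removed, retained)."""
        lines = [f"{'stage':<22}{'axis':<10}{'input':>8}{'removed':>9}{'retained':>10}"]
        for s in self.stages:
            lines.append(
                f"{s.name:<22}{s.axis:<10}{s.n_input:>8}{s.n_removed:>9}{s.n_retained:>10}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def _dosage_array(gm) -> np.ndarray:
    return gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm)


def locus_missingness(gm) -> np.ndarray:
    """Fraction of samples with a missing call at each locus, in [0, 1]."""
    X = _dosage_array(gm)
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    return (X == MISSING).mean(axis=0)


def minor_allele_frequency(gm) -> np.ndarray:
    """Per-locus minor allele frequency over non-missing calls, in [0, 0.5].

    A locus with zero non-missing calls gets NaN (undefined; treated as
    failing any MAF filter).
    """
    X = _dosage_array(gm)
    called = X != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, X, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return np.minimum(p, 1.0 - p)


def genotype_counts(gm) -> np.ndarray:
    """Per-locus (n_hom_ref, n_het, n_hom_alt) counts over non-missing calls."""
    X = _dosage_array(gm)
    return np.stack([(X == d).sum(axis=0) for d in (0, 1, 2)], axis=1)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact test for departure from Hardy–Weinberg proportions.

    Conditional on the observed allele counts, enumerates every heterozygote
    count of the same parity and sums the probabilities of all configurations
    no more probable than the observed one.  Returns p in (0, 1]; a
    monomorphic locus (single attainable configuration) gives exactly 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)

    # log P(het = h | n, n_minor) up to a shared constant:
    #   P(h) = n! 2^h / (n_hom_min! h! n_hom_maj!) / C(2n, n_minor)
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    valid = hom_major >= 0
    hs, hom_minor, hom_major = hs[valid], hom_minor[valid], hom_major[valid]
    lgamma = np.vectorize(math.lgamma)
    logp = hs * math.log(2.0) - (
        lgamma(hom_minor + 1.0) + lgamma(hs + 1.0) + lgamma(hom_major + 1.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hs == n_het][0]
    # tolerance guards against ties lost to floating point
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_test_chisq(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-degree-of-freedom chi-square HWE test (large-sample alternative)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped individuals")
    p = (2 * n_hom_ref + n_het) / (2.0 * n)
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    if (expected == 0).any():
        return 1.0
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = ((observed - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(gm, method: str = "exact") -> np.ndarray:
    """Per-locus HWE p-values; loci with zero calls get NaN."""
    counts = genotype_counts(gm)
    test = hwe_test if method == "exact" else hwe_test_chisq
    out = np.empty(len(counts))
    for j, (aa, ab, bb) in enumerate(counts):
        out[j] = test(int(aa), int(ab), int(bb)) if aa + ab + bb > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class LocusQCFilter(SelectorMixin, BaseEstimator):
    """Feature (locus) selector on missingness, MAF and optional HWE p-value.

    Parameters
    ----------
    max_missing : drop loci with missingness strictly above this fraction.
    min_maf : drop loci with MAF strictly below this fraction (NaN MAF fails).
    hwe_p : absolute p-value floor for the exact HWE test, or None to skip
        the HWE stage.
    hwe_method : "exact" (default) or "chisq".
    """

    def __init__(self, max_missing=0.05, min_maf=0.05, hwe_p=None, hwe_method="exact"):
        self.max_missing = max_missing
        self.min_maf = min_maf
        self.hwe_p = hwe_p
        self.hwe_method = hwe_method

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("X must be a non-empty samples x loci array")
        self.n_features_in_ = X.shape[1]
        self.missingness_ = locus_missingness(X)
        self.maf_ = minor_allele_frequency(X)
        pass_mm = self.missingness_ <= self.max_missing
        pass_maf = np.where(np.isnan(self.maf_), False, self.maf_ >= self.min_maf)
        self.support_5pct_ = pass_mm & pass_maf
        if self.hwe_p is not None:
            self.hwe_p_ = hwe_pvalues(X, method=self.hwe_method)
            pass_hwe = np.where(np.isnan(self.hwe_p_), False, self.hwe_p_ >= self.hwe_p)
            self.support_ = self.support_5pct_ & pass_hwe
        else:
            self.hwe_p_ = None
            self.support_ = self.support_5pct_
        return self

    def _get_support_mask(self):
        return self.support_


class SampleQCFilter(BaseEstimator):
    """Row (sample) filter on per-sample missingness.

    Missingness is assessed over the loci whose own missingness does not
    exceed ``locus_prefilter_missing``; a sample is dropped when its missing
    fraction over those loci strictly exceeds ``max_missing``.
    """

    def __init__(self, max_missing=0.20, locus_prefilter_missing=0.20):
        self.max_missing = max_missing
        self.locus_prefilter_missing = locus_prefilter_missing

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("X must be a non-empty samples x loci array")
        self.n_features_in_ = X.shape[1]
        locus_ok = locus_missingness(X) <= self.locus_prefilter_missing
        if not locus_ok.any():
            # degenerate prefilter: fall back to all loci
            locus_ok = np.ones(X.shape[1], dtype=bool)
        sub = X[:, locus_ok]
        self.sample_missingness_ = (sub == MISSING).mean(axis=1)
        self.sample_support_ = self.sample_missingness_ <= self.max_missing
        if not self.sample_support_.any():
            raise ValueError("all samples exceed the missingness threshold")
        return self

    def transform(self, X):
        return np.asarray(X)[self.sample_support_]


# ---------------------------------------------------------------------------
# GenotypeMatrix-level operations
# ---------------------------------------------------------------------------

def filter_samples(gm: GenotypeMatrix, cfg: FilterConfig | None = None):
    """Drop high-missingness samples; returns (matrix with all loci, report)."""
    cfg = cfg or FilterConfig()
    est = SampleQCFilter(
        max_missing=cfg.sample_max_missing,
        locus_prefilter_missing=cfg.locus_prefilter_missing,
    ).fit(gm.dosages)
    keep = est.sample_support_
    report = FilterReport()
    report.add(
        FilterStage(
            name="sample_missingness",
            axis="samples",
            n_input=gm.n_samples,
            n_removed=int((~keep).sum()),
            n_retained=int(keep.sum()),
            removed_ids=list(gm.sample_ids[~keep]),
            params={
                "sample_max_missing": cfg.sample_max_missing,
                "locus_prefilter_missing": cfg.locus_prefilter_missing,
            },
        )
    )
    return gm.subset(sample_mask=keep), report


def apply_locus_filters(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None, hwe: bool = True
):
    """Sequential locus filtering: missingness+MAF, then (optionally) HWE.

    Returns ``(filtered matrix, FilterReport)``.  With ``hwe=False`` the result
    is the "5%-only" treatment; with ``hwe=True`` it only remains to LD-prune
    to obtain the fully filtered ("FF") marker set.
    """
    cfg = cfg or FilterConfig()
    hwe_p = None
    if hwe:
        hwe_p = (
            cfg.hwe_bonferroni_p
            if cfg.hwe_bonferroni_p is not None
            else cfg.hwe_alpha / gm.n_loci
        )
    est = LocusQCFilter(
        max_missing=cfg.locus_max_missing, min_maf=cfg.min_maf, hwe_p=hwe_p
    ).fit(gm.dosages)

    report = FilterReport()
    ids = gm.locus_ids
    keep5 = est.support_5pct_
    report.add(
        FilterStage(
            name="locus_missingness_maf",
            axis="loci",
            n_input=gm.n_loci,
            n_removed=int((~keep5).sum()),
            n_retained=int(keep5.sum()),
            removed_ids=list(ids[~keep5]),
            params={"locus_max_missing": cfg.locus_max_missing, "min_maf": cfg.min_maf},
        )
    )
    keep = est.support_
    if hwe:
        removed_hwe = keep5 & ~keep
        report.add(
            FilterStage(
                name="hwe",
                axis="loci",
                n_input=int(keep5.sum()),
                n_removed=int(removed_hwe.sum()),
                n_retained=int(keep.sum()),
                removed_ids=list(ids[removed_hwe]),
                params={"hwe_p": hwe_p},
            )
        )
    if not keep.any():
        stage = "hwe" if hwe else "locus_missingness_maf"
        raise ValueError(f"no loci survive filtering (failed at stage {stage!r})")
    return gm.subset(locus_mask=keep), report
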