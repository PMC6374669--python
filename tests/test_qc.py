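import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldcohorts.io import MISSING
from ldcohorts.qc import (
    FilterConfig,
    apply_locus_filters,
    filter_samples,
    hwe_test,
    hwe_test_chisq,
    locus_missingness,
    minor_allele_frequency,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracle: exact HWE by rational-arithmetic enumeration
# ---------------------------------------------------------------------------

def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE p-value with Fraction weights (no floats)."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)

    def weight(h):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_minor < 0 or hom_major < 0:
            return None
        return Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_minor) * math.factorial(h) * math.factorial(hom_major),
        )

    weights = {h: w for h in range(n_minor % 2, n_minor + 1, 2) if (w := weight(h))}
    total = sum(weights.values())
    w_obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= w_obs) / total)


HWE_CASES = [
    (57, 14, 50),   # strong heterozygote deficit
    (107, 68, 0),   # heterozygote excess, no alt homozygote
    (10, 21, 10),
    (0, 1, 0),
    (25, 50, 25),
    (3, 0, 3),
    (90, 9, 1),
    (68, 28, 4),    # n = 100, near-HWE
]


@pytest.mark.parametrize("counts", HWE_CASES)
def test_hwe_exact_matches_enumeration(counts):
    """hwe_test equals full rational enumeration over heterozygote counts."""
    assert hwe_test(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-9)


def test_hwe_exact_enumeration_sweep():
    """Systematic agreement with the enumeration oracle up to n = 200."""
    rng = np.random.default_rng(0)
    for _ in range(40):
        n = int(rng.integers(1, 201))
        aa = int(rng.integers(0, n + 1))
        ab = int(rng.integers(0, n - aa + 1))
        bb = n - aa - ab
        assert hwe_test(aa, ab, bb) == pytest.approx(hwe_oracle(aa, ab, bb), rel=1e-9)


def test_hwe_monomorphic_is_one():
    assert hwe_test(42, 0, 0) == 1.0
    assert hwe_test(0, 0, 17) == 1.0


def test_hwe_pvalue_unimodal_in_het_count():
    """With allele counts fixed, p is maximal near 2pq*n and falls toward the
    extremes of the attainable heterozygote range."""
    n, n_minor = 50, 30
    hs = list(range(n_minor % 2, n_minor + 1, 2))
    ps = []
    for h in hs:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        ps.append(hwe_test(hom_major, h, hom_minor))
    p = n_minor / (2 * n)
    mode = max(hs, key=lambda h: ps[hs.index(h)])
    expected_mode = 2 * p * (1 - p) * n
    assert abs(mode - expected_mode) <= 2
    k = hs.index(mode)
    assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(k))
    assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(k, len(hs) - 1))


@given(
    st.integers(min_value=0, max_value=80),
    st.integers(min_value=0, max_value=80),
    st.integers(min_value=0, max_value=80),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_hwe_properties(aa, ab, bb):
    """p in (0, 1] and invariant to swapping the homozygote classes."""
    if aa + ab + bb == 0:
        return
    p = hwe_test(aa, ab, bb)
    assert 0 < p <= 1
    assert p == pytest.approx(hwe_test(bb, ab, aa), rel=1e-9)


def test_hwe_chisq_within_order_of_magnitude():
    """Exact and chi-square tests agree within an order of magnitude for
    large samples with adequate expected counts."""
    for counts in [(120, 60, 20), (300, 150, 50), (68, 28, 4)]:
        pe, pc = hwe_test(*counts), hwe_test_chisq(*counts)
        if pe > 1e-12:
            assert 0.1 <= pc / pe <= 10


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def test_locus_missingness_values():
    X = np.zeros((8, 3), dtype=int)
    X[0, 1] = MISSING
    X[:, 2] = MISSING
    np.testing.assert_allclose(locus_missingness(X), [0.0, 1 / 8, 1.0])


def test_maf_examples_and_brute_force():
    assert minor_allele_frequency(np.array([[0], [0], [1], [2]]))[0] == pytest.approx(0.375)
    assert minor_allele_frequency(np.array([[0], [0], [0], [0]]))[0] == 0.0
    assert np.isnan(minor_allele_frequency(np.full((4, 1), MISSING))[0])

    rng = np.random.default_rng(3)
    col = rng.integers(0, 3, size=50).astype(np.int8)
    col[rng.random(50) < 0.1] = MISSING
    # brute-force: enumerate both alleles of every called genotype
    alleles = []
    for d in col:
        if d != MISSING:
            alleles += [1] * d + [0] * (2 - d)
    p = np.mean(alleles)
    expected = min(p, 1 - p)
    assert minor_allele_frequency(col[:, None])[0] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def test_sample_filter_brute_force_10x10():
    """Retained samples equal an exhaustive per-sample missingness recount."""
    rng = np.random.default_rng(7)
    X = rng.integers(0, 3, size=(10, 10)).astype(np.int8)
    # locus 0 very gappy (prefiltered out); samples 3,4 gappy elsewhere
    X[:, 0] = MISSING
    X[3, 1:8] = MISSING
    X[4, 1:4] = MISSING
    gm = make_matrix(X)
    cfg = FilterConfig()
    filtered, report = filter_samples(gm, cfg)

    keep_loci = (X == MISSING).mean(axis=0) <= cfg.locus_prefilter_missing
    expected_keep = [
        i
        for i in range(10)
        if (X[i, keep_loci] == MISSING).mean() <= cfg.sample_max_missing
    ]
    assert list(filtered.sample_ids) == [f"s{i:03d}" for i in expected_keep]
    assert filtered.n_loci == gm.n_loci  # loci untouched by the sample stage
    st = report.stage("sample_missingness")
    assert st.n_removed + st.n_retained == st.n_input


def test_locus_filter_planted_truth():
    """100 loci with 20 planted low-MAF and 10 planted gappy loci: the
    missingness+MAF stage retains exactly the 70 clean ones."""
    rng = np.random.default_rng(11)
    n = 60
    clean = rng.binomial(2, 0.4, size=(n, 70)).astype(np.int8)
    low_maf = np.zeros((n, 20), dtype=np.int8)
    low_maf[0, :] = 1  # one het in 60 -> MAF 1/120 < 0.05
    gappy = rng.binomial(2, 0.4, size=(n, 10)).astype(np.int8)
    gappy[: int(0.2 * n)] = MISSING  # 20% missing > 5%
    X = np.concatenate([clean, low_maf, gappy], axis=1)
    gm = make_matrix(X)
    out, report = apply_locus_filters(gm, FilterConfig(), hwe=False)
    assert set(out.locus_ids) == set(gm.locus_ids[:70])
    st = report.stage("locus_missingness_maf")
    assert st.n_removed == 30 and st.n_retained == 70


def test_boundary_values_are_retained():
    """Missingness of exactly 0.05 and MAF of exactly 0.05 survive (strict
    inequalities in the removal rule)."""
    n = 40
    X = np.zeros((n, 2), dtype=np.int8)
    X[:2, 0] = MISSING          # missingness exactly 0.05
    X[2:18, 0] = 1              # keep MAF comfortable: 16/76 ~ 0.21
    X[:4, 1] = 1                # MAF exactly 4/80 = 0.05
    gm = make_matrix(X)
    out, _ = apply_locus_filters(gm, FilterConfig(), hwe=False)
    assert out.n_loci == 2


def test_sex_paralogue_pattern_survives_hwe():
    """A locus where 39% of 175 samples are heterozygous and the rest
    homozygous-reference shows excess heterozygosity with exact p well above
    the 2.5e-5 cutoff — the sex cohort survives HWE filtering and can only be
    removed by LD pruning."""
    n = 175
    n_het = int(round(0.39 * n))
    p = hwe_test(n - n_het, n_het, 0)
    assert p > 2.5e-5
    assert p < 0.05  # it is a real departure nonetheless


def test_filter_commutes_with_locus_reordering():
    rng = np.random.default_rng(5)
    X = rng.integers(0, 3, size=(30, 40)).astype(np.int8)
    X[rng.random(X.shape) < 0.08] = MISSING
    gm = make_matrix(X)
    perm = rng.permutation(40)
    gm_perm = gm.subset(locus_mask=perm)
    out1, _ = apply_locus_filters(gm, FilterConfig(), hwe=True)
    out2, _ = apply_locus_filters(gm_perm, FilterConfig(), hwe=True)
    assert set(out1.locus_ids) == set(out2.locus_ids)
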