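"""Synthetic genotype datasets with a known linkage-cohort architecture.

The generator emulates the statistical structure the detection method
assumes, so that every pipeline stage can be verified against planted truth:

* a **sex block** of X/Y-paralogue-like loci — heterogametic (male) samples
  are heterozygous at every block locus apart from a small genotyping-noise
  rate, homogametic (female) samples homozygous-reference apart from a smaller
  rate;
* a geographically differentiated **island block** — every block locus copies
  one latent biallelic haplotype per sample (complete within-block LD) whose
  alternate-allele frequency differs between the two demes by a configured
  amount;
* a small **third block** with the same latent-haplotype construction but no
  deme association;
* a **neutral background** of independent loci: ancestral frequencies drawn
  from a configurable law, per-deme frequencies from a Balding–Nichols beta
  model governed by an F_ST parameter, genotypes binomial per sample.

Block loci are concentrated on a few scaffolds (skewed partition), neutral
loci scattered; uniform missingness is applied last.  Supplementary samples
are inter-deme F1s: one allele per deme at each neutral/island locus, so they
project between the parental clusters.  The seed fully determines the output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    LOCUS_COLUMNS,
    MISSING,
    GenotypeMatrix,
    write_sample_table,
    write_vcf,
)

_NUCS = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the study conditions the method targets
    (175 wild + 13 lab-bred samples, 2,077 SNPs on ~1,000 scaffolds, planted
    blocks of 217/88/37 loci, 39% males, 99.3%/99.9% heterozygosity contrast,
    25% inter-deme differential at the island block)."""

    seed: int = 0
    n_wild: int = 175
    n_supplementary: int = 13
    male_fraction: float = 0.39
    north_fraction: float = 0.5
    n_loci: int = 2077
    n_scaffolds: int = 1000
    sex_block_size: int = 217
    island_block_size: int = 88
    third_block_size: int = 37
    island_deme_diff: float = 0.25
    island_base_freq: float = 0.5     # alt freq in the north deme; south = base - diff
    third_block_freq: float = 0.35
    sex_block_noise: float = 0.007    # male het -> hom flip rate
    sex_block_female_noise: float = 0.001  # female hom-ref -> het flip rate
    neutral_maf_low: float = 0.05
    neutral_maf_high: float = 0.5
    deme_fst: float = 0.02
    missing_rate: float = 0.02
    # scaffolds carrying each block (loci partitioned with a 1/rank skew)
    block_scaffold_concentration: dict = field(
        default_factory=lambda: {"sex": 62, "island": 18, "third": 8}
    )

    def __post_init__(self) -> None:
        errors = []
        if self.sex_block_size + self.island_block_size + self.third_block_size >= self.n_loci:
            errors.append("block sizes must sum to less than n_loci")
        for name in (
            "male_fraction",
            "north_fraction",
            "island_deme_diff",
            "island_base_freq",
            "third_block_freq",
            "sex_block_noise",
            "sex_block_female_noise",
            "deme_fst",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.island_base_freq - self.island_deme_diff <= 1.0:
            errors.append("island_base_freq - island_deme_diff outside [0, 1]")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class TruthTable:
    """Generative ground truth: per-locus block labels and per-deme
    frequencies; per-sample sex, deme and role."""

    loci: pd.DataFrame    # locus_id, block, scaffold, p_north, p_south
    samples: pd.DataFrame  # sample_id, sex, deme, role

    def block_ids(self, block: str) -> set:
        return set(self.loci.loc[self.loci["block"] == block, "locus_id"])


def _skewed_partition(total: int, n_parts: int, rng) -> np.ndarray:
    """Partition ``total`` into ``n_parts`` positive counts with a 1/rank skew,
    so a few parts carry most of the mass (scaffold concentration)."""
    n_parts = min(n_parts, total)
    weights = 1.0 / np.arange(1, n_parts + 1)
    weights /= weights.sum()
    counts = np.ones(n_parts, dtype=int)
    extra = rng.multinomial(total - n_parts, weights)
    return counts + extra


def simulate(cfg: SimulationConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Generate a genotype matrix plus its truth table from ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_wild + cfg.n_supplementary
    n_neutral = cfg.n_loci - cfg.sex_block_size - cfg.island_block_size - cfg.third_block_size

    # ---- samples ----------------------------------------------------------
    n_males = int(round(cfg.male_fraction * cfg.n_wild))
    n_north = int(round(cfg.north_fraction * cfg.n_wild))
    sex = np.array(["male"] * n_males + ["female"] * (cfg.n_wild - n_males), dtype=object)
    rng.shuffle(sex)
    deme = np.array(["north"] * n_north + ["south"] * (cfg.n_wild - n_north), dtype=object)
    rng.shuffle(deme)
    supp_sex = np.where(
        rng.random(cfg.n_supplementary) < cfg.male_fraction, "male", "female"
    )
    sample_truth = pd.DataFrame(
        {
            "sample_id": [f"wild{i:04d}" for i in range(cfg.n_wild)]
            + [f"lab{i:03d}" for i in range(cfg.n_supplementary)],
            "sex": np.concatenate([sex, supp_sex]),
            "deme": np.concatenate([deme, np.array(["hybrid"] * cfg.n_supplementary)]),
            "role": ["wild"] * cfg.n_wild + ["supplementary"] * cfg.n_supplementary,
        }
    )
    is_male = (sample_truth["sex"] == "male").to_numpy()
    wild_deme = sample_truth["deme"].to_numpy()
    is_north = wild_deme == "north"
    is_south = wild_deme == "south"
    is_hybrid = wild_deme == "hybrid"

    # ---- locus scaffold layout -------------------------------------------
    scaffold_names = np.array([f"scaffold{i:04d}" for i in range(1, cfg.n_scaffolds + 1)])
    order = rng.permutation(cfg.n_scaffolds)
    cursor = 0
    block_scaffolds = {}
    for block, size in (
        ("sex", cfg.sex_block_size),
        ("island", cfg.island_block_size),
        ("third", cfg.third_block_size),
    ):
        n_sc = cfg.block_scaffold_concentration.get(block, 1)
        sc = scaffold_names[order[cursor : cursor + n_sc]]
        cursor += n_sc
        counts = _skewed_partition(size, len(sc), rng)
        block_scaffolds[block] = np.repeat(sc, counts)
    neutral_pool = scaffold_names[order[cursor:]]
    neutral_sc = rng.choice(neutral_pool, size=n_neutral, replace=True)

    blocks = np.array(
        ["sex"] * cfg.sex_block_size
        + ["island"] * cfg.island_block_size
        + ["third"] * cfg.third_block_size
        + ["neutral"] * n_neutral,
        dtype=object,
    )
    scaffolds = np.concatenate(
        [block_scaffolds["sex"], block_scaffolds["island"], block_scaffolds["third"], neutral_sc]
    )

    # ---- genotypes --------------------------------------------------------
    X = np.empty((n_samples, cfg.n_loci), dtype=np.int8)
    p_north = np.empty(cfg.n_loci)
    p_south = np.empty(cfg.n_loci)
    b = blocks

    # sex block: males het (noise -> hom-ref), females hom-ref (noise -> het)
    sx = np.flatnonzero(b == "sex")
    male_flip = rng.random((n_samples, len(sx))) < cfg.sex_block_noise
    female_flip = rng.random((n_samples, len(sx))) < cfg.sex_block_female_noise
    sex_geno = np.where(is_male[:, None], np.where(male_flip, 0, 1), np.where(female_flip, 1, 0))
    X[:, sx] = sex_geno
    p_north[sx] = p_south[sx] = np.nan  # frequency not deme-structured

    # island block: one latent haplotype per sample, deme-differentiated
    il = np.flatnonzero(b == "island")
    q_n = cfg.island_base_freq
    q_s = cfg.island_base_freq - cfg.island_deme_diff
    latent = np.empty(n_samples, dtype=np.int8)
    latent[is_north] = rng.binomial(2, q_n, is_north.sum())
    latent[is_south] = rng.binomial(2, q_s, is_south.sum())
    latent[is_hybrid] = (
        rng.binomial(1, q_n, is_hybrid.sum()) + rng.binomial(1, q_s, is_hybrid.sum())
    )
    X[:, il] = latent[:, None]
    p_north[il], p_south[il] = q_n, q_s

    # third block: latent haplotype, no deme structure
    th = np.flatnonzero(b == "third")
    latent3 = rng.binomial(2, cfg.third_block_freq, n_samples).astype(np.int8)
    X[:, th] = latent3[:, None]
    p_north[th] = p_south[th] = cfg.third_block_freq

    # neutral background: Balding-Nichols deme frequencies around an
    # ancestral frequency drawn from the configured law
    ne = np.flatnonzero(b == "neutral")
    anc = rng.uniform(cfg.neutral_maf_low, cfg.neutral_maf_high, len(ne))
    if cfg.deme_fst > 0:
        shape = (1.0 - cfg.deme_fst) / cfg.deme_fst
        pn = rng.beta(anc * shape, (1.0 - anc) * shape)
        ps = rng.beta(anc * shape, (1.0 - anc) * shape)
    else:
        pn = ps = anc
    p_north[ne], p_south[ne] = pn, ps
    geno_ne = np.empty((n_samples, len(ne)), dtype=np.int8)
    geno_ne[is_north] = rng.binomial(2, pn, (is_north.sum(), len(ne)))
    geno_ne[is_south] = rng.binomial(2, ps, (is_south.sum(), len(ne)))
    geno_ne[is_hybrid] = rng.binomial(1, pn, (is_hybrid.sum(), len(ne))) + rng.binomial(
        1, ps, (is_hybrid.sum(), len(ne))
    )
    X[:, ne] = geno_ne

    # ---- missingness ------------------------------------------------------
    if cfg.missing_rate > 0:
        X[rng.random(X.shape) < cfg.missing_rate] = MISSING

    # ---- locus metadata, sorted in genome order ---------------------------
    positions = rng.integers(1, 1_000_000, size=cfg.n_loci)
    ref_idx = rng.integers(0, 4, size=cfg.n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=cfg.n_loci)) % 4
    loci = pd.DataFrame(
        {
            "scaffold": scaffolds,
            "position": positions,
            "ref": _NUCS[ref_idx],
            "alt": _NUCS[alt_idx],
            "block": blocks,
            "p_north": p_north,
            "p_south": p_south,
        }
    )
    # resolve any position collision within a scaffold (row order untouched,
    # so alignment with the dosage columns is preserved)
    dup = loci.duplicated(subset=["scaffold", "position"])
    while dup.any():
        loci.loc[dup, "position"] = loci.loc[dup, "position"] + 1
        dup = loci.duplicated(subset=["scaffold", "position"])
    order = np.lexsort((loci["position"].to_numpy(), loci["scaffold"].to_numpy()))
    loci = loci.iloc[order].reset_index(drop=True)
    X = X[:, order]
    loci["locus_id"] = loci["scaffold"] + ":" + loci["position"].astype(str)

    samples = pd.DataFrame(
        {
            "sample_id": sample_truth["sample_id"],
            "role": sample_truth["role"],
            "group": sample_truth["deme"].where(sample_truth["role"] == "wild"),
            "known_sex": sample_truth["sex"].where(
                sample_truth["role"] == "supplementary", "unknown"
            ),
        }
    )
    gm = GenotypeMatrix(dosages=X, loci=loci[LOCUS_COLUMNS], samples=samples)
    truth = TruthTable(
        loci=loci[["locus_id", "block", "scaffold", "p_north", "p_south"]],
        samples=sample_truth,
    )
    return gm, truth


def emit_fixture(cfg: SimulationConfig, out_dir) -> dict:
    """Write VCF + sample metadata + truth tables + config; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm, truth = simulate(cfg)
    paths = {
        "vcf": out / "genotypes.vcf",
        "samples": out / "samples.tsv",
        "truth_loci": out / "truth_loci.tsv",
        "truth_samples": out / "truth_samples.tsv",
        "config": out / "config.json",
    }
    write_vcf(gm, paths["vcf"])
    write_sample_table(gm.samples, paths["samples"])
    truth.loci.to_csv(paths["truth_loci"], sep="\t", index=False)
    truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    paths["config"].write_text(cfg.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}
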