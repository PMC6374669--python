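"""Genotype matrix container and VCF / metadata-table I/O.

The in-memory representation is a dense samples x loci table of alternate-allele
dosages (0, 1, 2) with ``MISSING = -1`` as the sentinel for uncalled genotypes,
plus two pandas DataFrames holding locus metadata (``locus_id``, ``scaffold``,
``position``, ``ref``, ``alt``) and sample metadata (``sample_id``, ``role``,
``group``, ``known_sex``).  VCF POS stays 1-based in metadata; array indices are
0-based.  Phase in the GT field is ignored: all downstream statistics are
genotypic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.  Never counted as an allele.
MISSING: int = -1

LOCUS_COLUMNS = ["locus_id", "scaffold", "position", "ref", "alt"]
SAMPLE_COLUMNS = ["sample_id", "role", "group", "known_sex"]

VALID_ROLES = {"wild", "supplementary"}


def _default_sample_table(sample_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "role": "wild",
            "group": None,
            "known_sex": "unknown",
        }
    )


@dataclass
class GenotypeMatrix:
    """Samples x loci integer dosage table with locus/sample metadata.

    ``dosages[i, j]`` is the count of alternate alleles carried by sample ``i``
    at locus ``j`` (0, 1, 2) or :data:`MISSING`.  Dosage 1 is a heterozygote.
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x loci array")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"dosage values outside {{0,1,2,{MISSING}}}: "
                f"first offender at index {tuple(np.argwhere(bad)[0])}"
            )
        self.loci = self.loci.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if len(self.loci) != self.dosages.shape[1]:
            raise ValueError(
                f"{len(self.loci)} locus records but {self.dosages.shape[1]} dosage columns"
            )
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError(
                f"{len(self.samples)} sample records but {self.dosages.shape[0]} dosage rows"
            )
        if self.loci["locus_id"].duplicated().any():
            dup = self.loci.loc[self.loci["locus_id"].duplicated(), "locus_id"].iloc[0]
            raise ValueError(f"duplicate locus_id {dup!r}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[
                self.samples["sample_id"].duplicated(), "sample_id"
            ].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def locus_ids(self) -> np.ndarray:
        return self.loci["locus_id"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset(self, sample_mask=None, locus_mask=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the selected samples/loci.

        Masks may be boolean arrays or integer index arrays; ``None`` keeps
        everything.  The original matrix is never modified.
        """
        si = np.arange(self.n_samples) if sample_mask is None else np.asarray(sample_mask)
        li = np.arange(self.n_loci) if locus_mask is None else np.asarray(locus_mask)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if li.dtype == bool:
            li = np.flatnonzero(li)
        if si.size == 0 or li.size == 0:
            raise ValueError("empty selection: subset would have zero samples or loci")
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(si, li)].copy(),
            loci=self.loci.iloc[li].reset_index(drop=True),
            samples=self.samples.iloc[si].reset_index(drop=True),
        )

    def genome_order(self) -> np.ndarray:
        """Locus indices sorted by (scaffold, position), stable."""
        return np.lexsort(
            (self.loci["position"].to_numpy(), self.loci["scaffold"].to_numpy())
        )


def read_vcf(path, strict: bool = False) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    Only the GT field is consumed.  Multi-allelic and non-SNP records are
    skipped with a logged count, or raise when ``strict`` is true.  ``./.``
    becomes :data:`MISSING`.  Sample order follows the header; locus order
    follows the records.
    """
    vf = pysam.VariantFile(str(path))
    sample_ids = list(vf.header.samples)
    if not sample_ids:
        raise ValueError(f"{path}: VCF contains zero samples")

    rows = []
    loci = []
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            if strict:
                raise ValueError(
                    f"{path}: non-biallelic-SNP record at {rec.chrom}:{rec.pos}"
                )
            n_skipped += 1
            continue
        dos = np.empty(len(sample_ids), dtype=np.int8)
        for i, sid in enumerate(sample_ids):
            gt = rec.samples[sid].get("GT", (None, None))
            if gt is None or any(a is None for a in gt):
                dos[i] = MISSING
            else:
                dos[i] = sum(gt)
        rows.append(dos)
        loci.append(
            (f"{rec.chrom}:{rec.pos}", rec.chrom, rec.pos, rec.ref, alts[0])
        )
    vf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"{path}: VCF contains zero usable SNP records")

    loci_df = pd.DataFrame(loci, columns=LOCUS_COLUMNS)
    return GenotypeMatrix(
        dosages=np.vstack(rows).T,
        loci=loci_df,
        samples=_default_sample_table(sample_ids),
    )


_GT_CODES = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file.

    Genotypes are emitted unphased: 0/0, 0/1, 1/1, ./. .
    """
    if gm.n_samples == 0 or gm.n_loci == 0:
        raise ValueError("refusing to write an empty GenotypeMatrix")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for scaffold in pd.unique(gm.loci["scaffold"]):
        header.contigs.add(str(scaffold))
    for sid in gm.sample_ids:
        header.add_sample(str(sid))
    vf = pysam.VariantFile(str(path), "w", header=header)
    try:
        for j in range(gm.n_loci):
            loc = gm.loci.iloc[j]
            rec = vf.new_record(
                contig=str(loc["scaffold"]),
                start=int(loc["position"]) - 1,
                alleles=(str(loc["ref"]), str(loc["alt"])),
                id=str(loc["locus_id"]),
            )
            for i in range(gm.n_samples):
                rec.samples[i]["GT"] = _GT_CODES[int(gm.dosages[i, j])]
                rec.samples[i].phased = False
            vf.write(rec)
    finally:
        vf.close()


def read_sample_table(path) -> pd.DataFrame:
    """Read a headered sample metadata table (TSV or CSV).

    Required column: ``sample_id``.  Optional: ``role`` (wild/supplementary),
    ``group``, ``known_sex`` (male/female/unknown).
    """
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "sample_id" not in table.columns:
        raise ValueError(f"{path}: sample table must contain a 'sample_id' column")
    for col, default in (("role", "wild"), ("group", None), ("known_sex", "unknown")):
        if col not in table.columns:
            table[col] = default
    bad_roles = set(table["role"].dropna()) - VALID_ROLES
    if bad_roles:
        raise ValueError(f"{path}: unknown role value(s) {sorted(bad_roles)}")
    return table[SAMPLE_COLUMNS]


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def attach_sample_metadata(gm: GenotypeMatrix, table: pd.DataFrame) -> GenotypeMatrix:
    """Return a copy of ``gm`` with sample metadata merged in by sample_id."""
    merged = pd.DataFrame({"sample_id": gm.sample_ids}).merge(
        table, on="sample_id", how="left"
    )
    merged["role"] = merged["role"].fillna("wild")
    merged["known_sex"] = merged["known_sex"].fillna("unknown")
    return GenotypeMatrix(gm.dosages.copy(), gm.loci.copy(), merged[SAMPLE_COLUMNS])
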