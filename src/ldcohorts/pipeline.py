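"""End-to-end linkage-cohort detection pipeline.

Stages: sample QC -> locus QC ("5%-only" marker set) -> on that set, both
(a) PCA with loading cohorts and supplementary projection, and (b) LD network
clustering; in parallel, HWE + LD pruning produce the fully filtered ("FF")
set whose PCA serves as the conventional-filtering contrast.  Integration
cross-tabulates LD clusters with loading cohorts, summarizes cohorts per
scaffold, identifies the sex axis by its heterozygosity contrast, calls sample
sex, and measures the inter-deme allele-frequency differential per cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .qc import FilterConfig, FilterReport, FilterStage, apply_locus_filters, filter_samples
from .ld import LDPruner, pairwise_r2
from .ldnet import LDNetworkClusters, NetworkConfig
from .pca import GenotypePCA, fit_pca, loading_cohort, project
from .integrate import (
    group_allele_freq_diff,
    heterozygosity_sex_call,
    overlap_table,
    scaffold_summary,
)


@dataclass
class PipelineResult:
    report: FilterReport
    gm_5pct: GenotypeMatrix
    gm_ff: GenotypeMatrix
    pca_5pct: "GenotypePCA"
    pca_ff: "GenotypePCA"
    scores_5pct: pd.DataFrame          # all samples (fitted + projected)
    scores_ff: pd.DataFrame
    pc_cohorts: dict                   # "PC1".. -> set of locus ids
    ld_estimator: LDNetworkClusters
    ld_clusters: dict                  # label -> set of locus ids
    overlap: object
    scaffold_summaries: dict           # cohort name -> ScaffoldSummary
    sex_axis: int | None
    sex_calls: pd.DataFrame | None
    deme_differentials: dict           # cohort name -> summary dict
    params: dict = field(default_factory=dict)


def _all_scores(model, gm) -> pd.DataFrame:
    scores = project(model, gm)
    df = pd.DataFrame(
        scores, columns=[f"PC{k}" for k in range(1, model.n_axes_ + 1)]
    )
    df.insert(0, "sample_id", gm.sample_ids)
    df.insert(1, "role", gm.samples["role"].to_numpy())
    return df


def identify_sex_axis(gm: GenotypeMatrix, pc_cohorts: dict, min_contrast: float = 0.5):
    """Pick the axis whose cohort behaves like an X/Y-paralogue block.

    A candidate cohort must split samples into a high- and a low-
    heterozygosity cluster with mean gap of at least ``min_contrast``.  Among
    candidates, cohorts are ranked by agreement between the heterozygosity
    call and the known sexes of sexed (typically lab-bred) samples when any
    are present — the same evidence that anchored the original beetle-data
    interpretation.  Without known sexes, the tiebreak is the scarcity of
    homozygous-alternate genotypes: at paralogous SNPs the alternate allele
    rides on the Y copy, so hom-alt calls are essentially absent, unlike a
    geographically structured block where both homozygotes occur.

    Returns (axis number, contrast gap) or (None, best gap) when no cohort
    qualifies.
    """
    known = gm.samples["known_sex"].isin(["male", "female"]).to_numpy()
    known_sex = gm.samples["known_sex"].to_numpy(dtype=object)
    candidates = []
    for name, ids in pc_cohorts.items():
        if not ids:
            continue
        calls = heterozygosity_sex_call(gm, ids)
        frac = calls["het_fraction"].to_numpy()
        ok = ~np.isnan(frac)
        hi, lo = frac[ok & (frac > 0.5)], frac[ok & (frac <= 0.5)]
        if len(hi) == 0 or len(lo) == 0:
            continue
        gap = float(hi.mean() - lo.mean())
        if gap < min_contrast:
            continue
        if known.sum() >= 3:
            agree = float(
                (calls["call"].to_numpy(dtype=object)[known] == known_sex[known]).mean()
            )
        else:
            agree = np.nan
        idx = np.flatnonzero(np.isin(gm.locus_ids, list(ids)))
        sub = gm.dosages[:, idx]
        called = (sub != MISSING).sum()
        hom_alt = float((sub == 2).sum() / called) if called else 1.0
        score = agree if not np.isnan(agree) else gap * (1.0 - 2.0 * hom_alt)
        candidates.append((score, gap, int(name.removeprefix("PC"))))
    if not candidates:
        return None, 0.0
    score, gap, axis = max(candidates, key=lambda t: (t[0], t[1], -t[2]))
    return axis, gap


def run_pipeline(
    gm: GenotypeMatrix,
    filter_cfg: FilterConfig | None = None,
    net_cfg: NetworkConfig | None = None,
    n_axes: int = 4,
    loading_threshold: float = 0.050,
    scale_loci: bool = True,
    min_r2_stored: float = 0.1,
    min_cluster_frac: float = 0.01,
) -> PipelineResult:
    """Run the full detection chain on a genotype matrix.

    ``min_cluster_frac`` sets the headline size floor for LD clusters as a
    fraction of the analysed loci (strictly more than 1% by default).
    """
    filter_cfg = filter_cfg or FilterConfig()
    net_cfg = net_cfg or NetworkConfig()

    # --- QC ---------------------------------------------------------------
    gm_s, report = filter_samples(gm, filter_cfg)
    gm5, rep5 = apply_locus_filters(gm_s, filter_cfg, hwe=False)
    report.extend(rep5)
    gm_hwe, rep_hwe = apply_locus_filters(gm_s, filter_cfg, hwe=True)
    for st in rep_hwe.stages:
        if st.name == "hwe":
            report.add(st)

    # --- FF: LD pruning on the HWE-passed set ------------------------------
    wild = gm_hwe.samples["role"].eq("wild").to_numpy()
    pruner = LDPruner(r2_cutoff=0.5).fit(
        gm_hwe.dosages[wild], order=gm_hwe.genome_order()
    )
    report.add(
        FilterStage(
            name="ld_prune",
            axis="loci",
            n_input=gm_hwe.n_loci,
            n_removed=int((~pruner.support_).sum()),
            n_retained=int(pruner.support_.sum()),
            removed_ids=list(gm_hwe.locus_ids[~pruner.support_]),
            params={"r2_cutoff": 0.5},
        )
    )
    gm_ff = gm_hwe.subset(locus_mask=pruner.support_)

    # --- PCA on both treatments -------------------------------------------
    pca5 = fit_pca(gm5, n_axes=n_axes, scale_loci=scale_loci)
    pca_ff = fit_pca(gm_ff, n_axes=n_axes, scale_loci=scale_loci)
    scores5 = _all_scores(pca5, gm5)
    scores_ff = _all_scores(pca_ff, gm_ff)
    pc_cohorts = {
        f"PC{k}": loading_cohort(pca5, k, loading_threshold).id_set()
        for k in range(1, pca5.n_axes_ + 1)
    }

    # --- LD network on the 5%-only set (wild samples) ----------------------
    wild5 = gm5.samples["role"].eq("wild").to_numpy()
    min_loci = int(math.floor(min_cluster_frac * gm5.n_loci)) + 1
    net = LDNetworkClusters(
        min_r2_stored=min_r2_stored,
        e_min=net_cfg.e_min,
        phi=net_cfg.phi,
        r2_grid_step=net_cfg.r2_grid_step,
        min_loci=min_loci,
    ).fit(gm5.dosages[wild5])
    ids5 = gm5.locus_ids
    ld_clusters = {c.label: set(ids5[c.members]) for c in net.clusters_}

    # --- integration --------------------------------------------------------
    overlap = overlap_table(pc_cohorts, ld_clusters)
    summaries = {
        name: scaffold_summary(ids, gm5.loci)
        for name, ids in pc_cohorts.items()
        if ids
    }
    sex_axis, contrast = identify_sex_axis(gm5, pc_cohorts)
    sex_calls = (
        heterozygosity_sex_call(gm5, pc_cohorts[f"PC{sex_axis}"])
        if sex_axis is not None
        else None
    )
    differentials = {}
    if gm5.samples["group"].notna().sum() and gm5.samples["group"].nunique() == 2:
        for name, ids in pc_cohorts.items():
            if name == f"PC{sex_axis}" or not ids:
                continue
            try:
                _, summary = group_allele_freq_diff(gm5, ids)
            except ValueError:
                continue
            differentials[name] = summary

    return PipelineResult(
        report=report,
        gm_5pct=gm5,
        gm_ff=gm_ff,
        pca_5pct=pca5,
        pca_ff=pca_ff,
        scores_5pct=scores5,
        scores_ff=scores_ff,
        pc_cohorts=pc_cohorts,
        ld_estimator=net,
        ld_clusters=ld_clusters,
        overlap=overlap,
        scaffold_summaries=summaries,
        sex_axis=sex_axis,
        sex_calls=sex_calls,
        deme_differentials=differentials,
        params={
            "n_axes": n_axes,
            "loading_threshold": loading_threshold,
            "scale_loci": scale_loci,
            "min_r2_stored": min_r2_stored,
            "min_cluster_loci": min_loci,
            "sex_axis_contrast": contrast,
        },
    )
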