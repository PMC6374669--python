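"""Genotype PCA with supplementary-sample projection and loading cohorts.

The decomposition is an eigenanalysis of the correlation matrix of allele
dosages over the *fitted* samples (covariance when ``scale=False``), done via
SVD of the standardized matrix.  Missing dosages are mean-imputed per locus
(equivalently: zero after standardization).  Loading vectors are unit-norm per
axis, with the sign fixed so the largest-magnitude loading on each axis is
positive.  Samples flagged as supplementary are projected onto the fitted axes
afterwards so they cannot influence the axes — the "grafting" treatment used
for lab-bred individuals.

A *loading cohort* is the set of loci whose absolute loading on one axis
strictly exceeds a threshold (0.050 by default; the uniform reference loading
is 1/sqrt(n_loci), about 0.022 at 2,077 loci, so the default flags loci with
more than twice uniform weight).  Which axis is "the sex axis" is never
decided by index: see :func:`ldcohorts.integrate.heterozygosity_sex_call` for
the downstream diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .io import MISSING, GenotypeMatrix


class GenotypePCA(TransformerMixin, BaseEstimator):
    """PCA of a dosage matrix with missing-aware centering/scaling.

    Parameters
    ----------
    n_components : number of axes to keep (all if None).
    scale : standardize each locus to unit variance (correlation-matrix PCA,
        the default, matching the convention of the duality-diagram PCA tools
        this analysis style comes from); False gives covariance-matrix PCA.

    Fitted attributes
    -----------------
    eigenvalues_ : per-axis variances (divisor n), non-increasing.
    loadings_ : (n_loci, n_axes) unit-norm axis vectors.
    scores_ : (n_fitted_samples, n_axes) sample coordinates.
    center_, scale_ : per-locus standardization vectors (scale_ is 1 when
        scaling is disabled or a locus is invariant).
    """

    def __init__(self, n_components: int | None = None, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        called = X != MISSING
        Z = np.where(called, X, 0.0).astype(float)
        Z -= self.center_
        Z /= self.scale_
        Z[~called] = 0.0  # mean imputation
        return Z

    def fit(self, X, y=None):
        X = np.asarray(X)
        n, p = X.shape
        if n < 2 or p < 2:
            raise ValueError("need at least 2 samples and 2 loci")
        self.n_features_in_ = p
        called = X != MISSING
        n_called = called.sum(axis=0)
        if (n_called == 0).any():
            raise ValueError("locus with zero non-missing calls; filter first")
        vals = np.where(called, X, 0.0)
        self.center_ = vals.sum(axis=0) / n_called
        # population (divisor-n) standard deviation over non-missing calls
        sq = np.where(called, (X - self.center_) ** 2, 0.0).sum(axis=0)
        sd = np.sqrt(sq / n_called)
        self.invariant_ = sd == 0
        if self.invariant_.all():
            raise ValueError("matrix has no variable locus")
        self.scale_ = np.where(self.invariant_, 1.0, sd) if self.scale else np.ones(p)

        Z = self._standardize(X)
        k = min(n, p) if self.n_components is None else min(self.n_components, n, p)
        U, s, Vt = linalg.svd(Z, full_matrices=False)
        self.eigenvalues_ = (s[:k] ** 2) / n
        loadings = Vt[:k].T
        # sign convention: largest-|loading| entry positive on each axis
        extremes = np.argmax(np.abs(loadings), axis=0)
        signs = np.sign(loadings[extremes, np.arange(k)])
        signs[signs == 0] = 1.0
        self.loadings_ = loadings * signs
        self.scores_ = Z @ self.loadings_
        self.n_axes_ = k
        return self

    def transform(self, X):
        """Project (possibly supplementary) samples onto the fitted axes.

        Missing dosages are imputed to the fitted center, i.e. contribute
        zero; a fully missing sample lands at the origin.
        """
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} loci, got {X.shape[1]}"
            )
        return self._standardize(X) @ self.loadings_


@dataclass
class LoadingCohort:
    """Loci whose |loading| on one axis strictly exceeds a threshold."""

    axis: int                 # 1-based
    threshold: float
    locus_indices: np.ndarray
    locus_ids: np.ndarray | None
    loadings: np.ndarray
    note: str = ""

    @property
    def size(self) -> int:
        return len(self.locus_indices)

    def id_set(self) -> set:
        src = self.locus_ids if self.locus_ids is not None else self.locus_indices
        return set(src.tolist())


def fit_pca(
    gm: GenotypeMatrix,
    n_axes: int = 4,
    scale_loci: bool = True,
    fit_roles=("wild",),
) -> GenotypePCA:
    """Fit a :class:`GenotypePCA` on the samples whose role is in ``fit_roles``.

    The fitted model remembers the locus ids and fitted sample ids so that
    :func:`project` can verify alignment.
    """
    fit_mask = gm.samples["role"].isin(fit_roles).to_numpy()
    if fit_mask.sum() < 2:
        raise ValueError("need at least two fitted samples")
    model = GenotypePCA(n_components=n_axes, scale=scale_loci)
    model.fit(gm.dosages[fit_mask])
    model.locus_ids_ = gm.locus_ids.copy()
    model.fitted_sample_ids_ = gm.sample_ids[fit_mask].copy()
    return model


def project(model: GenotypePCA, gm: GenotypeMatrix) -> np.ndarray:
    """Scores for supplementary samples on axes fitted elsewhere.

    The loci of ``gm`` must match the fitted loci exactly (id and order).
    """
    fitted_ids = getattr(model, "locus_ids_", None)
    if fitted_ids is not None:
        ids = gm.locus_ids
        if len(ids) != len(fitted_ids) or (ids != fitted_ids).any():
            if len(ids) != len(fitted_ids):
                raise ValueError(
                    f"locus mismatch: model fitted on {len(fitted_ids)} loci, "
                    f"got {len(ids)}"
                )
            k = int(np.flatnonzero(ids != fitted_ids)[0])
            raise ValueError(
                f"locus mismatch at index {k}: {ids[k]!r} != {fitted_ids[k]!r}"
            )
    return model.transform(gm.dosages)


def loading_profile(model: GenotypePCA, axis: int) -> pd.DataFrame:
    """|loading| of every locus on ``axis`` (1-based), sorted descending.

    This is the "descending loading" profile whose plateaus and steep declines
    delimit cohorts visually; export it to plot a profile figure.
    """
    if not 1 <= axis <= model.n_axes_:
        raise ValueError(f"axis {axis} out of range 1..{model.n_axes_}")
    lo = np.abs(model.loadings_[:, axis - 1])
    order = np.argsort(-lo, kind="stable")
    ids = getattr(model, "locus_ids_", None)
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(lo) + 1),
            "locus_index": order,
            "locus_id": ids[order] if ids is not None else order,
            "abs_loading": lo[order],
        }
    )


def loading_cohort(
    model: GenotypePCA, axis: int, threshold: float = 0.050
) -> LoadingCohort:
    """Cohort of loci with |loading| strictly above ``threshold`` on ``axis``."""
    if not 1 <= axis <= model.n_axes_:
        raise ValueError(f"axis {axis} out of range 1..{model.n_axes_}")
    lo = model.loadings_[:, axis - 1]
    idx = np.flatnonzero(np.abs(lo) > threshold)
    ids = getattr(model, "locus_ids_", None)
    return LoadingCohort(
        axis=axis,
        threshold=threshold,
        locus_indices=idx,
        locus_ids=ids[idx] if ids is not None else None,
        loadings=lo[idx],
        note=f"|loading| > {threshold} on axis {axis}",
    )
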