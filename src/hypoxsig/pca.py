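"""Cohort PCA and projection of external samples onto its components.

Follows the R ``prcomp`` conventions: samples are observations, genes
are variables, centering always, variable scaling off by default, SVD
under the hood. Component signs are fixed so the largest-magnitude
loading of each component is positive, making results deterministic.
Cohort values are log2(x+1)-transformed by default before centering
(normalized cohort scales are heavy-tailed; raw mode is available).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix

__all__ = ["PCAModel", "fit_pca", "project_samples"]

_TRANSFORMS = {
    "identity": lambda x: x,
    "log2p1": lambda x: np.log2(x + 1.0),
}


@dataclass
class PCAModel:
    """Centers, loadings and explained variance of a fitted cohort PCA."""

    genes: pd.Index
    centers: np.ndarray           # per-gene means on the transformed scale
    scales: np.ndarray | None     # per-gene sd when scaling, else None
    loadings: np.ndarray          # genes x components, orthonormal columns
    explained_variance_ratio: np.ndarray
    transform: str = "log2p1"

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(
    cohort: ExpressionMatrix,
    transform: str = "log2p1",
    n_components: int | None = None,
    scale: bool = False,
) -> tuple[PCAModel, pd.DataFrame]:
    """Fit PCA on cohort samples; returns the model and the cohort
    sample coordinates (samples x components)."""
    if transform not in _TRANSFORMS:
        raise ValidationError(f"unknown transform: {transform!r}")
    n_samples = len(cohort.sample_ids)
    if n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    X = _TRANSFORMS[transform](cohort.values.to_numpy(dtype=float)).T  # samples x genes
    centers = X.mean(axis=0)
    Xc = X - centers
    scales = None
    if scale:
        scales = Xc.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
        Xc = Xc / scales
    total_var = (Xc**2).sum() / (n_samples - 1)
    if total_var <= 0:
        raise ValidationError("cohort matrix is constant; PCA is undefined")

    max_k = min(n_samples - 1, X.shape[1])
    k = max_k if n_components is None else int(n_components)
    if not (1 <= k <= max_k):
        raise ValidationError(
            f"n_components must be in [1, {max_k}] for this cohort"
        )
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :max_k], S[:max_k], Vt[:max_k]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(max_k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    ev = S**2 / (n_samples - 1)
    ratio = ev / ev.sum()

    model = PCAModel(
        genes=cohort.values.index,
        centers=centers,
        scales=scales,
        loadings=Vt[:k].T.copy(),
        explained_variance_ratio=ratio[:k].copy(),
        transform=transform,
    )
    coords = pd.DataFrame(
        (U[:, :k] * S[:k]),
        index=cohort.values.columns,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    return model, coords


def project_samples(
    model: PCAModel,
    expr: ExpressionMatrix,
    min_gene_overlap: float = 0.5,
) -> pd.DataFrame:
    """Project new samples onto a fitted model's components.

    Coordinates are (t(x) - centers) @ loadings over the genes shared
    with the model; model genes absent from ``expr`` are imputed at the
    center value, contributing 0 after centering. Genes in ``expr`` that
    the model never saw are ignored. Raises when the shared fraction of
    model genes falls below ``min_gene_overlap``.
    """
    shared = model.genes.intersection(expr.values.index)
    frac = len(shared) / len(model.genes)
    if frac < min_gene_overlap:
        raise ValidationError(
            f"only {frac:.1%} of the model's genes are present in the "
            f"samples (threshold {min_gene_overlap:.0%}); missing "
            f"{len(model.genes) - len(shared)} of {len(model.genes)}"
        )
    pos = model.genes.get_indexer(shared)
    X = _TRANSFORMS[model.transform](
        expr.values.loc[shared].to_numpy(dtype=float)
    ).T  # samples x shared genes
    Xc = X - model.centers[pos]
    if model.scales is not None:
        Xc = Xc / model.scales[pos]
    coords = Xc @ model.loadings[pos, :]
    return pd.DataFrame(
        coords,
        index=expr.values.columns,
        columns=[f"PC{j + 1}" for j in range(model.n_components)],
    )
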