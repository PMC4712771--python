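"""Transcriptome-derived hypoxia signature and per-sample scoring.

The signature is the set of genes differentially expressed between
hypoxia-treated and untreated cells (adjusted p below threshold, no
fold-change magnitude filter), each weighted by its log2 fold-change.
A sample's hypoxia score is the weighted sum of its expression over the
signature genes: samples over-expressing hypoxia-induced genes and
under-expressing hypoxia-suppressed genes score high.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ClinicalTable, ExpressionMatrix
from .stats import RankTestResult, wilcoxon_rank_sum

__all__ = [
    "HypoxiaSignature",
    "ScoreReport",
    "build_signature",
    "score_samples",
    "compare_outcomes",
]


@dataclass
class HypoxiaSignature:
    """Gene -> log2 fold-change weight map with provenance."""

    weights: pd.Series  # index: gene_id, finite values
    contrast: str = "hypoxia:untreated"
    padj_max: float = 0.05

    def __post_init__(self) -> None:
        if len(self.weights) == 0:
            raise ValidationError("signature is empty")
        if self.weights.index.has_duplicates:
            raise ValidationError("signature has duplicate genes")
        if not np.isfinite(self.weights.to_numpy(dtype=float)).all():
            raise ValidationError("signature weights must be finite")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.weights.index)


@dataclass
class ScoreReport:
    """Per-sample scores with accounting of signature-gene coverage."""

    scores: pd.Series  # index: sample_id
    n_genes_used: int
    n_genes_missing: int
    transform: str = "identity"
    meta: dict = field(default_factory=dict)


def build_signature(
    detable_hypoxia_vs_untreated: pd.DataFrame,
    padj_max: float = 0.05,
    contrast: str = "hypoxia:untreated",
) -> HypoxiaSignature:
    """Signature = {gene: log2fc} over genes with padj < padj_max.

    Genes with infinite fold-change sentinels or the ``untestable`` flag
    are excluded (their weights are undefined). Raises if nothing
    survives the threshold.
    """
    t = detable_hypoxia_vs_untreated
    keep = (
        (t["padj"] < padj_max)
        & np.isfinite(t["log2FoldChange"])
        & (t["flags"] != "untestable")
    )
    if not keep.any():
        raise ValidationError(
            f"no gene passes padj < {padj_max}; review the threshold or the "
            "contrast before building a signature"
        )
    w = t.loc[keep, "log2FoldChange"].astype(float)
    return HypoxiaSignature(weights=w, contrast=contrast, padj_max=padj_max)


_TRANSFORMS = {
    "identity": lambda x: x,
    "log2p1": lambda x: np.log2(x + 1.0),
}


def score_samples(
    signature: HypoxiaSignature,
    expr: ExpressionMatrix,
    transform: str = "identity",
    mean: bool = False,
    zscore: bool = False,
) -> ScoreReport:
    """score(s) = sum over signature genes g present in expr of
    w_g * t(x_gs).

    ``transform``: ``identity`` (the definition's plain product) or
    ``log2p1`` (robust alternative for heavy-tailed cohort scales).
    Signature genes missing from the matrix contribute 0 and are counted
    in ``n_genes_missing``. ``mean`` divides by the number of genes used;
    ``zscore`` standardizes scores across samples for display.
    """
    if transform not in _TRANSFORMS:
        raise ValidationError(f"unknown transform: {transform!r}")
    present = signature.weights.index.intersection(expr.values.index)
    if len(present) == 0:
        raise ValidationError(
            "signature and expression matrix share no genes; check that "
            "both use the same gene-ID namespace"
        )
    w = signature.weights.reindex(present).to_numpy(dtype=float)
    x = _TRANSFORMS[transform](expr.values.loc[present].to_numpy(dtype=float))
    scores = pd.Series(w @ x, index=expr.values.columns, name="hypoxia_score")
    if mean:
        scores = scores / len(present)
    if zscore:
        sd = scores.std(ddof=1)
        scores = (scores - scores.mean()) / (sd if sd > 0 else 1.0)
    return ScoreReport(
        scores=scores,
        n_genes_used=int(len(present)),
        n_genes_missing=int(len(signature) - len(present)),
        transform=transform,
        meta={"mean": mean, "zscore": zscore, "contrast": signature.contrast},
    )


def compare_outcomes(
    report: ScoreReport,
    clinical: ClinicalTable,
) -> dict:
    """Compare score distributions between disease-free and
    recurred/progressed patients (two-sided rank-sum).

    Returns per-group sizes and medians plus the ``RankTestResult``.
    Samples with unknown outcome or absent from the score report are
    ignored; each compared group needs at least two samples.
    """
    scored = set(report.scores.index)
    free = [s for s in clinical.samples_with_outcome("disease_free") if s in scored]
    recur = [s for s in clinical.samples_with_outcome("recurred_progressed")
             if s in scored]
    if len(free) < 2 or len(recur) < 2:
        raise ValidationError(
            "each outcome group needs >=2 scored samples "
            f"(disease_free: {len(free)}, recurred_progressed: {len(recur)})"
        )
    x = report.scores.reindex(recur).to_numpy(dtype=float)
    y = report.scores.reindex(free).to_numpy(dtype=float)
    result: RankTestResult = wilcoxon_rank_sum(x, y, alternative="two_sided")
    return {
        "n_recurred_progressed": len(recur),
        "n_disease_free": len(free),
        "median_recurred_progressed": float(np.median(x)),
        "median_disease_free": float(np.median(y)),
        "test": result,
    }
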