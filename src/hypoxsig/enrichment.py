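"""Hypergeometric over-representation analysis of gene sets.

For a query of n genes drawn from a universe of N, a pathway with K
members inside the universe, and k genes in common with the query, the
enrichment p-value is the upper tail P[X >= k] with
X ~ Hypergeometric(N, K, n). One-sided over-representation only; BH
adjustment is applied across the pathways tested in one call. The
universe should be the set of genes actually tested for differential
expression, not the whole genome.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .deseq import adjust_bh
from .errors import ValidationError
from .io import GeneSetCollection

__all__ = ["EnrichmentResult", "enrich"]


@dataclass
class EnrichmentResult:
    pathway: str
    description: str
    k: int  # overlap
    K: int  # pathway size within universe
    n: int  # query size
    N: int  # universe size
    p_value: float
    padj: float = float("nan")
    overlap_genes: tuple[str, ...] = field(default_factory=tuple)


def enrich(
    query_genes,
    gene_sets: GeneSetCollection,
    universe,
) -> list[EnrichmentResult]:
    """Test every pathway for over-representation in the query.

    Pathways are intersected with the universe before testing; the query
    must be a subset of the universe. Results are sorted by p-value.
    """
    universe = frozenset(universe)
    query = frozenset(query_genes)
    if not query:
        raise ValidationError("empty query gene set")
    if not universe:
        raise ValidationError("empty universe")
    stray = query - universe
    if stray:
        raise ValidationError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
        )
    N, n = len(universe), len(query)
    results = []
    for gs in gene_sets:
        members = gs.genes & universe
        if not members:
            continue
        K = len(members)
        overlap = members & query
        k = len(overlap)
        # P[X >= k]; sf(k-1) is the exact upper tail
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                pathway=gs.name,
                description=gs.description,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=min(p, 1.0),
                overlap_genes=tuple(sorted(overlap)),
            )
        )
    if results:
        padj = adjust_bh([r.p_value for r in results])
        for r, q in zip(results, padj):
            r.padj = float(q)
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results into the output TSV layout."""
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "description": r.description,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "pval": r.p_value,
                "padj": r.padj,
                "genes": ",".join(r.overlap_genes),
            }
            for r in results
        ]
    )
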