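"""Differential-expression calling and contrast-overlap set algebra.

A gene is called differentially expressed when its BH-adjusted p-value
is below the significance cut AND its linear fold-change (the ratio of
normalized condition means, 2**log2fc) lies outside the reciprocal pair
(fc_up, fc_down). All-or-nothing genes (±inf log2fc) pass the
fold-change filter by convention — they are maximally changed — while
genes flagged ``untestable`` (zero counts everywhere) are excluded from
every set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["DEGeneSets", "call_de", "overlap_sets"]


@dataclass
class DEGeneSets:
    """Up/down DE sets per contrast plus their overlap decomposition."""

    up_hypoxia: frozenset[str]
    down_hypoxia: frozenset[str]
    up_cocl2: frozenset[str]
    down_cocl2: frozenset[str]
    both_up: frozenset[str]
    both_down: frozenset[str]
    hypoxia_only_up: frozenset[str]
    hypoxia_only_down: frozenset[str]
    cocl2_only_up: frozenset[str]
    cocl2_only_down: frozenset[str]

    def summary_counts(self) -> dict[str, int]:
        return {k: len(getattr(self, k)) for k in (
            "up_hypoxia", "down_hypoxia", "up_cocl2", "down_cocl2",
            "both_up", "both_down", "hypoxia_only_up", "hypoxia_only_down",
            "cocl2_only_up", "cocl2_only_down")}


def call_de(
    detable: pd.DataFrame,
    padj_max: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> tuple[frozenset[str], frozenset[str]]:
    """Split a DE table into (up, down) gene sets by padj and fold-change.

    up = {padj < padj_max and FC > fc_up}; down = {padj < padj_max and
    FC < fc_down}, with FC the linear ratio 2**log2fc.
    """
    if not (fc_down < 1.0 < fc_up) or padj_max <= 0:
        raise ValidationError(
            "thresholds must satisfy fc_down < 1 < fc_up and padj_max > 0"
        )
    testable = detable["flags"] != "untestable"
    sig = (detable["padj"] < padj_max) & testable
    l2fc = detable["log2FoldChange"]
    # ±inf log2fc compares correctly against the finite log-thresholds
    up = frozenset(detable.index[sig & (l2fc > np.log2(fc_up))])
    down = frozenset(detable.index[sig & (l2fc < np.log2(fc_down))])
    return up, down


def overlap_sets(
    hypoxia_up: frozenset[str],
    hypoxia_down: frozenset[str],
    cocl2_up: frozenset[str],
    cocl2_down: frozenset[str],
) -> DEGeneSets:
    """Direction-consistent overlap decomposition of the two contrasts'
    DE sets: shared (both), hypoxia-exclusive and CoCl2-exclusive genes,
    separately for up- and down-regulation."""
    hu, hd = frozenset(hypoxia_up), frozenset(hypoxia_down)
    cu, cd = frozenset(cocl2_up), frozenset(cocl2_down)
    return DEGeneSets(
        up_hypoxia=hu,
        down_hypoxia=hd,
        up_cocl2=cu,
        down_cocl2=cd,
        both_up=hu & cu,
        both_down=hd & cd,
        hypoxia_only_up=hu - cu,
        hypoxia_only_down=hd - cd,
        cocl2_only_up=cu - hu,
        cocl2_only_down=cd - hd,
    )
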