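"""Conditional-dependence pattern classification and gene-set overlap tests.

An mRNA is called *conditionally dependent* on eIF2A when its TE drops
appreciably both (1) on eliminating eIF2A in starved (SM-treated) cells and
(2) on starving cells that lack eIF2A, while showing a lesser reduction, no
change, or an increase (3) on starving WT cells and (4) on eliminating eIF2A
from unstarved cells.  The heat-map inspection that originally defined this
pattern is replaced by explicit, configurable log2 thresholds, gated on the
discovery contrast's FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .config import AnalysisConfig
from .diffte import ContrastResult

__all__ = ["PatternProfile", "build_profiles", "classify_conditional", "overlap_enrichment"]

#: Order of the four diagnostic contrasts: c1 = mutant/WT under SM,
#: c2 = SM/untreated in the mutant, c3 = SM/untreated in WT, c4 = mutant/WT untreated.
CONTRAST_KEYS = ("c1", "c2", "c3", "c4")


@dataclass
class PatternProfile:
    """Per-gene log2 TE changes and FDRs across the four diagnostic contrasts."""

    table: pd.DataFrame  # columns c1..c4, q1..q4, label

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def genes_with_label(self, label: str) -> Set[str]:
        return set(self.table.index[self.table["label"] == label])


def build_profiles(results: Sequence[ContrastResult]) -> PatternProfile:
    """Assemble the four-contrast profile table (labels start as 'untested').

    ``results`` must be the four diagnostic contrasts in :data:`CONTRAST_KEYS`
    order.  A gene is untested if any contrast excluded it.
    """
    if len(results) != 4:
        raise ValueError("exactly four contrast results are required")
    genes = results[0].table.index
    for r in results[1:]:
        if not r.table.index.equals(genes):
            genes = genes.intersection(r.table.index)
    cols = {}
    tested = pd.Series(True, index=genes)
    for key, r in zip(CONTRAST_KEYS, results):
        sub = r.table.loc[genes]
        cols[key] = sub["log2_effect"]
        cols["q" + key[1]] = sub["q"]
        tested &= sub["status"] == "tested"
    table = pd.DataFrame(cols, index=genes)
    table["label"] = np.where(tested, "unlabelled", "untested")
    return PatternProfile(table)


def classify_conditional(
    profiles: PatternProfile,
    config: Optional[AnalysisConfig] = None,
) -> PatternProfile:
    """Label each profile conditional_dependent / not_conditional / untested.

    conditional_dependent requires c1 and c2 at or below
    ``classifier_down_log2``, c3 and c4 at or above ``classifier_lesser_log2``,
    and the discovery contrast's FDR q1 below ``fdr_loose``.
    """
    config = config or AnalysisConfig()
    t = profiles.table
    down = config.classifier_down_log2
    lesser = config.classifier_lesser_log2
    tested = t["label"] != "untested"
    hit = (
        (t["c1"] <= down)
        & (t["c2"] <= down)
        & (t["c3"] >= lesser)
        & (t["c4"] >= lesser)
        & (t["q1"] < config.fdr_loose)
    )
    out = t.copy()
    out.loc[tested, "label"] = np.where(hit[tested], "conditional_dependent", "not_conditional")
    return PatternProfile(out)


def overlap_enrichment(
    set_a: Set[str], set_b: Set[str], universe: Set[str]
) -> Tuple[int, float, float]:
    """Hypergeometric upper-tail test of the overlap between two gene sets.

    Returns (k, expected, p) where k = \\|a & b\\|, expected = \\|a\\|\\|b\\|/\\|U\\|,
    and p = P(X >= k) drawing \\|a\\| genes from a universe containing \\|b\\|
    successes.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be contained in the universe")
    k = len(set_a & set_b)
    M, n, N = len(universe), len(set_b), len(set_a)
    expected = N * n / M if M else 0.0
    p = float(scipy.stats.hypergeom.sf(k - 1, M, n, N))
    return k, expected, p
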