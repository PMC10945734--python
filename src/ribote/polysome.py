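"""Polysome-gradient qPCR reconstruction of per-mRNA translational efficiency.

A whole-cell extract is resolved on a sucrose gradient; pooled fractions
(80S, 2-mer, 3-mer, ... polysomes) are quantified for a target mRNA and 18S
rRNA by qPCR.  Per fraction, the target's 18S-relative abundance (2^-dCT) is
corrected for the sampled fraction volume and RT input, for RNA-extraction
losses (A260 share over 18S share), and for gradient-to-gradient recovery;
the corrected amounts, weighted by ribosomes per mRNA, are summed and divided
by the ACT1-normalized input abundance to give the TE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "GradientFraction",
    "Gradient",
    "GradientDataset",
    "TEEstimate",
    "pm_ratio",
    "qpcr_abundance",
    "volume_corrections",
    "recovery_factor",
    "gradient_recovery_factor",
    "reconstruct_te",
    "reconstruct_all",
    "summarize_delta_te",
]

logger = logging.getLogger(__name__)

RRNA_18S = "18S"
ACT1 = "ACT1"


@dataclass
class GradientFraction:
    """One pooled gradient fraction (80S or an n-mer polysome class)."""

    fraction_id: str
    ribosome_weight: int          # ribosomes per mRNA: 1 for 80S, 2 for disomes, ...
    a260_area: float              # area under the A260 trace, arbitrary units
    pooled_volume_ul: float
    rt_input_fraction_volume_ul: float  # volume containing the 5 ug used for RT
    ct: Dict[str, float] = field(default_factory=dict)  # target -> CT, incl. 18S
    rna_extraction_volume_ul: float = 300.0

    def __post_init__(self) -> None:
        if self.ribosome_weight < 1:
            raise ValueError(f"fraction {self.fraction_id}: ribosome_weight must be >= 1")
        for name in ("a260_area", "pooled_volume_ul", "rt_input_fraction_volume_ul",
                     "rna_extraction_volume_ul"):
            if getattr(self, name) <= 0 and name != "a260_area":
                raise ValueError(f"fraction {self.fraction_id}: {name} must be > 0")
        if self.a260_area < 0:
            raise ValueError(f"fraction {self.fraction_id}: negative a260_area")


@dataclass
class Gradient:
    """One gradient (one culture/replicate) with its fractions and input CTs."""

    gradient_id: str
    fractions: List[GradientFraction]
    input_ct: Dict[str, float]    # unfractionated extract: targets, 18S, ACT1
    genotype: str = ""
    condition: str = ""
    replicate: int = 1
    monosome_area: float = 0.0
    polysome_area: float = 0.0
    input_volume_fraction: float = 0.2  # RNA extracted from 1/5 of the input WCE
    rna_extraction_total_ul: float = 25.0

    def __post_init__(self) -> None:
        weights = [f.ribosome_weight for f in self.fractions]
        if any(b <= a for a, b in zip(weights, weights[1:])):
            raise ValueError(
                f"gradient {self.gradient_id}: ribosome weights must strictly increase"
            )
        if not self.monosome_area:
            self.monosome_area = sum(
                f.a260_area for f in self.fractions if f.ribosome_weight == 1
            )
        if not self.polysome_area:
            self.polysome_area = sum(
                f.a260_area for f in self.fractions if f.ribosome_weight > 1
            )

    @property
    def total_mono_poly_area(self) -> float:
        return self.monosome_area + self.polysome_area


@dataclass
class GradientDataset:
    """Gradients processed in parallel (sharing a gradient-recovery baseline)."""

    gradients: List[Gradient]

    def __post_init__(self) -> None:
        ids = [g.gradient_id for g in self.gradients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gradient_id")

    def __getitem__(self, gradient_id: str) -> Gradient:
        for g in self.gradients:
            if g.gradient_id == gradient_id:
                return g
        raise KeyError(gradient_id)


@dataclass
class TEEstimate:
    """TE of one mRNA in one gradient."""

    gradient_id: str
    target: str
    te: float
    available: bool = True
    n_fractions_used: int = 0


def pm_ratio(monosome_area: float, polysome_area: float) -> float:
    """Bulk polysome-to-monosome A260 ratio."""
    if monosome_area <= 0:
        raise ValueError("monosome_area must be > 0")
    return polysome_area / monosome_area


def qpcr_abundance(ct_target: float, ct_18s: float) -> float:
    """18S-relative abundance by the 2^-CT method: 2^-(CT_target - CT_18S)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_18s)):
        raise ValueError("CT values must be finite")
    return 2.0 ** (-(ct_target - ct_18s))


def volume_corrections(fraction: GradientFraction, extraction_total_ul: float = 25.0) -> float:
    """Fraction-volume and RT-input corrections:
    (pooled volume / extraction volume) x (25 uL / volume containing 5 ug RNA)."""
    return (fraction.pooled_volume_ul / fraction.rna_extraction_volume_ul) * (
        extraction_total_ul / fraction.rt_input_fraction_volume_ul
    )


def recovery_factor(fraction_a260_share: float, fraction_18s_share: float) -> float:
    """RNA-recovery correction: A260 share of the fraction over its 18S share."""
    if fraction_18s_share <= 0:
        raise ValueError("18S share must be > 0")
    if not 0 < fraction_a260_share <= 1 or fraction_18s_share > 1:
        raise ValueError("shares must lie in (0, 1]")
    return fraction_a260_share / fraction_18s_share


def gradient_recovery_factor(mono_poly_totals: Sequence[float]) -> List[float]:
    """Per-gradient recovery multipliers: mean(totals) / total_g."""
    totals = list(mono_poly_totals)
    if not totals:
        raise ValueError("at least one gradient required")
    if any(t <= 0 for t in totals):
        raise ValueError("totals must be > 0")
    mean = sum(totals) / len(totals)
    return [mean / t for t in totals]


def _fraction_18s_amounts(gradient: Gradient) -> List[Optional[float]]:
    """Volume-corrected 18S amounts per fraction (None where CT missing)."""
    amounts: List[Optional[float]] = []
    for f in gradient.fractions:
        ct = f.ct.get(RRNA_18S)
        if ct is None or not math.isfinite(ct):
            amounts.append(None)
        else:
            amounts.append(2.0 ** (-ct) * volume_corrections(f, gradient.rna_extraction_total_ul))
    return amounts


def reconstruct_te(
    gradient: Gradient,
    target: str,
    gradient_recovery: float = 1.0,
) -> TEEstimate:
    """TE of ``target`` in one gradient via the full normalization chain.

    Fractions missing a CT for the target or 18S are excluded with a warning;
    the estimate is flagged unavailable if no fraction or a required input CT
    is missing.
    """
    for key in (target, RRNA_18S, ACT1):
        ct = gradient.input_ct.get(key)
        if ct is None or not math.isfinite(ct):
            logger.warning("gradient %s: missing input CT for %s", gradient.gradient_id, key)
            return TEEstimate(gradient.gradient_id, target, math.nan, available=False)

    amounts_18s = _fraction_18s_amounts(gradient)
    total_area = sum(f.a260_area for f in gradient.fractions)
    total_18s = sum(a for a in amounts_18s if a is not None)
    if total_area <= 0 or total_18s <= 0:
        return TEEstimate(gradient.gradient_id, target, math.nan, available=False)

    weighted_sum = 0.0
    n_used = 0
    for f, a18 in zip(gradient.fractions, amounts_18s):
        ct_t = f.ct.get(target)
        if ct_t is None or not math.isfinite(ct_t) or a18 is None:
            logger.warning(
                "gradient %s fraction %s: missing CT; fraction excluded",
                gradient.gradient_id, f.fraction_id,
            )
            continue
        rel = qpcr_abundance(ct_t, f.ct[RRNA_18S])
        vc = volume_corrections(f, gradient.rna_extraction_total_ul)
        rf = recovery_factor(f.a260_area / total_area, a18 / total_18s)
        a_i = rel * vc * rf * gradient_recovery
        weighted_sum += f.ribosome_weight * a_i
        n_used += 1
    if n_used == 0:
        return TEEstimate(gradient.gradient_id, target, math.nan, available=False)

    input_scale = 1.0 / gradient.input_volume_fraction
    input_target = qpcr_abundance(gradient.input_ct[target], gradient.input_ct[RRNA_18S]) * input_scale
    input_act1 = qpcr_abundance(gradient.input_ct[ACT1], gradient.input_ct[RRNA_18S]) * input_scale
    te = weighted_sum / (input_target / input_act1)
    return TEEstimate(gradient.gradient_id, target, te, available=True, n_fractions_used=n_used)


def reconstruct_all(dataset: GradientDataset, targets: Sequence[str]) -> pd.DataFrame:
    """TE per target per gradient, applying cross-gradient recovery factors.

    Returns a frame with columns gradient_id, genotype, condition, replicate,
    target, te, available.
    """
    grf = gradient_recovery_factor([g.total_mono_poly_area for g in dataset.gradients])
    rows = []
    for g, factor in zip(dataset.gradients, grf):
        for target in targets:
            est = reconstruct_te(g, target, gradient_recovery=factor)
            rows.append(
                {
                    "gradient_id": g.gradient_id,
                    "genotype": g.genotype,
                    "condition": g.condition,
                    "replicate": g.replicate,
                    "target": target,
                    "te": est.te,
                    "available": est.available,
                }
            )
    return pd.DataFrame(rows)


def summarize_delta_te(
    estimates: pd.DataFrame,
    target: str,
    treated: str = "SM",
    untreated: str = "untreated",
) -> pd.DataFrame:
    """Per-strain SM-induced TE change with a between-strain Welch t-test.

    For each genotype, per-replicate ratios TE(treated)/TE(untreated) are
    paired by replicate index; the output has one row per genotype with the
    mean ratio, its SEM, n, and the two-sided t-test p-value for the
    difference in mean ratios between the two genotypes (identical degenerate
    samples give p = 1).
    """
    sub = estimates[(estimates["target"] == target) & estimates["available"]]
    ratios: Dict[str, List[float]] = {}
    for geno, block in sub.groupby("genotype"):
        t = block[block["condition"] == treated].set_index("replicate")["te"]
        u = block[block["condition"] == untreated].set_index("replicate")["te"]
        common = t.index.intersection(u.index)
        if len(common) < 2:
            raise ValueError(
                f"target {target}, genotype {geno}: need >= 2 paired replicates, got {len(common)}"
            )
        if len(t) != len(u) or len(common) != len(t):
            raise ValueError(f"target {target}, genotype {geno}: unpaired replicates")
        ratios[geno] = list((t.loc[common] / u.loc[common]).to_numpy())
    genos = sorted(ratios)
    if len(genos) != 2:
        raise ValueError("exactly two genotypes are required for the between-strain test")
    a, b = (np.asarray(ratios[g]) for g in genos)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
    else:
        import warnings

        with warnings.catch_warnings():
            # near-identical replicate ratios trigger a scipy precision warning
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(scipy.stats.ttest_ind(a, b, equal_var=False).pvalue)
    rows = []
    for geno in genos:
        r = np.asarray(ratios[geno])
        rows.append(
            {
                "target": target,
                "genotype": geno,
                "mean_delta_te": float(r.mean()),
                "sem": float(r.std(ddof=1) / np.sqrt(r.size)),
                "n": int(r.size),
                "t_p": p,
            }
        )
    return pd.DataFrame(rows)
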