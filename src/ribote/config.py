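"""Analysis configuration shared across the pipeline.

All thresholds that the downstream analyses apply live here so that a single
YAML file documents an entire run.  Defaults follow the study design this
package models: a 3'-end footprint shift of 18 nt (first motif codon in the
E site), a +/-50 nt pause-score window, a 100-occurrence motif floor, uORF
filters of mean RPF >= 2 and mean CDS RPF >= 32, FDR thresholds of 0.25
(loose, for highly correlated replicate pairs) and 0.01 (strict), and a
1.41-fold (0.5 log2) selection threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    """Tunable parameters for every pipeline stage.

    Parameters
    ----------
    shift_nt
        Offset subtracted from footprint 3'-end coordinates when assigning
        ribosome positions (nt).
    window_nt
        Half-width of the flanking window used for pause-score backgrounds (nt).
    min_motif_occurrences
        Tripeptide motifs observed fewer times than this across the
        translatome are excluded from pause-score summaries.
    uorf_min_mean_rpf, cds_min_mean_rpf
        Mean raw RPF count floors (over the combined samples of a contrast)
        below which a uORF, or its host CDS, disqualifies the uORF from RRO
        analysis.
    fdr_strict, fdr_loose
        BH FDR thresholds used for discovery calls.
    fold_threshold
        Fold-change used by strict ">fold" gene-set selections.
    classifier_down_log2, classifier_lesser_log2
        Log2 thresholds of the conditional-dependence pattern classifier:
        contrasts 1-2 must fall at or below ``classifier_down_log2`` and
        contrasts 3-4 at or above ``classifier_lesser_log2``.
    dispersion_shrink
        Weight pulling gene-wise NB dispersion estimates toward the fitted
        mean-dispersion trend; a float in [0, 1] or ``"auto"`` for an
        empirical-Bayes weight derived from the data.
    te_pseudocount
        Optional pseudocount added to RNA counts when forming per-sample TE
        ratios (0 disables; zero-RNA genes are then excluded).
    te_cds_only
        If True (default) mRNA reads are counted over the CDS span only,
        mirroring the RPF region; if False, whole-transcript mRNA counts are
        used where region information is available.
    pause_numerator
        ``"span"`` uses the mean rpm over the whole 9-nt motif span as the
        pause-score numerator; ``"a_site"`` uses the A-site codon only.
    pause_flank_excludes_motif
        If True (default) the motif span is excluded from its own background
        window.
    rng_seed
        Seed recorded for provenance; simulators take explicit seeds.
    """

    shift_nt: int = 18
    window_nt: int = 50
    min_motif_occurrences: int = 100
    uorf_min_mean_rpf: float = 2.0
    cds_min_mean_rpf: float = 32.0
    fdr_strict: float = 0.01
    fdr_loose: float = 0.25
    fold_threshold: float = 1.41
    classifier_down_log2: float = -0.5
    classifier_lesser_log2: float = -0.25
    dispersion_shrink: Union[float, str] = "auto"
    te_pseudocount: float = 0.0
    te_cds_only: bool = True
    pause_numerator: str = "span"
    pause_flank_excludes_motif: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.shift_nt < 0:
            raise ValueError("shift_nt must be >= 0")
        if self.window_nt <= 0:
            raise ValueError("window_nt must be > 0")
        for name in ("min_motif_occurrences", "uorf_min_mean_rpf", "cds_min_mean_rpf",
                     "fdr_strict", "fdr_loose", "fold_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.classifier_down_log2 > 0 or self.classifier_lesser_log2 > 0:
            raise ValueError("classifier thresholds must be <= 0")
        if isinstance(self.dispersion_shrink, str):
            if self.dispersion_shrink != "auto":
                raise ValueError("dispersion_shrink must be a float in [0,1] or 'auto'")
        elif not 0.0 <= float(self.dispersion_shrink) <= 1.0:
            raise ValueError("dispersion_shrink must be in [0, 1]")
        if self.pause_numerator not in ("span", "a_site"):
            raise ValueError("pause_numerator must be 'span' or 'a_site'")


def load_config(path: Union[str, Path]) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML mapping (missing keys take defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


def save_config(config: AnalysisConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
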