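"""Tripeptide pause scores from shifted footprint tracks.

Footprint 3'-end counts are shifted 18 nt upstream so that, for a tripeptide
motif, the first codon sits in the ribosomal E site and the third in the A
site.  The pause score of one motif occurrence is the mean rpm over the 9-nt
motif span divided by the mean rpm of the +/-50 nt flanking window (motif
span excluded by default); a motif's score is the arithmetic mean over its
occurrences, and motifs seen fewer than 100 times across the translatome are
excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .config import AnalysisConfig
from .track import FootprintTrack

__all__ = [
    "PauseScoreTable",
    "shift_assign",
    "motif_sites",
    "pause_scores",
    "compare_pause",
]

logger = logging.getLogger(__name__)

MOTIF_NT = 9  # three codons


@dataclass
class PauseScoreTable:
    """Mean pause score per tripeptide motif.

    ``table`` is indexed by motif with columns mean_score, n_occurrences,
    n_scored (occurrences with a nonzero flank mean) and included.
    """

    table: pd.DataFrame

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["included"]]


def shift_assign(
    raw_3prime: Dict[str, np.ndarray],
    shift_nt: int,
    library_size: Optional[float] = None,
) -> FootprintTrack:
    """Move 3'-end counts ``shift_nt`` upstream to ribosome positions.

    Counts that would land below position 0 are dropped (and counted in
    ``dropped_reads``); total reads are otherwise conserved.
    """
    if shift_nt < 0:
        raise ValueError("shift_nt must be >= 0")
    shifted: Dict[str, np.ndarray] = {}
    dropped = 0.0
    for tid, arr in raw_3prime.items():
        arr = np.asarray(arr, dtype=float)
        out = np.zeros_like(arr)
        if shift_nt == 0:
            out[:] = arr
        else:
            out[: max(arr.size - shift_nt, 0)] = arr[shift_nt:]
            dropped += float(arr[:shift_nt].sum())
    # positions i carry reads whose 3' end was at i + shift
        shifted[tid] = out
    if dropped:
        logger.info("shift_assign: dropped %.0f reads shifted below position 0", dropped)
    return FootprintTrack(shifted, library_size=library_size, dropped_reads=dropped)


def motif_sites(
    annotation: GenomeAnnotation,
    peptides: Dict[str, str],
    window_nt: int = 50,
) -> Dict[str, List[Tuple[str, int]]]:
    """Occurrence list per tripeptide motif, keeping only window-safe sites.

    For the tripeptide starting at codon k of a CDS, the 9-nt span is
    [cds_start + 3k, cds_start + 3k + 9); the occurrence is kept only if the
    +/-``window_nt`` flanks fit inside the CDS.  Returns motif ->
    [(transcript_id, span_start_in_transcript_coords), ...].
    """
    sites: Dict[str, List[Tuple[str, int]]] = {}
    for tx in annotation:
        pep = peptides.get(tx.transcript_id)
        if pep is None:
            continue
        if len(pep) != tx.n_codons - 1:
            raise ValueError(
                f"transcript {tx.transcript_id}: peptide length {len(pep)} != "
                f"{tx.n_codons - 1} (CDS codons minus stop)"
            )
        cds_len = tx.cds_length
        for k in range(len(pep) - 2):
            start_in_cds = 3 * k
            if start_in_cds < window_nt:
                continue
            if start_in_cds + MOTIF_NT + window_nt > cds_len:
                continue
            motif = pep[k : k + 3]
            sites.setdefault(motif, []).append((tx.transcript_id, tx.cds_start + start_in_cds))
    return sites


def pause_scores(
    track: FootprintTrack,
    sites: Dict[str, List[Tuple[str, int]]],
    config: Optional[AnalysisConfig] = None,
) -> PauseScoreTable:
    """Mean pause score per motif from one library's track.

    Occurrences with a zero flank mean are skipped (logged, not scored as
    infinite).  Motifs with fewer than ``config.min_motif_occurrences``
    occurrences are marked not included.
    """
    config = config or AnalysisConfig()
    if not any(sites.values()):
        raise ValueError("empty site lists for all motifs")
    w = config.window_nt
    rpm_cache: Dict[str, np.ndarray] = {}
    rows = []
    n_skipped_total = 0
    for motif, occ in sorted(sites.items()):
        scores = []
        for tid, s in occ:
            rpm = rpm_cache.get(tid)
            if rpm is None:
                rpm = rpm_cache[tid] = track.rpm(tid)
            span = rpm[s : s + MOTIF_NT]
            if config.pause_numerator == "a_site":
                num = float(span[6:9].mean())
            else:
                num = float(span.mean())
            if config.pause_flank_excludes_motif:
                flank = np.concatenate([rpm[s - w : s], rpm[s + MOTIF_NT : s + MOTIF_NT + w]])
            else:
                flank = rpm[s - w : s + MOTIF_NT + w]
            den = float(flank.mean())
            if den == 0.0:
                n_skipped_total += 1
                continue
            scores.append(num / den)
        rows.append(
            {
                "motif": motif,
                "mean_score": float(np.mean(scores)) if scores else np.nan,
                "n_occurrences": len(occ),
                "n_scored": len(scores),
                "included": len(occ) >= config.min_motif_occurrences,
            }
        )
    if n_skipped_total:
        logger.info("pause_scores: skipped %d occurrences with zero flank mean", n_skipped_total)
    table = pd.DataFrame(rows).set_index("motif")
    return PauseScoreTable(table)


def compare_pause(
    table_a: PauseScoreTable,
    table_b: PauseScoreTable,
    a_site_residue: Optional[str] = None,
) -> pd.DataFrame:
    """Inner join of two pause-score tables on motifs included in both.

    Returns a frame with columns score_a, score_b and (if ``a_site_residue``
    is given) ``flagged`` marking motifs whose third residue — the A-site
    codon under the E-site-first convention — equals it.
    """
    a = table_a.included["mean_score"]
    b = table_b.included["mean_score"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no motifs included in both tables")
    out = pd.DataFrame({"score_a": a.loc[common], "score_b": b.loc[common]})
    if a_site_residue is not None:
        if len(a_site_residue) != 1:
            raise ValueError("a_site_residue must be a single amino-acid letter")
        out["flagged"] = [m[2] == a_site_residue for m in common]
    return out
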