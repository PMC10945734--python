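"""Quantification: region counts, rpkm, and per-sample translational efficiency.

Translational efficiency (TE) of a gene is the ratio of its ribosome-footprint
(RPF) reads summed over the CDS to its mRNA reads, after per-library size
normalization.  TE is computed per (genotype, condition, replicate) cell from
the paired RPF and RNA libraries of that cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .design import Assay, Condition, Genotype, SampleDesign
from .track import FootprintTrack

__all__ = ["CountTable", "TEMatrix", "count_region", "rpkm", "compute_te", "counts_from_track"]


@dataclass
class CountTable:
    """Gene x sample integer read counts plus optional uORF region counts.

    ``counts`` columns are sample_ids aligned with ``samples``; CDS counts for
    RPF libraries and (by default) CDS-span mRNA counts for RNA libraries.
    ``region_counts`` rows are uorf_ids over the RPF samples.
    """

    counts: pd.DataFrame
    samples: List[SampleDesign]
    region_counts: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise ValueError("counts columns must match design sample_ids in order")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("non-integer counts")
        self.counts = self.counts.astype(np.int64)
        if self.region_counts is not None:
            rc = self.region_counts.to_numpy()
            if (rc < 0).any():
                raise ValueError("negative region counts")
            self.region_counts = self.region_counts.astype(np.int64)
        # resolve library sizes: design override, else column sum
        self._library_sizes = {}
        for s in self.samples:
            col_sum = int(self.counts[s.sample_id].sum())
            self._library_sizes[s.sample_id] = (
                s.library_size if s.library_size is not None else col_sum
            )

    @property
    def genes(self) -> List[str]:
        return list(self.counts.index)

    def library_size(self, sample_id: str) -> int:
        return self._library_sizes[sample_id]

    def sample(self, sample_id: str) -> SampleDesign:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select(
        self,
        genotype: Optional[Genotype] = None,
        condition: Optional[Condition] = None,
        assay: Optional[Assay] = None,
        cells: Optional[Sequence[Tuple[Genotype, Condition]]] = None,
    ) -> List[SampleDesign]:
        """Samples matching the given factors (None matches everything)."""
        out = []
        for s in self.samples:
            if genotype is not None and s.genotype != genotype:
                continue
            if condition is not None and s.condition != condition:
                continue
            if assay is not None and s.assay != assay:
                continue
            if cells is not None and s.cell not in [tuple(c) for c in cells]:
                continue
            out.append(s)
        return out

    def subset(self, sample_ids: Sequence[str]) -> "CountTable":
        samples = [self.sample(sid) for sid in sample_ids]
        rc = None
        if self.region_counts is not None:
            keep = [sid for sid in sample_ids if sid in self.region_counts.columns]
            rc = self.region_counts[keep].copy() if keep else None
        return CountTable(self.counts[list(sample_ids)].copy(), samples, rc)


@dataclass
class TEMatrix:
    """Per-gene, per-cell TE values; genes with undefined TE are excluded with a reason."""

    te: pd.DataFrame          # gene x cell-key, positive reals
    excluded_genes: pd.Series  # gene -> reason code

    @property
    def log2_te(self) -> pd.DataFrame:
        return np.log2(self.te)


def count_region(
    track: FootprintTrack,
    annotation: GenomeAnnotation,
    region: Union[str, Tuple[str, int, int]],
) -> int:
    """Integer read count over a region of a transcript.

    ``region`` is either a transcript id (its CDS), a uORF id, or an explicit
    (transcript_id, start, end) half-open span.
    """
    if isinstance(region, tuple):
        tid, start, end = region
    elif region in annotation:
        tx = annotation[region]
        tid, start, end = tx.transcript_id, tx.cds_start, tx.cds_end
    else:
        tx = annotation.host_of(region)  # raises KeyError for unknown ids
        u = next(u for u in tx.uorfs if u.uorf_id == region)
        tid, start, end = tx.transcript_id, u.start, u.end
    if tid not in track.density:
        return 0
    arr = track.density[tid]
    return int(round(float(arr[start:end].sum())))


def counts_from_track(
    track: FootprintTrack,
    annotation: GenomeAnnotation,
    sample: SampleDesign,
) -> Tuple[pd.Series, pd.Series]:
    """CDS counts per gene and uORF counts per uORF for one library's track."""
    cds = pd.Series(
        {tx.transcript_id: count_region(track, annotation, tx.transcript_id) for tx in annotation},
        name=sample.sample_id,
    )
    uorf = pd.Series(
        {u.uorf_id: count_region(track, annotation, u.uorf_id) for u in annotation.uorfs()},
        name=sample.sample_id,
        dtype=np.int64,
    )
    return cds, uorf


def rpkm(count: float, region_length: int, library_size: float) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_length <= 0:
        raise ValueError("region_length must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count / ((region_length / 1e3) * (library_size / 1e6))


def compute_te(
    counts: CountTable,
    size_factors: pd.Series,
    pseudocount: float = 0.0,
) -> TEMatrix:
    """Per-cell TE = (RPF count / RPF size factor) / (RNA count / RNA size factor).

    Samples are paired within each (genotype, condition, replicate) cell.
    Genes with a zero RNA count in any paired sample are excluded with reason
    ``zero_rna`` unless ``pseudocount`` > 0.
    """
    pairs: Dict[Tuple[str, str, int], Dict[Assay, SampleDesign]] = {}
    for s in counts.samples:
        key = (s.genotype.value, s.condition.value, s.replicate)
        pairs.setdefault(key, {})[s.assay] = s
    for key, d in pairs.items():
        if set(d) != {Assay.RPF, Assay.RNA}:
            raise ValueError(f"cell {key} lacks a paired RPF/RNA sample")

    te_cols = {}
    zero_rna = pd.Series(False, index=counts.counts.index)
    for (geno, cond, rep), d in pairs.items():
        rpf = counts.counts[d[Assay.RPF].sample_id].astype(float)
        rna = counts.counts[d[Assay.RNA].sample_id].astype(float) + pseudocount
        zero_rna |= rna == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            te_cols[f"{geno}:{cond}:{rep}"] = (
                (rpf / size_factors[d[Assay.RPF].sample_id])
                / (rna / size_factors[d[Assay.RNA].sample_id])
            )
    te = pd.DataFrame(te_cols, index=counts.counts.index)
    # zero RPF with nonzero RNA gives TE 0, which has no log2; exclude as zero_rpf
    zero_rpf = (te == 0).any(axis=1) & ~zero_rna
    excluded = pd.Series(
        np.where(zero_rna, "zero_rna", np.where(zero_rpf, "zero_rpf", "")),
        index=te.index,
    )
    excluded = excluded[excluded != ""]
    return TEMatrix(te=te.drop(index=excluded.index), excluded_genes=excluded)
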