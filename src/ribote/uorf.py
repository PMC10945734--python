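"""uORF relative ribosome occupancy (RRO) and uORF-group TE summaries.

RRO of a uORF is its RPF count divided by the RPF count of the host CDS, a
within-library ratio (no size factors needed).  uORFs with mean RPF counts
below 2, or host CDS mean RPF counts below 32, over the combined samples of a
comparison are excluded.  Changes in RRO between genotypes reuse the
interaction machinery of :mod:`ribote.diffte` with (uORF, CDS) counts playing
the roles of (RPF, RNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
import scipy.stats

from .annotation import GenomeAnnotation
from .config import AnalysisConfig
from .design import Assay, SampleDesign
from .diffte import ContrastResult, ContrastSpec, DifferentialTE, DifferentialTEResults
from .quant import CountTable

__all__ = ["RROTable", "GroupSummary", "compute_rro", "delta_rro", "group_te_summary"]


@dataclass
class RROTable:
    """Per-uORF RRO values and filter flags.

    ``rro`` is uORF x sample; ``summary`` carries mean_uorf_rpf, mean_cds_rpf
    and filter_status (pass / low_uorf / low_cds) per uORF.
    """

    rro: pd.DataFrame
    summary: pd.DataFrame

    @property
    def passing(self) -> List[str]:
        return list(self.summary.index[self.summary["filter_status"] == "pass"])


@dataclass
class GroupSummary:
    """Median TE change of one gene group per contrast, with a Mann-Whitney U
    test against the all-mRNA background."""

    group: str
    n: int
    median_log2_effect: float
    mannwhitney_p: float


def _host_map(annotation: GenomeAnnotation) -> Dict[str, str]:
    return {u.uorf_id: u.transcript_id for u in annotation.uorfs()}


def compute_rro(
    counts: CountTable,
    annotation: GenomeAnnotation,
    config: Optional[AnalysisConfig] = None,
) -> RROTable:
    """RRO per uORF per RPF sample, with the count filters applied.

    Mean counts are arithmetic means of raw counts over all RPF samples in
    ``counts`` (the combined samples of the comparison); ``low_uorf`` takes
    precedence over ``low_cds`` when both filters fail.
    """
    config = config or AnalysisConfig()
    if counts.region_counts is None:
        raise ValueError("CountTable has no uORF region counts")
    hosts = _host_map(annotation)
    rpf_cols = [s.sample_id for s in counts.samples
                if s.assay == Assay.RPF and s.sample_id in counts.region_counts.columns]
    if not rpf_cols:
        raise ValueError("no RPF samples with region counts")
    uorf_ids = list(counts.region_counts.index)
    for uid in uorf_ids:
        if uid not in hosts:
            raise ValueError(f"uORF {uid} not in annotation")
        if hosts[uid] not in counts.counts.index:
            raise ValueError(f"uORF {uid}: host CDS {hosts[uid]} missing from counts")
    u = counts.region_counts.loc[uorf_ids, rpf_cols].to_numpy(dtype=float)
    c = counts.counts.loc[[hosts[x] for x in uorf_ids], rpf_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rro = np.where(c > 0, u / np.maximum(c, 1e-300), np.nan)
    mean_u = u.mean(axis=1)
    mean_c = c.mean(axis=1)
    status = np.where(
        mean_u < config.uorf_min_mean_rpf,
        "low_uorf",
        np.where(mean_c < config.cds_min_mean_rpf, "low_cds", "pass"),
    )
    return RROTable(
        rro=pd.DataFrame(rro, index=uorf_ids, columns=rpf_cols),
        summary=pd.DataFrame(
            {
                "host": [hosts[x] for x in uorf_ids],
                "mean_uorf_rpf": mean_u,
                "mean_cds_rpf": mean_c,
                "filter_status": status,
            },
            index=pd.Index(uorf_ids, name="uorf_id"),
        ),
    )


def delta_rro(
    counts: CountTable,
    annotation: GenomeAnnotation,
    contrast: ContrastSpec,
    config: Optional[AnalysisConfig] = None,
    method: str = "wald",
) -> DifferentialTEResults:
    """Differential RRO between the contrast's cells for filter-passing uORFs.

    Builds a per-uORF two-assay table (uORF counts as the footprint role, host
    CDS counts as the denominator role) and fits the same NB interaction
    model as :func:`ribote.diffte.delta_te`.  Size factors are unit: RRO is a
    within-library ratio, so depth cancels.
    """
    config = config or AnalysisConfig()
    cells = [tuple(contrast.numerator_cell), tuple(contrast.denominator_cell)]
    rpf_samples = [s for s in counts.select(cells=cells) if s.assay == Assay.RPF]
    sub = counts.subset([s.sample_id for s in rpf_samples])
    rro = compute_rro(sub, annotation, config)
    passing = rro.passing
    if not passing:
        raise ValueError("no uORFs pass the count filters")
    hosts = _host_map(annotation)

    role_samples: List[SampleDesign] = []
    cols: Dict[str, pd.Series] = {}
    for s in rpf_samples:
        for role, assay in (("uorf", Assay.RPF), ("cds", Assay.RNA)):
            sid = f"{s.sample_id}:{role}"
            role_samples.append(
                SampleDesign(
                    sample_id=sid,
                    genotype=s.genotype,
                    condition=s.condition,
                    replicate=s.replicate,
                    assay=assay,
                )
            )
            if role == "uorf":
                cols[sid] = counts.region_counts.loc[passing, s.sample_id]
            else:
                host_counts = counts.counts.loc[[hosts[x] for x in passing], s.sample_id]
                cols[sid] = pd.Series(host_counts.to_numpy(), index=passing)
    table = pd.DataFrame(cols, index=passing)
    role_table = CountTable(table[[s.sample_id for s in role_samples]], role_samples)
    unit_sf = pd.Series(1.0, index=[s.sample_id for s in role_samples])
    model = DifferentialTE(role_table, contrast, config=config, size_factors_=unit_sf)
    return model.fit(method)


def group_te_summary(
    result: ContrastResult,
    groups: Dict[str, Set[str]],
    disjoint_background: bool = False,
) -> List[GroupSummary]:
    """Median log2 TE change per gene group with a two-sided Mann-Whitney U
    p-value versus all tested mRNAs.

    By default the background includes the group itself (a group is compared
    against "all mRNAs"); set ``disjoint_background`` to exclude it.
    """
    tested = result.tested["log2_effect"]
    out = []
    for name, genes in groups.items():
        members = sorted(set(genes) & set(tested.index))
        if not members:
            raise ValueError(f"group {name} has no tested genes")
        missing = set(genes) - set(result.table.index)
        if missing:
            raise ValueError(f"group {name}: genes not in result: {sorted(missing)[:5]}")
        values = tested.loc[members]
        background = tested.drop(index=members) if disjoint_background else tested
        u = scipy.stats.mannwhitneyu(values, background, alternative="two-sided")
        out.append(
            GroupSummary(
                group=name,
                n=len(members),
                median_log2_effect=float(values.median()),
                mannwhitney_p=float(u.pvalue),
            )
        )
    return out
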