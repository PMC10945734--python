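"""Readers and writers for the pipeline's external formats.

Counts, designs, uORF lists and all result tables are TSV; footprint tracks
are bedGraph in transcript coordinates; qPCR plates and fraction metadata are
CSV.  Floats are written with 6 significant digits, so every table
round-trips within 1e-5 relative error.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .design import SampleDesign, read_design
from .diffte import ContrastResult, ContrastSpec
from .polysome import Gradient, GradientDataset, GradientFraction
from .quant import CountTable
from .track import FootprintTrack

__all__ = [
    "load_counts",
    "write_counts",
    "write_results",
    "read_results",
    "write_table",
    "read_table",
    "write_bedgraph",
    "read_bedgraph",
    "write_gradient_csvs",
    "read_gradient_csvs",
]

FLOAT_FORMAT = "%.6g"

PathLike = Union[str, Path]


def load_counts(
    tsv_path: PathLike,
    design_path: PathLike,
    region_tsv_path: Optional[PathLike] = None,
) -> CountTable:
    """Load a gene x sample count TSV plus its design table (and optional uORF
    region counts).  Library sizes default to column sums unless the design
    overrides them."""
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    samples = read_design(design_path)
    ids = [s.sample_id for s in samples]
    missing = set(df.columns) - set(ids)
    if missing:
        raise ValueError(f"samples in counts missing from design: {sorted(missing)}")
    region = None
    if region_tsv_path is not None:
        region = pd.read_csv(region_tsv_path, sep="\t", index_col=0)
    # CountTable validates non-negative integers and column order
    return CountTable(df[ids], samples, region)


def write_counts(counts: CountTable, tsv_path: PathLike,
                 region_tsv_path: Optional[PathLike] = None) -> None:
    counts.counts.to_csv(tsv_path, sep="\t")
    if region_tsv_path is not None and counts.region_counts is not None:
        counts.region_counts.to_csv(region_tsv_path, sep="\t")


def write_table(df: pd.DataFrame, path: PathLike, sort_index: bool = True) -> None:
    """Deterministic TSV: fixed column order, sorted rows, 6 significant digits."""
    out = df.sort_index() if sort_index else df
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_results(result: ContrastResult, path: PathLike) -> None:
    """Write a contrast result as TSV (gene, log2_effect, se, p, q, status),
    gene-sorted; a header comment records the contrast definition."""
    cols = list(ContrastResult.REQUIRED_COLUMNS)
    with open(path, "w") as fh:
        c = result.contrast
        fh.write(
            f"# contrast={c.name}\tnumerator={c.numerator_cell[0].value}:{c.numerator_cell[1].value}"
            f"\tdenominator={c.denominator_cell[0].value}:{c.denominator_cell[1].value}"
            f"\tfdr_threshold={c.fdr_threshold:g}\n"
        )
        result.table[cols].sort_index().to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)


def read_results(path: PathLike) -> ContrastResult:
    from .design import Condition, Genotype

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# contrast="):
            raise ValueError(f"{path}: missing contrast header")
        fields = dict(item.split("=", 1) for item in header[2:].strip().split("\t"))
        table = pd.read_csv(fh, sep="\t", index_col=0)

    def parse_cell(text: str):
        geno, cond = text.split(":")
        return (Genotype(geno), Condition(cond))

    spec = ContrastSpec(
        name=fields["contrast"],
        numerator_cell=parse_cell(fields["numerator"]),
        denominator_cell=parse_cell(fields["denominator"]),
        fdr_threshold=float(fields["fdr_threshold"]),
    )
    return ContrastResult(contrast=spec, table=table)


# ---------------------------------------------------------------------------
# bedGraph tracks (transcript coordinates, 0-based half-open)


def write_bedgraph(track: FootprintTrack, path: PathLike) -> None:
    """Run-length-merged bedGraph of per-nt density; zero runs are omitted."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph library_size={track.library_size:g}\n')
        for tid in sorted(track.density):
            arr = track.density[tid]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{tid}\t{s}\t{e}\t{FLOAT_FORMAT % v}\n")


def read_bedgraph(path: PathLike, annotation: GenomeAnnotation) -> FootprintTrack:
    """Read a transcript-space bedGraph; transcript lengths come from the annotation."""
    density = {tx.transcript_id: np.zeros(tx.length) for tx in annotation}
    library_size = None
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")):
                for token in line.split():
                    if token.startswith("library_size="):
                        library_size = float(token.split("=", 1)[1])
                continue
            tid, s, e, v = line.rstrip("\n").split("\t")
            if tid not in density:
                raise ValueError(f"bedGraph transcript {tid} not in annotation")
            s, e = int(s), int(e)
            if not 0 <= s < e <= density[tid].size:
                raise ValueError(f"bedGraph interval {tid}:{s}-{e} outside transcript")
            density[tid][s:e] = float(v)
    return FootprintTrack(density, library_size=library_size)


# ---------------------------------------------------------------------------
# Polysome gradient CSVs


def write_gradient_csvs(
    dataset: GradientDataset, qpcr_path: PathLike, fractions_path: PathLike
) -> None:
    """qPCR plate CSV (gradient_id, fraction_id|input, target, ct) and fraction
    metadata CSV (geometry, areas, volumes, design factors)."""
    qpcr_rows, frac_rows = [], []
    for g in dataset.gradients:
        for target, ct in sorted(g.input_ct.items()):
            qpcr_rows.append(
                {"gradient_id": g.gradient_id, "fraction_id": "input", "target": target, "ct": ct}
            )
        for f in g.fractions:
            for target, ct in sorted(f.ct.items()):
                qpcr_rows.append(
                    {"gradient_id": g.gradient_id, "fraction_id": f.fraction_id,
                     "target": target, "ct": ct}
                )
            frac_rows.append(
                {
                    "gradient_id": g.gradient_id,
                    "fraction_id": f.fraction_id,
                    "ribosome_weight": f.ribosome_weight,
                    "a260_area": f.a260_area,
                    "pooled_volume_ul": f.pooled_volume_ul,
                    "rt_input_fraction_volume_ul": f.rt_input_fraction_volume_ul,
                    "rna_extraction_volume_ul": f.rna_extraction_volume_ul,
                    "genotype": g.genotype,
                    "condition": g.condition,
                    "replicate": g.replicate,
                }
            )
    pd.DataFrame(qpcr_rows).to_csv(qpcr_path, index=False, float_format="%.10g")
    pd.DataFrame(frac_rows).to_csv(fractions_path, index=False, float_format="%.10g")


def read_gradient_csvs(qpcr_path: PathLike, fractions_path: PathLike) -> GradientDataset:
    qpcr = pd.read_csv(qpcr_path)
    frac = pd.read_csv(fractions_path)
    gradients = []
    for gid, fblock in frac.groupby("gradient_id", sort=False):
        qblock = qpcr[qpcr["gradient_id"] == gid]
        fractions = []
        for row in fblock.itertuples(index=False):
            cts = qblock[qblock["fraction_id"] == row.fraction_id]
            fractions.append(
                GradientFraction(
                    fraction_id=str(row.fraction_id),
                    ribosome_weight=int(row.ribosome_weight),
                    a260_area=float(row.a260_area),
                    pooled_volume_ul=float(row.pooled_volume_ul),
                    rt_input_fraction_volume_ul=float(row.rt_input_fraction_volume_ul),
                    rna_extraction_volume_ul=float(row.rna_extraction_volume_ul),
                    ct=dict(zip(cts["target"], cts["ct"])),
                )
            )
        inputs = qblock[qblock["fraction_id"] == "input"]
        gradients.append(
            Gradient(
                gradient_id=str(gid),
                fractions=fractions,
                input_ct=dict(zip(inputs["target"], inputs["ct"])),
                genotype=str(fblock["genotype"].iloc[0]),
                condition=str(fblock["condition"].iloc[0]),
                replicate=int(fblock["replicate"].iloc[0]),
            )
        )
    return GradientDataset(gradients)
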