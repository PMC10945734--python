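"""Transcript-space annotation: CDS spans and uORF records.

Everything downstream works in transcript-relative, 0-based, half-open
coordinates with the transcript in 5'->3' orientation.  GFF3 input
(1-based, closed) is converted at the boundary; BED12 is already half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "StartCodonClass",
    "UorfSource",
    "UorfRecord",
    "Transcript",
    "GenomeAnnotation",
    "load_annotation",
    "write_annotation_gff3",
    "write_annotation_bed12",
    "write_uorf_tsv",
]


class StartCodonClass(str, Enum):
    """uORF start-codon class: canonical AUG or near-cognate (NCC)."""

    AUG = "AUG"
    NCC = "NCC"


class UorfSource(str, Enum):
    """Which published compilation a uORF belongs to."""

    annotated = "annotated"
    conserved = "conserved"
    functional = "functional"


@dataclass(frozen=True)
class UorfRecord:
    """One upstream ORF on a transcript (0-based half-open nt offsets)."""

    uorf_id: str
    transcript_id: str
    start: int
    end: int
    start_codon_class: StartCodonClass
    annotation_source: UorfSource

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"uORF {self.uorf_id}: start ({self.start}) must precede end ({self.end})"
            )
        if self.start < 0:
            raise ValueError(f"uORF {self.uorf_id}: negative start {self.start}")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(
                f"uORF {self.uorf_id}: length {self.end - self.start} not a multiple of 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """A transcript with one main CDS and optional uORFs."""

    transcript_id: str
    length: int
    cds_start: int
    cds_end: int
    uorfs: List[UorfRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.transcript_id
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise ValueError(
                f"transcript {t}: CDS [{self.cds_start}, {self.cds_end}) outside [0, {self.length})"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"transcript {t}: CDS length {self.cds_end - self.cds_start} not a multiple of 3"
            )
        for u in self.uorfs:
            self._check_uorf(u)

    def _check_uorf(self, u: UorfRecord) -> None:
        if u.end > self.cds_end or u.start >= self.length:
            raise ValueError(
                f"uORF {u.uorf_id} [{u.start}, {u.end}) extends past the CDS end "
                f"({self.cds_end}) of transcript {self.transcript_id}"
            )

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3


class GenomeAnnotation:
    """Ordered collection of transcripts, indexable by id."""

    def __init__(self, transcripts: Sequence[Transcript]):
        self._transcripts: Dict[str, Transcript] = {}
        for tx in transcripts:
            if tx.transcript_id in self._transcripts:
                raise ValueError(f"duplicate transcript id {tx.transcript_id}")
            self._transcripts[tx.transcript_id] = tx

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._transcripts.values())

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self._transcripts[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return list(self) == list(other)

    @property
    def transcript_ids(self) -> List[str]:
        return list(self._transcripts)

    def uorfs(self) -> List[UorfRecord]:
        """All uORFs across the annotation, in transcript order."""
        return [u for tx in self for u in tx.uorfs]

    def host_of(self, uorf_id: str) -> Transcript:
        for tx in self:
            for u in tx.uorfs:
                if u.uorf_id == uorf_id:
                    return tx
        raise KeyError(f"unknown uORF id {uorf_id}")


# ---------------------------------------------------------------------------
# Parsing

def _load_gff3(path: Union[str, Path]) -> Dict[str, Transcript]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: Dict[str, Transcript] = {}
    lengths: Dict[str, int] = {}
    for feat in db.features_of_type(("transcript", "mRNA")):
        tid = feat.attributes.get("ID", [feat.seqid])[0]
        lengths[tid] = feat.end - (feat.start - 1)
        if feat.start != 1:
            raise ValueError(f"transcript {tid}: expected transcript-relative GFF starting at 1")
    cds_spans: Dict[str, List[tuple]] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", [feat.seqid])
        cds_spans.setdefault(parents[0], []).append((feat.start - 1, feat.end))
    for tid, length in lengths.items():
        spans = sorted(cds_spans.get(tid, []))
        if not spans:
            raise ValueError(f"transcript {tid}: no CDS feature")
        start, end = spans[0][0], spans[-1][1]
        transcripts[tid] = Transcript(tid, length, start, end)
    return transcripts


_BED12_COLS = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def _load_bed12(path: Union[str, Path]) -> Dict[str, Transcript]:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS, comment="#")
    transcripts: Dict[str, Transcript] = {}
    for row in df.itertuples(index=False):
        if row.chromStart != 0:
            raise ValueError(f"transcript {row.name}: expected transcript-relative BED starting at 0")
        transcripts[str(row.name)] = Transcript(
            str(row.name), int(row.chromEnd), int(row.thickStart), int(row.thickEnd)
        )
    return transcripts


def _load_uorf_tsv(path: Union[str, Path]) -> List[UorfRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "uorf_start", "uorf_end", "start_codon_class", "annotation_source"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"uORF table missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        uid = getattr(row, "uorf_id", None) or f"{row.transcript_id}_uorf{i}"
        records.append(
            UorfRecord(
                uorf_id=str(uid),
                transcript_id=str(row.transcript_id),
                start=int(row.uorf_start),
                end=int(row.uorf_end),
                start_codon_class=StartCodonClass(str(row.start_codon_class)),
                annotation_source=UorfSource(str(row.annotation_source)),
            )
        )
    return records


def load_annotation(
    path: Union[str, Path],
    uorf_tsv_path: Optional[Union[str, Path]] = None,
) -> GenomeAnnotation:
    """Load transcripts (GFF3 or BED12, inferred from extension) plus an optional uORF table.

    Raises ``ValueError`` naming the offending record for any invariant
    violation (coordinates out of range, CDS length not a multiple of 3,
    uORF outside its transcript, unknown host transcript).
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        transcripts = _load_bed12(path)
    else:
        transcripts = _load_gff3(path)
    if uorf_tsv_path is not None:
        for u in _load_uorf_tsv(uorf_tsv_path):
            if u.transcript_id not in transcripts:
                raise ValueError(f"uORF {u.uorf_id}: unknown transcript {u.transcript_id}")
            tx = transcripts[u.transcript_id]
            tx._check_uorf(u)
            tx.uorfs.append(u)
    return GenomeAnnotation(list(transcripts.values()))


# ---------------------------------------------------------------------------
# Writing

def write_annotation_gff3(annotation: GenomeAnnotation, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in annotation:
            fh.write(
                f"{tx.transcript_id}\tribote\ttranscript\t1\t{tx.length}\t.\t+\t.\t"
                f"ID={tx.transcript_id}\n"
            )
            fh.write(
                f"{tx.transcript_id}\tribote\tCDS\t{tx.cds_start + 1}\t{tx.cds_end}\t.\t+\t0\t"
                f"ID={tx.transcript_id}.cds;Parent={tx.transcript_id}\n"
            )


def write_annotation_bed12(annotation: GenomeAnnotation, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for tx in annotation:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        tx.transcript_id, 0, tx.length, tx.transcript_id, 0, "+",
                        tx.cds_start, tx.cds_end, "0", 1, f"{tx.length},", "0,",
                    )
                )
                + "\n"
            )


def write_uorf_tsv(annotation: GenomeAnnotation, path: Union[str, Path]) -> None:
    rows = [
        {
            "uorf_id": u.uorf_id,
            "transcript_id": u.transcript_id,
            "uorf_start": u.start,
            "uorf_end": u.end,
            "start_codon_class": u.start_codon_class.value,
            "annotation_source": u.annotation_source.value,
        }
        for u in annotation.uorfs()
    ]
    pd.DataFrame(rows, columns=[
        "uorf_id", "transcript_id", "uorf_start", "uorf_end",
        "start_codon_class", "annotation_source",
    ]).to_csv(path, sep="\t", index=False)
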