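"""Experiment-design table: which library is which.

The study design is a 2 genotype (WT, eIF2A-delta) x 2 condition (untreated,
SM) x 2 replicate factorial, sequenced with paired assays (RPF = ribosome
footprints, RNA = matched RNA-seq), i.e. 16 libraries in the default layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import List, Optional, Tuple, Union

import pandas as pd

__all__ = ["Genotype", "Condition", "Assay", "SampleDesign", "read_design", "write_design"]


class Genotype(str, Enum):
    WT = "WT"
    eIF2AD = "eIF2AD"  # eIF2A deletion


class Condition(str, Enum):
    untreated = "untreated"
    SM = "SM"  # sulfometuron methyl (Ile/Val starvation)


class Assay(str, Enum):
    RPF = "RPF"
    RNA = "RNA"


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing library and its place in the factorial design."""

    sample_id: str
    genotype: Genotype
    condition: Condition
    replicate: int
    assay: Assay
    library_size: Optional[int] = None  # defaults to the column sum of its counts

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id}: replicate must be >= 1")
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError(f"sample {self.sample_id}: library_size must be > 0")

    @property
    def cell(self) -> Tuple[Genotype, Condition]:
        """The (genotype, condition) cell this sample belongs to."""
        return (self.genotype, self.condition)


def _check_unique(samples: List[SampleDesign]) -> None:
    seen = {}
    for s in samples:
        key = (s.genotype, s.condition, s.replicate, s.assay)
        if key in seen:
            raise ValueError(
                f"samples {seen[key]} and {s.sample_id} share design cell {key}"
            )
        seen[key] = s.sample_id
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in design")


def read_design(path: Union[str, Path]) -> List[SampleDesign]:
    """Read a design TSV with columns sample_id, genotype, condition, replicate, assay
    and an optional library_size override column."""
    df = pd.read_csv(path, sep="\t")
    samples = []
    for row in df.itertuples(index=False):
        lib = getattr(row, "library_size", None)
        lib = None if lib is None or pd.isna(lib) else int(lib)
        samples.append(
            SampleDesign(
                sample_id=str(row.sample_id),
                genotype=Genotype(str(row.genotype)),
                condition=Condition(str(row.condition)),
                replicate=int(row.replicate),
                assay=Assay(str(row.assay)),
                library_size=lib,
            )
        )
    _check_unique(samples)
    return samples


def write_design(samples: List[SampleDesign], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype.value,
                "condition": s.condition.value,
                "replicate": s.replicate,
                "assay": s.assay.value,
                "library_size": s.library_size if s.library_size is not None else "",
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def factorial_design(replicates: int = 2) -> List[SampleDesign]:
    """The study's default 2x2xN design with paired RPF/RNA libraries."""
    samples = []
    for geno in Genotype:
        for cond in Condition:
            for rep in range(1, replicates + 1):
                for assay in Assay:
                    samples.append(
                        SampleDesign(
                            sample_id=f"{geno.value}_{cond.value}_{rep}_{assay.value}",
                            genotype=geno,
                            condition=cond,
                            replicate=rep,
                            assay=assay,
                        )
                    )
    return samples
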