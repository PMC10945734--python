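"""Per-nucleotide footprint-density tracks in transcript coordinates."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

__all__ = ["FootprintTrack"]


@dataclass
class FootprintTrack:
    """Per-transcript footprint assignment density.

    ``density`` holds raw read counts (or expected reads) per nucleotide in
    transcript coordinates; ``rpm`` rescales by library size.  Tracks are
    position-assigned (e.g. already shifted from footprint 3' ends).
    """

    density: Dict[str, np.ndarray]
    library_size: Optional[float] = None
    dropped_reads: float = 0.0  # reads shifted off the 5' end during assignment

    def __post_init__(self) -> None:
        for tid, arr in self.density.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"transcript {tid}: negative density")
            self.density[tid] = arr
        if self.library_size is None:
            self.library_size = self.total_reads()
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")

    def total_reads(self) -> float:
        return float(sum(arr.sum() for arr in self.density.values()))

    def rpm(self, transcript_id: str) -> np.ndarray:
        """Reads per million mapped reads along one transcript."""
        return self.density[transcript_id] * 1e6 / self.library_size

    def scaled(self, factor: float) -> "FootprintTrack":
        """A copy with density (and library size) multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("factor must be > 0")
        return FootprintTrack(
            {t: arr * factor for t, arr in self.density.items()},
            library_size=self.library_size * factor,
            dropped_reads=self.dropped_reads * factor,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FootprintTrack):
            return NotImplemented
        if set(self.density) != set(other.density):
            return False
        return all(np.array_equal(self.density[t], other.density[t]) for t in self.density)
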