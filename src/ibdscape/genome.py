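"""Genetic maps of the autosomal genome.

All chromosome lengths are stored in Morgans.  The identity-by-descent and
ancestry-tract machinery needs only per-autosome genetic lengths, so a genome
is represented as an ordered mapping ``chromosome label -> length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeMap", "default_genome_map"]

# Sex-averaged autosomal genetic lengths (Morgans), rounded from published
# human linkage maps; total ~35.9 M.
_DEFAULT_LENGTHS_M = {
    "1": 2.930, "2": 2.716, "3": 2.232, "4": 2.210, "5": 2.120,
    "6": 1.919, "7": 1.872, "8": 1.685, "9": 1.668, "10": 1.850,
    "11": 1.582, "12": 1.800, "13": 1.257, "14": 1.204, "15": 1.413,
    "16": 1.400, "17": 1.288, "18": 1.202, "19": 1.120, "20": 1.082,
    "21": 0.628, "22": 0.727,
}


@dataclass(frozen=True)
class GenomeMap:
    """Per-autosome genetic lengths in Morgans.

    Parameters
    ----------
    lengths : dict
        Mapping from chromosome label to genetic length in Morgans.  Labels
        are normalised to strings.  All lengths must be positive.
    """

    lengths: dict = field(default_factory=lambda: dict(_DEFAULT_LENGTHS_M))

    def __post_init__(self):
        norm = {str(k): float(v) for k, v in self.lengths.items()}
        if not norm:
            raise ValueError("genome map must contain at least one chromosome")
        for c, length in norm.items():
            if not length > 0:
                raise ValueError(f"chromosome {c} has non-positive length {length}")
        object.__setattr__(self, "lengths", norm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def lengths_morgans(self) -> np.ndarray:
        return np.array(list(self.lengths.values()), dtype=float)

    @property
    def total_morgans(self) -> float:
        return float(self.lengths_morgans.sum())

    @property
    def total_cM(self) -> float:
        return 100.0 * self.total_morgans

    def length_cM(self, chrom) -> float:
        return 100.0 * self.lengths[str(chrom)]

    def __len__(self) -> int:
        return len(self.lengths)


def default_genome_map() -> GenomeMap:
    """The default 22-autosome map (~35.9 Morgans total)."""
    return GenomeMap(dict(_DEFAULT_LENGTHS_M))
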