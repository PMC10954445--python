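"""Reference genome container shared by all pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from .seqcore import GenomeIndex


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    coding: bool = True

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class ReferenceGenome:
    """Chromosome sequences plus the annotation tracks the analyses use.

    ``arms`` maps chromosome -> (cen_start, cen_end): the centromeric
    interval separating the p and q arm.  ``satellites`` are 0-based
    half-open intervals of annotated satellite arrays.
    """

    sequences: dict[str, str]
    arms: dict[str, tuple[int, int]] = field(default_factory=dict)
    satellites: list[tuple[str, int, int, str]] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @cached_property
    def index(self) -> GenomeIndex:
        return GenomeIndex(self.sequences)

    def excluded_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Satellite + centromere intervals unavailable to uniform nulls."""
        out = [(s, e) for c, s, e, _ in self.satellites if c == chrom]
        if chrom in self.arms:
            out.append(self.arms[chrom])
        out.sort()
        merged: list[tuple[int, int]] = []
        for s, e in out:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged
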