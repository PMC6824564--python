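"""Core domain containers for plastome analysis.

Coordinates are 0-based, half-open everywhere in memory; report writers
convert to 1-based inclusive (GenBank convention) at the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._seq import revcomp

GENIC_KINDS = frozenset({"gene", "CDS", "tRNA", "rRNA", "pseudogene"})


@dataclass
class Feature:
    """One annotated element: a gene, CDS, tRNA, rRNA or pseudogene.

    `intervals` holds the exon intervals in genome order; a gap between
    two consecutive intervals of the same feature is an intron.
    """

    kind: str
    name: str
    intervals: list[tuple[int, int]]
    strand: str = "+"
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"feature {self.name!r} has no intervals")
        for s, e in self.intervals:
            if s >= e:
                raise ValueError(
                    f"feature {self.name!r}: empty/reversed interval ({s}, {e})")

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0][0], self.intervals[-1][1]


@dataclass
class QuadripartitePartition:
    """The four canonical plastome compartments, tiling the genome once."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    at_content: float = 0.0

    @property
    def lsc_len(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ir_len(self) -> int:
        return self.irb[1] - self.irb[0]

    @property
    def ssc_len(self) -> int:
        return self.ssc[1] - self.ssc[0]

    def compartment_of(self, position: int) -> str:
        n = self.lsc_len + self.ssc_len + 2 * self.ir_len
        for name, (s, e) in (("LSC", self.lsc), ("IRb", self.irb),
                             ("SSC", self.ssc), ("IRa", self.ira)):
            if s <= position < e or (e > n and position < e - n):
                return name
        return "unassigned"


@dataclass
class RegionLabel:
    """Functional (CDS/intron/IGS) and compartment placement of a position."""

    functional: str
    compartment: str = "unassigned"
    flanking: Optional[str] = None  # "geneA-geneB", IGS only

    def __post_init__(self) -> None:
        if (self.flanking is not None) != (self.functional == "IGS"):
            raise ValueError("flanking genes defined iff functional == IGS")


@dataclass
class PlastomeRecord:
    """A single circular plastome with its annotation."""

    taxon_label: str
    sequence: str
    is_circular: bool = True
    features: list[Feature] = field(default_factory=list)
    partition: Optional[QuadripartitePartition] = None

    def __post_init__(self) -> None:
        if not self.taxon_label:
            raise ValueError("taxon_label must be non-empty")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"{self.taxon_label}: feature {f.name!r} interval "
                        f"({s}, {e}) outside sequence of length {n}")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Subsequence with circular wrap when end exceeds the length."""
        n = self.length_bp
        if end <= n:
            return self.sequence[start:end]
        if not self.is_circular:
            raise IndexError("interval beyond end of linear sequence")
        return self.sequence[start:] + self.sequence[: end - n]

    def ir_pair_ok(self) -> bool:
        if self.partition is None:
            return True
        p = self.partition
        return self.slice(*p.irb) == revcomp(self.slice(*p.ira))
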