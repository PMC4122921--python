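"""Shared domain records used across the simulation, annotation and counting layers.

Coordinates are 0-based half-open everywhere inside the package; file readers
convert from the 1-based inclusive conventions of RepeatMasker ``.out`` and GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TEAnnotation:
    """One located repeat hit.

    ``repeat_id`` names the consensus element (the counting unit: copies of the
    same repeat ID on any scaffold are consolidated into a single feature).
    ``pct_identity`` is percent identity of the hit to its consensus, in [0, 100].
    ``score`` is a Smith-Waterman-style integer alignment score.
    """

    scaffold: str
    start: int
    end: int
    strand: str
    repeat_id: str
    superfamily: str
    classification_path: tuple[str, ...] = ()
    pct_identity: float = 100.0
    score: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"annotation {self.repeat_id}@{self.scaffold}: start {self.start} >= end {self.end}"
            )
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A housekeeping-gene stand-in (CEGMA-like single-copy gene).

    The counting span runs from the start of the first exon to the end of the
    last exon, introns included.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: invalid exon [{s}, {e})")

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s


@dataclass(frozen=True)
class AlignmentRecord:
    """Best-hit placement of one sequenced fragment on the assembly.

    Mirrors end-to-end best-match mapping: each fragment appears at most once;
    fragments without a contiguous placement carry ``is_aligned=False``.
    """

    fragment_id: str
    scaffold: str
    start: int
    end: int
    is_aligned: bool = True

    def __post_init__(self) -> None:
        if self.is_aligned and self.start >= self.end:
            raise ValueError(f"fragment {self.fragment_id}: start {self.start} >= end {self.end}")


@dataclass
class CladeReport:
    """A maximal single-species clade in an element phylogeny."""

    species: str
    size: int
    node_id: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.size != len(self.members) or self.size < 1:
            raise ValueError("clade size must equal member count and be >= 1")
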