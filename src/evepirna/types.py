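"""Core domain types shared across the pipeline.

Coordinates are 1-based and inclusive throughout the package.  The 5' end of
a minus-strand alignment is the *rightmost* base of its footprint in plus
coordinates; the ping-pong overlap statistic depends on this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSeq:
    """A named nucleotide sequence (virus genome, EVE locus or host contig)."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int, new_id: Optional[str] = None) -> "ReferenceSeq":
        """Subsequence over the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(f"interval [{start},{end}] outside 1..{len(self.sequence)}")
        return ReferenceSeq(new_id or f"{self.id}:{start}-{end}", self.sequence[start - 1 : end])


@dataclass
class SmallRead:
    """A small-RNA read; quality is a list of Phred scores or None."""

    id: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        if any(b not in "ACGTN" for b in self.sequence):
            raise ValueError(f"read {self.id}: non-DNA characters in sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: quality length {len(self.quality)} != sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SmallReadAlignment:
    """A read placed on a reference.

    ``pos`` is the 1-based leftmost coordinate of the footprint; ``five_prime``
    is the coordinate of the read's 5' base (= pos on '+', pos+len-1 on '-').
    ``weight`` = 1/n_best distributes multi-mappers across equally-best hits.
    """

    read_id: str
    ref_id: str
    pos: int
    strand: str  # '+' or '-'
    mismatches: int
    read_length: int
    n_best: int

    @property
    def weight(self) -> float:
        return 1.0 / self.n_best

    @property
    def end(self) -> int:
        return self.pos + self.read_length - 1

    @property
    def five_prime(self) -> int:
        return self.pos if self.strand == "+" else self.end


@dataclass
class Hsp:
    """Ungapped high-scoring segment pair between a host contig and the virus.

    For orientation '-', contig_start pairs with virus_end: the contig segment
    is the reverse complement of virus[virus_start..virus_end].
    """

    contig_start: int
    contig_end: int
    virus_start: int
    virus_end: int
    orientation: str  # '+' or '-'
    matches: int
    aligned_columns: int
    score: int

    def __post_init__(self) -> None:
        if self.contig_end - self.contig_start != self.virus_end - self.virus_start:
            raise ValueError("ungapped HSP intervals must have equal length")
        if self.matches > self.aligned_columns:
            raise ValueError("matches cannot exceed aligned columns")

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start + 1

    @property
    def diagonal(self) -> int:
        # Invariant along an ungapped alignment: contig-virus offset ('+') or sum ('-').
        if self.orientation == "+":
            return self.contig_start - self.virus_start
        return self.contig_start + self.virus_end


@dataclass
class EveFragment:
    """One EVE segment: a chained run of collinear same-orientation HSPs."""

    contig_start: int
    contig_end: int
    virus_start: int
    virus_end: int
    orientation: str
    matches: int
    aligned_columns: int
    n_hsps: int = 1

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.aligned_columns

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start + 1

    def contig_to_virus(self, pos: int) -> int:
        """Map a contig coordinate inside the fragment to a virus coordinate."""
        if not (self.contig_start <= pos <= self.contig_end):
            raise ValueError(f"position {pos} outside fragment contig interval")
        if self.orientation == "+":
            return self.virus_start + (pos - self.contig_start)
        return self.virus_end - (pos - self.contig_start)


@dataclass
class ReadClassification:
    """Four-way origin call from zero-mismatch mapping to virus and EVE."""

    read_id: str
    cls: str  # virus_only | eve_only | shared | unmapped
    virus_strand: Optional[str] = None
    eve_strand: Optional[str] = None


@dataclass
class SimulationTruth:
    """Planted ground truth: references, fragment table, per-read labels."""

    virus: ReferenceSeq
    host_contig: ReferenceSeq
    planted_fragments: list[EveFragment]
    # read id -> dict(class, template, true_5p_position, true_strand, ...)
    read_labels: dict[str, dict] = field(default_factory=dict)
    eve_start: int = 0  # contig coordinate where the EVE region begins
    eve_end: int = 0

    def eve_locus(self, flank: int = 0) -> ReferenceSeq:
        """The EVE region of the host contig (optionally with flanks) as a reference."""
        start = max(1, self.eve_start - flank)
        end = min(len(self.host_contig), self.eve_end + flank)
        return self.host_contig.slice(start, end, new_id="eve_locus")

    def fragments_on_locus(self, flank: int = 0) -> list[EveFragment]:
        """Fragment table with contig coordinates shifted to eve_locus coordinates."""
        offset = max(1, self.eve_start - flank) - 1
        out = []
        for f in self.planted_fragments:
            out.append(
                EveFragment(
                    contig_start=f.contig_start - offset,
                    contig_end=f.contig_end - offset,
                    virus_start=f.virus_start,
                    virus_end=f.virus_end,
                    orientation=f.orientation,
                    matches=f.matches,
                    aligned_columns=f.aligned_columns,
                    n_hsps=f.n_hsps,
                )
            )
        return out
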