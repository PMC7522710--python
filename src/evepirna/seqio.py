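"""Readers/writers for FASTA/FASTQ/SAM/TSV plus read trimming and size selection.

FASTA/FASTQ parsing is delegated to Biopython; SAM output is a minimal dialect
(@HD/@SQ header, FLAG 0/16, 1-based POS, ``<len>M`` CIGAR, NM tag) sufficient
for samtools/pysam and the downstream profiling steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import ReferenceSeq, SmallRead, SmallReadAlignment, revcomp


def read_fasta(path: str | Path) -> list[ReferenceSeq]:
    """All records of a FASTA file, order preserved; empty file -> empty list."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ReferenceSeq(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ReferenceSeq], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SmallRead]:
    """Phred+33 FASTQ; malformed records raise with the offending line number."""
    reads: list[SmallRead] = []
    it = FastqGeneralIterator(str(path))
    index = 0
    while True:
        try:
            title, seq, qual = next(it)
        except StopIteration:
            return reads
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record near line {index * 4 + 1}: {exc}") from exc
        index += 1
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record near line {(index - 1) * 4 + 1}: "
                             f"sequence/quality length mismatch for {title}")
        reads.append(SmallRead(title.split()[0], seq.upper(), [ord(c) - 33 for c in qual]))


def write_fastq(reads: Iterable[SmallRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else [40] * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{''.join(chr(q + 33) for q in qual)}\n")


def write_sam(
    alignments: Iterable[SmallReadAlignment],
    references: Iterable[ReferenceSeq],
    path: str | Path,
    reads_by_id: Optional[dict[str, SmallRead]] = None,
) -> None:
    """Minimal SAM: FLAG 16 for minus strand, SEQ in reference orientation, NM tag."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref in references:
            fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref.sequence)}\n")
        for a in alignments:
            flag = 0 if a.strand == "+" else 16
            seq = qual = "*"
            if reads_by_id is not None and a.read_id in reads_by_id:
                r = reads_by_id[a.read_id]
                seq = r.sequence if a.strand == "+" else revcomp(r.sequence)
                if r.quality is not None:
                    q = r.quality if a.strand == "+" else r.quality[::-1]
                    qual = "".join(chr(x + 33) for x in q)
            fh.write(
                f"{a.read_id}\t{flag}\t{a.ref_id}\t{a.pos}\t255\t{a.read_length}M"
                f"\t*\t0\t0\t{seq}\t{qual}\tNM:i:{a.mismatches}\n"
            )


@dataclass
class TrimStats:
    input: int = 0
    kept: int = 0
    no_adapter: int = 0
    low_quality: int = 0
    too_short: int = 0
    too_long: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def find_adapter(sequence: str, adapter: str, max_error_rate: float = 0.1, min_overlap: int = 3) -> Optional[int]:
    """Leftmost 0-based start of a 3'-adapter occurrence, or None.

    The adapter prefix is matched against the read suffix starting at each
    position; a hit needs >= min_overlap columns and <= max_error_rate
    mismatches over the overlap.
    """
    n = len(sequence)
    for s in range(n - min_overlap + 1):
        overlap = min(len(adapter), n - s)
        allowed = int(max_error_rate * overlap)
        mm = 0
        for a, b in zip(sequence[s : s + overlap], adapter[:overlap]):
            if a != b:
                mm += 1
                if mm > allowed:
                    break
        else:
            return s
    return None


def trim_and_filter(
    reads: Iterable[SmallRead],
    adapter: str,
    min_phred: float = 20,
    size_window: tuple[int, int] = (19, 33),
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
    require_adapter: bool = True,
) -> tuple[list[SmallRead], TrimStats]:
    """3'-adapter trimming, mean-quality filter and size selection.

    A read is kept when (i) the adapter is found (unless ``require_adapter`` is
    False, in which case adapterless reads pass untrimmed), (ii) the mean Phred
    of the trimmed insert is strictly greater than ``min_phred``, and (iii) the
    trimmed length lies inside ``size_window``.  With ``require_adapter=False``
    the operation is idempotent.
    """
    if require_adapter and not adapter:
        raise ValueError("adapter sequence required when trimming is requested")
    lo, hi = size_window
    kept: list[SmallRead] = []
    stats = TrimStats()
    for read in reads:
        stats.input += 1
        cut = find_adapter(read.sequence, adapter, max_error_rate, min_overlap) if adapter else None
        if cut is None:
            if require_adapter:
                stats.no_adapter += 1
                continue
            trimmed = read
        else:
            # iterate to a fixpoint: residual partial-adapter suffixes created by
            # the cut are removed too, which makes trimming idempotent
            while cut is not None and cut > 0:
                read = SmallRead(
                    read.id,
                    read.sequence[:cut],
                    read.quality[:cut] if read.quality is not None else None,
                )
                cut = find_adapter(read.sequence, adapter, max_error_rate, min_overlap)
            if cut == 0:  # adapter dimer: empty insert
                stats.too_short += 1
                continue
            trimmed = read
        if trimmed.quality is not None:
            if sum(trimmed.quality) / len(trimmed.quality) <= min_phred:
                stats.low_quality += 1
                continue
        if len(trimmed) < lo:
            stats.too_short += 1
            continue
        if len(trimmed) > hi:
            stats.too_long += 1
            continue
        kept.append(trimmed)
        stats.kept += 1
    return kept, stats


def write_tsv(rows: list[dict], path: str | Path, header_lines: Optional[list[str]] = None) -> None:
    """Plain TSV with optional '#'-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        if not rows:
            return
        cols = list(dict.fromkeys(c for row in rows for c in row))
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, ".")) for c in cols) + "\n")
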