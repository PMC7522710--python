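"""Ungapped small-RNA alignment to small references with mismatch strata.

Seed-and-verify over a k-mer hash of the reference: candidate placements come
from the first and last k-mers of the read (and of its reverse complement) and
are verified by full-length comparison.  Only the best mismatch stratum is
reported (all 0-mismatch placements if any exist, else all 1-mismatch ones),
with multi-mappers down-weighted by 1/n_best.

Seed completeness: with k <= floor(readlen/2) the first and last k-mer windows
are disjoint, so a single mismatch cannot evade both — every placement with
<= 1 mismatch is found.  ``align_reads`` caps k accordingly for the shortest
read in the batch.

``BruteForceAligner`` is an independent exhaustive-scan implementation used as
an oracle; it shares no candidate-generation code with the seeded path.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .types import ReferenceSeq, SmallRead, SmallReadAlignment, revcomp


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class KmerIndex:
    """Positions (1-based) of every k-mer of the reference plus strand."""

    def __init__(self, ref: ReferenceSeq, k: int = 12):
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > len(ref.sequence):
            raise ValueError(f"reference {ref.id} shorter than k={k}")
        self.ref = ref
        self.k = k
        self._arr = _encode(ref.sequence)
        self._table: dict[str, list[int]] = {}
        seq = ref.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            self._table.setdefault(kmer, []).append(i + 1)

    def lookup(self, kmer: str) -> list[int]:
        return self._table.get(kmer, [])


def _stratum(hits: dict[tuple[int, str], int]) -> Optional[tuple[list[tuple[int, str]], int]]:
    if not hits:
        return None
    best = min(hits.values())
    placements = sorted(
        (pos, strand) for (pos, strand), mm in hits.items() if mm == best
    )  # '+' < '-' lexicographically: ord('+')=43 < ord('-')=45
    return placements, best


def align_read(read: SmallRead, index: KmerIndex, max_mismatch: int = 1) -> list[SmallReadAlignment]:
    """Best-stratum placements of a read on both strands; [] when unmapped."""
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    k = index.k
    L = len(read.sequence)
    if L < k:
        raise ValueError(f"read {read.id} shorter than seed length {k}")
    ref_arr = index._arr
    ref_len = ref_arr.size
    hits: dict[tuple[int, str], int] = {}
    for strand, query in (("+", read.sequence), ("-", revcomp(read.sequence))):
        q_arr = _encode(query)
        offsets = {0, L - k}
        if L < 2 * k:  # degenerate short read: seed every offset (completeness not guaranteed)
            offsets = set(range(L - k + 1))
        seen: set[int] = set()
        for off in offsets:
            for p in index.lookup(query[off : off + k]):
                pos = p - off
                if pos < 1 or pos + L - 1 > ref_len or pos in seen:
                    continue
                seen.add(pos)
                mm = int(np.count_nonzero(ref_arr[pos - 1 : pos - 1 + L] != q_arr))
                if mm <= max_mismatch:
                    hits[(pos, strand)] = mm
    result = _stratum(hits)
    if not result:
        return []
    placements, best = result
    n_best = len(placements)
    return [
        SmallReadAlignment(
            read_id=read.id, ref_id=index.ref.id, pos=pos, strand=strand,
            mismatches=best, read_length=L, n_best=n_best,
        )
        for pos, strand in placements
    ]


def align_reads(
    reads: Iterable[SmallRead],
    ref: ReferenceSeq,
    max_mismatch: int = 1,
    k: int = 12,
) -> list[SmallReadAlignment]:
    """Align a batch; k is capped at floor(min readlen / 2) for completeness."""
    reads = list(reads)
    if not reads:
        return []
    k_eff = max(1, min(k, min(len(r.sequence) for r in reads) // 2))
    index = KmerIndex(ref, k_eff)
    out: list[SmallReadAlignment] = []
    for r in reads:
        out.extend(align_read(r, index, max_mismatch))
    return out


class BruteForceAligner:
    """Exhaustive scan over every offset and strand; the aligner's oracle."""

    def __init__(self, ref: ReferenceSeq):
        self.ref = ref
        self._arr = _encode(ref.sequence)
        self._windows: dict[int, np.ndarray] = {}

    def _window(self, L: int) -> np.ndarray:
        if L not in self._windows:
            self._windows[L] = np.lib.stride_tricks.sliding_window_view(self._arr, L)
        return self._windows[L]

    def align(self, read: SmallRead, max_mismatch: int = 1) -> list[SmallReadAlignment]:
        L = len(read.sequence)
        if L > self._arr.size:
            return []
        win = self._window(L)
        hits: dict[tuple[int, str], int] = {}
        for strand, query in (("+", read.sequence), ("-", revcomp(read.sequence))):
            mm = (win != _encode(query)).sum(axis=1)
            for i in np.nonzero(mm <= max_mismatch)[0]:
                hits[(int(i) + 1, strand)] = int(mm[i])
        result = _stratum(hits)
        if not result:
            return []
        placements, best = result
        n_best = len(placements)
        return [
            SmallReadAlignment(
                read_id=read.id, ref_id=self.ref.id, pos=pos, strand=strand,
                mismatches=best, read_length=L, n_best=n_best,
            )
            for pos, strand in placements
        ]
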