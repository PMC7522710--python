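"""EVE discovery: local ungapped homology between a host contig and a virus.

Exact k-mer seeds (both virus strands) are extended ungapped in both
directions under an X-drop rule (match +1, mismatch -2), deduplicated per
diagonal, filtered by score, then chained into fragments: same-orientation
HSPs on the same diagonal whose gap is at most ``max_gap`` are merged.  When
the sequences are supplied at chaining time, fragment identity is recounted
column-by-column over the merged interval so that reported percent identity is
exactly reproducible from the two sequences; without sequences, inter-HSP gap
columns are scored as mismatches.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .types import EveFragment, Hsp, ReferenceSeq, revcomp

MATCH = 1
MISMATCH = -2


def _extend(c: str, t: str, i: int, j: int, k: int, xdrop: int) -> tuple[int, int, int, int]:
    """X-drop extension of an exact seed c[i:i+k]==t[j:j+k] (0-based).

    Returns (left_off, right_off, extra_matches, extra_cols).
    """
    # rightwards
    cur = best = 0
    m_run = best_m = 0
    off = 0
    right_off = 0
    while i + k + off < len(c) and j + k + off < len(t):
        if c[i + k + off] == t[j + k + off]:
            cur += MATCH
            m_run += 1
        else:
            cur += MISMATCH
        off += 1
        if cur > best:
            best, right_off, best_m = cur, off, m_run
        if cur < best - xdrop:
            break
    right_m = best_m
    # leftwards
    cur = best = 0
    m_run = best_m = 0
    off = 0
    left_off = 0
    while i - 1 - off >= 0 and j - 1 - off >= 0:
        if c[i - 1 - off] == t[j - 1 - off]:
            cur += MATCH
            m_run += 1
        else:
            cur += MISMATCH
        off += 1
        if cur > best:
            best, left_off, best_m = cur, off, m_run
        if cur < best - xdrop:
            break
    return left_off, right_off, right_m + best_m, left_off + right_off


def _scan(contig: str, target: str, k: int, xdrop: int, min_score: int) -> list[tuple]:
    """Plus-orientation HSPs between contig and target as 0-based tuples."""
    table: dict[str, list[int]] = {}
    for j in range(len(target) - k + 1):
        kmer = target[j : j + k]
        if "N" not in kmer:
            table.setdefault(kmer, []).append(j)
    hsps: list[tuple] = []
    covered: dict[int, int] = {}  # diagonal -> contig end (0-based) of last HSP
    for i in range(len(contig) - k + 1):
        kmer = contig[i : i + k]
        if "N" in kmer:
            continue
        for j in table.get(kmer, ()):
            d = i - j
            if d in covered and i <= covered[d]:
                continue
            left, right, extra_m, extra_c = _extend(contig, target, i, j, k, xdrop)
            cs, ce = i - left, i + k - 1 + right
            ts = j - left
            matches = k + extra_m
            cols = k + extra_c
            score = matches * MATCH + (cols - matches) * MISMATCH
            covered[d] = ce
            if score >= min_score:
                hsps.append((cs, ce, ts, ts + cols - 1, matches, cols, score))
    return hsps


def find_hsps(
    contig: ReferenceSeq,
    virus: ReferenceSeq,
    k: int = 11,
    xdrop: int = 20,
    min_score: int = 30,
) -> list[Hsp]:
    """Ungapped local similarities between contig and virus, both orientations."""
    if not contig.sequence or not virus.sequence:
        raise ValueError("both sequences must be non-empty")
    vlen = len(virus.sequence)
    out: list[Hsp] = []
    for orientation, target in (("+", virus.sequence), ("-", revcomp(virus.sequence))):
        for cs, ce, ts, te, matches, cols, score in _scan(
            contig.sequence, target, k, xdrop, min_score
        ):
            if orientation == "+":
                vs, ve = ts + 1, te + 1
            else:  # map rc-target coordinates back to virus + strand
                vs, ve = vlen - te, vlen - ts
            out.append(
                Hsp(
                    contig_start=cs + 1, contig_end=ce + 1,
                    virus_start=vs, virus_end=ve,
                    orientation=orientation, matches=matches,
                    aligned_columns=cols, score=score,
                )
            )
    out.sort(key=lambda h: (h.contig_start, h.orientation))
    return out


def _recount(f: EveFragment, contig: ReferenceSeq, virus: ReferenceSeq) -> EveFragment:
    """Exact column-by-column identity over the fragment's reported intervals."""
    matches = 0
    for p in range(f.contig_start, f.contig_end + 1):
        v = virus.sequence[f.contig_to_virus(p) - 1]
        c = contig.sequence[p - 1]
        if f.orientation == "-":
            v = revcomp(v)
        if v == c:
            matches += 1
    f.matches = matches
    f.aligned_columns = f.length
    return f


def chain_into_fragments(
    hsps: list[Hsp],
    max_gap: int = 50,
    contig: Optional[ReferenceSeq] = None,
    virus: Optional[ReferenceSeq] = None,
) -> list[EveFragment]:
    """Merge collinear same-orientation, same-diagonal HSPs into fragments.

    Both the contig gap and the virus gap between chained HSPs are bounded by
    ``max_gap`` (they are equal on a shared diagonal).  Supplying the sequences
    makes fragment identity an exact recount over the merged interval.
    """
    groups: dict[tuple[str, int], list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.orientation, h.diagonal), []).append(h)
    fragments: list[EveFragment] = []
    for (orientation, _), members in groups.items():
        members.sort(key=lambda h: h.contig_start)
        run = [members[0]]
        for h in members[1:]:
            gap = h.contig_start - run[-1].contig_end - 1
            if 0 <= gap <= max_gap:
                run.append(h)
            else:
                fragments.append(_merge_run(run, orientation))
                run = [h]
        fragments.append(_merge_run(run, orientation))
    if contig is not None and virus is not None:
        fragments = [_recount(f, contig, virus) for f in fragments]
    fragments.sort(key=lambda f: f.contig_start)
    return fragments


def _merge_run(run: list[Hsp], orientation: str) -> EveFragment:
    cs = run[0].contig_start
    ce = run[-1].contig_end
    vs = min(h.virus_start for h in run)
    ve = max(h.virus_end for h in run)
    matches = sum(h.matches for h in run)
    cols = sum(h.aligned_columns for h in run)
    gap_cols = (ce - cs + 1) - cols  # inter-HSP gap columns scored as mismatches
    return EveFragment(
        contig_start=cs, contig_end=ce, virus_start=vs, virus_end=ve,
        orientation=orientation, matches=matches,
        aligned_columns=cols + gap_cols, n_hsps=len(run),
    )


def fragment_identity_report(fragments: list[EveFragment]) -> tuple[pd.DataFrame, dict]:
    """Per-fragment identity table and the length-weighted overall identity."""
    if not fragments:
        raise ValueError("no fragments to report")
    rows = [
        {
            "fragment": i + 1,
            "contig_start": f.contig_start,
            "contig_end": f.contig_end,
            "virus_start": f.virus_start,
            "virus_end": f.virus_end,
            "orientation": f.orientation,
            "length": f.length,
            "n_hsps": f.n_hsps,
            "percent_identity": round(f.percent_identity, 2),
        }
        for i, f in enumerate(fragments)
    ]
    total_cols = sum(f.aligned_columns for f in fragments)
    total_matches = sum(f.matches for f in fragments)
    summary = {
        "n_fragments": len(fragments),
        "overall_identity": 100.0 * total_matches / total_cols,
        "min_identity": min(f.percent_identity for f in fragments),
        "max_identity": max(f.percent_identity for f in fragments),
    }
    return pd.DataFrame(rows), summary


def write_bed(fragments: list[EveFragment], contig_id: str, path: str | Path) -> None:
    """Fragment contig intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            fh.write(
                f"{contig_id}\t{f.contig_start - 1}\t{f.contig_end}\t"
                f"fragment_{i + 1}\t{int(round(f.percent_identity * 10))}\t{f.orientation}\n"
            )
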