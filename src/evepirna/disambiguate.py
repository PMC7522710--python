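"""EVE-vs-virus read disambiguation by zero-mismatch mapping to both references.

A read is ``virus_only`` when it maps perfectly to the virus and not to the
EVE locus, ``eve_only`` in the converse case, ``shared`` when it maps to both
(it spans no diagnostic site), ``unmapped`` otherwise.  Sequencing errors push
genuine reads to ``unmapped`` rather than to the wrong class — a conservative
consequence of the exact-match rule.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .align import align_reads
from .signature import orient_relative_to_virus
from .types import EveFragment, ReadClassification, ReferenceSeq, SmallRead


def classify_reads(
    reads: list[SmallRead],
    virus: ReferenceSeq,
    eve_locus: ReferenceSeq,
    fragments: Optional[list[EveFragment]] = None,
    k: int = 12,
) -> tuple[list[ReadClassification], pd.DataFrame]:
    """Four-way origin call per read plus a per-class strand/size summary.

    ``fragments`` (EVE fragment table in eve_locus coordinates) enables
    conversion of eve-only strands into virus orientation; without it the
    summary reports eve-locus strands and conversion-dependent columns are
    empty.
    """
    v_hits = {}
    for a in align_reads(reads, virus, max_mismatch=0, k=k):
        v_hits.setdefault(a.read_id, []).append(a)
    e_hits = {}
    for a in align_reads(reads, eve_locus, max_mismatch=0, k=k):
        e_hits.setdefault(a.read_id, []).append(a)

    calls: list[ReadClassification] = []
    rows = []
    for r in reads:
        v = v_hits.get(r.id, [])
        e = e_hits.get(r.id, [])
        if v and e:
            cls = "shared"
        elif v:
            cls = "virus_only"
        elif e:
            cls = "eve_only"
        else:
            cls = "unmapped"
        v_strand = v[0].strand if v else None
        e_strand = e[0].strand if e else None
        # virus-orientation strand: direct for virus hits, via fragments for EVE hits
        virus_oriented = v_strand
        if virus_oriented is None and e and fragments:
            converted, _ = orient_relative_to_virus([e[0]], fragments)
            if converted:
                virus_oriented = converted[0].strand
        calls.append(ReadClassification(r.id, cls, v_strand, e_strand))
        rows.append(
            {
                "read_id": r.id,
                "class": cls,
                "length": len(r.sequence),
                "virus_strand": v_strand or ".",
                "eve_strand": e_strand or ".",
                "virus_oriented_strand": virus_oriented or ".",
            }
        )
    per_read = pd.DataFrame(rows)
    summary = (
        per_read.groupby(["class", "virus_oriented_strand"], as_index=False)
        .size()
        .rename(columns={"size": "n_reads"})
    )
    return calls, summary


def diagnostic_site_density(
    virus: ReferenceSeq, eve_locus: ReferenceSeq, fragments: list[EveFragment]
) -> float:
    """Fraction of EVE fragment columns at which EVE and virus differ.

    Reported alongside classifications so users can judge the power of the
    exact-match disambiguation (zero density -> everything is shared).
    """
    from .simulate import diagnostic_sites

    sites = diagnostic_sites(virus, eve_locus, fragments)
    n_diff = sum(len(v) for v in sites.values())
    n_cols = sum(f.length for f in fragments)
    return n_diff / n_cols if n_cols else 0.0
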