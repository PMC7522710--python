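#!/usr/bin/env python
"""Scan the host contig against the virus genome and report EVE structure.

Finds ungapped local similarities, chains them into fragments, and writes the
fragment table (TSV + BED) with per-fragment and overall percent identity.
Compares the discovered structure with the planted truth table when present.
"""

import argparse
from pathlib import Path

import pandas as pd

from evepirna.discovery import chain_into_fragments, find_hsps, fragment_identity_report, write_bed
from evepirna.seqio import read_fasta

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

contig = read_fasta(args.datadir / "host_contig.fasta")[0]
virus = read_fasta(args.datadir / "virus.fasta")[0]
hsps = find_hsps(contig, virus)
fragments = chain_into_fragments(hsps, contig=contig, virus=virus)
df, summary = fragment_identity_report(fragments)
df.to_csv(args.outdir / "fragments_found.tsv", sep="\t", index=False)
write_bed(fragments, contig.id, args.outdir / "fragments_found.bed")

print(df.to_string(index=False))
print(
    f"\n{summary['n_fragments']} fragments, overall identity "
    f"{summary['overall_identity']:.1f}% "
    f"(range {summary['min_identity']:.1f}-{summary['max_identity']:.1f}%)"
)

truth_path = args.datadir / "fragments_truth.tsv"
if truth_path.exists():
    truth = pd.read_csv(truth_path, sep="\t", comment="#")
    if len(truth) == len(df):
        err = (
            (truth["contig_start"] - df["contig_start"]).abs().max(),
            (truth["contig_end"] - df["contig_end"]).abs().max(),
        )
        same_orient = (truth["orientation"] == df["orientation"]).all()
        print(f"vs planted truth: boundary error <= {max(err)} nt, "
              f"orientations {'all correct' if same_orient else 'MISMATCHED'}")
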