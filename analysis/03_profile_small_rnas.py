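#!/usr/bin/env python
"""Align the control library to the virus and profile it: strand-resolved size
spectrum (siRNA peak at 21 nt, piRNA hump at 26-30 nt) and coverage tracks.
"""

import argparse
from pathlib import Path

from evepirna.align import align_reads
from evepirna.profile import (
    coverage_track,
    plot_coverage,
    plot_size_spectrum,
    size_spectrum,
    write_bedgraph,
)
from evepirna.seqio import read_fasta, read_fastq, write_sam

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

virus = read_fasta(args.datadir / "virus.fasta")[0]
reads = read_fastq(args.datadir / "control_reads.fastq")
alignments = align_reads(reads, virus, max_mismatch=1, k=12)
write_sam(alignments, [virus], args.outdir / "control_vs_virus.sam",
          {r.id: r for r in reads})
mapped = len({a.read_id for a in alignments})
print(f"{mapped}/{len(reads)} reads mapped to the virus genome")

spectrum = size_spectrum(alignments)
spectrum.to_dataframe().to_csv(args.outdir / "size_spectrum.tsv", sep="\t", index=False)
plot_size_spectrum(spectrum, args.outdir / "size_spectrum.png", "sRNAs mapping to the virus")
peak = max(
    ((n, spectrum.count(n, "+") + spectrum.count(n, "-")) for n in range(19, 34)),
    key=lambda t: t[1],
)
print(f"size spectrum peak: {peak[0]} nt ({peak[1]:.0f} weighted reads)")

for tag, size_class in (("21nt", (21, 21)), ("26-30nt", (26, 30))):
    track = coverage_track(alignments, len(virus), size_class, ref_id=virus.id)
    track.to_dataframe().to_csv(args.outdir / f"coverage_{tag}.tsv", sep="\t", index=False)
    plot_coverage(track, args.outdir / f"coverage_{tag}.png", f"{tag} coverage")
    for strand, name in (("+", "fwd"), ("-", "rev")):
        write_bedgraph(track, args.outdir / f"coverage_{tag}.{name}.bedGraph", strand)
    frac_uncovered = track.uncovered.mean()
    print(f"{tag}: {100 * (1 - frac_uncovered):.1f}% of the virus covered")
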