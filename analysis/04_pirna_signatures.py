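#!/usr/bin/env python
"""piRNA signature analysis of the control library: sequence-logo matrices
(1U/10A biases by orientation) and the ping-pong 5'-overlap spectrum.
"""

import argparse
from pathlib import Path

from evepirna.align import align_reads
from evepirna.seqio import read_fasta, read_fastq
from evepirna.signature import (
    bias_fractions,
    nucleotide_profile,
    overlap_spectrum,
    plot_overlap_spectrum,
)

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

virus = read_fasta(args.datadir / "virus.fasta")[0]
reads = read_fastq(args.datadir / "control_reads.fastq")
alignments = align_reads(reads, virus, max_mismatch=1, k=12)
reads_by_id = {r.id: r for r in reads}

for orientation in ("sense", "antisense"):
    prof = nucleotide_profile(alignments, reads_by_id, (26, 30), orientation)
    prof.to_dataframe().to_csv(args.outdir / f"logo_{orientation}.tsv", sep="\t", index=False)
    bias = bias_fractions(prof)
    print(f"{orientation:9s} 26-30 nt reads: n={prof.n_reads:.0f}  "
          f"1U={bias['u1']:.3f}  10A={bias['a10']:.3f}")

spec = overlap_spectrum(alignments, size_class=(26, 30))
spec.to_dataframe().to_csv(args.outdir / "overlap_spectrum.tsv", sep="\t", index=False)
plot_overlap_spectrum(spec, args.outdir / "overlap_spectrum.png", "5' overlap z-scores")
peak = int(spec.distances[spec.counts.argmax()])
print(f"overlap spectrum: peak at {peak} nt, ping-pong z(10) = {spec.ping_pong_z:.2f}")
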