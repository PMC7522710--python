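#!/usr/bin/env python
"""Generate the study-condition synthetic libraries used by the later steps.

Writes, under results/data/: the virus genome, the EVE-bearing host contig and
EVE locus (FASTA), a control infection library (siRNAs + primary + secondary
piRNAs) and an EVE-ablated library (background piRNA-sized reads only), both
as FASTQ with ground-truth label tables.
"""

import argparse
from pathlib import Path

from evepirna.seqio import write_fasta, write_fastq, write_tsv
from evepirna.simulate import SimulationConfig, simulate

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/data"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

control = SimulationConfig(
    seed=args.seed, n_sirna=2000, n_primary=4000, n_secondary=4000
)
truth, reads, stats = simulate(control)
write_fasta([truth.virus], args.outdir / "virus.fasta")
write_fasta([truth.host_contig], args.outdir / "host_contig.fasta")
write_fasta([truth.eve_locus()], args.outdir / "eve_locus.fasta")
write_fastq(reads, args.outdir / "control_reads.fastq")
write_tsv(
    [
        {
            "fragment": i + 1, "contig_start": f.contig_start, "contig_end": f.contig_end,
            "virus_start": f.virus_start, "virus_end": f.virus_end,
            "orientation": f.orientation, "percent_identity": round(f.percent_identity, 2),
        }
        for i, f in enumerate(truth.planted_fragments)
    ],
    args.outdir / "fragments_truth.tsv",
)
write_tsv(
    [{"read_id": rid, **lab} for rid, lab in truth.read_labels.items()],
    args.outdir / "control_read_labels.tsv",
)
print(f"control library: {stats}")

knockout = SimulationConfig(seed=args.seed, n_sirna=2000, n_background=8000)
truth_ko, reads_ko, stats_ko = simulate(knockout)
write_fastq(reads_ko, args.outdir / "knockout_reads.fastq")
print(f"knockout library: {stats_ko}")
print(f"outputs in {args.outdir}")
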