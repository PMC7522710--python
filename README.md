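# evepirna

Small-RNA analysis of **endogenous viral elements (EVEs)** and their cognate
viruses. Some insect genomes carry integrated fragments of RNA-virus genomes;
when such an EVE sits inside a piRNA cluster it is transcribed into primary
piRNAs that can recognise the RNA of a related, actively replicating virus and
trigger **ping-pong amplification** — a heritable, sequence-specific layer of
antiviral immunity. This package implements the complete desk-side analysis
needed to demonstrate that interaction from sequence data:

- **EVE discovery** — ungapped seed-and-extend local alignment of a host
  contig against a viral genome, chaining of collinear segments into
  fragments, per-fragment orientation and percent identity (the typical EVE is
  a mosaic of viral fragments, some inserted in reverse orientation).
- **Small-RNA alignment** — a strand-aware short-read aligner for small
  references with an exact mismatch-stratum contract (all 0-mismatch
  placements, else all 1-mismatch placements; multi-mappers weighted 1/n).
- **Profiling** — strand-resolved read-length spectra (21-nt siRNA peak,
  26–30 nt piRNA hump) and per-nucleotide 5′-end/depth coverage tracks.
- **piRNA signature statistics** — positional nucleotide-bias matrices
  (1U bias of primary piRNAs, 10A bias of secondary piRNAs) and the
  ping-pong **5′-overlap spectrum**: with S(i) and A(j) the weighted 5′-end
  counts of opposite-strand 26–30 nt reads,

  ```
  c(d) = Σᵢ S(i)·A(i + d − 1),   d = 1..30
  z(d) = (c(d) − mean c) / sd c      (population sd over all 30 bins)
  ```

  Ping-pong amplification appears as a sharp peak of z(10), because secondary
  piRNA 5′ ends overlap primary 5′ ends by exactly 10 nt.
- **Read disambiguation** — classification of reads as EVE-derived vs
  virus-derived by zero-mismatch mapping to both references, with strand
  composition expressed in virus coordinates.
- **A synthetic-data generator** that plants an EVE (several viral fragments,
  some flipped, ~4% diverged) into a host contig and emits labelled siRNA /
  primary-piRNA / secondary-piRNA read populations with the exact ping-pong
  geometry, so every analysis step can be validated against ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(seed 1 throughout; outputs under `results/`):

```bash
python analysis/01_simulate_libraries.py     # references + labelled reads
python analysis/02_discover_eve.py           # EVE structure
python analysis/04_pirna_signatures.py       # 1U/10A biases + ping-pong z
python analysis/06_knockout_contrast.py      # EVE-ablation contrast
```

`02_discover_eve.py` prints the recovered EVE structure:

```
4 fragments, overall identity 95.7% (range 94.7-96.5%)
vs planted truth: boundary error <= 1 nt, orientations all correct
```

i.e. the scan recovers all four planted viral fragments (two of them
reverse-oriented) with near-exact boundaries, and the realized identity
reflects the 4% divergence planted between EVE and virus.

`04_pirna_signatures.py` prints the signature table:

```
sense     26-30 nt reads: n=4815  1U=0.368  10A=0.835
antisense 26-30 nt reads: n=1690  1U=0.897  10A=0.243
overlap spectrum: peak at 10 nt, ping-pong z(10) = 5.34
```

Antisense piRNAs carry the primary 1U mark (~0.9, the planted enforcement
level), sense piRNAs the secondary 10A mark, and the 5′-overlap spectrum
peaks at exactly 10 nt with a strong z-score — the ping-pong signature.

`06_knockout_contrast.py` repeats the analysis over 20 seeds with and without
the EVE:

```
median control z10 = 5.31, median knockout z10 = 0.27, contrast = 5.05
control peak at 10 nt in 20/20 runs
```

Removing the EVE (hence all primary piRNAs) abolishes the signature.

A `evepirna` command-line tool exposes each stage (`simulate`, `trim`,
`align`, `discover`, `profile`, `signature`, `disambiguate`, `run`,
`prevalence`); `evepirna run config.yaml` executes the whole pipeline from a
YAML config, and e.g.

```bash
$ evepirna prevalence 28 31
90.3% (CI 75.1%-96.7%)
```

gives a carrier-prevalence point estimate with a Wilson score interval.

## Layout

```
src/evepirna/     library: simulate, seqio, align, discovery, profile,
                  signature, disambiguate, pipeline, cli
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property and end-to-end)
docs/methods.md   model assumptions, parameter choices, limitations
```
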