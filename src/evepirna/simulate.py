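"""Synthetic virus/EVE/small-RNA read generator with ground-truth labels.

Emulates the read populations the analysis assumes: a ~10.7 kb positive-strand
RNA virus; an endogenous viral element (EVE) built from several viral fragments,
some orientation-flipped, diverged from the virus and embedded in host flanks;
21-nt siRNAs from both viral strands; 26-30 nt primary piRNAs produced from the
EVE transcript with a 1U bias; and secondary piRNAs produced from the viral
genome whose 5' ends overlap antisense primary 5' ends by exactly 10 nt
(the ping-pong geometry).  Every read carries a provenance label so analyses
can be scored against planted truth.

Model notes
-----------
* ``u1_enforcement`` is the exact 1U fraction of primary piRNAs: with that
  probability a start is drawn among template positions whose first base is
  T(U), otherwise among non-U positions.
* Secondary piRNAs are triggered by antisense primaries that begin with U,
  reflecting the preferential loading of 1U piRNAs onto PIWI proteins; if no
  antisense primary starts with U the sampler falls back to all antisense
  primaries.  The secondary template is always the virus, the primary template
  always the EVE — that asymmetry is the model, not a knob.
* ``n_background`` adds piRNA-sized reads drawn uniformly from both viral
  strands with no positional coupling: a ping-pong-free degradation population
  used for knockout-style contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .types import EveFragment, ReferenceSeq, SimulationTruth, SmallRead, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory."""

    seed: int
    virus_length: int = 10700
    n_fragments: int = 4
    fragment_length_range: tuple[int, int] = (300, 2000)
    flipped_fragments: tuple[int, ...] = (2, 3)  # 0-based fragment indices
    divergence: float = 0.04
    host_flank_length: int = 5000
    n_sirna: int = 0
    n_primary: int = 0
    n_secondary: int = 0
    n_background: int = 0
    sirna_length: int = 21
    pirna_length_range: tuple[int, int] = (26, 30)
    u1_enforcement: float = 0.9
    size_selection: tuple[int, int] = (19, 33)
    error_rate: float = 0.001
    gc_content: float = 0.5
    quality_phred: int = 40
    degrade_tail: int = 0  # if >0, last N bases get Phred 2 (for trimmer tests)

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")
        for name in ("virus_length", "host_flank_length", "sirna_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.fragment_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid fragment_length_range")
        self.flipped_fragments = tuple(sorted(set(self.flipped_fragments)))
        if any(i < 0 or i >= self.n_fragments for i in self.flipped_fragments):
            raise ValueError("flipped_fragments indices outside range(n_fragments)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("simulation config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("fragment_length_range", "pirna_length_range", "size_selection",
                    "flipped_fragments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def make_virus_genome(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> ReferenceSeq:
    """I.i.d. random genome at the configured GC content; stands in for the virus."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    return ReferenceSeq("virus", _random_dna(rng, config.virus_length, config.gc_content))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, np.ndarray]:
    """Apply i.i.d. substitutions; returns (mutated, 0-based changed positions)."""
    if rate <= 0:
        return seq, np.empty(0, dtype=int)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), hit


def plant_eve(
    virus: ReferenceSeq,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    max_tries: int = 200,
) -> tuple[ReferenceSeq, list[EveFragment]]:
    """Copy viral fragments into a host contig and return the truth table.

    Fragments are drawn without overlap on the virus, reverse-complemented when
    flipped, diverged at the configured substitution rate, concatenated without
    spacers and embedded between random host flanks.  ``matches`` per fragment
    counts unsubstituted sites, so percent identity is exact planted identity.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    L = len(virus)
    lo, hi = config.fragment_length_range
    if config.n_fragments * hi > L:
        hi = max(lo, L // (config.n_fragments + 1))

    # draw non-overlapping virus intervals with bounded retries
    for _ in range(max_tries):
        lengths = rng.integers(lo, hi + 1, size=config.n_fragments)
        starts = np.sort(rng.integers(1, L - int(lengths.max()) + 1, size=config.n_fragments))
        intervals = [(int(s), int(s) + int(l) - 1) for s, l in zip(starts, lengths)]
        ok = all(intervals[i][1] < intervals[i + 1][0] for i in range(len(intervals) - 1))
        ok = ok and all(e <= L for _, e in intervals)
        if ok:
            break
    else:
        raise RuntimeError(
            f"could not place {config.n_fragments} non-overlapping fragments after {max_tries} tries"
        )

    pieces: list[str] = []
    fragments: list[EveFragment] = []
    offset = config.host_flank_length  # EVE starts right after the 5' flank
    cursor = offset + 1
    for idx, (vs, ve) in enumerate(intervals):
        segment = virus.sequence[vs - 1 : ve]
        if idx in config.flipped_fragments:
            segment = revcomp(segment)
            orientation = "-"
        else:
            orientation = "+"
        mutated, subs = _mutate(segment, config.divergence, rng)
        pieces.append(mutated)
        n = len(mutated)
        fragments.append(
            EveFragment(
                contig_start=cursor,
                contig_end=cursor + n - 1,
                virus_start=vs,
                virus_end=ve,
                orientation=orientation,
                matches=n - subs.size,
                aligned_columns=n,
            )
        )
        cursor += n

    eve_seq = "".join(pieces)
    flank5 = _random_dna(rng, config.host_flank_length, config.gc_content)
    flank3 = _random_dna(rng, config.host_flank_length, config.gc_content)
    contig = ReferenceSeq("host_contig", flank5 + eve_seq + flank3)
    return contig, fragments


def diagnostic_sites(virus: ReferenceSeq, contig: ReferenceSeq, fragments: list[EveFragment]) -> dict[int, list[int]]:
    """Contig positions (per fragment index) where EVE and virus disagree.

    Recovered by direct comparison through the fragment mapping, so it is exact
    for planted truth and meaningful for discovered fragments alike.
    """
    sites: dict[int, list[int]] = {}
    for i, f in enumerate(fragments):
        diffs = []
        for p in range(f.contig_start, f.contig_end + 1):
            v = virus.sequence[f.contig_to_virus(p) - 1]
            c = contig.sequence[p - 1]
            if f.orientation == "-":
                v = revcomp(v)
            if v != c:
                diffs.append(p)
        sites[i] = diffs
    return sites


def make_truth(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> SimulationTruth:
    """Virus + EVE-bearing contig + fragment table under one seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    virus = make_virus_genome(config, rng)
    contig, fragments = plant_eve(virus, config, rng)
    return SimulationTruth(
        virus=virus,
        host_contig=contig,
        planted_fragments=fragments,
        eve_start=fragments[0].contig_start,
        eve_end=fragments[-1].contig_end,
    )


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    mutated, _ = _mutate(seq, rate, rng)
    return mutated


def _quality(length: int, config: SimulationConfig) -> list[int]:
    q = [config.quality_phred] * length
    if config.degrade_tail > 0:
        for i in range(max(0, length - config.degrade_tail), length):
            q[i] = 2
    return q


def simulate_reads(
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SmallRead], dict]:
    """Emit siRNA / primary / secondary / background populations with labels.

    Returns (reads, stats); per-read labels are written into
    ``truth.read_labels``.  Reads falling outside the size-selection window
    after generation are discarded and counted in ``stats['size_rejected']``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    virus = truth.virus.sequence
    contig = truth.host_contig.sequence
    vlen = len(virus)
    plo, phi = config.pirna_length_range
    slo, shi = config.size_selection
    reads: list[SmallRead] = []
    labels = truth.read_labels
    size_rejected = 0

    def emit(read_id: str, seq: str, label: dict) -> None:
        nonlocal size_rejected
        seq = _apply_errors(seq, config.error_rate, rng)
        if not (slo <= len(seq) <= shi):
            size_rejected += 1
            return
        reads.append(SmallRead(read_id, seq, _quality(len(seq), config)))
        labels[read_id] = label

    # --- siRNAs: 21 nt, uniform over the virus, both strands equiprobable
    if config.n_sirna > 0:
        n = config.sirna_length
        lefts = rng.integers(1, vlen - n + 2, size=config.n_sirna)
        strands = rng.choice(np.array(["+", "-"]), size=config.n_sirna)
        for k, (left, strand) in enumerate(zip(lefts, strands)):
            left = int(left)
            seq = virus[left - 1 : left + n - 1]
            if strand == "-":
                seq = revcomp(seq)
            emit(
                f"sirna:{k:06d}",
                seq,
                {
                    "class": "sirna",
                    "template": "virus",
                    "true_5p_position": left if strand == "+" else left + n - 1,
                    "true_strand": str(strand),
                },
            )

    # --- primary piRNAs: from the EVE transcript (contig + strand), 1U-biased starts
    primaries: list[dict] = []
    if config.n_primary > 0:
        frags = truth.planted_fragments
        if not frags:
            raise ValueError("primary piRNAs requested but no planted fragments")
        weights = np.array([f.length for f in frags], dtype=float)
        weights /= weights.sum()
        # per fragment: sorted array of 0-based contig starts whose base is T / not T
        t_starts, o_starts = [], []
        for f in frags:
            pos = np.arange(f.contig_start, f.contig_end + 1)
            is_t = np.frombuffer(contig[f.contig_start - 1 : f.contig_end].encode(), np.uint8) == ord("T")
            t_starts.append(pos[is_t])
            o_starts.append(pos[~is_t])
        frag_idx = rng.choice(len(frags), size=config.n_primary, p=weights)
        lens = rng.integers(plo, phi + 1, size=config.n_primary)
        enforce = rng.random(config.n_primary) < config.u1_enforcement
        for k in range(config.n_primary):
            f = frags[frag_idx[k]]
            L = int(lens[k])
            limit = f.contig_end - L + 1
            pool = t_starts[frag_idx[k]] if enforce[k] else o_starts[frag_idx[k]]
            pool = pool[pool <= limit]
            if pool.size == 0:  # degenerate fragment composition: fall back to any start
                pool = np.arange(f.contig_start, limit + 1)
            start = int(pool[rng.integers(pool.size)])
            seq = contig[start - 1 : start + L - 1]
            virus_5p = f.contig_to_virus(start)
            virus_strand = "+" if f.orientation == "+" else "-"
            label = {
                "class": "primary_pirna",
                "template": "eve",
                "true_5p_position": start,
                "true_strand": "+",  # EVE transcript orientation on the contig
                "virus_5p": virus_5p,
                "virus_strand": virus_strand,
                "fragment": int(frag_idx[k]),
                "first_base": seq[0],
            }
            emit(f"primary:{k:06d}", seq, label)
            primaries.append(label)

    # --- secondary piRNAs: virus + strand, 5' end 10-nt-overlapping an antisense primary
    if config.n_secondary > 0:
        antisense = [p for p in primaries if p["virus_strand"] == "-"]
        if not antisense:
            raise ValueError("secondary piRNAs requested but no antisense primary piRNAs exist")
        # PIWI 1U loading preference: partners are U-starting antisense primaries
        pool = [p for p in antisense if p["first_base"] == "T"] or antisense
        for k in range(config.n_secondary):
            for _ in range(100):
                partner = pool[rng.integers(len(pool))]
                j = partner["virus_5p"]
                i = j - 9  # exact 10-nt 5' overlap
                L = int(rng.integers(plo, phi + 1))
                if 1 <= i and i + L - 1 <= vlen:
                    break
            else:
                raise RuntimeError("could not place a secondary piRNA inside the virus")
            seq = virus[i - 1 : i + L - 1]
            emit(
                f"secondary:{k:06d}",
                seq,
                {
                    "class": "secondary_pirna",
                    "template": "virus",
                    "true_5p_position": i,
                    "true_strand": "+",
                    "partner_5p": j,
                },
            )

    # --- background: piRNA-sized, uniform, both strands, no ping-pong structure
    if config.n_background > 0:
        lens = rng.integers(plo, phi + 1, size=config.n_background)
        strands = rng.choice(np.array(["+", "-"]), size=config.n_background)
        for k in range(config.n_background):
            L = int(lens[k])
            left = int(rng.integers(1, vlen - L + 2))
            seq = virus[left - 1 : left + L - 1]
            if strands[k] == "-":
                seq = revcomp(seq)
            emit(
                f"background:{k:06d}",
                seq,
                {
                    "class": "background",
                    "template": "virus",
                    "true_5p_position": left if strands[k] == "+" else left + L - 1,
                    "true_strand": str(strands[k]),
                },
            )

    stats = {
        "requested": config.n_sirna + config.n_primary + config.n_secondary + config.n_background,
        "emitted": len(reads),
        "size_rejected": size_rejected,
    }
    return reads, stats


def simulate(config: SimulationConfig) -> tuple[SimulationTruth, list[SmallRead], dict]:
    """One-call generator: references, fragment truth, labelled reads."""
    rng = np.random.default_rng(config.seed)
    truth = make_truth(config, rng)
    reads, stats = simulate_reads(truth, config, rng)
    return truth, reads, stats
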