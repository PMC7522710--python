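"""piRNA signature statistics: positional nucleotide bias and the ping-pong
5'-overlap spectrum.

The overlap statistic counts weighted pairs of opposite-strand reads whose 5'
ends overlap by d nt: with S(i) the weighted + strand 5'-end count at position
i and A(j) the weighted - strand 5'-end count at plus-strand coordinate j,

    c(d) = sum_i S(i) * A(i + d - 1),      d = 1..Dmax

Probabilities are p(d) = c(d)/sum(c) and the z-score of each bin is computed
against the mean and population SD over all Dmax bins (the d=10 bin is part of
its own background, matching the convention of the signature tools used for
ping-pong analysis).  A ping-pong signal appears as z(10) >> 0.

Nucleotide profiles (sequence-logo matrices) are computed from the read
sequences as read (5'->3'), truncated to 20 nt and reported as RNA, so
sequencing errors and template divergence show through rather than being
masked by the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import EveFragment, SmallRead, SmallReadAlignment

RNA_BASES = ("A", "C", "G", "U")
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@dataclass
class NucleotideProfile:
    """Per-position base frequencies (A,C,G,U) and information content."""

    counts: np.ndarray  # (positions, 4) weighted base counts
    n_reads: float
    orientation: str
    trim_to: int = 20

    @property
    def frequencies(self) -> np.ndarray:
        """(positions, 4); rows with zero coverage are NaN."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)

    @property
    def information(self) -> np.ndarray:
        """I(p) = 2 + sum_b f log2 f in bits (0*log0 := 0, no correction)."""
        f = self.frequencies
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + np.nansum(term, axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        f = self.frequencies
        df = pd.DataFrame(f, columns=list(RNA_BASES))
        df.insert(0, "position", np.arange(1, f.shape[0] + 1))
        df["information"] = self.information
        return df


def nucleotide_profile(
    alignments: Iterable[SmallReadAlignment],
    reads_by_id: dict[str, SmallRead],
    size_class: tuple[int, int] = (26, 30),
    orientation: str = "sense",
    region: Optional[tuple[int, int]] = None,
    trim_to: int = 20,
) -> NucleotideProfile:
    """Logo matrix of reads of one orientation whose 5' end lies in region.

    ``sense`` selects + strand alignments (reads running with the reference),
    ``antisense`` - strand ones.  Reads are weighted by alignment weight.
    """
    if orientation not in ("sense", "antisense"):
        raise ValueError("orientation must be 'sense' or 'antisense'")
    want = "+" if orientation == "sense" else "-"
    lo, hi = size_class
    counts = np.zeros((trim_to, 4))
    n = 0.0
    for a in alignments:
        if a.strand != want or not (lo <= a.read_length <= hi):
            continue
        if region is not None and not (region[0] <= a.five_prime <= region[1]):
            continue
        seq = reads_by_id[a.read_id].sequence[:trim_to]
        for p, base in enumerate(seq):
            if base in _BASE_IDX:
                counts[p, _BASE_IDX[base]] += a.weight
        n += a.weight
    return NucleotideProfile(counts=counts, n_reads=n, orientation=orientation, trim_to=trim_to)


def bias_fractions(profile: NucleotideProfile) -> dict[str, float]:
    """1U and 10A fractions of a profile; errors on an empty profile."""
    if profile.n_reads == 0:
        raise ValueError("profile contains no reads; bias fractions undefined")
    f = profile.frequencies
    return {"u1": float(f[0, 3]), "a10": float(f[9, 0])}


@dataclass
class OverlapSpectrum:
    """Weighted 5'-overlap pair counts, probabilities and z-scores."""

    distances: np.ndarray  # 1..Dmax
    counts: np.ndarray
    total_pairs: float

    @property
    def probabilities(self) -> np.ndarray:
        if self.total_pairs == 0:
            return np.zeros_like(self.counts)
        return self.counts / self.total_pairs

    @property
    def z_scores(self) -> np.ndarray:
        """Per-bin z against mean/population-SD over all bins; NaN when SD=0."""
        sd = self.counts.std()  # population SD, the bin included in its background
        if sd == 0:
            return np.full_like(self.counts, np.nan)
        return (self.counts - self.counts.mean()) / sd

    @property
    def ping_pong_z(self) -> float:
        """z-score of the 10-nt overlap bin (NaN when the spectrum is flat)."""
        return float(self.z_scores[np.where(self.distances == 10)[0][0]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "overlap": self.distances,
                "count": self.counts,
                "probability": self.probabilities,
                "z": self.z_scores,
            }
        )


def five_prime_counts(
    alignments: Iterable[SmallReadAlignment],
    size_class: tuple[int, int] = (26, 30),
) -> tuple[dict[int, float], dict[int, float]]:
    """Weighted 5'-end count maps (plus, minus) for a size class."""
    lo, hi = size_class
    plus: dict[int, float] = {}
    minus: dict[int, float] = {}
    for a in alignments:
        if not (lo <= a.read_length <= hi):
            continue
        target = plus if a.strand == "+" else minus
        target[a.five_prime] = target.get(a.five_prime, 0.0) + a.weight
    return plus, minus


def overlap_spectrum(
    alignments: Iterable[SmallReadAlignment],
    size_class: tuple[int, int] = (26, 30),
    region: Optional[tuple[int, int]] = None,
    dmax: int = 30,
) -> OverlapSpectrum:
    """c(d) = sum_i S(i) A(i+d-1) for d=1..dmax.

    A pair is attributed to ``region`` by the + strand read's 5' position; the
    - strand partner may lie outside it.
    """
    plus, minus = five_prime_counts(alignments, size_class)
    if region is not None:
        plus = {i: w for i, w in plus.items() if region[0] <= i <= region[1]}
    distances = np.arange(1, dmax + 1)
    counts = np.zeros(dmax)
    for i, s in plus.items():
        for d in distances:
            a = minus.get(i + int(d) - 1)
            if a:
                counts[d - 1] += s * a
    return OverlapSpectrum(distances=distances, counts=counts, total_pairs=float(counts.sum()))


def orient_relative_to_virus(
    alignments_on_eve: Iterable[SmallReadAlignment],
    fragments: list[EveFragment],
    virus_id: str = "virus",
) -> tuple[list[SmallReadAlignment], int]:
    """Re-express EVE-locus alignments in virus coordinates through fragments.

    Strand flips for orientation '-' fragments (a + strand read on a flipped
    fragment is antisense to the virus).  Alignments not fully contained in
    any fragment are dropped; the drop count is returned.
    """
    if not fragments:
        raise ValueError("fragment table is empty; cannot orient alignments")
    out: list[SmallReadAlignment] = []
    dropped = 0
    for a in alignments_on_eve:
        frag = next(
            (f for f in fragments if f.contig_start <= a.pos and a.end <= f.contig_end),
            None,
        )
        if frag is None:
            dropped += 1
            continue
        if frag.orientation == "+":
            new_pos = frag.contig_to_virus(a.pos)
            new_strand = a.strand
        else:
            new_pos = frag.contig_to_virus(a.end)  # footprint reverses
            new_strand = "-" if a.strand == "+" else "+"
        out.append(
            SmallReadAlignment(
                read_id=a.read_id, ref_id=virus_id, pos=new_pos, strand=new_strand,
                mismatches=a.mismatches, read_length=a.read_length, n_best=a.n_best,
            )
        )
    return out, dropped


def plot_overlap_spectrum(spectrum: OverlapSpectrum, path: str | Path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(spectrum.distances, spectrum.z_scores, color="#555555")
    ax.set_xlabel("5' overlap (nt)")
    ax.set_ylabel("z-score")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
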