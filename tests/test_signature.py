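"""Signature statistics: logo matrices, 1U/10A bias, overlap spectrum
closed forms and oracle, region handling, and EVE->virus orientation."""

import numpy as np
import pytest

from evepirna.align import align_reads
from evepirna.signature import (
    bias_fractions,
    nucleotide_profile,
    orient_relative_to_virus,
    overlap_spectrum,
)
from evepirna.simulate import SimulationConfig, simulate
from evepirna.types import EveFragment, SmallRead, SmallReadAlignment


def _aln(pos, strand, length=28, read_id="r", n_best=1, ref="virus"):
    return SmallReadAlignment(read_id, ref, pos, strand, 0, length, n_best)


def _brute_force_counts(alignments, size_class=(26, 30), region=None, dmax=30):
    """Independent oracle: double loop over all opposite-strand pairs."""
    lo, hi = size_class
    sel = [a for a in alignments if lo <= a.read_length <= hi]
    counts = np.zeros(dmax)
    for a in sel:
        if a.strand != "+":
            continue
        if region is not None and not (region[0] <= a.five_prime <= region[1]):
            continue
        for b in sel:
            if b.strand != "-":
                continue
            d = b.five_prime - a.five_prime + 1
            if 1 <= d <= dmax:
                counts[d - 1] += a.weight * b.weight
    return counts


def test_single_bin_closed_form():
    """One nonzero bin among D gives z = sqrt(D-1) at that bin, exactly."""
    aln = [
        _aln(1, "+", read_id="s1"), _aln(1, "+", read_id="s2"),
        _aln(1, "-", 10, read_id="a1"), _aln(1, "-", 10, read_id="a2"),
        _aln(1, "-", 10, read_id="a3"),
    ]
    # three minus reads of length 10 with five_prime = 10; two plus reads at 1
    spec = overlap_spectrum(aln, size_class=(1, 40), dmax=30)
    assert spec.counts[9] == 6.0
    assert spec.counts.sum() == 6.0
    assert spec.probabilities[9] == 1.0
    assert spec.ping_pong_z == pytest.approx(np.sqrt(29), abs=1e-12)
    assert spec.ping_pong_z == pytest.approx(5.385, abs=1e-3)


def test_no_pairs_gives_null_z():
    spec = overlap_spectrum([_aln(1, "+")], size_class=(26, 30))
    assert spec.total_pairs == 0
    assert np.isnan(spec.z_scores).all()
    assert np.isnan(spec.ping_pong_z)


def test_z_scale_invariance():
    """z is identical whether computed on counts or probabilities."""
    rng = np.random.default_rng(0)
    from evepirna.signature import OverlapSpectrum

    counts = rng.integers(0, 50, size=30).astype(float)
    a = OverlapSpectrum(np.arange(1, 31), counts, counts.sum())
    b = OverlapSpectrum(np.arange(1, 31), counts / counts.sum(), 1.0)
    np.testing.assert_allclose(a.z_scores, b.z_scores, atol=1e-12)


def test_overlap_counts_match_brute_force(virus_alignments):
    sub = virus_alignments[:1500]
    spec = overlap_spectrum(sub, size_class=(26, 30))
    np.testing.assert_allclose(spec.counts, _brute_force_counts(sub), atol=1e-9)


def test_region_restriction_and_additivity(virus_alignments):
    sub = virus_alignments[:1500]
    whole = overlap_spectrum(sub, region=(1, 10700))
    left = overlap_spectrum(sub, region=(1, 5000))
    right = overlap_spectrum(sub, region=(5001, 10700))
    np.testing.assert_allclose(whole.counts, left.counts + right.counts, atol=1e-9)
    np.testing.assert_allclose(
        left.counts, _brute_force_counts(sub, region=(1, 5000)), atol=1e-9
    )


def test_identical_reads_full_information():
    reads = {f"r{i}": SmallRead(f"r{i}", "T" + "CG" * 13) for i in range(5)}
    aln = [_aln(1, "+", 27, read_id=f"r{i}") for i in range(5)]
    prof = nucleotide_profile(aln, reads, size_class=(26, 30))
    assert prof.n_reads == 5
    np.testing.assert_allclose(prof.information, np.full(20, 2.0), atol=1e-12)
    bias = bias_fractions(prof)
    assert bias["u1"] == 1.0  # reads start with T == U
    assert bias["a10"] == 0.0


def test_empty_profile_bias_is_an_error():
    prof = nucleotide_profile([], {}, size_class=(26, 30))
    assert prof.n_reads == 0
    with pytest.raises(ValueError):
        bias_fractions(prof)


def test_u1_recovery_from_simulated_primaries(infection_library):
    """Position-1 U frequency of EVE-mapped primaries recovers u1_enforcement."""
    conf, truth, reads, _ = infection_library
    prim = [r for r in reads if truth.read_labels[r.id]["class"] == "primary_pirna"]
    eve = truth.eve_locus()
    aln = align_reads(prim, eve, max_mismatch=1, k=12)
    prof = nucleotide_profile(aln, {r.id: r for r in prim}, (26, 30), "sense")
    u1 = bias_fractions(prof)["u1"]
    sd = np.sqrt(0.9 * 0.1 / prof.n_reads)
    assert abs(u1 - conf.u1_enforcement) < 4 * sd + 0.01


def test_perfect_a10_without_divergence():
    conf = SimulationConfig(
        seed=41, n_primary=400, n_secondary=800,
        divergence=0.0, u1_enforcement=1.0, error_rate=0.0,
    )
    truth, reads, _ = simulate(conf)
    sec = [r for r in reads if truth.read_labels[r.id]["class"] == "secondary_pirna"]
    aln = align_reads(sec, truth.virus, max_mismatch=0, k=12)
    prof = nucleotide_profile(aln, {r.id: r for r in sec}, (26, 30), "sense")
    assert bias_fractions(prof)["a10"] == 1.0


def test_directional_bias_pattern(infection_library, virus_alignments, reads_by_id):
    """Antisense reads carry the 1U mark, sense reads the 10A mark."""
    anti = nucleotide_profile(virus_alignments, reads_by_id, (26, 30), "antisense")
    sense = nucleotide_profile(virus_alignments, reads_by_id, (26, 30), "sense")
    b_anti, b_sense = bias_fractions(anti), bias_fractions(sense)
    assert b_anti["u1"] > b_anti["a10"]
    assert b_sense["a10"] > b_sense["u1"]


def test_ping_pong_peak_at_10(virus_alignments):
    spec = overlap_spectrum(virus_alignments, size_class=(26, 30))
    assert spec.distances[spec.counts.argmax()] == 10
    assert spec.ping_pong_z > 4


def test_orient_hand_built_fragment_boundaries():
    """Off-by-one audit on a 20-nt fragment, both orientations, both ends."""
    fwd = EveFragment(101, 120, 501, 520, "+", 20, 20)
    rev = EveFragment(101, 120, 501, 520, "-", 20, 20)
    # plus fragment: contig 101 -> virus 501; strand preserved
    out, dropped = orient_relative_to_virus([_aln(101, "+", 20, ref="eve")], [fwd])
    assert dropped == 0 and (out[0].pos, out[0].strand, out[0].five_prime) == (501, "+", 501)
    # minus fragment: footprint reverses; contig end 120 -> virus 501
    out, _ = orient_relative_to_virus([_aln(101, "+", 20, ref="eve")], [rev])
    assert (out[0].pos, out[0].strand) == (501, "-")
    assert out[0].five_prime == 520  # 5' base (contig 101) maps to virus 520
    # read at the 3' edge of the minus fragment, 10 nt long: contig 111..120
    out, _ = orient_relative_to_virus([_aln(111, "+", 10, ref="eve")], [rev])
    assert (out[0].pos, out[0].end) == (501, 510)
    # minus-strand read on a minus fragment comes out sense to the virus
    out, _ = orient_relative_to_virus([_aln(101, "-", 20, ref="eve")], [rev])
    assert out[0].strand == "+"
    # alignments outside every fragment are dropped and counted
    out, dropped = orient_relative_to_virus([_aln(300, "+", 20, ref="eve")], [fwd])
    assert out == [] and dropped == 1
    with pytest.raises(ValueError):
        orient_relative_to_virus([_aln(101, "+", 20)], [])


def test_primaries_from_flipped_fragments_antisense_after_conversion(infection_library):
    conf, truth, reads, _ = infection_library
    flipped = set(conf.flipped_fragments)
    prim = [
        r for r in reads
        if truth.read_labels[r.id]["class"] == "primary_pirna"
        and truth.read_labels[r.id]["fragment"] in flipped
    ]
    eve = truth.eve_locus()
    aln = align_reads(prim, eve, max_mismatch=1, k=12)
    converted, dropped = orient_relative_to_virus(aln, truth.fragments_on_locus())
    frac_anti = sum(a.weight for a in converted if a.strand == "-") / sum(
        a.weight for a in converted
    )
    assert frac_anti >= 0.99
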