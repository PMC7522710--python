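"""EVE discovery: seed/extend correctness, chaining, identity exactness,
recovery of planted fragment structure and strand symmetry."""

import numpy as np
import pytest

from evepirna.discovery import (
    chain_into_fragments,
    find_hsps,
    fragment_identity_report,
    write_bed,
)
from evepirna.simulate import SimulationConfig, make_truth
from evepirna.types import Hsp, ReferenceSeq, revcomp


def _random_seq(rng, n):
    return rng.choice(np.frombuffer(b"ACGT", np.uint8), size=n).tobytes().decode()


def test_exact_substring_found_forward(rng):
    virus = ReferenceSeq("virus", _random_seq(rng, 3000))
    insert = virus.sequence[999:1499]  # 500 nt
    contig = ReferenceSeq("contig", _random_seq(rng, 1000) + insert + _random_seq(rng, 1000))
    frags = chain_into_fragments(find_hsps(contig, virus), contig=contig, virus=virus)
    assert len(frags) == 1
    f = frags[0]
    assert f.orientation == "+"
    assert f.percent_identity == 100.0
    assert (f.contig_start, f.contig_end) == (1001, 1500)
    assert (f.virus_start, f.virus_end) == (1000, 1499)


def test_exact_substring_found_reverse(rng):
    virus = ReferenceSeq("virus", _random_seq(rng, 3000))
    insert = revcomp(virus.sequence[999:1499])
    contig = ReferenceSeq("contig", _random_seq(rng, 800) + insert + _random_seq(rng, 800))
    frags = chain_into_fragments(find_hsps(contig, virus), contig=contig, virus=virus)
    assert len(frags) == 1
    f = frags[0]
    assert f.orientation == "-"
    assert (f.virus_start, f.virus_end) == (1000, 1499)  # virus interval unchanged
    assert (f.contig_start, f.contig_end) == (801, 1300)


def test_chain_merges_same_diagonal_hsps():
    a = Hsp(101, 200, 501, 600, "+", 98, 100, 92)
    b = Hsp(211, 300, 611, 700, "+", 88, 90, 82)  # 10-nt gap, same diagonal
    frags = chain_into_fragments([a, b], max_gap=50)
    assert len(frags) == 1
    f = frags[0]
    assert (f.contig_start, f.contig_end) == (101, 300)
    assert (f.virus_start, f.virus_end) == (501, 700)
    # without sequences the 10 gap columns are scored as mismatches
    assert f.aligned_columns == 200 and f.matches == 98 + 88
    assert f.n_hsps == 2


def test_chain_respects_gap_and_orientation():
    a = Hsp(101, 200, 501, 600, "+", 98, 100, 92)
    far = Hsp(301, 400, 701, 800, "+", 98, 100, 92)  # gap 100 > max_gap
    assert len(chain_into_fragments([a, far], max_gap=50)) == 2
    # opposite orientations are never merged, however close
    flip = Hsp(205, 304, 501, 600, "-", 98, 100, 92)
    assert len(chain_into_fragments([a, flip], max_gap=50)) == 2


def test_planted_structure_recovered(infection_library):
    _, truth, _, _ = infection_library
    hsps = find_hsps(truth.host_contig, truth.virus)
    found = chain_into_fragments(hsps, contig=truth.host_contig, virus=truth.virus)
    assert len(found) == len(truth.planted_fragments)
    for got, want in zip(found, truth.planted_fragments):
        assert got.orientation == want.orientation
        assert abs(got.contig_start - want.contig_start) <= 11
        assert abs(got.contig_end - want.contig_end) <= 11


def test_hsp_coverage_of_diverged_fragment(infection_library):
    """Union of HSPs covers >=95% of each planted interval at 4% divergence."""
    _, truth, _, _ = infection_library
    hsps = find_hsps(truth.host_contig, truth.virus)
    for want in truth.planted_fragments:
        covered = np.zeros(want.length, dtype=bool)
        for h in hsps:
            lo = max(h.contig_start, want.contig_start)
            hi = min(h.contig_end, want.contig_end)
            if lo <= hi:
                covered[lo - want.contig_start : hi - want.contig_start + 1] = True
        assert covered.mean() >= 0.95


def test_identity_recomputable_from_sequences(infection_library):
    """Reported identity is exactly reproducible from the two sequences."""
    _, truth, _, _ = infection_library
    contig, virus = truth.host_contig, truth.virus
    found = chain_into_fragments(find_hsps(contig, virus), contig=contig, virus=virus)
    for f in found:
        matches = 0
        for p in range(f.contig_start, f.contig_end + 1):
            v = virus.sequence[f.contig_to_virus(p) - 1]
            c = contig.sequence[p - 1]
            if f.orientation == "-":
                v = revcomp(v)
            matches += v == c
        assert f.percent_identity == 100.0 * matches / f.length


def test_symmetry_under_contig_reverse_complement(infection_library):
    _, truth, _, _ = infection_library
    contig, virus = truth.host_contig, truth.virus
    fwd = chain_into_fragments(find_hsps(contig, virus), contig=contig, virus=virus)
    rc_contig = ReferenceSeq("rc", revcomp(contig.sequence))
    rev = chain_into_fragments(find_hsps(rc_contig, virus), contig=rc_contig, virus=virus)
    n = len(contig.sequence)
    mirrored = sorted(
        ((n - f.contig_end + 1, n - f.contig_start + 1, "-" if f.orientation == "+" else "+")
         for f in fwd)
    )
    got = sorted((f.contig_start, f.contig_end, f.orientation) for f in rev)
    assert got == mirrored


def test_identity_report_and_bed(tmp_path, infection_library):
    _, truth, _, _ = infection_library
    found = chain_into_fragments(
        find_hsps(truth.host_contig, truth.virus),
        contig=truth.host_contig, virus=truth.virus,
    )
    df, summary = fragment_identity_report(found)
    assert summary["n_fragments"] == 4
    # planted at 4% divergence: overall identity near 96% (3 binomial SDs)
    cols = sum(f.aligned_columns for f in found)
    sd = 100 * np.sqrt(0.04 * 0.96 / cols)
    assert abs(summary["overall_identity"] - 96.0) < 3 * sd
    assert list(df["percent_identity"]) == [round(f.percent_identity, 2) for f in found]
    bed = tmp_path / "frags.bed"
    write_bed(found, truth.host_contig.id, bed)
    lines = bed.read_text().strip().split("\n")
    assert len(lines) == 4
    start0, end0 = int(lines[0].split("\t")[1]), int(lines[0].split("\t")[2])
    assert (start0, end0) == (found[0].contig_start - 1, found[0].contig_end)


def test_empty_inputs():
    with pytest.raises(ValueError):
        find_hsps(ReferenceSeq("c", ""), ReferenceSeq("v", "ACGT"))
    assert chain_into_fragments([]) == []
    with pytest.raises(ValueError):
        fragment_identity_report([])


def test_no_homology_gives_no_hits():
    contig = ReferenceSeq("c", "AT" * 500)
    virus = ReferenceSeq("v", "GC" * 500)
    assert find_hsps(contig, virus) == []
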