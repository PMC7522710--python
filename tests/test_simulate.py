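"""Generator contracts: determinism, planted structure, read-population biases."""

import numpy as np
import pytest
import yaml

from evepirna.simulate import (
    SimulationConfig,
    diagnostic_sites,
    make_truth,
    make_virus_genome,
    plant_eve,
    simulate,
)
from evepirna.types import revcomp


def test_virus_genome_length_and_composition():
    conf = SimulationConfig(seed=1, virus_length=100)
    virus = make_virus_genome(conf)
    assert len(virus.sequence) == 100
    gc_only = make_virus_genome(SimulationConfig(seed=1, virus_length=500, gc_content=1.0))
    assert set(gc_only.sequence) <= {"G", "C"}


def test_determinism_byte_identical():
    conf = SimulationConfig(seed=9, n_sirna=200, n_primary=300, n_secondary=300)
    a = simulate(conf)
    b = simulate(conf)
    assert a[0].virus.sequence == b[0].virus.sequence
    assert a[0].host_contig.sequence == b[0].host_contig.sequence
    assert [(r.id, r.sequence, r.quality) for r in a[1]] == [
        (r.id, r.sequence, r.quality) for r in b[1]
    ]


def test_zero_divergence_gives_full_identity():
    conf = SimulationConfig(seed=2, divergence=0.0)
    truth = make_truth(conf)
    assert all(f.percent_identity == 100.0 for f in truth.planted_fragments)
    # and no diagnostic sites anywhere
    sites = diagnostic_sites(truth.virus, truth.host_contig, truth.planted_fragments)
    assert all(len(v) == 0 for v in sites.values())


def test_divergence_realized_identity_binomial():
    conf = SimulationConfig(seed=3, divergence=0.04)
    truth = make_truth(conf)
    cols = sum(f.aligned_columns for f in truth.planted_fragments)
    matches = sum(f.matches for f in truth.planted_fragments)
    sd = np.sqrt(0.04 * 0.96 / cols)
    assert abs(matches / cols - 0.96) < 3 * sd


def test_flipped_fragment_is_reverse_complement():
    conf = SimulationConfig(seed=4, divergence=0.0)
    truth = make_truth(conf)
    contig, virus = truth.host_contig.sequence, truth.virus.sequence
    for idx, f in enumerate(truth.planted_fragments):
        segment = virus[f.virus_start - 1 : f.virus_end]
        planted = contig[f.contig_start - 1 : f.contig_end]
        expected = revcomp(segment) if f.orientation == "-" else segment
        assert planted == expected
        assert (f.orientation == "-") == (idx in conf.flipped_fragments)


@pytest.mark.parametrize("seed", [1, 5, 23])
def test_fragment_intervals_disjoint_and_in_bounds(seed):
    conf = SimulationConfig(seed=seed)
    truth = make_truth(conf)
    frags = truth.planted_fragments
    for f in frags:
        assert 1 <= f.virus_start <= f.virus_end <= len(truth.virus)
        assert 1 <= f.contig_start <= f.contig_end <= len(truth.host_contig)
    ordered = sorted(frags, key=lambda f: f.virus_start)
    assert all(a.virus_end < b.virus_start for a, b in zip(ordered, ordered[1:]))
    # adjacency on the contig: no spacers between planted fragments
    assert all(a.contig_end + 1 == b.contig_start for a, b in zip(frags, frags[1:]))


def test_error_free_sirnas_are_exact_virus_substrings():
    conf = SimulationConfig(seed=6, n_sirna=1000, error_rate=0.0)
    truth, reads, _ = simulate(conf)
    virus = truth.virus.sequence
    for r in reads:
        assert r.sequence in virus or revcomp(r.sequence) in virus
        assert len(r.sequence) == conf.sirna_length


def test_forced_u1_bias():
    conf = SimulationConfig(seed=6, n_primary=2000, u1_enforcement=1.0, error_rate=0.0)
    _, reads, _ = simulate(conf)
    assert all(r.sequence[0] == "T" for r in reads)


def test_emergent_10a_is_exact_without_divergence():
    conf = SimulationConfig(
        seed=8, n_primary=500, n_secondary=1000,
        divergence=0.0, u1_enforcement=1.0, error_rate=0.0,
    )
    truth, reads, _ = simulate(conf)
    secondaries = [r for r in reads if truth.read_labels[r.id]["class"] == "secondary_pirna"]
    assert len(secondaries) == 1000
    assert all(r.sequence[9] == "A" for r in secondaries)


def test_conservation_and_unique_labels():
    # size selection rejects 28-30 nt reads -> emitted + rejected == requested
    conf = SimulationConfig(
        seed=10, n_sirna=300, n_primary=600, n_secondary=600, size_selection=(19, 27)
    )
    truth, reads, stats = simulate(conf)
    assert stats["emitted"] + stats["size_rejected"] == stats["requested"]
    assert stats["size_rejected"] > 0
    ids = [r.id for r in reads]
    assert len(ids) == len(set(ids))
    assert set(ids) == set(truth.read_labels)


def test_secondaries_require_antisense_primaries():
    conf = SimulationConfig(seed=11, n_primary=100, n_secondary=100, flipped_fragments=())
    truth = make_truth(conf)
    with pytest.raises(ValueError, match="antisense"):
        simulate(conf)
    conf2 = SimulationConfig(seed=11, n_primary=0, n_secondary=100)
    with pytest.raises(ValueError):
        simulate(conf2)
    del truth


def test_config_validation_and_yaml(tmp_path):
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, divergence=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, virus_length=0)
    path = tmp_path / "conf.yaml"
    path.write_text("seed: 3\nn_sirna: 10\nbogus_knob: 5\n")
    with pytest.raises(ValueError, match="bogus_knob"):
        SimulationConfig.from_yaml(path)
    path.write_text("n_sirna: 10\n")
    with pytest.raises(ValueError, match="seed"):
        SimulationConfig.from_yaml(path)
    path.write_text(yaml.safe_dump({"seed": 3, "n_sirna": 10, "size_selection": [19, 33]}))
    conf = SimulationConfig.from_yaml(path)
    assert conf.seed == 3 and conf.size_selection == (19, 33)


def test_degraded_tail_qualities():
    conf = SimulationConfig(seed=12, n_sirna=5, degrade_tail=4)
    _, reads, _ = simulate(conf)
    for r in reads:
        assert r.quality[-4:] == [2, 2, 2, 2]
        assert all(q == conf.quality_phred for q in r.quality[:-4])
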