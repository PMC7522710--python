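"""End-to-end orchestration: simulate -> trim -> align -> discover -> profile
-> signature -> disambiguate, driven by a YAML config, plus the prevalence
helper for carrier-frequency estimates.

Every output TSV carries provenance header lines (tool version, config hash,
seed).  A stage whose outputs already exist in the run directory is skipped,
so re-running a single stage from cached upstream outputs is byte-identical
to a full run (everything downstream of the seed is deterministic).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import yaml
from statsmodels.stats.proportion import proportion_confint

from . import __version__
from .align import align_reads
from .disambiguate import classify_reads, diagnostic_site_density
from .discovery import chain_into_fragments, find_hsps, fragment_identity_report, write_bed
from .profile import coverage_track, size_spectrum
from .seqio import trim_and_filter, write_fasta, write_fastq, write_sam, write_tsv
from .signature import bias_fractions, nucleotide_profile, overlap_spectrum
from .simulate import SimulationConfig, simulate
from .types import ReferenceSeq, SmallRead

log = logging.getLogger("evepirna")

_TOP_KEYS = {"seed", "output_dir", "simulation", "trim", "align", "signature", "discover"}


def prevalence(positive: int, tested: int, conf: float = 0.95) -> dict[str, float]:
    """Carrier prevalence as a percentage with a Wilson score interval."""
    if tested <= 0:
        raise ValueError("tested must be positive")
    if not (0 <= positive <= tested):
        raise ValueError("positive must lie in [0, tested]")
    lo, hi = proportion_confint(positive, tested, alpha=1 - conf, method="wilson")
    return {
        "percent": 100.0 * positive / tested,
        "ci_low": 100.0 * lo,
        "ci_high": 100.0 * hi,
    }


def _config_hash(config: dict) -> str:
    # output_dir is excluded: the same analysis in two directories is the same run
    payload = {k: v for k, v in config.items() if k != "output_dir"}
    blob = yaml.safe_dump(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _validate(config: dict) -> None:
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("seed", "output_dir"):
        if key not in config:
            raise ValueError(f"config missing required key: {key}")


def run(config_path: str | Path) -> Path:
    """Execute the configured stages; returns the run directory."""
    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    return run_dict(config)


def run_dict(config: dict) -> Path:
    _validate(config)
    chash = _config_hash(config)
    header = [f"evepirna {__version__}", f"config_hash: {chash}", f"seed: {config['seed']}"]
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- simulate ------------------------------------------------------
    sim_conf = SimulationConfig(seed=config["seed"], **(config.get("simulation") or {}))
    truth, reads, sim_stats = simulate(sim_conf)
    eve_locus = truth.eve_locus()
    frag_table = truth.fragments_on_locus()
    if not (outdir / "reads.fastq").exists():
        write_fasta([truth.virus], outdir / "virus.fasta")
        write_fasta([truth.host_contig], outdir / "host_contig.fasta")
        write_fasta([eve_locus], outdir / "eve_locus.fasta")
        write_fastq(reads, outdir / "reads.fastq")
        write_tsv(
            [
                {
                    "fragment": i + 1,
                    "contig_start": f.contig_start, "contig_end": f.contig_end,
                    "virus_start": f.virus_start, "virus_end": f.virus_end,
                    "orientation": f.orientation,
                    "percent_identity": round(f.percent_identity, 2),
                }
                for i, f in enumerate(truth.planted_fragments)
            ],
            outdir / "fragments_truth.tsv", header,
        )
        write_tsv(
            [{"read_id": rid, **{k: v for k, v in lab.items()}} for rid, lab in truth.read_labels.items()],
            outdir / "read_labels.tsv", header,
        )
    log.info("simulate: requested=%d emitted=%d size_rejected=%d",
             sim_stats["requested"], sim_stats["emitted"], sim_stats["size_rejected"])

    # ---- trim (only when an adapter is configured) ---------------------
    trim_conf = config.get("trim") or {}
    if trim_conf.get("adapter"):
        reads, trim_stats = trim_and_filter(
            reads,
            adapter=trim_conf["adapter"],
            min_phred=trim_conf.get("min_phred", 20),
            size_window=tuple(trim_conf.get("size_window", (19, 33))),
        )
        write_tsv([trim_stats.as_dict()], outdir / "trim_stats.tsv", header)
        log.info("trim: %s", trim_stats.as_dict())

    # ---- align ---------------------------------------------------------
    align_conf = config.get("align") or {}
    mm = int(align_conf.get("max_mismatch", 1))
    k = int(align_conf.get("k", 12))
    virus_aln = align_reads(reads, truth.virus, max_mismatch=mm, k=k)
    eve_aln = align_reads(reads, eve_locus, max_mismatch=mm, k=k)
    reads_by_id = {r.id: r for r in reads}
    if not (outdir / "virus.sam").exists():
        write_sam(virus_aln, [truth.virus], outdir / "virus.sam", reads_by_id)
        write_sam(eve_aln, [eve_locus], outdir / "eve_locus.sam", reads_by_id)
    n_virus_mapped = len({a.read_id for a in virus_aln})
    log.info("align: %d reads, %d mapped to virus, %d alignments on EVE locus",
             len(reads), n_virus_mapped, len(eve_aln))

    # ---- discover ------------------------------------------------------
    disc_conf = config.get("discover") or {}
    hsps = find_hsps(
        truth.host_contig, truth.virus,
        k=disc_conf.get("k", 11), xdrop=disc_conf.get("xdrop", 20),
        min_score=disc_conf.get("min_score", 30),
    )
    found = chain_into_fragments(hsps, disc_conf.get("max_gap", 50),
                                 contig=truth.host_contig, virus=truth.virus)
    frag_df, frag_summary = fragment_identity_report(found)
    frag_df.to_csv(outdir / "fragments_found.tsv", sep="\t", index=False)
    write_bed(found, truth.host_contig.id, outdir / "fragments_found.bed")
    log.info("discover: %d fragments, overall identity %.2f%%",
             frag_summary["n_fragments"], frag_summary["overall_identity"])

    # ---- profile -------------------------------------------------------
    spectrum = size_spectrum(virus_aln)
    spectrum.to_dataframe().to_csv(outdir / "size_spectrum.tsv", sep="\t", index=False)
    for tag, size_class in (("21nt", (21, 21)), ("26-30nt", (26, 30))):
        track = coverage_track(virus_aln, len(truth.virus), size_class, ref_id=truth.virus.id)
        track.to_dataframe().to_csv(outdir / f"coverage_{tag}.tsv", sep="\t", index=False)

    # ---- signature -----------------------------------------------------
    sig_conf = config.get("signature") or {}
    size_class = tuple(sig_conf.get("size_class", (26, 30)))
    region = tuple(sig_conf["region"]) if sig_conf.get("region") else None
    dmax = int(sig_conf.get("dmax", 30))
    profiles = {}
    for orientation in ("sense", "antisense"):
        prof = nucleotide_profile(virus_aln, reads_by_id, size_class, orientation, region)
        prof.to_dataframe().to_csv(outdir / f"logo_{orientation}.tsv", sep="\t", index=False)
        profiles[orientation] = prof
    spec = overlap_spectrum(virus_aln, size_class, region, dmax)
    spec.to_dataframe().to_csv(outdir / "overlap_spectrum.tsv", sep="\t", index=False)

    # ---- disambiguate --------------------------------------------------
    calls, summary = classify_reads(reads, truth.virus, eve_locus, frag_table, k=k)
    summary.to_csv(outdir / "classification_summary.tsv", sep="\t", index=False)

    # ---- report: collation only, no recomputation ----------------------
    report = {
        "version": __version__,
        "config_hash": chash,
        "seed": config["seed"],
        "reads": {"emitted": sim_stats["emitted"], "mapped_to_virus": n_virus_mapped},
        "fragments": frag_summary,
        "ping_pong_z": None if spec.total_pairs == 0 else spec.ping_pong_z,
        "diagnostic_site_density": diagnostic_site_density(
            truth.virus, eve_locus, frag_table
        ),
        "class_counts": {c: sum(1 for x in calls if x.cls == c)
                         for c in ("virus_only", "eve_only", "shared", "unmapped")},
    }
    for orientation, prof in profiles.items():
        if prof.n_reads > 0:
            report[f"bias_{orientation}"] = bias_fractions(prof)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return outdir
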