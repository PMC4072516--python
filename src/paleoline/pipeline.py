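"""End-to-end orchestration: history analysis and master reconstruction.

Chains the stages (scan -> co-segregation -> family history; walk -> CpG
correction -> verification -> annotation), writes all intermediates as
plain text, and stamps every output with the RNG seed and a hash of the
full configuration so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import coseg, history, walker
from ._seq import write_fasta
from .scan import ScanConfig
from .simulate import SimulationParams


@dataclass
class PipelineConfig:
    """All stage parameters plus reproducibility metadata.

    ``profile`` swaps scale defaults: "paper" keeps the genome-scale
    subfamily floor of 250; "desk" lowers it to 25 so the pipeline is
    exercisable on synthetic megabase-scale data.
    """

    sim: SimulationParams = field(default_factory=SimulationParams)
    scan: ScanConfig = field(default_factory=ScanConfig)
    coseg: coseg.CosegConfig = field(default_factory=coseg.CosegConfig)
    walk: walker.WalkConfig = field(default_factory=walker.WalkConfig)
    family_threshold: float = 3.5
    discovery_rounds: int = 2
    rng_seed: int = 0
    profile: str = "desk"

    def __post_init__(self):
        if self.profile not in ("desk", "paper"):
            raise ValueError("profile must be 'desk' or 'paper'")
        if self.profile == "desk" and self.coseg.min_subfamily_size == 250:
            self.coseg = dataclasses.replace(self.coseg,
                                             min_subfamily_size=25)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stamp(self) -> str:
        return f"paleoline seed={self.rng_seed} config={self.hash()}"

    def snapshot(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config.json", "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


@dataclass
class HistoryResult:
    models: list
    hits: list
    assignments: pd.DataFrame
    partition: history.FamilyPartition
    landscape: history.AgeLandscape
    peaks: list
    dispersion: list
    ages: dict


@dataclass
class ReconstructionResult:
    consensus: str
    uncorrected_consensus: str
    state: walker.WalkState
    support: walker.ColumnSupport
    corrections: list
    verification: walker.VerificationReport | None
    annotation: ann.AnnotatedElement


def _check_reads(reads) -> None:
    seqs = reads.reads if hasattr(reads, "reads") else reads
    if not seqs:
        raise ValueError("no reads supplied; nothing to analyse")


def run_history(reads, seed_query: str, config: PipelineConfig,
                outdir: str | Path | None = None) -> HistoryResult:
    """scan -> co-segregation -> families -> landscape -> peaks -> dispersion."""
    _check_reads(reads)
    if not seed_query:
        raise ValueError("empty seed query")
    models, hits = coseg.iterate_discovery(
        reads, seed_query, config.scan, config.coseg,
        rounds=config.discovery_rounds)
    assignments = coseg.assignments_frame(hits)
    consensuses = [(f"sf{m.subfamily_id}", m.consensus) for m in models]
    youth = {f"sf{m.subfamily_id}":
             float(pd.Series(m.member_identities).mean())
             for m in models if m.member_identities}
    partition = history.cluster_families(consensuses, config.family_threshold,
                                         youth=youth)
    landscape = history.build_landscape(assignments, partition)
    peaks = history.call_peaks(landscape)
    dispersion = history.dispersion_diagnostic(assignments, landscape,
                                               partition)
    ages = history.calibrate_ages(landscape)
    if outdir is not None:
        outdir = Path(outdir)
        config.snapshot(outdir)
        stamp = config.stamp()
        coseg.write_subfamilies(models, outdir, header_comment=stamp)
        partition.distance_matrix.to_csv(outdir / "distance_matrix.tsv",
                                         sep="\t")
        history.write_landscape(landscape, outdir / "landscape.tsv", stamp)
        history.write_peaks(peaks, outdir / "peaks.tsv", stamp)
        with open(outdir / "families.tsv", "w") as fh:
            fh.write(f"# {stamp}\nfamily\tsubfamilies\trelative_age\n")
            for fam, subs in partition.families.items():
                fh.write(f"{fam}\t{','.join(subs)}\t"
                         f"{ages.get(fam, float('nan')):.2f}\n")
        with open(outdir / "dispersion.tsv", "w") as fh:
            fh.write(f"# {stamp}\nfamily\tmean_divergence\tpeak_divergence"
                     "\tmean_minus_peak\tvariance_mean_ratio"
                     "\toverdispersed\n")
            for d in dispersion:
                fh.write(f"{d.family_id}\t{d.mean_divergence:.3f}"
                         f"\t{d.peak_divergence:.3f}\t{d.mean_minus_peak:.3f}"
                         f"\t{d.variance_mean_ratio:.3f}"
                         f"\t{int(d.overdispersed)}\n")
        with open(outdir / "subfamily_tree.nwk", "w") as fh:
            fh.write(history.nj_tree(partition.distance_matrix) + "\n")
    return HistoryResult(models, hits, assignments, partition, landscape,
                         peaks, dispersion, ages)


def run_reconstruct(reads, seed: str, config: PipelineConfig,
                    outdir: str | Path | None = None,
                    apply_cpg_correction: bool = True,
                    review: bool = False,
                    verify: bool = True) -> ReconstructionResult:
    """walk -> CpG correction -> verification -> annotation."""
    _check_reads(reads)
    if len(seed) < 100:
        raise ValueError("reconstruction seed must be >= 100 bp")
    read_pairs = reads.reads if hasattr(reads, "reads") else reads
    state, support, corrections, uncorrected = walker.reconstruct(
        seed, read_pairs, config.walk,
        apply_cpg_correction=apply_cpg_correction)
    verification = None
    if verify:
        verification = walker.verify_reconstruction(
            state.consensus, read_pairs, config.walk,
            rng_seed=config.rng_seed)
    annotation = ann.annotate(state.consensus)
    if outdir is not None:
        outdir = Path(outdir)
        config.snapshot(outdir)
        stamp = config.stamp()
        write_fasta([("reconstructed_consensus", state.consensus)],
                    outdir / "consensus.fa", header_comment=stamp)
        _write_support(support, outdir / "column_support.tsv", stamp,
                       full=review)
        with open(outdir / "cpg_corrections.tsv", "w") as fh:
            fh.write(f"# {stamp}\nposition\toriginal_dinucleotide\n")
            for pos, old in corrections:
                fh.write(f"{pos}\t{old}\n")
        with open(outdir / "verification.tsv", "w") as fh:
            fh.write(f"# {stamp}\n")
            if verification:
                fh.write(f"rerun_identity\t{verification.identity:.3f}\n"
                         f"rerun_length\t{verification.rerun_length}\n"
                         f"seed_interval\t{verification.seed_interval}\n"
                         f"low_support\t{verification.low_support_intervals}\n")
        _write_annotation(annotation, outdir / "annotation.tsv", stamp)
    return ReconstructionResult(state.consensus, uncorrected, state, support,
                                corrections, verification, annotation)


def _write_support(support: walker.ColumnSupport, path: Path, stamp: str,
                   full: bool = False) -> None:
    maj = support.majority_fraction()
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\ncolumn\tdepth\tA\tC\tG\tT\tgap"
                 "\tmajority_fraction\n")
        step = 1 if full else 1
        for i in range(0, len(support.coverage), step):
            a, c, g, t, gap = support.counts[i]
            fh.write(f"{i}\t{support.coverage[i]}\t{a}\t{c}\t{g}\t{t}\t{gap}"
                     f"\t{maj[i]:.3f}\n")


def _write_annotation(el: ann.AnnotatedElement, path: Path,
                      stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\nfeature\tstart\tend\tnote\n")

        def iv(x):
            return (x.start, x.end) if hasattr(x, "start") else x
        if el.orf1:
            fh.write(f"ORF1\t{el.orf1.start + 1}\t{el.orf1.end}\t"
                     f"{el.orf1.codons} codons\n")
        if el.igr:
            fh.write(f"IGR\t{el.igr[0] + 1}\t{el.igr[1]}\t"
                     f"{el.igr_length} bp\n")
        if el.orf2:
            fh.write(f"ORF2\t{el.orf2.start + 1}\t{el.orf2.end}\t"
                     f"{el.orf2.codons} codons\n")
        if el.alt_orf2_start is not None:
            elong = el.orf2.start - el.alt_orf2_start
            fh.write(f"alt_ORF2_start\t{el.alt_orf2_start + 1}\t"
                     f"{el.alt_orf2_start + 3}\t+{elong} bp\n")
        if el.a_content is not None:
            fh.write(f"A_content\t.\t.\t{el.a_content}%\n")
        for w in el.warnings:
            fh.write(f"warning\t.\t.\t{w}\n")
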