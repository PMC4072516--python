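"""Forward simulation of an L1 master lineage and its genomic graveyard.

The generative model mirrors how mammalian LINE-1 history is read from a
genome: a single *master* element drifts and successively spawns families;
each family deposits copies in bursts; every copy is 5'-truncated (the
reverse transcriptase usually fails to finish), then decays neutrally, with
methyl-CpG sites decaying an order of magnitude faster toward TG/CA; the
"genome" is finally shredded into ~2x shotgun reads.  Every locus carries
its ground truth (family, truncation point, realized divergence, strand) so
each analysis stage can be validated by parameter recovery.

Divergence bookkeeping: a burst's ``age`` is the *overall* expected per-site
substitution fraction of its copies.  The non-CpG per-site rate r is solved
from  f*min(m*r, cap) + (1-f)*r = age  (f = CpG fraction of the master,
m = cpg_rate_multiplier), so the mean observed divergence equals the burst
age regardless of the CpG setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import revcomp, write_fasta

_STOPS = {"TAA", "TAG", "TGA"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

_STAGE_MASTERS, _STAGE_DEPOSIT, _STAGE_READS = 11, 13, 17


@dataclass(frozen=True)
class FamilySpec:
    """One family in the lineage: its divergence from the previous master
    and its deposition bursts as (age, copy count) pairs."""

    spawn_divergence: float
    bursts: tuple[tuple[float, int], ...]

    def __post_init__(self):
        if not (0.0 <= self.spawn_divergence <= 0.75):
            raise ValueError(
                f"spawn_divergence {self.spawn_divergence} outside [0, 0.75]")
        ages = [a for a, _ in self.bursts]
        if any(not (0.0 <= a <= 0.75) for a in ages):
            raise ValueError("burst ages must lie in [0, 0.75]")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("burst ages must be strictly increasing")
        if any(n < 1 for _, n in self.bursts):
            raise ValueError("burst sizes must be >= 1")


def _coerce_schedule(schedule) -> tuple[FamilySpec, ...]:
    out = []
    for entry in schedule:
        if isinstance(entry, FamilySpec):
            out.append(entry)
        else:  # (spawn_divergence, burst_size, burst_age) triple
            d, n, a = entry
            out.append(FamilySpec(float(d), ((float(a), int(n)),)))
    return tuple(out)


@dataclass
class SimulationParams:
    """Knobs of the generative model.  Lengths in bases, rates as fractions."""

    master_length: int = 6000
    family_schedule: Sequence = field(
        default_factory=lambda: (FamilySpec(0.0, ((0.08, 500),)),))
    truncation_full_length_prob: float = 0.05
    truncation_mean_retained: int = 1200
    min_retained: int = 100
    cpg_rate_multiplier: float = 10.0
    cpg_density: float = 0.008          # planted CpG dinucleotides per base
    age_region_length: int = 575        # 3' window that defines copy age
    transition_bias: float = 4.0        # ts:tv odds at ordinary sites
    cpg_transition_bias: float = 19.0   # ts:tv odds at CpG sites (-> TG/CA)
    cpg_rate_cap: float = 0.95
    indel_rate: float = 0.0
    minus_strand_prob: float = 0.5
    read_length: int = 700
    coverage: float = 2.0
    background_a_content: float = 0.30
    master_a_content: float = 0.43      # L1 coding strands are A-rich
    utr5_length: int = 300
    orf1_codons: int = 338
    igr_length: int = 445
    utr3_length: int = 200
    polya_length: int = 30
    # an upstream in-frame ATG is absorbed into ORF2 by any longest-ORF
    # annotator, shortening the reported IGR; off by default so the
    # annotated architecture matches the construction
    plant_alt_orf2_start: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.master_length < 600:
            raise ValueError("master_length must be >= 600")
        if not self.family_schedule:
            raise ValueError("family_schedule must be non-empty")
        _coerce_schedule(self.family_schedule)
        for name in ("truncation_full_length_prob", "minus_strand_prob",
                     "background_a_content", "master_a_content"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.cpg_rate_multiplier < 1.0:
            raise ValueError("cpg_rate_multiplier must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length < 200:
            raise ValueError("read_length must be >= 200")


@dataclass
class MasterRecord:
    family_id: str
    sequence: str
    spawn_divergence: float
    annotation: dict  # orf1/igr/orf2/utr intervals, 0-based half-open


@dataclass
class SimulatedLocus:
    """A deposited copy with its ground truth."""

    locus_id: str
    sequence: str          # master orientation
    true_family: str
    true_master: str
    truncation_point: int  # offset from the master 5' end
    true_divergence: float
    strand: str


@dataclass
class TraceReadSet:
    """Shotgun-style reads plus full provenance for recovery tests."""

    reads: list[tuple[str, str]]
    provenance: dict[str, tuple[int, int, str]]  # read -> genome interval
    genome: str
    locus_coords: dict[str, tuple[int, int, str]]

    def to_fasta(self, path: str | Path, header_comment: str | None = None):
        write_fasta(self.reads, path, header_comment=header_comment)


def _rng(params: SimulationParams, stage: int) -> np.random.Generator:
    return np.random.default_rng([params.rng_seed, stage])


def _random_bases(rng, n: int, probs) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _base_probs(a_content: float) -> np.ndarray:
    rest = 1.0 - a_content
    return np.array([a_content, rest * 0.3, rest * 0.3, rest * 0.4])  # A,C,G,T


def _random_orf(rng, n_codons: int, probs) -> str:
    """ATG + (n-2) random non-stop codons + TAA."""
    codons = []
    while len(codons) < n_codons - 2:
        c = _random_bases(rng, 3, probs).tobytes().decode()
        if c not in _STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _inframe_stop_created(seq: list[str], pos: int, orf: tuple[int, int]) -> bool:
    s, e = orf
    if not (s <= pos < e):
        return False
    c0 = s + ((pos - s) // 3) * 3
    return "".join(seq[c0:c0 + 3]) in _STOPS


def make_master(params: SimulationParams,
                rng: np.random.Generator | None = None) -> MasterRecord:
    """Build the founding master with canonical L1 architecture.

    Layout: 5'UTR | ORF1 | IGR | ORF2 | 3'UTR | poly-A.  ORF2 absorbs the
    length budget left by the other segments.  CpG dinucleotides are planted
    at ``cpg_density`` and an in-frame alternative ORF2 start is placed 36 bp
    into the IGR when requested.
    """
    params.validate()
    if rng is None:
        rng = _rng(params, _STAGE_MASTERS)
    probs = _base_probs(params.master_a_content)
    L = params.master_length
    orf1_len = params.orf1_codons * 3
    fixed = (params.utr5_length + orf1_len + params.igr_length +
             params.utr3_length + params.polya_length)
    orf2_len = ((L - fixed) // 3) * 3
    if orf2_len < 300:
        raise ValueError("master_length too short for the requested segments")
    utr5 = _random_bases(rng, params.utr5_length, probs).tobytes().decode()
    orf1 = _random_orf(rng, params.orf1_codons, probs)
    igr = _random_bases(rng, params.igr_length, probs).tobytes().decode()
    orf2 = _random_orf(rng, orf2_len // 3, probs)
    utr3 = _random_bases(rng, params.utr3_length, probs).tobytes().decode()
    seq = list(utr5 + orf1 + igr + orf2 + utr3 + "A" * params.polya_length)

    orf1_iv = (params.utr5_length, params.utr5_length + orf1_len)
    igr_iv = (orf1_iv[1], orf1_iv[1] + params.igr_length)
    orf2_iv = (igr_iv[1], igr_iv[1] + orf2_len)
    utr3_iv = (orf2_iv[1], orf2_iv[1] + params.utr3_length)

    # plant CpG dinucleotides, skipping placements that would break an ORF
    n_cpg = int(round(params.cpg_density * L))
    planted = 0
    tries = 0
    while planted < n_cpg and tries < 50 * n_cpg:
        tries += 1
        i = int(rng.integers(1, utr3_iv[1] - 2))
        old = seq[i], seq[i + 1]
        seq[i], seq[i + 1] = "C", "G"
        bad = any(_inframe_stop_created(seq, p, orf)
                  for p in (i, i + 1) for orf in (orf1_iv, orf2_iv))
        if bad:
            seq[i], seq[i + 1] = old
        else:
            planted += 1

    if params.plant_alt_orf2_start and params.igr_length >= 45:
        # an in-frame ATG 36 bp upstream of ORF2, nothing in between
        start = orf2_iv[0] - 36
        seq[start:start + 3] = list("ATG")
        for p in range(start + 3, orf2_iv[0], 3):
            while "".join(seq[p:p + 3]) in _STOPS or "".join(seq[p:p + 3]) == "ATG":
                seq[p:p + 3] = list(
                    _random_bases(rng, 3, probs).tobytes().decode())

    ann = {"utr5": (0, orf1_iv[0]), "orf1": orf1_iv, "igr": igr_iv,
           "orf2": orf2_iv, "utr3": utr3_iv,
           "polya": (utr3_iv[1], utr3_iv[1] + params.polya_length)}
    return MasterRecord("F0", "".join(seq), 0.0, ann)


def query_region(master: MasterRecord, length: int = 575) -> str:
    """The 3'-end window of ORF2 used as the detection query."""
    _, e = master.annotation["orf2"]
    return master.sequence[e - length:e]


def cpg_site_mask(master_seq: str) -> np.ndarray:
    """Boolean mask flagging both bases of every CG dinucleotide."""
    arr = np.frombuffer(master_seq.encode(), dtype=np.uint8)
    mask = np.zeros(len(arr), dtype=bool)
    cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    mask[:-1] |= cg
    mask[1:] |= cg
    return mask


def _solve_rates(age: float, f_cpg: float, mult: float, cap: float
                 ) -> tuple[float, float]:
    """Per-site rates (non-CpG, CpG) whose mixture equals ``age``."""
    if age <= 0:
        return 0.0, 0.0
    r = age / (f_cpg * mult + (1.0 - f_cpg))
    if mult * r > cap:  # CpG channel saturated
        r = min(1.0, (age - f_cpg * cap) / (1.0 - f_cpg)) if f_cpg < 1 else 0.0
        return max(r, 0.0), cap
    return r, mult * r


def _mutate(seq: str, rate: np.ndarray, ts_frac: np.ndarray,
            rng: np.random.Generator,
            protect: np.ndarray | None = None,
            preserve_orfs: Sequence[tuple[int, int]] = ()) -> tuple[str, int]:
    """Per-site substitution; returns (sequence, substitution count)."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if protect is not None:
        hit &= ~protect
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return seq, 0
    ts = rng.random(len(idx)) < ts_frac[idx]
    coin = rng.integers(0, 2, size=len(idx))
    out = list(seq)
    for j, pos in enumerate(idx):
        base = seq[pos]
        if base not in _TRANSITION:
            continue
        new = _TRANSITION[base] if ts[j] else _TRANSVERSIONS[base][coin[j]]
        if preserve_orfs:
            old = out[pos]
            out[pos] = new
            if any(_inframe_stop_created(out, pos, orf) for orf in preserve_orfs):
                # redraw among the remaining alternatives; one is always safe
                for alt in "ACGT":
                    if alt in (base, new):
                        continue
                    out[pos] = alt
                    if not any(_inframe_stop_created(out, pos, orf)
                               for orf in preserve_orfs):
                        break
                else:
                    out[pos] = old
                    continue
        else:
            out[pos] = new
    n_sub = sum(1 for a, b in zip(seq, out) if a != b)
    return "".join(out), n_sub


def evolve_master_lineage(params: SimulationParams,
                          preserve_orfs: bool = True) -> list[MasterRecord]:
    """Chain of family masters, each drifted from its predecessor.

    Master i+1 differs from master i by the scheduled spawn divergence
    (binomial per-site sampling).  ORF reading frames are kept open and the
    poly-A tail untouched, since a master is by definition competent.
    """
    params.validate()
    schedule = _coerce_schedule(params.family_schedule)
    rng = _rng(params, _STAGE_MASTERS)
    founder = make_master(params, rng)
    masters: list[MasterRecord] = []
    prev_seq = founder.sequence
    protect = np.zeros(len(prev_seq), dtype=bool)
    pa0, pa1 = founder.annotation["polya"]
    protect[pa0:pa1] = True
    for (s, e) in (founder.annotation["orf1"], founder.annotation["orf2"]):
        protect[s:s + 3] = True      # start codon
        protect[e - 3:e] = True      # stop codon
    frames = ((founder.annotation["orf1"], founder.annotation["orf2"])
              if preserve_orfs else ())
    ts_frac = np.full(len(prev_seq),
                      params.transition_bias / (params.transition_bias + 1.0))
    for i, fam in enumerate(schedule):
        rate = np.full(len(prev_seq), fam.spawn_divergence)
        seq, _ = _mutate(prev_seq, rate, ts_frac, rng,
                         protect=protect, preserve_orfs=frames)
        masters.append(MasterRecord(f"F{i}", seq, fam.spawn_divergence,
                                    founder.annotation))
        prev_seq = seq
    return masters


def deposit_copies(masters: Sequence[MasterRecord],
                   params: SimulationParams) -> list[SimulatedLocus]:
    """Deposit 5'-truncated, neutrally decayed copies for every burst."""
    params.validate()
    schedule = _coerce_schedule(params.family_schedule)
    if len(masters) != len(schedule):
        raise ValueError("masters and family_schedule lengths differ")
    rng = _rng(params, _STAGE_DEPOSIT)
    loci: list[SimulatedLocus] = []
    counter = 0
    for master, fam in zip(masters, schedule):
        L = len(master.sequence)
        cpg = cpg_site_mask(master.sequence)
        # Copy age is read from identity within the 3' scan window, so the
        # burst age is delivered there exactly; CpG-density differences
        # between that window and the rest of the element make locus-wide
        # divergence fluctuate around the age by construction.
        oe = master.annotation["orf2"][1]
        lo = max(oe - params.age_region_length, 0)
        f_cpg = float(cpg[lo:oe].mean())
        for age, size in fam.bursts:
            r_non, r_cpg = _solve_rates(age, f_cpg, params.cpg_rate_multiplier,
                                        params.cpg_rate_cap)
            for _ in range(size):
                counter += 1
                if rng.random() < params.truncation_full_length_prob:
                    retained = L
                else:
                    retained = int(rng.geometric(
                        1.0 / params.truncation_mean_retained))
                    retained = min(max(retained, params.min_retained), L)
                start = L - retained
                sub = master.sequence[start:]
                rate = np.where(cpg[start:], r_cpg, r_non)
                ts = np.where(
                    cpg[start:],
                    params.cpg_transition_bias / (params.cpg_transition_bias + 1),
                    params.transition_bias / (params.transition_bias + 1))
                seq, n_sub = _mutate(sub, rate, ts, rng)
                if params.indel_rate > 0:
                    seq = _apply_indels(seq, params.indel_rate, rng)
                strand = "-" if rng.random() < params.minus_strand_prob else "+"
                loci.append(SimulatedLocus(
                    locus_id=f"L{counter:06d}", sequence=seq,
                    true_family=master.family_id,
                    true_master=master.sequence, truncation_point=start,
                    true_divergence=n_sub / retained, strand=strand))
    return loci


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    n = rng.binomial(len(seq), rate)
    out = list(seq)
    for _ in range(n):
        pos = int(rng.integers(0, len(out)))
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:
            del out[pos:pos + size]
        else:
            ins = _random_bases(rng, size, _base_probs(0.25)).tobytes().decode()
            out[pos:pos] = list(ins)
    return "".join(out)


def fragment_to_reads(loci: Sequence[SimulatedLocus], background_length: int,
                      params: SimulationParams) -> TraceReadSet:
    """Embed loci in an i.i.d. background and shred into ~coverage-fold reads."""
    params.validate()
    rng = _rng(params, _STAGE_READS)
    bg = _random_bases(rng, background_length,
                       _base_probs(params.background_a_content)
                       ).tobytes().decode()
    cuts = np.sort(rng.integers(0, background_length + 1, size=len(loci)))
    pieces, locus_coords = [], {}
    prev = 0
    offset = 0
    for locus, cut in zip(loci, cuts):
        pieces.append(bg[prev:cut])
        offset += cut - prev
        emb = locus.sequence if locus.strand == "+" else revcomp(locus.sequence)
        pieces.append(emb)
        locus_coords[locus.locus_id] = (offset, offset + len(emb), locus.strand)
        offset += len(emb)
        prev = cut
    pieces.append(bg[prev:])
    genome = "".join(pieces)

    G, rl = len(genome), params.read_length
    n_reads = int(round(params.coverage * G / rl))
    starts = rng.integers(0, max(G - rl, 1), size=n_reads)
    strands = rng.random(n_reads) < 0.5
    reads, provenance = [], {}
    for i, (s, minus) in enumerate(zip(starts, strands)):
        rid = f"read_{i + 1:06d}"
        frag = genome[s:s + rl]
        reads.append((rid, revcomp(frag) if minus else frag))
        provenance[rid] = (int(s), int(s) + len(frag), "-" if minus else "+")
    return TraceReadSet(reads, provenance, genome, locus_coords)


def simulate_genome(params: SimulationParams, background_length: int = 200_000
                    ) -> tuple[list[MasterRecord], list[SimulatedLocus],
                               TraceReadSet]:
    """Convenience: full chain masters -> loci -> reads."""
    masters = evolve_master_lineage(params)
    loci = deposit_copies(masters, params)
    reads = fragment_to_reads(loci, background_length, params)
    return masters, loci, reads


def write_ground_truth(loci: Sequence[SimulatedLocus],
                       readset: TraceReadSet, path: str | Path,
                       header_comment: str | None = None) -> None:
    """TSV of per-locus truth: family, truncation, divergence, strand, coords."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("locus_id\tfamily\ttruncation_point\tdivergence\tstrand"
                 "\tgenome_start\tgenome_end\n")
        for loc in loci:
            g0, g1, _ = readset.locus_coords[loc.locus_id]
            fh.write(f"{loc.locus_id}\t{loc.true_family}\t{loc.truncation_point}"
                     f"\t{loc.true_divergence:.6f}\t{loc.strand}\t{g0}\t{g1}\n")
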