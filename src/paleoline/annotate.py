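"""Annotation of a reconstructed element and construct-design utilities.

A canonical L1 carries two non-overlapping plus-strand reading frames:
ORF1 (nucleic-acid chaperone) and ORF2 (endonuclease + reverse
transcriptase), separated by an intergenic region (IGR) that is required
for ORF2 translation.  This module finds that architecture (two longest
non-overlapping ORFs), derives the IGR, measures A-content over
ORF1+IGR+ORF2, looks for an alternative in-frame ORF2 start inside the
IGR, and compares a focal protein against a multi-species alignment to
list private changes at otherwise conserved sites.  The construct
utilities (composition-preserving IGR shuffle; AUG->AGU knockout in all
three frames, sparing the ORF2 start) mirror standard reporter-assay
designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

_STOPS = {"TAA", "TAG", "TGA"}
MIN_ORF_CODONS = 100  # floor for a "qualifying" ORF in full annotation


@dataclass
class OrfInterval:
    start: int  # 0-based, at the A of ATG
    end: int    # half-open, past the stop codon

    @property
    def codons(self) -> int:
        return (self.end - self.start) // 3


@dataclass
class AnnotatedElement:
    sequence: str
    orf1: OrfInterval | None
    orf2: OrfInterval | None
    igr: tuple[int, int] | None      # [orf1.end, orf2.start)
    alt_orf2_start: int | None
    a_content: float | None          # percent over ORF1+IGR+ORF2
    igr_length: int | None
    warnings: list[str]


@dataclass
class ConservationReport:
    focal_taxon: str
    conserved_sites: list[int]                       # alignment columns
    private_changes: list[tuple[int, str, str]]      # (column, focal, others)

    @property
    def count(self) -> int:
        return len(self.private_changes)


def find_orfs(sequence: str, min_codons: int = 2) -> list[OrfInterval]:
    """All plus-strand ATG->stop spans (stop included), any frame."""
    seq = sequence.upper()
    out = []
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in _STOPS:
                for s in starts:
                    orf = OrfInterval(s, i + 3)
                    if orf.codons >= min_codons:
                        out.append(orf)
                starts = []
    return sorted(out, key=lambda o: (o.start, o.end))


def _two_longest_nonoverlapping(orfs: list[OrfInterval]
                                ) -> tuple[OrfInterval | None,
                                           OrfInterval | None]:
    """Greedy: longest ORF first (ties to the 5'-most start), then the
    longest that does not overlap it."""
    if not orfs:
        return None, None
    ranked = sorted(orfs, key=lambda o: (-o.codons, o.start))
    first = ranked[0]
    second = None
    for o in ranked[1:]:
        if o.end <= first.start or o.start >= first.end:
            second = o
            break
    if second is None:
        return first, None
    a, b = sorted([first, second], key=lambda o: o.start)
    return a, b


def a_content(region: str) -> float:
    """Percent A on the coding strand, to one decimal."""
    if not region:
        raise ValueError("empty region")
    return round(100.0 * region.upper().count("A") / len(region), 1)


def annotate(sequence: str, min_codons: int = MIN_ORF_CODONS
             ) -> AnnotatedElement:
    """Annotate ORF1/IGR/ORF2 on the plus strand.

    The two longest non-overlapping ORFs (by codon count) become ORF1 and
    ORF2 in positional order; A-content is computed over ORF1+IGR+ORF2.
    Inputs without two qualifying ORFs get a partial annotation plus a
    warning.
    """
    warnings = []
    orfs = find_orfs(sequence, min_codons=2)
    qualifying = [o for o in orfs if o.codons >= min_codons]
    pool = qualifying if len(qualifying) >= 2 else orfs
    if len(qualifying) < 2:
        warnings.append(
            f"fewer than 2 ORFs of >= {min_codons} codons; "
            "partial annotation")
    orf1, orf2 = _two_longest_nonoverlapping(pool)
    igr = alt = acont = igr_len = None
    if orf1 and orf2:
        igr = (orf1.end, orf2.start)
        igr_len = igr[1] - igr[0]
        region = sequence[orf1.start:orf1.end] + \
            sequence[igr[0]:igr[1]] + sequence[orf2.start:orf2.end]
        acont = a_content(region)
        element = AnnotatedElement(sequence, orf1, orf2, igr, None, acont,
                                   igr_len, warnings)
        element.alt_orf2_start = alt_orf2_start(element)
        return element
    if orf1 and not orf2:
        acont = a_content(sequence[orf1.start:orf1.end])
    return AnnotatedElement(sequence, orf1, orf2, igr, alt, acont, igr_len,
                            warnings)


def alt_orf2_start(element: AnnotatedElement) -> int | None:
    """Nearest in-frame ATG within the IGR upstream of ORF2, with no
    intervening in-frame stop; None when absent."""
    if element.orf2 is None or element.igr is None:
        return None
    seq = element.sequence.upper()
    igr_start, orf2_start = element.igr[0], element.orf2.start
    pos = orf2_start - 3
    while pos >= igr_start:
        codon = seq[pos:pos + 3]
        if codon in _STOPS:
            return None
        if codon == "ATG":
            return pos
        pos -= 3
    return None


def alt_orf2_elongation(element: AnnotatedElement) -> int | None:
    """How many bases longer ORF2 becomes from its alternative start."""
    alt = element.alt_orf2_start
    if alt is None and element.orf2 is not None:
        alt = alt_orf2_start(element)
    return None if alt is None else element.orf2.start - alt


def private_changes(protein_alignment: Sequence[tuple[str, str]],
                    focal_taxon: str) -> ConservationReport:
    """Focal-taxon changes at sites conserved across all other taxa.

    Conserved sites are columns with exactly one residue among the
    non-focal taxa; columns with any non-focal gap are not conserved.
    A private change is a conserved column where the focal residue
    (non-gap) differs.
    """
    names = [n for n, _ in protein_alignment]
    if focal_taxon not in names:
        raise ValueError(f"focal taxon {focal_taxon!r} absent from alignment")
    others = [(n, s.upper()) for n, s in protein_alignment
              if n != focal_taxon]
    if len(others) < 3:
        raise ValueError("alignment needs >= 3 non-focal taxa")
    focal = dict((n, s.upper()) for n, s in protein_alignment)[focal_taxon]
    L = len(focal)
    if any(len(s) != L for _, s in others):
        raise ValueError("alignment rows have unequal lengths")
    conserved, changes = [], []
    for col in range(L):
        residues = {s[col] for _, s in others}
        if len(residues) != 1 or "-" in residues:
            continue
        conserved.append(col)
        ref = residues.pop()
        if focal[col] != ref and focal[col] != "-":
            changes.append((col, focal[col], ref))
    return ConservationReport(focal_taxon, conserved, changes)


def alignment_column_to_residue(aligned_seq: str, column: int,
                                offset: int = 1) -> int:
    """Residue number (default 1-based) of an alignment column in one row."""
    if aligned_seq[column] == "-":
        raise ValueError("column is a gap in this row")
    return sum(1 for c in aligned_seq[:column + 1] if c != "-") + offset - 1


def shuffle_igr(igr: str, rng_seed: int) -> str:
    """Uniform permutation of the IGR; length and composition preserved."""
    if not igr:
        raise ValueError("empty IGR")
    rng = np.random.default_rng(rng_seed)
    arr = np.array(list(igr))
    return "".join(rng.permutation(arr))


def remove_aug(igr: str, protect_suffix: int = 0) -> str:
    """Mutate every ATG at any offset to AGT, iterating to a fixed point.

    The final ``protect_suffix`` bases (e.g. the ORF2 start context) are
    left untouched.
    """
    seq = list(igr.upper())
    limit = len(seq) - protect_suffix
    changed = True
    while changed:
        changed = False
        for i in range(0, max(limit - 2, 0)):
            if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
                seq[i + 1], seq[i + 2] = "G", "T"
                changed = True
    return "".join(seq)
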