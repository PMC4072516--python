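"""Small nucleotide-sequence helpers shared across the pipeline."""

from __future__ import annotations

import math
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "ACGT"
IUPAC = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_iupac(seq: str, name: str = "sequence") -> None:
    bad = set(seq.upper()) - IUPAC
    if bad:
        raise ValueError(
            f"{name} contains non-IUPAC characters: {sorted(bad)}"
        )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercase sequence) pairs.

    Uses the Pearson dialect so the ';'-style provenance comments this
    package writes are accepted.
    """
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta-pearson")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                header_comment: str | None = None) -> None:
    """Write (id, seq) pairs as 70-column wrapped FASTA.

    ``header_comment`` is emitted as a leading ``;`` comment line so every
    output file carries its provenance (seed, config hash).
    """
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f";{header_comment}\n")
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def iter_fasta(path: str | Path) -> Iterator[SeqRecord]:
    return SeqIO.parse(str(path), "fasta-pearson")


def seq_from_genbank(path: str | Path) -> str:
    """Sequence (only) from a GenBank flatfile."""
    rec = next(SeqIO.parse(str(path), "genbank"))
    return str(rec.seq).upper()


def shannon_entropy(seq: str) -> float:
    """Base-2 entropy of the mononucleotide composition (0..2 bits)."""
    if not seq:
        return 0.0
    counts = Counter(seq.upper())
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def longest_run(seq: str, base: str) -> int:
    best = cur = 0
    for ch in seq:
        cur = cur + 1 if ch == base else 0
        best = max(best, cur)
    return best


def as_record(name: str, seq: str) -> SeqRecord:
    return SeqRecord(Seq(seq), id=name, description="")
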