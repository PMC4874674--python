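"""Sequence I/O, translation, pairwise identity and paralog assignment.

Conventions used throughout the package: nucleotide sequences are uppercase
strings over ``{A, C, G, T, N}``; all residue and codon indices in reports are
1-based with closed intervals; stop codons are written ``*`` and codons
containing ``N`` translate to ``X``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO, Align
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "GeneticCode",
    "STANDARD_CODE",
    "PairwiseAlignment",
    "read_fasta",
    "write_fasta",
    "translate",
    "reverse_complement",
    "global_align",
    "classify_paralog",
    "identity_table_tsv",
]

_VALID_NT = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A single nucleotide sequence with its FASTA header."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _VALID_NT
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and whitespace-stripped; record order is
    preserved.  Empty files, duplicate ids and non-nucleotide characters
    (other than ``N``) raise ``ValueError`` naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id, seq=str(rec.seq).upper(), description=rec.description
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path) -> None:
    """Write records as multi-FASTA, wrapped at 60 columns."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecs)


class GeneticCode:
    """The standard genetic code as an explicit 64-codon lookup table."""

    def __init__(self, table_id: int = 1):
        bio = CodonTable.unambiguous_dna_by_id[table_id]
        self.id = table_id
        self.table: dict[str, str] = dict(bio.forward_table)
        for stop in bio.stop_codons:
            self.table[stop] = "*"
        if len(self.table) != 64:
            raise ValueError("genetic code table must have 64 entries")
        self.stop_codons = tuple(sorted(bio.stop_codons))

    def __call__(self, codon: str) -> str:
        codon = codon.upper()
        if len(codon) != 3:
            raise ValueError(f"not a codon: {codon!r}")
        if "N" in codon or codon not in self.table:
            return "X"
        return self.table[codon]


STANDARD_CODE = GeneticCode()


def translate(seq: str, frame: int = 0, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate ``seq`` in the given frame; stops are ``*``, N-codons ``X``.

    The trailing partial codon, if any, is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame!r}")
    if len(seq) - frame < 3:
        raise ValueError("sequence shorter than one codon in this frame")
    seq = seq.upper()
    n = (len(seq) - frame) // 3
    return "".join(code(seq[frame + 3 * i : frame + 3 * i + 3]) for i in range(n))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment with affine gap costs."""

    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        cols = matches = 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" and y == "-":
                continue
            cols += 1
            # X marks translation ambiguity and never counts as a match
            if x == y and x != "X":
                matches += 1
        object.__setattr__(
            self, "percent_identity", matches / cols if cols else 0.0
        )

    def ungapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Needleman–Wunsch global alignment with affine gap penalties."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(
        aligned_a=str(aln[0]), aligned_b=str(aln[1]), score=float(aln.score)
    )


def classify_paralog(query: SequenceRecord, refs: list[SequenceRecord], **scoring):
    """Assign a query amplicon to the best-matching labelled reference.

    Mirrors the usual practice of naming an amplicon after its top genome
    alignment hit (e.g. a short product hitting PRDM7 at higher identity than
    PRDM9).  Returns ``(label, percent_identity, table)`` where ``table`` is a
    list of ``(label, percent_identity, score)`` in input reference order.
    Ties on identity are broken by input order.
    """
    if not refs:
        raise ValueError("classify_paralog requires at least one reference")
    if not query.seq:
        raise ValueError("empty query")
    table = []
    for ref in refs:
        aln = global_align(query.seq, ref.seq, **scoring)
        table.append((ref.id, aln.percent_identity, aln.score))
    best = max(table, key=lambda row: row[1])
    return best[0], best[1], table


def identity_table_tsv(query_id: str, table) -> str:
    """Render a classify_paralog identity table as TSV."""
    lines = ["query\tref\tidentity\tscore"]
    for label, ident, score in table:
        lines.append(f"{query_id}\t{label}\t{ident:.6f}\t{score:g}")
    return "\n".join(lines) + "\n"
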