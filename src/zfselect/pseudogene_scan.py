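"""Disruptive-mutation scan for pseudogenized zinc-finger regions.

A PRDM7-like paralog carries the same 84-bp repeat structure as its parent
gene but is disabled by premature stop codons and frameshifts.  This module
reports, per sequence, the reading frame, every in-frame stop, the number of
residues preceding the first stop ("after N residues" semantics: residues
strictly before the stop), and indels relative to a repeat consensus whose
lengths are not multiples of three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .seq_io import translate
from .zf_decompose import C2H2_RE

__all__ = [
    "DisruptionReport",
    "scan_orf",
    "detect_frameshift",
    "disruption_table",
]


@dataclass
class DisruptionReport:
    """Frame-wise stop-codon and frameshift findings for one sequence."""

    record_id: str
    frame: int
    stop_codon_indices: list[int]  # 1-based codon positions
    n_codons: int
    frameshift_flags: list[tuple[int, int]] = field(default_factory=list)
    low_confidence: bool = False

    @property
    def n_stops(self) -> int:
        return len(self.stop_codon_indices)

    @property
    def residues_before_first_stop(self) -> int:
        """Residues strictly preceding the first stop (full length if none)."""
        if not self.stop_codon_indices:
            return self.n_codons
        return min(self.stop_codon_indices) - 1

    @property
    def classification(self) -> str:
        premature = [i for i in self.stop_codon_indices if i < self.n_codons - 1]
        # stops in the final two codons are ordinary terminators
        disrupted = bool(premature) or bool(self.frameshift_flags)
        return "disrupted" if disrupted else "functional"


def _stops_in_frame(seq: str, frame: int) -> tuple[list[int], int]:
    aa = translate(seq, frame)
    return [i + 1 for i, ch in enumerate(aa) if ch == "*"], len(aa)


def scan_orf(seq: str, frame="auto", record_id: str = "") -> DisruptionReport:
    """Scan one sequence for premature stop codons.

    ``frame='auto'`` picks the frame minimizing the stop count; ties go to
    the frame with more C2H2 motif matches, then the lowest frame.  If every
    frame averages more than one stop per ten codons the report is flagged
    low-confidence.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if frame == "auto":
        candidates = []
        for f in (0, 1, 2):
            if len(seq) - f < 3:
                continue
            stops, n = _stops_in_frame(seq, f)
            motifs = len(C2H2_RE.findall(translate(seq, f)))
            candidates.append((len(stops), -motifs, f, stops, n))
        candidates.sort()
        _, _, frame, stops, n = candidates[0]
        low_conf = all(c[0] * 10 > c[4] for c in candidates)
    else:
        if frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1, 2 or 'auto', got {frame!r}")
        stops, n = _stops_in_frame(seq, frame)
        low_conf = len(stops) * 10 > n
    if low_conf:
        warnings.warn(
            f"{record_id or 'sequence'}: stop-ridden in every frame; low confidence"
        )
    return DisruptionReport(
        record_id=record_id,
        frame=frame,
        stop_codon_indices=stops,
        n_codons=n,
        low_confidence=low_conf,
    )


def detect_frameshift(seq: str, consensus_unit: str, record_id: str = ""):
    """Find out-of-frame indels relative to tandem copies of a repeat unit.

    ``seq`` is aligned locally (affine gap costs) against enough concatenated
    copies of ``consensus_unit`` to cover it, so flanking non-repeat context
    is clipped rather than forced into gaps.  Indel runs whose net length is
    not a multiple of 3 are returned as ``(1-based nt position in seq,
    signed offset)`` — positive for bases the sequence gained, negative for
    bases it lost.  Alignments under 50% identity are declined with a
    warning (returns None).
    """
    if len(consensus_unit) != 84:
        raise ValueError("consensus unit must be 84 nt")
    n_copies = max(2, -(-len(seq) // 84) + 1)
    target = consensus_unit * n_copies
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq, target)[0]
    blocks_q, blocks_t = aln.aligned  # matched block coordinates
    matches = cols = 0
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        cols += qe - qs
        matches += sum(a == b for a, b in zip(seq[qs:qe], target[ts:te]))
    if cols == 0 or matches / cols < 0.5:
        warnings.warn(
            f"{record_id or 'sequence'}: alignment identity below 50%; "
            "no frameshift call"
        )
        return None
    flags = []
    for k in range(1, len(blocks_q)):
        dq = int(blocks_q[k][0] - blocks_q[k - 1][1])  # bases seq gained
        dt = int(blocks_t[k][0] - blocks_t[k - 1][1])  # bases seq lost
        net = dq - dt
        if net % 3 != 0:
            flags.append((int(blocks_q[k - 1][1]) + 1, net))
    return flags


def disruption_table(reports: list[DisruptionReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "record_id": r.record_id,
                "frame": r.frame,
                "n_stops": r.n_stops,
                "first_stop_codon": (
                    min(r.stop_codon_indices) if r.stop_codon_indices else None
                ),
                "residues_before_first_stop": r.residues_before_first_stop,
                "frameshifts": ";".join(f"{p}:{o:+d}" for p, o in r.frameshift_flags),
                "classification": r.classification,
            }
        )
    return pd.DataFrame(rows)
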