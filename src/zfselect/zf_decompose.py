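"""Segmentation of C2H2 zinc-finger minisatellite amplicons.

A PRDM9-style amplicon carries one conserved 23-aa leading finger followed,
after a short spacer, by a tandem array of 84-nt (28-aa) C2H2 units.  The
C2H2 motif is ``C-x2-C-x12-H-x(3..5)-H``; DNA-binding specificity is set by
the residues at helix positions −9, −5, −2, −1, 2, 3 and 6 relative to the
recognition helix (position 1; there is no position 0).

All indices reported by this module are 1-based and intervals are closed.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, asdict

import pandas as pd

from .seq_io import translate

__all__ = [
    "NotAZFArrayError",
    "MalformedUnitError",
    "SegmentConfig",
    "ZincFingerUnit",
    "ZFArray",
    "C2H2_RE",
    "CONTACT_POSITIONS",
    "find_c2h2_anchors",
    "contact_residues_from_helix",
    "contact_residues",
    "segment_array",
    "assign_allele_label",
    "allele_to_n_fingers",
    "infer_allele_from_amplicon_length",
    "decomposition_table",
    "array_to_json",
]

# Strict array-unit motif: Cys2-Cys1 = 3, His1-Cys2 = 13, His2-His1 in 4..6.
# Lazy His2 quantifier: the nearest His closes the finger (His-rich context
# downstream must not stretch the motif and shift the unit phase).
C2H2_RE = re.compile(r"(?=(C..C.{12}H(.{3,5}?)H))")
# Permissive anchor finder for canonical fingers outside PRDM9 arrays
# (e.g. Zif268 finger 1 is C-x4-C).
C2H2_LOOSE_RE = re.compile(r"(?=(C(.{2,4}?)C.{12}H(.{3,5}?)H))")

CONTACT_POSITIONS = (-9, -5, -2, -1, 2, 3, 6)

UNIT_AA = 28
UNIT_NT = 84
LEAD_AA = 23


class NotAZFArrayError(ValueError):
    """Raised when no C2H2 motif is found in any reading frame."""


class MalformedUnitError(ValueError):
    """Raised when a contact-residue index falls outside the 28-aa unit."""


@dataclass(frozen=True)
class SegmentConfig:
    """Tunable segmentation parameters.

    ``preferred_cys1_offset`` fixes the unit phase: the 0-based position of
    Cys1 inside each 28-aa window (7 puts the canonical TGEKPYx linker at the
    unit start).  When the flanks cannot accommodate it the nearest feasible
    phase is used.
    """

    preferred_cys1_offset: int = 7
    unit_aa: int = UNIT_AA
    lead_aa: int = LEAD_AA


@dataclass(frozen=True)
class ZincFingerUnit:
    """One 84-nt / 28-aa tandem unit with its C2H2 anchors (1-based)."""

    index: int
    nt: str
    aa: str
    anchors: tuple[int, int, int, int]  # Cys1, Cys2, His1, His2

    def __post_init__(self) -> None:
        if len(self.nt) != UNIT_NT or len(self.aa) != UNIT_AA:
            raise MalformedUnitError(
                f"unit {self.index}: expected {UNIT_NT} nt / {UNIT_AA} aa, "
                f"got {len(self.nt)} nt / {len(self.aa)} aa"
            )
        c1, c2, h1, h2 = self.anchors
        if c2 - c1 != 3 or h1 - c2 != 13 or h2 - h1 not in (4, 5, 6):
            raise MalformedUnitError(
                f"unit {self.index}: anchors {self.anchors} violate C2H2 spacing"
            )

    @property
    def contacts(self) -> dict[int, str]:
        return contact_residues(self)


@dataclass
class ZFArray:
    """A decomposed amplicon: flanks + leading finger + tandem units."""

    record_id: str
    species: str
    leading_finger_nt: str
    leading_finger_aa: str
    spacer_nt: str
    units: list[ZincFingerUnit]
    upstream_flank: str
    downstream_flank: str
    frame: int = 0
    partial: bool = False  # tandem block interrupted mid-array

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def allele(self) -> str:
        return assign_allele_label(self.n_units)

    def reconstruct(self) -> str:
        return (
            self.upstream_flank
            + self.leading_finger_nt
            + self.spacer_nt
            + "".join(u.nt for u in self.units)
            + self.downstream_flank
        )


def find_c2h2_anchors(aa: str, loose: bool = False) -> list[tuple[int, int, int, int]]:
    """All (overlapping) C2H2 anchor quadruples in ``aa``, 0-based."""
    out = []
    pattern = C2H2_LOOSE_RE if loose else C2H2_RE
    for m in pattern.finditer(aa):
        motif = m.group(1)
        c1 = m.start()
        c2 = c1 + motif.index("C", 1)
        h1 = c2 + 13
        # His2 is the last residue of the motif
        h2 = c1 + len(motif) - 1
        out.append((c1, c2, h1, h2))
    return out


def contact_residues_from_helix(aa: str, his1: int) -> dict[int, str]:
    """DNA-contact residues given the 1-based His1 position in ``aa``.

    Helix position 1 sits six residues before His1, so position k maps to
    ``aa[his1 - (7 - k)]`` for k >= 1 and ``aa[his1 - (6 - k)]`` for k <= -1
    (1-based; there is no position 0).
    """
    out: dict[int, str] = {}
    for k in CONTACT_POSITIONS:
        idx = his1 - (7 - k) if k >= 1 else his1 - (6 - k)
        if not 1 <= idx <= len(aa):
            raise MalformedUnitError(
                f"contact position {k} maps to residue {idx}, outside 1..{len(aa)}"
            )
        out[k] = aa[idx - 1]
    return out


def contact_residues(unit: ZincFingerUnit) -> dict[int, str]:
    """Contact residues {−9, −5, −2, −1, 2, 3, 6} of one unit."""
    return contact_residues_from_helix(unit.aa, unit.anchors[2])


def _longest_run(anchors: list[int], step: int) -> list[int]:
    """Longest arithmetic run with the given step; earliest run on ties."""
    anchor_set = set(anchors)
    best_start, best_len = None, 0
    for p in anchors:
        if p - step in anchor_set:
            continue  # not a run start
        q, n = p, 1
        while q + step in anchor_set:
            q += step
            n += 1
        if n > best_len:
            best_start, best_len = p, n
    return [best_start + i * step for i in range(best_len)]


def segment_array(seq: str, record_id: str = "", species: str = "",
                  config: SegmentConfig = SegmentConfig()) -> ZFArray:
    """Decompose an amplicon into leading finger + tandem 84-nt units.

    The reading frame maximizing the count of C2H2 motifs is chosen (ties go
    to the lowest frame).  The tandem block is the maximal run of motif
    anchors spaced exactly 28 aa apart; the first motif-bearing window before
    the block provides the 23-aa leading finger.  Anything else goes to the
    flanks; re-concatenation of the parts is byte-exact.
    """
    seq = seq.upper()
    counts = []
    for frame in (0, 1, 2):
        if len(seq) - frame < 3:
            counts.append(0)
            continue
        # non-overlapping motif count for frame selection
        counts.append(_nonoverlap_count(translate(seq, frame)))
    frame = max(range(3), key=lambda f: (counts[f], -f))
    if counts[frame] == 0:
        raise NotAZFArrayError(f"{record_id or 'sequence'}: no C2H2 motif in any frame")
    aa = translate(seq, frame)
    anchors4 = find_c2h2_anchors(aa)
    cys1s = [a[0] for a in anchors4]
    span = {a[0]: a[3] - a[0] + 1 for a in anchors4}  # Cys1..His2 inclusive

    block = _longest_run(cys1s, config.unit_aa)
    if not block:
        raise NotAZFArrayError(f"{record_id or 'sequence'}: no tandem block found")
    p1 = block[0]
    n_units = len(block)

    partial = any(
        q > block[-1] and (q - p1) % config.unit_aa == 0 for q in cys1s
    ) or any(
        q < p1 and (p1 - q) % config.unit_aa == 0 and q not in block for q in cys1s
    )

    # leading finger: first anchor strictly before the block
    lead = next((a for a in anchors4 if a[0] < p1 and a[0] not in block), None)
    if lead is not None:
        lead_end = lead[3]  # His2, 0-based; finger = 23 aa ending at His2
        lead_start = lead_end - (config.lead_aa - 1)
        if lead_start < 0:
            lead_start, lead_end = 0, config.lead_aa - 1
    else:
        lead_start = lead_end = None

    # unit phase: Cys1 offset within window, as close to preferred as feasible
    span_max = max(span[p] for p in block)
    lo = max(0, p1 + config.unit_aa * n_units - len(aa))
    hi = min(config.unit_aa - span_max, p1 - ((lead_end + 1) if lead else 0))
    if hi < lo:
        raise NotAZFArrayError(
            f"{record_id or 'sequence'}: tandem block does not fit the sequence"
        )
    delta = min(max(config.preferred_cys1_offset, lo), hi)
    s = p1 - delta  # 0-based aa start of the tandem block

    units = []
    for i in range(n_units):
        a0 = s + i * config.unit_aa
        unit_aa = aa[a0 : a0 + config.unit_aa]
        unit_nt = seq[frame + 3 * a0 : frame + 3 * (a0 + config.unit_aa)]
        c1 = block[i] - a0
        m = next(
            (a for a in anchors4 if a[0] == block[i]),
            None,
        )
        anchors = (c1 + 1, m[1] - a0 + 1, m[2] - a0 + 1, m[3] - a0 + 1)
        units.append(ZincFingerUnit(index=i + 1, nt=unit_nt, aa=unit_aa, anchors=anchors))

    if lead is not None:
        up = seq[: frame + 3 * lead_start]
        lead_nt = seq[frame + 3 * lead_start : frame + 3 * (lead_end + 1)]
        lead_aa_str = aa[lead_start : lead_end + 1]
        spacer = seq[frame + 3 * (lead_end + 1) : frame + 3 * s]
    else:
        up = seq[: frame + 3 * s]
        lead_nt, lead_aa_str, spacer = "", "", ""
        warnings.warn(f"{record_id or 'sequence'}: no conserved leading finger found")
    down = seq[frame + 3 * (s + config.unit_aa * n_units) :]

    arr = ZFArray(
        record_id=record_id,
        species=species,
        leading_finger_nt=lead_nt,
        leading_finger_aa=lead_aa_str,
        spacer_nt=spacer,
        units=units,
        upstream_flank=up,
        downstream_flank=down,
        frame=frame,
        partial=partial,
    )
    if partial:
        warnings.warn(
            f"{record_id or 'sequence'}: tandem block interrupted mid-array; "
            "partial decomposition"
        )
    assert arr.reconstruct() == seq
    return arr


def _nonoverlap_count(aa: str) -> int:
    count = pos = 0
    while True:
        m = C2H2_RE.search(aa, pos)
        if not m:
            return count
        count += 1
        pos = m.start() + len(m.group(1))


_ALLELE_BASE_N = 6  # allele A has 6 fingers; one letter per added repeat


def assign_allele_label(n_fingers: int) -> str:
    """Length-allele letter: 6→A, 7→B, ..., 12→G; outside flagged."""
    if n_fingers < _ALLELE_BASE_N:
        warnings.warn(f"{n_fingers} fingers is below the A–G catalogue")
        return "A" + "-" * (_ALLELE_BASE_N - n_fingers)
    label = chr(ord("A") + n_fingers - _ALLELE_BASE_N)
    if n_fingers > 12:
        warnings.warn(f"{n_fingers} fingers is above the A–G catalogue ({label})")
    return label


def allele_to_n_fingers(letter: str) -> int:
    if len(letter) != 1 or not "A" <= letter <= "Z":
        raise ValueError(f"not an allele letter: {letter!r}")
    return _ALLELE_BASE_N + ord(letter) - ord("A")


def infer_allele_from_amplicon_length(
    length_bp: int, calibration: tuple[str, int]
) -> tuple[str, int]:
    """Call a length allele from amplicon size via the 84-bp repeat ladder.

    ``calibration`` is ``(known allele letter, its amplicon length in bp)``.
    Returns ``(allele letter, residual bp)``; residuals beyond ±10 bp warn of
    an ambiguous genotype.
    """
    known_letter, known_len = calibration
    known_n = allele_to_n_fingers(known_letter)
    n = known_n + round((length_bp - known_len) / UNIT_NT)
    residual = length_bp - (known_len + (n - known_n) * UNIT_NT)
    if abs(residual) > 10:
        warnings.warn(
            f"amplicon length {length_bp} bp is {residual:+d} bp off the repeat "
            "ladder; ambiguous genotype"
        )
    return assign_allele_label(n), residual


def decomposition_table(arrays: list[ZFArray]) -> pd.DataFrame:
    """Long-format per-unit table (one row per tandem unit)."""
    rows = []
    for arr in arrays:
        for u in arr.units:
            row = {
                "record_id": arr.record_id,
                "species": arr.species,
                "n_units": arr.n_units,
                "allele": arr.allele,
                "unit_index": u.index,
                "unit_aa": u.aa,
            }
            row.update({f"pos{k}": v for k, v in u.contacts.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def array_to_json(arr: ZFArray) -> str:
    d = {
        "record_id": arr.record_id,
        "species": arr.species,
        "frame": arr.frame,
        "coordinate_convention": "1-based, closed intervals",
        "n_units": arr.n_units,
        "allele": arr.allele,
        "partial": arr.partial,
        "leading_finger_aa": arr.leading_finger_aa,
        "units": [
            {
                "index": u.index,
                "aa": u.aa,
                "anchors": {
                    "Cys1": u.anchors[0],
                    "Cys2": u.anchors[1],
                    "His1": u.anchors[2],
                    "His2": u.anchors[3],
                },
                "contacts": {str(k): v for k, v in u.contacts.items()},
            }
            for u in arr.units
        ],
    }
    return json.dumps(d, indent=2)
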