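"""Catalogue of distinct 28-aa zinc-finger domains and panel summaries.

Domains are deduplicated on exact amino-acid identity, so synonymous
nucleotide changes collapse onto one code (a nucleotide-level mode is
available for minisatellite "DNA allele" style analyses).  Codes are small
integers assigned in order of first appearance, with the input sorted by
(species, record id) by default so catalogues are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .zf_decompose import ZFArray, CONTACT_POSITIONS

__all__ = [
    "DomainCatalog",
    "GenotypeRecord",
    "build_catalog",
    "array_schematic",
    "cross_species_stats",
    "genotype_summary",
]


@dataclass
class DomainCatalog:
    """Deduplicated domain sequences with integer codes (1..K)."""

    entries: list[tuple[int, str]]  # (code, 28-aa or 84-nt string)
    occurrence: dict[tuple[int, str], int]  # (code, species) -> unit count
    provenance: list[tuple[str, int, int]]  # (record_id, unit_index, code)
    level: str = "aa"  # "aa" (protein identity) or "nt"

    @property
    def size(self) -> int:
        return len(self.entries)

    def code_of(self, seq: str) -> int:
        try:
            return self._index[seq]
        except AttributeError:
            self._index = {s: c for c, s in self.entries}
            return self._index[seq]

    def species_of(self, code: int) -> set[str]:
        return {sp for (c, sp), n in self.occurrence.items() if c == code and n > 0}

    def species(self) -> list[str]:
        return sorted({sp for (_, sp) in self.occurrence})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code, seq in self.entries:
            sps = sorted(self.species_of(code))
            rows.append(
                {
                    "code": code,
                    "seq": seq,
                    "species": ",".join(sps),
                    "count": sum(
                        n for (c, _), n in self.occurrence.items() if c == code
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GenotypeRecord:
    """One diploid animal typed by its pair of length-allele letters."""

    animal_id: str
    species: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def genotype(self) -> str:
        return "".join(self.alleles)

    @property
    def heterozygous(self) -> bool:
        return self.alleles[0] != self.alleles[1]

    @property
    def in_catalogue(self) -> bool:
        return all(len(a) == 1 and "A" <= a <= "G" for a in self.alleles)


def build_catalog(arrays: list[ZFArray], level: str = "aa",
                  sort_input: bool = True) -> DomainCatalog:
    """Deduplicate tandem units across arrays into a coded catalogue.

    Leading fingers are excluded.  Codes follow first appearance after
    sorting arrays by (species, record_id); pass ``sort_input=False`` to
    keep caller order.
    """
    if level not in ("aa", "nt"):
        raise ValueError(f"level must be 'aa' or 'nt', got {level!r}")
    ordered = (
        sorted(arrays, key=lambda a: (a.species, a.record_id)) if sort_input
        else list(arrays)
    )
    entries: list[tuple[int, str]] = []
    index: dict[str, int] = {}
    occurrence: dict[tuple[int, str], int] = {}
    provenance: list[tuple[str, int, int]] = []
    for arr in ordered:
        for u in arr.units:
            key = u.aa if level == "aa" else u.nt
            if len(key) != (28 if level == "aa" else 84):
                raise ValueError(
                    f"{arr.record_id} unit {u.index}: wrong unit length {len(key)}"
                )
            code = index.get(key)
            if code is None:
                code = len(entries) + 1
                entries.append((code, key))
                index[key] = code
            occurrence[(code, arr.species)] = occurrence.get((code, arr.species), 0) + 1
            provenance.append((arr.record_id, u.index, code))
    return DomainCatalog(entries, occurrence, provenance, level)


def array_schematic(arr: ZFArray, catalog: DomainCatalog):
    """Ordered catalogue codes of one array plus its repeated-domain multiset."""
    codes = []
    for u in arr.units:
        key = u.aa if catalog.level == "aa" else u.nt
        try:
            codes.append(catalog.code_of(key))
        except KeyError:
            raise KeyError(
                f"{arr.record_id} unit {u.index}: domain not in catalogue"
            ) from None
    repeated = {c: codes.count(c) for c in set(codes) if codes.count(c) >= 2}
    return codes, repeated


def cross_species_stats(catalog: DomainCatalog):
    """Shared domains, per-species unique counts, and positional diversity.

    Returns ``(shared, unique_counts, diversity)`` where ``shared`` lists
    ``(code, sorted species)`` for domains seen in >= 2 species,
    ``unique_counts`` maps species -> number of domains private to it, and
    ``diversity`` maps each contact position to the number of distinct amino
    acids observed there across catalogue entries.
    """
    if len(catalog.species()) < 2:
        raise ValueError("cross-species statistics need >= 2 species")
    shared = []
    unique_counts = {sp: 0 for sp in catalog.species()}
    for code, _ in catalog.entries:
        sps = sorted(catalog.species_of(code))
        if len(sps) >= 2:
            shared.append((code, sps))
        elif len(sps) == 1:
            unique_counts[sps[0]] += 1
    diversity = {}
    if catalog.level == "aa":
        from .zf_decompose import contact_residues_from_helix, find_c2h2_anchors

        for k in CONTACT_POSITIONS:
            residues = set()
            for _, aa in catalog.entries:
                anchors = find_c2h2_anchors(aa)
                if not anchors:
                    continue
                his1 = anchors[0][2] + 1
                residues.add(contact_residues_from_helix(aa, his1)[k])
            diversity[k] = len(residues)
    return shared, unique_counts, diversity


def genotype_summary(records: list[GenotypeRecord]) -> pd.DataFrame:
    """Per-species genotype counts and heterozygosity.

    One row per species with one column per observed genotype class, the
    panel size, and heterozygosity as an exact fraction and a percentage.
    Genotypes with letters outside A..G are tallied under ``flagged``.
    """
    if not records:
        raise ValueError("no genotype records")
    rows = {}
    for rec in records:
        row = rows.setdefault(
            rec.species, {"species": rec.species, "n": 0, "het": 0, "flagged": 0}
        )
        row["n"] += 1
        if not rec.in_catalogue:
            row["flagged"] += 1
        row[rec.genotype] = row.get(rec.genotype, 0) + 1
        if rec.heterozygous:
            row["het"] += 1
    out = []
    for row in rows.values():
        frac = Fraction(row.pop("het"), row["n"])
        row["heterozygosity"] = frac
        row["heterozygosity_pct"] = round(float(frac) * 100, 2)
        out.append(row)
    df = pd.DataFrame(out).fillna(0)
    geno_cols = sorted(
        c for c in df.columns
        if c not in ("species", "n", "flagged", "heterozygosity", "heterozygosity_pct")
    )
    for c in geno_cols:
        df[c] = df[c].astype(int)
    return df[
        ["species", "n", *geno_cols, "flagged", "heterozygosity", "heterozygosity_pct"]
    ]
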