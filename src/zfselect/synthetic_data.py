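"""Ground-truth generators for every pipeline stage.

Three generators cover the three kinds of input the pipeline consumes:

* ``simulate_population`` — diploid panels of ruminant-like species carrying
  length alleles A–G (6–12 tandem fingers).  Each species owns a pool of
  domain variants derived from a species consensus by codon substitutions
  concentrated at the DNA-contact positions (−1, 2, 3, 6 by default), and
  each allele is a fixed draw of units from that pool, so repeated domains
  within arrays and species-private domains arise as in real panels.
* ``simulate_codon_alignment`` — forward simulation under a GY94 site-class
  mixture (M0/M1a/M2a/M7/M8) on a known tree, with the true class of every
  site recorded.
* ``simulate_pseudogene`` — a functional array disabled by explicit stop
  codons and frameshift lesions, with the full lesion list returned.

The consensus finger sequences shipped here are synthetic exemplars that
satisfy the C2H2 motif; they are not claimed to be real bovine sequences.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain_catalog import GenotypeRecord
from .seq_io import SequenceRecord, translate
from .trees import Tree, parse_newick
from .codon_model import (
    CODONS,
    CODON_AA,
    CODON_INDEX,
    simulate_mixture_alignment,
    f3x4_frequencies,
)
from .zf_decompose import ZFArray, allele_to_n_fingers
from .site_selection import CodonAlignment, class_distribution

__all__ = [
    "SpeciesConfig",
    "ArraySimConfig",
    "AlignmentSimConfig",
    "PopulationSim",
    "DEFAULT_PANEL",
    "UNIT_CONSENSUS_AA",
    "LEAD_CONSENSUS_AA",
    "back_translate",
    "simulate_population",
    "simulate_codon_alignment",
    "simulate_pseudogene",
]

# Synthetic exemplar fingers (valid C2H2 spacing; Cys1 at unit offset 8,
# His1 at 24, 1-based).  Back-translation uses rotating synonymous codons so
# the nucleotide background has all four bases at every codon position.
UNIT_CONSENSUS_AA = "TGEKPYECKECGKAFSQSSNLIRHQRTH"
LEAD_CONSENSUS_AA = "YECNECGKAFAQSSGLIRHRRTH"

UPSTREAM_FLANK = "TGCTCTCTGGCCTTCTCCAGTCAGAA"
SPACER = "GGATCCAAGTCA"  # 12 nt between leading finger and tandem block
DOWNSTREAM_FLANK = "GTCACAGGAGAATTACTGCAGC"

_CODONS_OF = {}
for _c, _a in zip(CODONS, CODON_AA):
    _CODONS_OF.setdefault(_a, []).append(_c)

# unit codon offsets (1-based) of the contact positions, given His1 = 24
_CONTACT_OFFSETS = {9: -9, 13: -5, 16: -2, 17: -1, 19: 2, 20: 3, 23: 6}
_ANCHOR_OFFSETS = {8, 11, 24, 28}  # Cys1, Cys2, His1, His2


def back_translate(aa: str, phase: int = 0) -> str:
    """Deterministic back-translation rotating among synonymous codons."""
    out = []
    for i, a in enumerate(aa):
        codons = _CODONS_OF[a]
        out.append(codons[(i + phase) % len(codons)])
    return "".join(out)


@dataclass(frozen=True)
class SpeciesConfig:
    name: str
    n_animals: int
    allele_freqs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.allele_freqs.values())
        if abs(total - 1) > 1e-9:
            raise ValueError(f"{self.name}: allele frequencies sum to {total}")


# Panel shaped like a five-species ruminant survey: genotype tables of the
# large ruminants use letters A-D, the small ruminants C-G; frequencies are
# the observed allele counts of such a survey.
DEFAULT_PANEL = (
    SpeciesConfig("cattle", 105, {"A": 73 / 210, "B": 94 / 210, "C": 41 / 210,
                                  "D": 2 / 210}),
    SpeciesConfig("yak", 10, {"A": 1.0}),
    SpeciesConfig("mithun", 20, {"A": 16 / 40, "B": 24 / 40}),
    SpeciesConfig("sheep", 45, {"C": 4 / 90, "D": 86 / 90}),
    SpeciesConfig("goat", 45, {"C": 9 / 90, "D": 21 / 90, "E": 13 / 90,
                               "F": 35 / 90, "G": 12 / 90}),
)


@dataclass(frozen=True)
class ArraySimConfig:
    """Conditions for a diploid zinc-finger panel simulation."""

    panel: tuple[SpeciesConfig, ...] = DEFAULT_PANEL
    domain_pool_size: int = 12          # distinct unit variants per species
    contact_bias: float = 5.0           # substitution-rate multiplier
    biased_positions: tuple[int, ...] = (-1, 2, 3, 6)
    mutation_rate: float = 0.02         # per-codon, pool variant vs consensus
    species_divergence: float = 0.05    # per-codon, species consensus vs root
    shared_pool_frac: float = 0.15      # chance a pool slot keeps an ancestral
                                        # domain common to all species
    unit_consensus_aa: str = UNIT_CONSENSUS_AA
    lead_consensus_aa: str = LEAD_CONSENSUS_AA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_bias < 1:
            raise ValueError("contact bias must be >= 1")
        if self.domain_pool_size < 1:
            raise ValueError("domain pool must be non-empty")


@dataclass
class PopulationSim:
    """A simulated panel with its complete ground truth."""

    genotypes: list[GenotypeRecord]
    haplotypes: list[SequenceRecord]    # two records per animal
    allele_seqs: dict[tuple[str, str], str]      # (species, letter) -> amplicon
    allele_units: dict[tuple[str, str], list[str]]  # unit aa per allele
    pool_aa: dict[str, list[str]]       # species -> distinct pool unit aa

    def distinct_domains(self, species: str | None = None) -> set[str]:
        units = set()
        for (sp, _), aas in self.allele_units.items():
            if species is None or sp == species:
                units.update(aas)
        return units


def _mutate_unit(nt: str, rng: np.random.Generator, rate: float, bias: float,
                 biased_offsets: set[int]) -> str:
    """Codon-substitution mutant of an 84-nt unit.

    Anchor codons (the two Cys and two His) are never touched and stops are
    never created, so every mutant remains a valid C2H2 unit.  Mutations are
    whole-codon replacements by a random sense codon; contact-position codons
    mutate at ``bias`` times the base rate.
    """
    codons = [nt[3 * i : 3 * i + 3] for i in range(28)]
    for i in range(28):
        off = i + 1
        if off in _ANCHOR_OFFSETS:
            continue
        p = min(rate * (bias if off in biased_offsets else 1.0), 1.0)
        if rng.random() < p:
            while True:
                new = CODONS[rng.integers(0, 61)]
                if new != codons[i]:
                    codons[i] = new
                    break
    return "".join(codons)


def simulate_population(config: ArraySimConfig = ArraySimConfig()) -> PopulationSim:
    """Draw a diploid panel with known domains, alleles and genotypes."""
    lead_nt = back_translate(config.lead_consensus_aa)
    root_unit_nt = back_translate(config.unit_consensus_aa)
    genotypes: list[GenotypeRecord] = []
    haplotypes: list[SequenceRecord] = []
    allele_seqs: dict[tuple[str, str], str] = {}
    allele_units: dict[tuple[str, str], list[str]] = {}
    pool_aa: dict[str, list[str]] = {}
    biased = set(
        off for off, pos in _CONTACT_OFFSETS.items()
        if pos in config.biased_positions
    )

    # a small ancestral pool shared by every species: domains identical
    # across species arise from it, mimicking the rare cross-species sharing
    # seen on a background of concerted within-species homogenization
    root_rng = np.random.default_rng([config.seed, 10_007])
    ancestral_pool = [
        _mutate_unit(root_unit_nt, root_rng, config.mutation_rate,
                     config.contact_bias, biased)
        for _ in range(4)
    ]

    for sp_idx, sp in enumerate(config.panel):
        rng = np.random.default_rng([config.seed, sp_idx])
        sp_consensus = _mutate_unit(
            root_unit_nt, rng, config.species_divergence, config.contact_bias,
            biased,
        )
        pool = []
        for _ in range(config.domain_pool_size):
            if rng.random() < config.shared_pool_frac:
                pool.append(ancestral_pool[rng.integers(0, len(ancestral_pool))])
            else:
                pool.append(
                    _mutate_unit(sp_consensus, rng, config.mutation_rate,
                                 config.contact_bias, biased)
                )
        pool_aa[sp.name] = sorted({translate(u) for u in pool})
        letters = sorted(sp.allele_freqs)
        freqs = np.array([sp.allele_freqs[l] for l in letters])
        for letter in letters:
            n = allele_to_n_fingers(letter)
            units = [pool[rng.integers(0, len(pool))] for _ in range(n)]
            allele_units[(sp.name, letter)] = [translate(u) for u in units]
            allele_seqs[(sp.name, letter)] = (
                UPSTREAM_FLANK + lead_nt + SPACER + "".join(units)
                + DOWNSTREAM_FLANK
            )
        for i in range(sp.n_animals):
            pair = tuple(
                letters[k] for k in rng.choice(len(letters), size=2, p=freqs)
            )
            animal = f"{sp.name}_{i + 1:03d}"
            genotypes.append(GenotypeRecord(animal, sp.name, pair))
            for h, letter in enumerate(sorted(pair), start=1):
                haplotypes.append(
                    SequenceRecord(
                        id=f"{animal}|h{h}|{letter}",
                        seq=allele_seqs[(sp.name, letter)],
                        description=f"species={sp.name} allele={letter}",
                    )
                )
    return PopulationSim(genotypes, haplotypes, allele_seqs, allele_units, pool_aa)


@dataclass(frozen=True)
class AlignmentSimConfig:
    """Conditions for a codon-alignment simulation with known site classes."""

    tree: str                      # Newick (branch lengths required)
    model: str = "M2a"
    params: dict = field(default_factory=lambda: {"p0": 0.65, "p1": 0.2,
                                                  "omega0": 0.1, "omega2": 5.0})
    n_sites: int = 300
    kappa: float = 2.0
    pi_concentration: float = 5.0  # Dirichlet concentration for codon freqs
    n_categories: int = 10
    seed: int = 0


def simulate_codon_alignment(config: AlignmentSimConfig):
    """Simulate an alignment under a site-class mixture on a known tree.

    Returns ``(alignment, true_classes, class_omegas)``; a site is truly
    under positive selection iff ``class_omegas[true_classes[site]] > 1``.
    """
    rng = np.random.default_rng(config.seed)
    tree = parse_newick(config.tree)
    taxa = sorted(tree.leaf_names())
    weights, omegas = class_distribution(
        config.model, config.params, config.n_categories
    )
    pi = rng.dirichlet(np.full(61, config.pi_concentration))
    codes, classes = simulate_mixture_alignment(
        tree, taxa, pi, config.kappa, weights, omegas, config.n_sites, rng
    )
    site_map = [(i // 28 + 1, i % 28 + 1) for i in range(config.n_sites)]
    aln = CodonAlignment(
        taxa=taxa, codes=codes, site_to_unit_position=site_map,
        helix_positions=[None] * config.n_sites,
    )
    return aln, classes, omegas


def simulate_pseudogene(base: ZFArray | str, stops: list[int],
                        frameshifts: list[tuple[int, int]] = (),
                        frame: int = 0):
    """Disable an array with premature stops and frameshift lesions.

    ``stops`` are 1-based codon indices (in the array's reading frame) that
    are replaced by TAA; ``frameshifts`` are ``(1-based nt position, offset)``
    with offset in {-2, -1, 1, 2} (positive inserts ``A`` bases, negative
    deletes).  Overlapping edits are refused.  Returns ``(sequence, truth)``
    where truth records every lesion applied.
    """
    if isinstance(base, ZFArray):
        seq, frame = base.reconstruct(), base.frame
    else:
        seq = str(base)
    edits = []  # (nt start, nt end, replacement)
    for codon in stops:
        start = frame + 3 * (codon - 1)
        if start + 3 > len(seq):
            raise ValueError(f"stop codon index {codon} beyond sequence end")
        edits.append((start, start + 3, "TAA"))
    for pos, offset in frameshifts:
        if offset not in (-2, -1, 1, 2):
            raise ValueError(f"frameshift offset must be in ±{{1,2}}, got {offset}")
        start = pos - 1
        if offset > 0:
            edits.append((start, start, "A" * offset))
        else:
            if start - offset > len(seq):
                raise ValueError(f"deletion at {pos} beyond sequence end")
            edits.append((start, start - offset, ""))
    edits.sort()
    for (s1, e1, _), (s2, _, _) in zip(edits, edits[1:]):
        if s2 < e1:
            raise ValueError("overlapping edits")
    out = []
    prev = 0
    for s, e, repl in edits:
        out.append(seq[prev:s])
        out.append(repl)
        prev = e
    out.append(seq[prev:])
    truth = {"stops": sorted(stops), "frameshifts": sorted(frameshifts),
             "frame": frame}
    return "".join(out), truth
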