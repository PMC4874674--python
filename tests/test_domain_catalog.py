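"""Domain catalogue, schematics, cross-species statistics, genotypes."""

from fractions import Fraction

import pytest

from zfselect.domain_catalog import (
    GenotypeRecord,
    array_schematic,
    build_catalog,
    cross_species_stats,
    genotype_summary,
)
from zfselect.synthetic_data import ArraySimConfig, SpeciesConfig, simulate_population
from zfselect.zf_decompose import segment_array
from conftest import make_amplicon, UNIT_NT


def _arrays_from_sim(seed=7, mutation=0.05):
    panel = (
        SpeciesConfig("cattle", 1, {"A": 0.5, "B": 0.5}),
        SpeciesConfig("goat", 1, {"C": 0.5, "D": 0.5}),
    )
    sim = simulate_population(
        ArraySimConfig(panel=panel, seed=seed, mutation_rate=mutation)
    )
    return [
        segment_array(seq, f"{sp}|{letter}", sp)
        for (sp, letter), seq in sorted(sim.allele_seqs.items())
    ]


class TestCatalog:
    def test_nine_identical_units(self):
        arr = segment_array(make_amplicon([UNIT_NT] * 9), "r", "cattle")
        cat = build_catalog([arr])
        assert cat.size == 1
        assert cat.occurrence[(1, "cattle")] == 9

    def test_set_union_oracle(self):
        """Catalogue size equals the size of the union of distinct unit
        strings, computed independently."""
        arrays = _arrays_from_sim()
        cat = build_catalog(arrays)
        oracle = {u.aa for a in arrays for u in a.units}
        assert cat.size == len(oracle)
        assert {aa for _, aa in cat.entries} == oracle

    def test_determinism_and_code_order(self):
        arrays = _arrays_from_sim()
        c1 = build_catalog(arrays)
        c2 = build_catalog(list(reversed(arrays)))  # sort_input normalizes
        assert c1.entries == c2.entries
        c3 = build_catalog(list(reversed(arrays)), sort_input=False)
        assert c3.size == c1.size  # size invariant under permutation
        assert [c for c, _ in c1.entries] == list(range(1, c1.size + 1))

    def test_catalog_never_exceeds_unit_count(self):
        arrays = _arrays_from_sim()
        assert build_catalog(arrays).size <= sum(a.n_units for a in arrays)


class TestSchematic:
    def test_repeated_domain_multiset(self):
        arrays = _arrays_from_sim(seed=9)
        cat = build_catalog(arrays)
        for arr in arrays:
            codes, repeated = array_schematic(arr, cat)
            assert len(codes) == arr.n_units
            # independent recount
            assert repeated == {
                c: codes.count(c) for c in set(codes) if codes.count(c) >= 2
            }

    def test_distinct_units_no_repeats(self):
        arrays = _arrays_from_sim(seed=9)
        cat = build_catalog(arrays)
        arr = arrays[0]
        codes, repeated = array_schematic(arr, cat)
        if len(set(codes)) == len(codes):
            assert repeated == {}

    def test_unknown_domain(self):
        arrays = _arrays_from_sim(seed=9)
        cat = build_catalog(arrays[:1])
        foreign = [a for a in arrays if a.species != arrays[0].species][0]
        with pytest.raises(KeyError, match="not in catalogue"):
            array_schematic(foreign, cat)


class TestCrossSpecies:
    def test_shared_and_unique(self):
        """Two species with one domain in common: the share list has exactly
        that domain and the unique counts exclude it."""
        a1 = segment_array(make_amplicon([UNIT_NT] * 6), "c1", "cattle")
        a2 = segment_array(make_amplicon([UNIT_NT] * 7), "g1", "goat")
        cat = build_catalog([a1, a2])
        shared, unique, diversity = cross_species_stats(cat)
        assert shared == [(1, ["cattle", "goat"])]
        assert unique == {"cattle": 0, "goat": 0}
        # a single catalogue entry: every contact position shows 1 residue
        assert set(diversity) == {-9, -5, -2, -1, 2, 3, 6}
        assert all(v == 1 for v in diversity.values())

    def test_positional_diversity_matches_direct_count(self):
        arrays = _arrays_from_sim(seed=11, mutation=0.08)
        cat = build_catalog(arrays)
        _, _, diversity = cross_species_stats(cat)
        from zfselect.zf_decompose import contact_residues_from_helix, find_c2h2_anchors

        for k, n in diversity.items():
            residues = set()
            for _, aa in cat.entries:
                his1 = find_c2h2_anchors(aa)[0][2] + 1
                residues.add(contact_residues_from_helix(aa, his1)[k])
            assert n == len(residues)

    def test_requires_two_species(self):
        a1 = segment_array(make_amplicon([UNIT_NT] * 6), "c1", "cattle")
        with pytest.raises(ValueError):
            cross_species_stats(build_catalog([a1]))


def _panel_records():
    """Genotype panels shaped like a two-table ruminant survey."""
    recs = []

    def add(species, genotype, count):
        for i in range(count):
            recs.append(
                GenotypeRecord(f"{species}_{genotype}_{i}", species,
                               (genotype[0], genotype[1]))
            )

    # large ruminants (A-D); panel sizes 25+40+40+10+20
    add("Bos taurus", "AA", 1); add("Bos taurus", "BB", 10)
    add("Bos taurus", "CC", 1); add("Bos taurus", "AB", 2)
    add("Bos taurus", "BC", 10); add("Bos taurus", "AC", 1)
    add("Bos indicus", "AA", 15); add("Bos indicus", "BB", 2)
    add("Bos indicus", "CC", 3); add("Bos indicus", "AB", 9)
    add("Bos indicus", "BC", 4); add("Bos indicus", "AC", 7)
    add("hybrid", "AA", 4); add("hybrid", "BB", 12); add("hybrid", "CC", 1)
    add("hybrid", "DD", 1); add("hybrid", "AB", 13); add("hybrid", "BC", 8)
    add("hybrid", "AC", 1)
    add("Bos grunniens", "AA", 10)
    add("Bos frontalis", "AA", 3); add("Bos frontalis", "BB", 7)
    add("Bos frontalis", "AB", 10)
    # small ruminants (C-G); panel sizes 45+45
    add("Ovis aries", "DD", 41); add("Ovis aries", "CD", 4)
    goat = {"CC": 1, "DD": 3, "EE": 2, "FF": 8, "GG": 1, "CD": 2, "DE": 4,
            "EF": 3, "FG": 6, "CE": 1, "DF": 7, "EG": 1, "CF": 3, "DG": 2,
            "CG": 1}
    for g, n in goat.items():
        add("Capra hircus", g, n)
    return recs


class TestGenotypeSummary:
    def test_panel_sizes_sum(self):
        df = genotype_summary(_panel_records()).set_index("species")
        assert df.loc["Bos taurus", "n"] == 25
        assert df.loc["Bos indicus", "n"] == 40
        assert df.loc["hybrid", "n"] == 40
        assert df.loc["Bos grunniens", "n"] == 10
        assert df.loc["Bos frontalis", "n"] == 20
        assert df.loc["Ovis aries", "n"] == 45
        assert df.loc["Capra hircus", "n"] == 45

    def test_sheep_heterozygosity_exact_fraction(self):
        """41 DD + 4 CD of 45: heterozygosity is exactly 4/45 (~8.9%), not
        a rounded 8%."""
        df = genotype_summary(_panel_records()).set_index("species")
        assert df.loc["Ovis aries", "heterozygosity"] == Fraction(4, 45)
        assert df.loc["Ovis aries", "CD"] == 4 and df.loc["Ovis aries", "DD"] == 41
        assert df.loc["Ovis aries", "heterozygosity_pct"] == pytest.approx(8.89, abs=0.01)

    def test_single_class_panel(self):
        df = genotype_summary(_panel_records()).set_index("species")
        assert df.loc["Bos grunniens", "AA"] == 10
        assert df.loc["Bos grunniens", "heterozygosity"] == 0

    def test_all_homozygous_zero_het(self):
        recs = [GenotypeRecord(f"a{i}", "sp", ("D", "D")) for i in range(5)]
        df = genotype_summary(recs)
        assert df.iloc[0]["heterozygosity"] == 0

    def test_flagged_letters(self):
        recs = [GenotypeRecord("a", "sp", ("D", "D")),
                GenotypeRecord("b", "sp", ("H", "H"))]
        df = genotype_summary(recs)
        assert df.iloc[0]["flagged"] == 1

    def test_genotype_classes_counted(self):
        df = genotype_summary(_panel_records()).set_index("species")
        row = df.loc["Capra hircus"]
        assert int(row["FF"]) == 8 and int(row["DF"]) == 7 and int(row["FG"]) == 6

    def test_empty_error(self):
        with pytest.raises(ValueError):
            genotype_summary([])
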